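# Methods

This note documents the models, numerical conventions and design choices
behind `swaymetrics`, and what its synthetic-data tests do and do not show.

## Signal model and calibration

A test is a short tri-axial acceleration recording (nominal 50 Hz,
~9.5 s) in the device frame, dominated by gravity. Calibration follows the
standard tilt-correction approach for body-worn accelerometry: the mean
acceleration vector over the trace estimates the vertical, the minimal
rotation taking it onto (0, 0, ‖g‖) is applied to every sample, and the two
rotated horizontal axes are assigned to medio-lateral (M-L) and
antero-posterior (A-P) by a configurable device-orientation convention
(default: device x → M-L, y → A-P, for a phone worn upright in a chest
harness; for a hand-held drift test the orientation is uncontrolled, which
is why only the orientation-free Net measures are used there). Horizontal
series are mean-subtracted, so residual misalignment cannot leak a DC
offset into amplitude features. Net acceleration is the per-sample radial
magnitude √(a_ML² + a_AP²) ≥ 0.

Traces are trimmed to their **last** 9 s before calibration. The ~0.5 s
surplus at the start of a recording most plausibly contains the subject's
reaction to the start cue; dropping the head of the trace removes that
transient. Which end to drop is a genuine free choice — trimming the tail
instead changes individual feature values slightly but none of the
pipeline's structural properties.

Assumptions: sampling is treated as uniform at the nominal rate (traces
whose median interval deviates more than 20 % are flagged and rejected
rather than resampled), and no pre-filtering is applied before feature
extraction — the spectral band edges below handle drift and
high-frequency content explicitly.

## Features

- **RMS** √(mean(a²)) on M-L, A-P and Net series; m/s².
- **Jerk** ∫(dAcc/dt)² dt, discretized with a forward first difference and
  rectangle rule: Σᵢ ((aᵢ₊₁−aᵢ)/Δt)²·Δt with Δt = 1/fs. This is the
  simplest scheme consistent with the integral, it is exactly
  k²·(N−1)·Δt for a ramp of slope k (the closed form the tests assert),
  and it makes results bit-reproducible. Net Jerk averages the two
  horizontal jerk integrals.
- **Spectra** are one-sided periodograms of the mean-subtracted series with
  a rectangular window and no segment averaging: a 9 s × 50 Hz test has
  450 samples, too few for Welch segmentation without destroying the
  0.1–1 Hz resolution where sway power lives. The density scaling makes
  the full-band integral of the PSD equal the series variance (Parseval,
  asserted to 1 %).
- **Spectral moments** μ₁ (centroid) and μ₂ (spread) are computed over a
  band (b₁, b₂) = **0.15–10 Hz** by default: the lower edge excludes
  residual drift/DC, the upper bounds voluntary and tremor-range sway at
  50 Hz sampling. Both edges are configuration parameters surfaced in every
  report; published posturography uses nearby but not identical bands, so
  absolute SC/SS values are convention-dependent. Zero in-band power (a
  flat signal) makes the moments undefined; they are returned as missing,
  never as zero.

## Panel construction

60 sway biomarkers = {RMS, Jerk, SC, SS} × {M-L, A-P, Net} × {EO-FA,
EO-FT, EC-FT} (36) plus the same 12 measures for two stance ratios:
EC-FT:EO-FT (Romberg — effect of removing vision) and EO-FT:EO-FA (effect
of narrowing stance). 16 drift biomarkers = 4 Net measures × {Dom, Ndom,
Sum, Diff} after relabeling hands by declared dominance.

Ordering of transforms: ratios and the Dom+Ndom sum are computed on the
**raw** measurement scale, then everything is log₁₀-transformed — so a
ratio column equals the difference of its constituent stance columns on
the log scale (an identity the tests assert). The Dom−Ndom **difference is
defined on the log scale**, log₁₀(Dom) − log₁₀(Ndom): a raw difference can
be zero or negative and has no log transform, and the log-ratio is the
only order-preserving choice that keeps the column finite. Non-positive
raw values (degenerate flat signals) become missing cells before the log.
Columns are never dropped: input gaps produce missing cells, so the panel
is always exactly 60 + 16 wide.

Outliers are flagged per biomarker with Tukey fences, Q1/Q3 ± 1.5×IQR,
computed with linear (type-7) quantile interpolation — stated explicitly
because fence positions are convention-sensitive — on training-split rows
only. Values are preserved; downstream analyses consult the flag.

## Reliability

ICC(2,1): two-way ANOVA of the n-subject × k-trial matrix into subject
(MSR), trial (MSC) and residual (MSE) mean squares,

    ICC = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)·(MSC − MSE)),

the absolute-agreement single-measurement form with trial number as the
rater; p-values from F = MSR/MSE on (n−1, (n−1)(k−1)) df, testing the null
of no subject effect, BH-FDR-adjusted across biomarkers. Subjects are
complete-case per biomarker (a subject missing either trial drops out for
that biomarker only), and outlier-flagged cells count as missing.
Biomarkers with ICC > 0.5 form the reliable set, following common
interpretive guidelines for moderate reliability. Only the point estimate
and F-test are provided — confidence intervals and the ICC(3,·)/ICC(2,k)
forms are out of scope, as the screen needs only the cutoff decision.

## Associations

The subject-level value of a biomarker is the **mean over non-outlier
trials** (using a single designated trial is the obvious alternative; the
mean is less noisy and uses all screened data). Pearson correlations (sex
encoded 0/1, i.e. point-biserial) are computed per diagnosis stratum with
≥ 10 subjects; clinical and imaging outcomes are restricted to
training-split rows so that validation subjects never inform feature
selection. BH adjustment is applied within one report family per call —
one family for a demographics grid, one for a clinical/imaging grid, one
for a set of pairwise group tests — mirroring how such analyses are
adjusted figure by figure.

The healthy-volunteer age band is the textbook OLS prediction interval for
a new observation: fit(x) ± t₀.₉₇₅,ₙ₋₂ · s · √(1 + 1/n + (x−x̄)²/Sxx). A
subject is called **abnormal one-sidedly**, above the upper bound only:
increased sway is the direction of dysfunction, and the lower tail has no
clinical reading here. With a two-sided 95 % band, the expected abnormal
rate in the reference population is therefore ≈ 2.5 %, and a group shifted
upward by 3 residual sd is expected abnormal at 1 − Φ(t − 3) ≈ 85 % — the
unit tests assert these tail-probability values. Ages more than 10 years
outside the reference range are flagged extrapolated. Both PI-exceedance
calls and raw age residuals are reported, since group summaries can
reasonably be built on either. Group differences use the two-sided
Wilcoxon rank-sum (Mann-Whitney U with tie correction, exact for small
samples via scipy's method selection) — standard screened methodology,
delegated to scipy rather than reimplemented.

## Predictive models

Features are the reliable biomarkers; subjects missing the outcome are
dropped and remaining missing cells are median-imputed from the training
split (the simplest auditable policy). Features are z-scored with
training-fold statistics inside cross-validation — required for
comparable penalties; the outcome stays on its native scale. Grids:
penalty strength logarithmic over 1e−3…1e3 (13 points), elastic-net mixing
∈ {0.1, 0.3, 0.5, 0.7, 0.9}, PCA components 1…min(10, p). PCA variants
refit the components on each training fold (no leakage); the CV sweep over
component counts exploits nesting — one max-rank PCA fit per fold serves
every smaller count by truncation. Component count is selected by CV like
any other hyperparameter; selecting by variance-explained is the common
alternative, but CV selection needs no extra threshold.

Within a family, ridge takes the CV-R²-maximizing penalty; the
l1-penalized families (lasso, elastic-net) take the **heaviest penalty
within one standard error of their best CV score** (the glmnet
`lambda.1se` convention). At the CV minimum, lasso's selected support is
unstable and over-includes noise features; the 1-SE rule is the standard
remedy and is what makes support recovery reproducible in the tests.
Across strategies the winner is the highest mean CV R² (a weak winner with
negative CV R² is still returned, flagged); exact ties break toward fewer
nonzero coefficients, then the fixed order ridge < elastic-net < lasso.

Validation happens once, on the untouched 20 % subject-level split:
Pearson r, R² = 1 − SS_res/SS_tot, and Lin's CCC with population (1/n)
variances. CCC ≤ |r| always (Lin's inequality, asserted on every report).
The baseline is the feature with the highest-magnitude training
correlation, fit by univariate OLS on training. Drift-only models target
the dominant-hand cerebellar examination score by default — the subpanel
those biomarkers actually track — while combined sway+drift models target
the global disability scales.

## Synthetic data: what it emulates and what it does not

The generator produces what the pipeline measures, not balance physiology:

- Horizontal sway = sum of sinusoids with a configurable line spectrum
  (default lines at 0.3/0.7/1.2 Hz, the band where quiet-stance power
  concentrates) plus 30 % band-limited Gaussian noise low-passed at 10 Hz,
  scaled to σ_ML = 0.03, σ_AP = 0.04 m/s² — typical quiet-stance trunk
  values. This gives analytic targets for RMS/SC/SS. It is *not* an
  inverted-pendulum model and has no closed-loop control, so it cannot
  emulate pathology-specific waveforms (tremor peaks, ataxic bursts).
- Stance difficulty multiplies the sway scale (EO-FA 1.0, EO-FT 1.3,
  EC-FT 1.8), giving the qualitative EC-FT > EO-FT > EO-FA ordering.
- Device tilt is a fixed per-subject rotation of the whole vector series
  (default 5°, random azimuth), exercising the calibration stage
  nontrivially; gravity is 9.81 m/s² plus small sway-proportional vertical
  noise.
- Subject-to-subject and trial-to-trial variability act on the log₁₀ sway
  scale with sd 0.15 and 0.05, so any log-amplitude biomarker has designed
  ICC = 0.15²/(0.15²+0.05²) = 0.9 *before* measurement noise; the
  finite-length estimate of a 9 s trace adds trial-level variance, so
  realized ICCs on extracted biomarkers sit below the designed value.
  Ratio and spectral biomarkers are not separately controlled, which is
  why a simulated study yields a mix of reliable and unreliable columns.
  Direct panel simulation (`simulate_biomarker_panel`) designs per-column
  ICC exactly for recovery tests.
- Cohort outcomes are linear in latent sway/drift severities (group
  offsets HV 0 … MS-PP 0.38 on the log scale, age slope 0.006/decade×10)
  with additive noise, then mapped to their scales: EDSS rounded to 0.5
  steps and clipped to [0, 10], CombiWISE clipped to [0, 100], NeurEx
  floored at 0; the balance-relevant examination composite is the square
  root of its three summed panel scores, and the drift composite sums
  per-hand subsystem scores.

All randomness derives from one seed via `SeedSequence` substreams keyed
on (subject, trial, condition), so any trace is reproducible independent
of generation order.

Because outcomes really are (noisy, clipped) linear functions of the
latent severities, passing tests show that the pipeline recovers structure
it is pointed at — designed ICCs, designed loadings, designed independent
contributions of the two tests — with correct error control. They do not
show that real sway biomarkers have these properties; clinical effect
sizes, non-linear severity-outcome relationships and real device artifacts
are outside what this generator can certify.

## Numerical conventions and degenerate inputs

- Quantiles: linear interpolation (type-7) everywhere.
- Rotation to vertical: Rodrigues formula; an exactly vertical mean uses
  the identity, an exactly inverted one a 180° flip about x; mean
  acceleration below 1 m/s² is an error ("cannot determine vertical").
- ICC degenerate cases: zero residual with zero subject variance, or a
  non-positive denominator, return missing; perfect agreement returns
  ICC 1 with p 0.
- Constant biomarkers or outcomes make correlations undefined: the cell is
  dropped, not zero-filled.
- An infinite fence multiplier flags nothing (fences involving ∞·0 for
  constant columns resolve to no flags).
- Problem sizes in tests and the acceptance script (20–60 subjects for
  end-to-end runs; 150–500 subjects and 10–20 seeds for recovery and
  coverage checks) are chosen so each property's sampling error is well
  inside its asserted tolerance while the whole suite stays fast.

## Known limitations

- The calibration convention (mean-gravity rotation + horizontal mean
  subtraction) is one of several in use; protocols that low-pass before
  feature extraction will produce different Jerk/SS values.
- SC/SS depend on the band edges and PSD normalization; comparisons across
  studies require matching conventions.
- The at-home sensitivity pairing (first in-clinic trial vs
  closest-by-date home trial) is supported as an explicit trial pairing in
  the reliability screen; date arithmetic for "closest-by-date" is the
  caller's responsibility.
- No gyroscope/magnetometer fusion, no raw-ADC unit conversion, no
  nonlinear sway measures (sample entropy, DFA, sway-path area).
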