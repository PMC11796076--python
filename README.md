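# swaymetrics

Digital biomarkers of **postural sway** and **pronator drift** from
smartphone accelerometry, with test–retest reliability screening and
regularized predictive models of neurological disability.

Quiet standing is never still: the brain integrates visual, vestibular and
proprioceptive input to keep the body upright, and the residual oscillation
— postural sway — grows with age and with neurological disease such as
multiple sclerosis. A chest-mounted smartphone's tri-axial accelerometer
captures this sway in a one-minute test (three ~9.5 s stances of increasing
difficulty: eyes open feet apart, eyes open feet together, eyes closed feet
together); a companion test records each outstretched hand during a
pronator-drift manoeuvre. `swaymetrics` turns those raw traces into a named
panel of digital biomarkers and carries them through the statistical
analyses a clinical-validation study needs, end to end and fully
reproducibly. It is aimed at researchers building or validating
sensor-based measures of balance and motor function.

## What it computes

**Calibration.** Each trace is trimmed to its last 9 s, the mean
acceleration vector is rotated onto the vertical (undoing device tilt), and
the horizontal components become the medio-lateral (M-L) and
antero-posterior (A-P) sway series plus their radial ("Net") combination.

**Four measurement families** per calibrated series:

- RMS = √((1/N) Σᵢ aᵢ²) — sway amplitude (m/s²)
- Jerk = ∫₀ᵗ (dAcc/dt)² dt — sway jerkiness, with
  Net Jerk = ½ ∫ ((dAcc_ML/dt)² + (dAcc_AP/dt)²) dt
- Spectral centroid SC = μ₁ = Σₖ fₖ sₖ / Σₖ sₖ — PSD-weighted mean sway
  frequency over band edges (b₁, b₂), default 0.15–10 Hz
- Spectral spread SS = μ₂ = √(Σₖ (fₖ−μ₁)² sₖ / Σₖ sₖ) — frequency dispersion

Per-stance values plus two condition ratios (EC-FT:EO-FT, the **Romberg
ratio**, and EO-FT:EO-FA) give **60 postural-sway biomarkers**; Net
measures per hand relabeled by dominance with Sum/Diff combinations give
**16 pronator-drift biomarkers**. All biomarkers are log₁₀-transformed.

**Reliability.** ICC(2,1) — two-way ANOVA, absolute agreement, single
measurement — over a subject's first two trials, with BH-FDR-adjusted
F-test p-values; biomarkers with ICC ≤ 0.5 are screened out, and cells
outside 1.5×IQR Tukey fences (fitted on training rows) are flagged.

**Associations.** Pearson correlations with demographics and clinical /
imaging outcomes (EDSS, CombiWISE, NeurEx™ and subpanels) per diagnosis
group; an OLS age regression on healthy volunteers with its 95 % prediction
interval, one-sided abnormality calls against the upper bound, and pairwise
Wilcoxon rank-sum comparisons of age residuals.

**Models.** Ridge / Lasso / Elastic-Net (each also as a PCA-component
variant) tuned by seeded five-fold CV on an 80/20 subject-level split,
selected by CV R², and validated blind with Pearson r, R² and Lin's
concordance correlation coefficient
CCC = 2·r·sₓ·s_y / (sₓ² + s_y² + (x̄ − ȳ)²), against a best-single-biomarker
baseline.

A synthetic-data module generates gravity-contaminated traces and cohort
tables with known ground truth (designed ICCs, outcome loadings, age
trends), so the whole pipeline is testable without patient data.

## Worked example

```bash
swaymetrics run --out demo_out --seed 5 --subjects 20
```

runs simulate → extract → reliability → correlate → model on a 20-subject
synthetic cohort and prints (abridged):

```
INFO swaymetrics.pipeline: extracted 60 sway / 16 drift biomarkers
INFO swaymetrics.pipeline: sway: 23 reliable biomarkers
INFO swaymetrics.pipeline: drift: 6 reliable biomarkers
INFO swaymetrics.pipeline: sway -> NeurEx Postural Sway: ridge+pca (CV R^2 0.618)
INFO swaymetrics.pipeline: combined -> CombiWISE: elastic-net+pca (CV R^2 0.650)
```

The first line is the structural guarantee — a complete trial set always
yields exactly 60 + 16 named biomarker columns. The reliable counts are the
biomarkers whose test–retest ICC(2,1) exceeded 0.5 in this simulated
cohort, and each model line names the winning regularization strategy for
one disability outcome with its mean cross-validated R². `demo_out/`
contains the panels, reliability tables, correlation grids, age-band
parameters, model reports and a `manifest.json` with a content hash per
artifact (re-running with the same seed reproduces every hash).

The same stages are available as a library — `simulate_cohort`,
`extract_panels`, `ReliabilityFilter`, `AgeReferenceBand`,
`DisabilityScaleRegressor` are sklearn-style estimators that compose with
scikit-learn tooling — and as individual subcommands
(`simulate | extract | reliability | correlate | model | report | run`).

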