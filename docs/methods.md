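# Methods

## Scope and data model

The package analyses plate-level results of allele-enrichment qPCR
assays: each well carries a threshold cycle (Ct), a melt-peak
temperature (Tm), the WT background copy number, and optional truth and
sequencing-confirmation labels.  "No amplification" is encoded as an
*absent* Ct (blank CSV cell); a parsed Ct of 0 is rejected outright.
This distinction is load-bearing: the occupancy statistics treat absent
Ct as an informative empty well, and an ambiguous zero would corrupt
the dropout fraction.

## QC gates

Three gates run in fixed precedence so each flagged well carries exactly
one primary reason: `min_ct` (Ct ≤ 10 — implausibly early signal),
`max_ct` (Ct ≥ 45 — beyond the run length), `tm_out_of_window` (melt
peak outside the target's specific-product window).  Wells without a Ct
pass.  The default run-length cap of 45 cycles is a conventional qPCR
protocol length, configurable per run.  Melt windows are per-assay
configuration; the shipped default (80.5–83.5 °C) matches the
simulator's specific-product distribution and must be recalibrated for
real chemistry — it is a configuration default, not a measured value.

## Occupancy estimators

* **Dropout:** λ̂ = −ln(n_empty/n_wells).  With zero observed empties
  the point estimate is undefined (−ln 0); the estimate is reported as
  the sentinel ">10" and never as a number.  The 95% CI inverts exact
  Clopper–Pearson bounds on the empty fraction through −ln (bounds swap
  because −ln is decreasing).  The fraction is computed from raw counts,
  never from a pre-rounded percentage, to avoid double rounding.
* **Censored MLE (default):** empty wells contribute the zero-class
  probability e^−λ; amplified wells contribute the probability of their
  interpolated copy number rounded to an integer and clamped to ≥ 1 —
  equivalently, the occupancy probability times the zero-truncated
  Poisson mass.  The likelihood is maximized by bounded 1-D search on
  (0, 50] to 1e−8.  Including the occupancy factor makes the estimator
  consistent (its expected score vanishes at the true λ); a variant that
  conditions the positive wells on positivity *twice* — dropping the
  occupancy factor — is biased low by roughly half at λ ≈ 1 and is
  deliberately not offered.
* **Rounded-Poisson mode:** rounds every observation (including
  interpolated values that round to 0) and takes the plain Poisson MLE,
  the sample mean.  The two modes differ exactly when interpolation
  yields sub-0.5 copy values for amplified wells.

The *proficiency check* is a two-sided exact binomial test (summing
outcome probabilities no larger than the observed one) of the
positive-well count against success probability 1 − e^−λ; a level
passes at p ≥ 0.05.  Note that published acceptance of dilution levels
is sometimes more lenient than this exact test: a level with 31/36
positives at a nominal mean of 3.5 copies fails it (p ≈ 0.004), though
it passes against the input implied by its own dropout fraction.  The
nominal means of halved dilution levels are themselves estimates, so
borderline outcomes at those levels should be read with that in mind.

## Curves

OLS of Ct on log10(copies) via `scipy.stats.linregress`; R² is the
squared Pearson correlation (1.0 by construction for two points or
collinear input).  Efficiency is 10^(−1/slope) − 1, reported as a
fraction internally and percent in reports.  Master curves pool all
QC-passing points from all plates into a single OLS — weighting plates
by their passing-point counts — rather than averaging per-plate
coefficients; the per-plate member fits are reported alongside so the
alternative convention can be audited.  Copy values for the halved
levels (E–G) derive from level D by exact halving, not independent
measurement.

## ΔCt interference

Deltas are recomputed from the paired mean-Ct columns, not read from
any pre-printed delta column (which can carry ±0.01 rounding
inconsistencies).  The summary reports the signed mean, the sample
(n−1) standard deviation, and the mean absolute delta — both signed and
absolute means are meaningful and are always labelled.  With the
bundled 25-pair panel the two SD conventions agree to two decimals.

## Performance metrics

* Display convention: any sensitivity/specificity ≥ 0.99 renders
  ">99%", including exactly 100% — a convention that avoids implying
  perfection from finite panels.
* MAF = mut/(mut + wt).  At 1:14,000 this is indistinguishable from
  mut/wt at reporting precision.  The percent display floors at 0.01%
  so a genuinely detected 0.0071% level (one copy in 14,000 WT) reports
  "0.01%" instead of vanishing to "0.00%".
* LoD: the lowest spiked copy level whose detection count is
  Poisson-consistent (proficiency check) — a detection-based rule, not
  a probit LoD95.
* Rate CIs are exact Clopper–Pearson (`statsmodels proportion_confint,
  method="beta"`).
* Precision: intra-assay cells are (group, standard) over raw replicate
  Cts; inter-assay cells first average Ct per plate and measure the SD
  of plate means.  Pass ⇔ SD ≤ 1 Ct; singleton cells are flagged
  insufficient and excluded from pass counts.

## Synthetic data generator

The generator emulates the validation's study conditions:

| parameter | default | why |
|---|---|---|
| standards | A–G = 5120, 640, 80, 10, 5, 2.5, 1.25 copies | 8-fold series A→D, halving D→G |
| replicates | 3/3/3/3/20/20/20 | deeper replication where occupancy is stochastic |
| WT background | 14,000 copies (~50 ng) | the interference condition |
| curve | slope −3.45, intercept 38.6, σ_Ct 0.3 | single-copy wells land at Ct ≈ 38–39; σ chosen to reproduce the observed precision pass rates |
| wt_shift | mean −0.32, SD 0.52 Ct | matches the measured ΔCt panel statistics |
| fp_rate | 0.04 per WT-only well | typical raw (pre-gating) false-signal rate |
| Tm | specific 82.0 ± 0.4 °C, non-specific 76.0 ± 1.5 °C | disjoint by default so the melt gate is testable |

Key modelling choices:

* Ct responds to log10 of the *realized* Poisson copy number, not the
  nominal mean, so sampling noise widens the Ct spread at low copy
  input — and concentrates precision-rule failures at the ~10-copy
  level, as real intra-assay tables show.
* The WT shift is drawn **once per standard level** and shared by its
  replicates: it models a property of the prepared reaction mix, not
  per-well noise.  Per-well draws would shrink the between-condition ΔCt
  SD and inflate within-run SD, both contrary to the measured data.
* False-positive wells get late Cts and non-specific melts; survivors
  of the melt gate sequence as WT with probability 0.9.  No mechanistic
  model of WT facilitation or cross-reactivity is attempted.

What the generator does **not** emulate: pipetting-volume error and
Poisson over-dispersion, inhibitor effects, plate-position effects,
between-operator systematic offsets, raw fluorescence curves, and
sequencing errors beyond the boolean confirmation flag.  Passing
recovery tests on synthetic data therefore demonstrates the statistical
machinery is correct under the assumed model, not that a particular wet
assay meets its specifications.

## Problem sizes and numerics

The recovery checks run at the study's scale: 60-well plates over 200
seeds for λ recovery (median relative error < 15% at λ ∈ {0.5, 1, 2,
4}; the λ = 0.5 case is the binding one at ≈ 13%), 10 plates × 4
standards × triplicate for the master curve (slope within ±0.15,
R² ≥ 0.94), 5,000 wells for dropout/MLE agreement (< 5%), and 3 assays
× 10 plates × 4 standards for the 120-cell precision check (≥ 118
pass).  The MLE search tolerance is 1e−8 on λ; curve degeneracies
(single copy level, zero slope) raise typed errors rather than
returning NaNs.  Random streams derive from a single integer seed per
(target, purpose), so identical config + seed reproduces plates byte
for byte.
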