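# Methods

## The measurement model

Dynamic perineal descent is the caudal displacement of the anorectal
junction (ARJ) between rest and maximum Valsalva, in mm. On EP and MRI the
ARJ is additionally located relative to the pubococcygeal line (PCL), giving
static descent (at rest) and descent at Valsalva; by construction

    dynamic = valsalva − static,

an identity the data model enforces exactly (observer noise is applied to
static and dynamic, and the observer's Valsalva value is their sum, so the
identity survives 0.1 mm rounding). Ultrasound (TPUS, EVUS) cannot image the
PCL and yields dynamic descent only. Sign convention: positive mm lie below
the PCL (caudal).

## Synthetic cohort generator

The generator emulates the cross-sectional study design the analysis is
meant for: n patients (default 131), a latent binary state "abnormal
descent" with prevalence 0.55, and per modality a true dynamic descent drawn
from a class-conditional normal. Class-conditional means and SDs are not
reported by descent studies directly; the defaults are solved from each
modality's published *operating point* (cut-off, sensitivity, specificity)
and marginal SD:

    sd      = marginal_sd / sqrt(1 + p(1−p)(z_sens + z_spec)²)
    mu_dis  = cutoff + z_sens·sd,   mu_heal = cutoff − z_spec·sd

so that a noiseless measurement binarised at the cut-off reproduces the
target sensitivity/specificity exactly (verified by a Monte-Carlo frequency
test at n = 100,000). Defaults use the operating points EP 20 mm
(0.784/0.730), MRI 35 mm (0.743/0.762), TPUS 15 mm (0.653/0.762), EVUS 15 mm
(0.582/0.775) and marginal SDs 10.8/16.4/9.7/11.3 mm.

Each exam is read by two observers with independent additive N(0, σ_obs)
noise; σ_obs defaults come from the reported SDs of between-observer
differences divided by √2 (EP 9.3, MRI 8.4, TPUS 8.8, EVUS 5.3 mm), which
makes the generator reproduce the reported ordering of interobserver ICCs
(good for MRI/EVUS, moderate-to-poor for EP/TPUS) without any further
tuning. An optional per-observer systematic offset (default 0) supports
studies where one observer reads systematically deeper. Whole exams go
missing completely at random with per-modality rates 1/131 (EP), 9/131
(MRI), 4/131 (TPUS), 0 (EVUS).

Static descent is drawn with marginal mean/SD 26.0 (10.3) mm on EP and 16.5
(11.7) mm on MRI, *negatively correlated* with dynamic descent (ρ = −0.29 EP,
−0.35 MRI). The correlations are implied by the published marginal SDs via
2·cov = SD(valsalva)² − SD(static)² − SD(dynamic)²; without them the
generated Valsalva SD contradicts the published marginal. Clinically the
negative sign is the familiar observation that a pelvic floor that is
already low at rest has little room left to move.

What the generator does **not** emulate:

- *Between-modality correlation of severity.* Given the binary state,
  modalities are conditionally independent — the same assumption the LCA
  makes. Real measurements share a continuous severity, so synthetic
  between-modality Bland–Altman SDs are wider (≈15–29 mm) than published
  ones (≈10–16 mm), between-modality ICCs are lower, and OLS transfer slopes
  are attenuated: the transferred cut-offs settle asymptotically at EP 20,
  MRI 35, TPUS 15 (raw 13.8) but EVUS raw ≈12.4 mm, one 5 mm grid step below
  the published 15 mm. Passing tests therefore demonstrate the estimators,
  not that the generator is a calibrated digital twin of the cohort.
- *Informative missingness and longitudinal structure* — exams vanish
  completely at random, once.
- *Covariates/conditions* are illustrative plumbing for the association
  stage (marginals matched to the published cohort; mild dependence on the
  latent state), not part of the measurement model.

## Agreement statistics

ICC is fixed to the single-measure, consistency, two-way variant, ICC(C,1):
(MS_subjects − MS_error)/(MS_subjects + MS_error) for two raters, so a
constant offset between observers does not lower agreement. The 95% CI is
the standard F-based interval; residual sums of squares within 1e-12 of the
total are snapped to zero so constant-offset data return exactly 1.
Subjects missing either observer are dropped per measurement type;
fewer than 3 complete pairs raises an insufficient-data error, zero total
variance a degenerate-input error.

Bland–Altman: δ = mean(A−B), SDd with the n−1 denominator, LOA = δ ±
1.96·SDd. CIs use SE(δ) = SDd/√n and the large-sample SE(LOA) = SDd·√(3/n).
Published LOA CIs in this literature are not always reconstructible from the
printed δ/SDd/n (printed half-widths can disagree with any plausible n), so
the CIs here are defined by the formulas above and are not compared against
printed CI columns. The LOA bounds themselves reproduce printed values to
within the rounding of the printed inputs (±0.05 on δ, ±1.96·0.05 on the SDd
term, ≈0.15 mm total).

## Cut-off calibration

The reference modality has literature thresholds only for *Valsalva*
descent (30/40/50 mm below the PCL). Calibration thresholds Valsalva
descent at such a value (default 40 mm, the middle literature value; the
threshold is a parameter) to form a pseudo-reference label, then scans all
observed dynamic-descent values (plus −∞) as candidate cut-offs, classifying
positive when value > threshold (strict; equality is negative everywhere in
the package), and picks the cut-off maximising Youden's J, breaking ties
toward the smallest threshold (favouring sensitivity). Transfer to other
modalities fits target = a + b·reference by OLS on complete pairs and
evaluates at the reference cut-off; the prediction is reported on the 5 mm
grid clinical cut-offs are quoted on, with the raw value retained.

## Latent class analysis

Two latent classes, J binary tests, conditional independence given the
class. Priors: prevalence ~ Beta(1,1); each test's class-conditional
positivity θ_jc ~ Beta(1,1). Gibbs sampling alternates (i) each patient's
class from its Bernoulli full conditional using that patient's *observed*
entries only (missing entries contribute no likelihood factor — MAR),
(ii) prevalence from its Beta full conditional, (iii) each θ_jc from its
Beta full conditional. Defaults: 100,000 iterations, 5,000 burn-in,
thinning 20 → 4,750 retained draws (thin applied after burn-in removal).

Numerical choices:

- *Label switching* is resolved per draw by relabelling so the "diseased"
  class has the larger mean positivity across tests — deterministic and
  matching the clinical semantics (abnormal descent → more positive tests).
- *Initialisation*: classes seeded by thresholding each patient's
  positive-test count at the cohort median; summaries are invariant to the
  chain seed within Monte-Carlo error (tested).
- *Point estimate* is the posterior mean (median also emitted; skewed
  posteriors at small n make the two differ visibly).
- Per-draw derived metrics: PPV = πse/(πse+(1−π)(1−sp)), NPV =
  (1−π)sp/((1−π)sp+π(1−se)), LR+ = se/(1−sp), LR− = (1−se)/sp, AUC =
  (se+sp)/2. Draws with sp = 1 give LR+ = ∞: excluded from the posterior
  mean (count logged) but retained for percentiles, which then use the
  nearest order statistic instead of linear interpolation.
- *Diagnostics*: effective sample size from the autocovariance with Geyer's
  initial-positive-sequence window, and a Geweke z comparing the first 10%
  against the last 50% of each chain with ESS-adjusted variances; flags at
  ESS < 400 or |z| > 3.

At the study's size (n ≈ 131, 4 tests) posteriors are wide and visibly
skewed — credibility intervals spanning 20–40 percentage points are the
expected behaviour, not a convergence failure; the diagnostics distinguish
the two.

## Associations

Spearman rank correlation (average ranks for ties, two-sided p, pairwise
complete deletion) with markers at 0.05/0.01; constant variables are flagged
undefined rather than raised. Group comparisons use the pooled-variance
independent t-test by default (Welch via `equal_var=False`). No
multiple-testing correction is applied, matching the exploratory reporting
style of the field's tables; treat stars accordingly.

## Pipeline and problem sizes

One global seed feeds a `SeedSequence` that derives independent substreams
per stage, so stages can be re-run in isolation and full reruns are
byte-identical (tested on file digests). Test-suite and acceptance runs use
deliberately reduced MCMC settings (e.g. 8,500 iterations / thinning 8 for
the 20-replicate recovery study; 21,000 / 20 for determinism runs): with a
conjugate sampler whose autocorrelation yields ESS in the thousands at these
settings, longer default chains change the reported summaries only in the
third decimal. The cut-off calibration quantity in the acceptance script is
computed on a 4,000-patient cohort because the Youden threshold at n = 131
carries a ±4 mm sampling SE, and the quantity of interest is the cut-off
implied by the generating conditions rather than one cohort's draw.

## Known limitations

- Two latent classes only; no conditional-dependence (random-effects) LCA,
  so correlated tests would bias accuracy estimates upward — by design, the
  generator satisfies the independence assumption.
- The generator's class-conditional normals are calibrated from marginal
  statistics and are illustrative, not estimates of any real population.
- LOA confidence intervals use large-sample approximations; no
  proportional-bias (regression-based) Bland–Altman extension.
- Likelihood-ratio posterior means are fragile when specificity draws
  approach 1; medians and CrIs are the stable summaries.
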