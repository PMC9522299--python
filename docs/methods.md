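# Methods

## The model

All statistics operate on a complete-case subject-by-session matrix
*Y* ∈ ℝⁿˣᵏ for one phenotype: *n* subjects measured at *k* sessions, where a
"session" is a scanning site in a travelling-heads design or a visit in a
test–retest design. The working model is the two-way layout

  yᵢⱼ = μ + βⱼ + aᵢ + eᵢⱼ,  aᵢ ~ N(0, σ²ₐ),  eᵢⱼ ~ N(0, σ²ₑ),

with the session effect βⱼ fixed and the subject effect random. The
decomposition SS_total = SS_subjects + SS_sessions + SS_error underlies the
session F test (F = MS_sessions / MS_error on (k−1), (n−1)(k−1) df) and the
consistency intraclass correlation

  ICC(3,1) = σ²ₐ / (σ²ₐ + σ²ₑ) = (MS_subjects − MS_error) / (MS_subjects + (k−1)·MS_error).

Fixing the session effect makes the ICC insensitive to additive per-session
offsets: it measures preservation of subject ranking, the component of
reliability that survives a site shift that post-hoc harmonisation could
remove. Absolute agreement, ICC(2,1), is available as an option because the
gap between the two definitions is itself informative about manufacturer
offsets.

### Estimators

Two routes to the variance components are implemented and coincide on
balanced complete data:

* the **ANOVA closed form** above, reported raw — small-sample estimates can
  be negative and are flagged, not truncated, because silent truncation
  biases class means upward at n = 8;
* **REML** for the balanced one-random-factor model, via its closed-form
  profile solution: interior σ̂²ₑ = MS_error, σ̂²ₐ = (MS_subjects −
  MS_error)/k; when the interior subject component would be negative the
  REML maximum sits on the boundary σ̂²ₐ = 0 with pooled σ̂²ₑ =
  (SS_subjects + SS_error)/((n−1)k). The interior solution was verified
  against an external mixed-model fit during development. At the boundary
  the two estimators necessarily differ (REML floors the ICC at 0); the
  equivalence property is therefore stated for interior solutions.

### Diagnostics

* **Sphericity.** With C a (k−1)×k orthonormal contrast basis and S the
  sample covariance of the session columns, V = CSCᵀ and Mauchly's
  W = det V / (tr V/(k−1))^(k−1), referred to χ² with k(k−1)/2 − 1 df via
  the standard first-order correction −(n−1)·d·ln W. The Greenhouse–Geisser
  ε = (tr V)² / ((k−1)·tr V²). k = 2 forces W = 1, ε = 1. W, χ² and ε were
  cross-checked against an independent implementation; p-values differ in
  the third decimal because that implementation adds a second-order term to
  the χ² approximation.
* **GG correction** is gated on Mauchly p < 0.05 (α_sphericity is a
  parameter): both dfs are multiplied by ε and the p-value recomputed; F is
  unchanged. Always-correct and Huynh–Feldt variants are out of scope.
* **Normality** is tested on the doubly-centred residuals
  rᵢⱼ = yᵢⱼ − ȳᵢ· − ȳ·ⱼ + ȳ··, i.e. on the noise term of the model rather
  than on raw per-site values (which would mix in subject heterogeneity).
* **Friedman's test** uses mid-ranks within subject and the tie-corrected
  χ² statistic — invariant to monotone within-subject transforms, the
  robustness cross-check on the ANOVA p-values.

### Multiplicity

Benjamini–Hochberg at q = 0.05 (default) is applied *within each phenotype
class* to the reported (GG-corrected where triggered) ANOVA p-values. The
within-class choice keeps a heavily affected class (e.g. tissue intensity
under a manufacturer change) from masking or inflating discoveries in
another; a constructed test documents where within-class and pooled
adjustment disagree.

## Benchmark resampling

The reference cohort is a large two-visit single-scanner table. For each
phenotype, `subset_size` subjects (default 8, matching the travelling-heads
cohort) are drawn without replacement per resample, `n_resamples` times
(default 1000), independently across draws, and the consistency ICC of each
subset×2 matrix is collected. Draws are integer-indexed permutations from a
`numpy` `SeedSequence`-derived generator, so distributions are reproducible
across platforms. An observed ICC is scored with the add-one doubled-tail
two-sided empirical p-value

  p = min(1, 2·min[(1 + #{icc* ≤ obs})/(B+1), (1 + #{icc* ≥ obs})/(B+1)]),

which never returns 0 from finite draws. Calibration note: this p is exactly
calibrated when the observed ICC is itself a subsample statistic of the same
cohort; pitting a *fresh* finite cohort against a single fixed reference
distribution shares the reference's Monte-Carlo error across all tests and
mildly inflates the dispersion of the p distribution. The calibration test
therefore draws a fresh reference distribution per replicate.

## Power

For the session F test the noncentral-F approximation uses

  λ = f²·n·k·ε/(1−ρ),  df₁ = (k−1)ε,  df₂ = (n−1)(k−1)ε,  f² = η²/(1−η²),

where ρ is the assumed common correlation among repeated measures and ε the
assumed nonsphericity. Defaults ρ = 0.5, ε = 1, α = 0.05 are the
conventional assumptions of this calculator when no pilot estimate exists;
with n = 8, k = 4 they give power 0.8775 at η² = 0.2 and 0.5117 at
η² = 0.1. A bridging test confirms the formula against Monte-Carlo
rejection rates of the package's own ANOVA under a generator with matching
noncentrality.

## Synthetic cohorts

The generator draws yᵢⱼ = μ + bⱼ + sⱼ·(aᵢ + eᵢⱼ): an additive site offset
bⱼ and a multiplicative scale sⱼ that multiplies both the subject effect
and the noise. This is the minimal model in which a scale change perturbs
sphericity (unequal variances of session differences) while preserving the
within-site ranking of subjects — the signature expected of a manufacturer
difference. With all scales equal the theoretical consistency ICC is
σ²ₐ/(σ²ₐ+σ²ₑ) exactly, which anchors parameter-recovery tests. Defaults
emulate the study design the package targets: 8 subjects × 4 sites (three
null "Siemens" sites, one "GE" site whose offset/scale are free
parameters — no quantitative manufacturer-effect model exists to calibrate
them against), and a 2,817-subject × 2-visit reference cohort with no site
terms. Missingness is completely at random per record (scanner failure, not
value-dependent), and effects/noise are normal; what the generator does
*not* emulate — heavy-tailed artefacts, motion, age/sex structure,
inter-visit ageing drift, spatially correlated phenotypes — bounds what
green tests say about real data: they validate the statistical machinery
under its own assumptions, not robustness to violations beyond the
shift/scale family.

## Numerical choices

* Complete-case filtering per analysed session subset, with a hard floor of
  n = 3 surviving subjects (below this the error term has < 4 df); skipped
  phenotypes are reported with reasons, never dropped silently.
* Deterministic lexicographic ordering of subjects and sessions everywhere;
  all randomness fans out from one integer seed via `SeedSequence`.
* Sums of squares at floating-error scale of the total (≤ 1e−12 relative)
  are treated as exactly zero: SS_sessions = 0 reports F = 0, p = 1;
  SS_error = 0 (perfectly additive data) reports F = +∞, p = 0 with a
  degenerate flag and ICC = 1, so scans over thousands of phenotypes never
  abort.
* A singular contrast covariance (n − 1 < k − 1) marks Mauchly
  not-estimable with ε at its lower bound 1/(k−1); no GG gating occurs.
* η² is *partial* (SS_sessions/(SS_sessions+SS_error)) by default — the
  within-subject convention consistent with the power module — with the
  classical variant switchable.

## Problem sizes in the test suite

Simulation-based checks use 500 phenotypes per condition for recovery and
FDR properties, 2000 replicates for type-I calibration of the F test, 500
replicates × 500 resamples for empirical-p calibration, and a 2,817-subject
reference cohort where the test-retest design itself is under test; these
sizes put Monte-Carlo error comfortably inside the asserted tolerances.

## Known limitations

* ICC confidence intervals are not computed; negative ICCs are reported raw.
* The ANOVA ICC estimator is biased slightly low at n = 8 (≈ −0.04 at true
  ICC 0.5–0.8); recovery tolerances account for this.
* The Mauchly χ² approximation is first-order and anti-conservative at
  small n; its calibration is asserted at n = 60.
* No post-hoc pairwise site contrasts, no deconfounding, no harmonisation
  (COMBAT/GAM-style) — the pipeline detects and quantifies site effects, it
  does not remove them.
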