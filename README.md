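# idprel

Multi-site reliability analysis for imaging-derived phenotypes (IDPs).

When the same MRI protocol is deployed across several sites and scanner
manufacturers, every scalar phenotype extracted from the images — a regional
volume, a cortical thickness, a tract FA — can pick up a site-specific shift
in its mean value, a change of scale, or both. A *travelling-heads* design
(the same small group of subjects scanned at every site) lets those site
effects be separated from between-subject variance. `idprel` implements the
statistical battery for such a study:

* **Site-effect testing** per phenotype: one-within-factor repeated-measures
  ANOVA on the site factor, with Shapiro–Wilk normality on the interaction
  residuals, Mauchly's sphericity test, Greenhouse–Geisser df correction
  when sphericity is rejected, and Friedman's rank test as a nonparametric
  cross-check. Benjamini–Hochberg FDR is applied within each phenotype
  class.
* **Reliability** per phenotype: the "consistency" intraclass correlation
  ICC(3,1) from the two-way model *y*ᵢⱼ = μ + βⱼ + aᵢ + eᵢⱼ with site βⱼ
  fixed and subject aᵢ random,

  ICC(3,1) = σ²ₐ / (σ²ₐ + σ²ₑ) = (MS_subjects − MS_error) / (MS_subjects + (k−1)·MS_error),

  by the closed ANOVA form or by REML (identical on balanced data), plus
  pairwise-site ICCs, Pearson/Spearman between-site correlation matrices and
  per-class summaries.
* **Benchmarking** against a large single-scanner test–retest reference
  cohort: repeatedly subsample the reference to the travelling-heads size
  (default 8 subjects, 1000 draws), collect the ICC distribution, and score
  each observed multi-site ICC with an add-one doubled-tail two-sided
  empirical p-value.
* **Design power** for the site F test via the noncentral F distribution
  with λ = f²·n·k·ε/(1−ρ), f² = η²/(1−η²).
* **Synthetic cohorts** with known variance components, per-site additive
  offsets, multiplicative scalings, a manufacturer-level effect and missing
  sessions — ground truth for every statistic above.

## Worked example

Simulate one phenotype with true ICC 0.8 measured by 8 subjects at three
Siemens-like sites and one GE-like site that adds an offset of 0.8 and a
scale factor of 1.5, then run the battery:

```python
import idprel as ip

config = ip.GeneratorConfig(
    n_subjects=8,
    sessions=ip.default_travelling_heads_sessions(ge_offset=0.8, ge_scale=1.5),
    idp_specs=ip.specs_for_icc(1, 0.8, "volumes", prefix="gm_vol_"),
    seed=42,
)
table = ip.generate_travelling_heads(config)
matrix = table.extract_matrix("gm_vol_0001")
print(ip.SiteEffectModel(matrix).fit().summary())
print(ip.IccModel(matrix).fit(method="reml", absolute=True).summary())
```

```
Site-effect battery: gm_vol_0001 (8 subjects x 4 sessions)
----------------------------------------------------------------
RM-ANOVA        F(1.33, 9.34) = 6.023, p = 0.02901 [GG-corrected]
partial eta^2   0.4625
Mauchly         W = 0.0697, X2(5) = 15.24, p = 0.009381, GG eps = 0.4449
Shapiro-Wilk    W = 0.9698, p = 0.4931
Friedman        Q(3) = 7.65, p = 0.05383

Consistency ICC(3,1) [reml]  8 subjects x 4 sessions
--------------------------------------------------------
ICC             0.8055  (good)
sigma2_subject  0.981271
sigma2_error    0.236959
ICC(2,1) abs.   0.7178
```

Reading the output: the GE-like offset produces a significant site effect on
the mean (GG-corrected p = 0.029 — the correction was triggered because the
GE scale change broke sphericity, Mauchly p = 0.009). The consistency ICC
barely notices the offset (0.81, close to the generating 0.80) because
ICC(3,1) removes site means by construction, while the absolute-agreement
ICC(2,1), which penalises them, drops to 0.72. Restricting to the three
null Siemens-like sites raises the consistency ICC to 0.92 for this
realisation, and the analytic power of this 8×4 design to detect a large
site effect (η² = 0.2) is 0.8775.

The same analyses run from the shell:

```bash
idprel simulate --config sim.yaml --out study.tsv
idprel site-effects --table study.tsv --sessions siemens --out scan.tsv
idprel icc --table study.tsv --method reml --pairwise --out icc.tsv
idprel benchmark --reference ref.tsv --observed study.tsv --out bench.tsv
idprel power --n 8 --k 4 --eta2 0.2
idprel run --config run.yaml     # full pipeline, all subsets, TSV + manifest
```

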