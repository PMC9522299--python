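"""Benchmarking multi-site ICCs against a large test-retest reference cohort.

A travelling-heads ICC from n = 8 subjects is a noisy quantity. To judge
whether it is unusually low (or high) relative to single-scanner test-retest
reliability, the same-size experiment is emulated inside the reference
cohort: repeatedly draw ``subset_size`` subjects at random from the
reference table (without replacement within a draw, independently across
draws), compute the consistency ICC of each subset's n x 2 matrix, and use
the resulting distribution as an empirical null. An observed ICC is then
scored with an add-one doubled-tail two-sided empirical p-value.

All resampling is integer-indexed and driven by a single integer seed, so a
distribution is reproducible across runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._core import icc_consistency as _icc_batch
from .errors import ConfigurationError, InsufficientDataError
from .tables import IDPTable

__all__ = [
    "ReferenceDistribution",
    "resample_reference_iccs",
    "empirical_two_sided_p",
    "icc_concordance",
    "ConcordanceResult",
    "reference_violin_summary",
]

#: Quantiles reported for violin-style summaries of a reference distribution.
VIOLIN_QUANTILES = (0.025, 0.25, 0.50, 0.75, 0.975)


@dataclass(frozen=True)
class ReferenceDistribution:
    """Resampled reference ICCs for one phenotype."""

    idp_name: str
    icc_samples: np.ndarray
    subset_size: int
    n_resamples: int
    seed: int

    @property
    def n_valid(self) -> int:
        return int(np.isfinite(self.icc_samples).sum())


def resample_reference_iccs(
    reference: IDPTable,
    idp_name: str,
    subset_size: int = 8,
    n_resamples: int = 1000,
    seed: int = 0,
) -> ReferenceDistribution:
    """Subsample the reference cohort and collect consistency ICCs.

    The reference table must have exactly two sessions (a test-retest
    design). Each draw takes ``subset_size`` complete-case subjects without
    replacement; subjects may recur across draws (at N ~ 2,800 the overlap
    is negligible).
    """
    sessions = reference.session_labels
    if len(sessions) != 2:
        raise ConfigurationError(
            f"reference cohort must have exactly 2 sessions, got {len(sessions)}"
        )
    matrix = reference.extract_matrix(idp_name, sessions=sessions)
    n = matrix.n_subjects
    if subset_size > n:
        raise InsufficientDataError(
            f"subset_size {subset_size} exceeds {n} complete subjects", n_complete=n
        )
    rng = np.random.default_rng(seed)
    # vectorised sampling without replacement: first subset_size entries of a
    # random permutation per draw
    order = np.argsort(rng.random((n_resamples, n)), axis=1)[:, :subset_size]
    subsets = matrix.values[order]  # (B, m, 2)
    iccs = _icc_batch(subsets)
    return ReferenceDistribution(
        idp_name=idp_name,
        icc_samples=np.asarray(iccs, dtype=float),
        subset_size=subset_size,
        n_resamples=n_resamples,
        seed=seed,
    )


def empirical_two_sided_p(icc_observed: float, ref: ReferenceDistribution) -> float:
    """Two-sided empirical p-value of an observed ICC against the reference.

    Add-one doubled-tail convention::

        p = min(1, 2 * min((1 + #{icc* <= obs}) / (B + 1),
                           (1 + #{icc* >= obs}) / (B + 1)))

    which never returns 0 from a finite number of draws.
    """
    samples = ref.icc_samples[np.isfinite(ref.icc_samples)]
    if samples.size == 0:
        raise ConfigurationError("reference distribution has no valid samples")
    b = samples.size
    lo = (1 + np.sum(samples <= icc_observed)) / (b + 1)
    hi = (1 + np.sum(samples >= icc_observed)) / (b + 1)
    return float(min(1.0, 2.0 * min(lo, hi)))


@dataclass(frozen=True)
class ConcordanceResult:
    """Correlation of per-phenotype ICCs across two cohorts."""

    pearson_r: float
    spearman_r: float
    n_idps: int
    degenerate: bool = False


def icc_concordance(icc_a, icc_b) -> ConcordanceResult:
    """Pearson and Spearman correlation of two per-phenotype ICC vectors.

    ``icc_a`` / ``icc_b`` are aligned vectors (or dicts keyed by phenotype,
    intersected automatically). Pairs with a non-finite entry are dropped;
    fewer than 3 surviving pairs is an error. A constant vector yields a
    degenerate (NaN) result, flagged rather than raised.
    """
    if isinstance(icc_a, dict) and isinstance(icc_b, dict):
        shared = sorted(set(icc_a) & set(icc_b))
        a = np.array([icc_a[i] for i in shared], dtype=float)
        b = np.array([icc_b[i] for i in shared], dtype=float)
    else:
        a = np.asarray(icc_a, dtype=float)
        b = np.asarray(icc_b, dtype=float)
        if a.shape != b.shape:
            raise ValueError("ICC vectors must align")
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if a.size < 3:
        raise InsufficientDataError(
            f"need >= 3 shared phenotypes, got {a.size}", n_complete=int(a.size)
        )
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return ConcordanceResult(np.nan, np.nan, int(a.size), degenerate=True)
    return ConcordanceResult(
        pearson_r=float(stats.pearsonr(a, b).statistic),
        spearman_r=float(stats.spearmanr(a, b).statistic),
        n_idps=int(a.size),
    )


def reference_violin_summary(ref: ReferenceDistribution) -> dict:
    """Plotting-ready quantiles (2.5, 25, 50, 75, 97.5%) of the samples."""
    samples = ref.icc_samples[np.isfinite(ref.icc_samples)]
    if samples.size == 0:
        raise ConfigurationError("reference distribution has no valid samples")
    qs = np.quantile(samples, VIOLIN_QUANTILES)
    return {f"q{100 * q:g}": float(v) for q, v in zip(VIOLIN_QUANTILES, qs)}
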