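"""Per-phenotype site-effect inference.

For each phenotype's complete-case subject-by-session matrix the battery is:

* repeated-measures ANOVA on the session factor (two-way within-subject
  decomposition; F = MS_sessions / MS_error) with partial eta squared;
* Mauchly's test of sphericity on the contrast covariance, with the
  Greenhouse-Geisser epsilon, and a GG degrees-of-freedom correction applied
  to the ANOVA p-value when sphericity is rejected;
* Shapiro-Wilk normality on the doubly-centred residuals
  ``r_ij = y_ij - mean_i - mean_j + grand mean``;
* Friedman's rank test as a nonparametric cross-check.

A scan over all phenotypes applies Benjamini-Hochberg FDR to the reported
(GG-corrected where applicable) p-values *within each phenotype class*, so a
class with many affected members does not mask discoveries in another.

The statsmodels-style entry point is :class:`SiteEffectModel`; module-level
functions expose the individual statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import linalg, stats
from statsmodels.stats.multitest import multipletests

from ._core import ss_decomposition
from .errors import InsufficientDataError
from .tables import IDPTable, SubjectBySessionMatrix

__all__ = [
    "AnovaResult",
    "SphericityResult",
    "NormalityResult",
    "FriedmanResult",
    "SiteEffectModel",
    "SiteEffectResults",
    "rm_anova",
    "mauchly_test",
    "apply_gg",
    "friedman_test",
    "shapiro_residuals",
    "fdr_adjust",
    "site_effect_scan",
]


@dataclass(frozen=True)
class AnovaResult:
    """Session-effect F test from the two-way within-subject decomposition."""

    F: float
    df_effect: float
    df_error: float
    p_uncorrected: float
    p_reported: float
    eta_squared: float
    gg_applied: bool = False
    degenerate: bool = False
    ss_subjects: float = np.nan
    ss_sessions: float = np.nan
    ss_error: float = np.nan


@dataclass(frozen=True)
class SphericityResult:
    """Mauchly's W with its chi-square approximation and the GG epsilon."""

    W: float
    chi_square: float
    df: int
    p: float
    epsilon_gg: float
    estimable: bool = True


@dataclass(frozen=True)
class NormalityResult:
    """Shapiro-Wilk on the interaction residuals of the two-way layout."""

    statistic: float
    p: float
    estimable: bool = True


@dataclass(frozen=True)
class FriedmanResult:
    """Friedman rank statistic (mid-rank ties, tie-corrected chi-square)."""

    Q: float
    df: int
    p: float


def rm_anova(matrix: SubjectBySessionMatrix, eta: str = "partial") -> AnovaResult:
    """One-within-factor repeated-measures ANOVA on the session columns.

    ``eta`` selects the effect size: ``"partial"`` (default)
    ``SS_sessions / (SS_sessions + SS_error)`` or ``"classical"``
    ``SS_sessions / SS_total``. Perfectly additive data (``SS_error == 0``)
    yield ``F = +inf, p = 0`` with the degenerate flag set rather than an
    exception, so scans over thousands of phenotypes never abort.
    """
    y = matrix.values
    n, k = y.shape
    ss_subj, ss_sess, ss_err = (float(s) for s in ss_decomposition(y))
    # zero within floating error of the total variation is zero
    tiny = 1e-12 * (ss_subj + ss_sess + ss_err)
    ss_sess = 0.0 if ss_sess <= tiny else ss_sess
    ss_err = 0.0 if ss_err <= tiny else ss_err
    df1, df2 = float(k - 1), float((n - 1) * (k - 1))
    if eta == "partial":
        denom = ss_sess + ss_err
        eta_sq = ss_sess / denom if denom > 0 else 0.0
    elif eta == "classical":
        total = ss_subj + ss_sess + ss_err
        eta_sq = ss_sess / total if total > 0 else 0.0
    else:
        raise ValueError(f"eta must be 'partial' or 'classical', got {eta!r}")
    if ss_sess == 0.0:
        # no session effect at all; degenerate only if the error term also
        # vanished (row-constant matrix)
        return AnovaResult(
            F=0.0, df_effect=df1, df_error=df2, p_uncorrected=1.0, p_reported=1.0,
            eta_squared=eta_sq, degenerate=ss_err == 0.0,
            ss_subjects=ss_subj, ss_sessions=ss_sess, ss_error=ss_err,
        )
    if ss_err == 0.0:
        return AnovaResult(
            F=np.inf, df_effect=df1, df_error=df2, p_uncorrected=0.0, p_reported=0.0,
            eta_squared=eta_sq, degenerate=True,
            ss_subjects=ss_subj, ss_sessions=ss_sess, ss_error=ss_err,
        )
    f = (ss_sess / df1) / (ss_err / df2)
    p = float(stats.f.sf(f, df1, df2))
    return AnovaResult(
        F=f, df_effect=df1, df_error=df2, p_uncorrected=p, p_reported=p,
        eta_squared=eta_sq,
        ss_subjects=ss_subj, ss_sessions=ss_sess, ss_error=ss_err,
    )


def mauchly_test(matrix: SubjectBySessionMatrix) -> SphericityResult:
    """Mauchly's sphericity test and the Greenhouse-Geisser epsilon.

    With ``C`` a (k-1) x k orthonormal contrast basis and ``S`` the sample
    covariance of the session columns, ``V = C S C'`` and::

        W   = det(V) / (tr(V) / (k-1))^(k-1)
        X2  = -(n-1) * d * ln W,   d = 1 - (2(k-1)^2 + (k-1) + 2) / (6(k-1)(n-1))
        eps = tr(V)^2 / ((k-1) * tr(V^2))

    against chi-square with ``k(k-1)/2 - 1`` df. ``k = 2`` forces
    ``W = 1, eps = 1, p = 1`` (a single contrast variance is trivially
    spherical). A singular contrast covariance (``n - 1 < k - 1``) is flagged
    not-estimable with epsilon at its lower bound ``1/(k-1)``.
    """
    y = matrix.values
    n, k = y.shape
    df = k * (k - 1) // 2 - 1
    if k == 2:
        return SphericityResult(W=1.0, chi_square=0.0, df=df, p=1.0, epsilon_gg=1.0)
    c = linalg.helmert(k, full=False)  # orthonormal rows
    v = c @ np.cov(y, rowvar=False) @ c.T
    eigvals = linalg.eigvalsh(v)
    if n - 1 < k - 1 or eigvals[0] <= 0:
        return SphericityResult(
            W=np.nan, chi_square=np.nan, df=df, p=np.nan,
            epsilon_gg=1.0 / (k - 1), estimable=False,
        )
    tr = eigvals.sum()
    w = float(np.prod(eigvals) / (tr / (k - 1)) ** (k - 1))
    d = 1.0 - (2 * (k - 1) ** 2 + (k - 1) + 2) / (6.0 * (k - 1) * (n - 1))
    chi2 = float(-(n - 1) * d * np.log(w))
    p = float(stats.chi2.sf(chi2, df))
    eps = float(tr**2 / ((k - 1) * (eigvals**2).sum()))
    return SphericityResult(W=w, chi_square=chi2, df=df, p=p, epsilon_gg=eps)


def apply_gg(
    anova: AnovaResult,
    sphericity: SphericityResult,
    alpha_sphericity: float = 0.05,
) -> AnovaResult:
    """Greenhouse-Geisser correction, gated on the Mauchly test.

    If ``sphericity.p < alpha_sphericity`` both degrees of freedom are
    multiplied by epsilon and the p-value is recomputed; F is unchanged.
    Otherwise the input is returned with ``gg_applied = False``.
    """
    if not sphericity.estimable or not sphericity.p < alpha_sphericity:
        return replace(anova, gg_applied=False)
    eps = sphericity.epsilon_gg
    df1, df2 = anova.df_effect * eps, anova.df_error * eps
    if anova.degenerate:
        return replace(anova, df_effect=df1, df_error=df2, gg_applied=True)
    p = float(stats.f.sf(anova.F, df1, df2))
    return replace(
        anova, df_effect=df1, df_error=df2, p_reported=p, gg_applied=True
    )


def friedman_test(matrix: SubjectBySessionMatrix) -> FriedmanResult:
    """Friedman's rank test of the session effect.

    Mid-ranks within each subject; the tie-corrected chi-square statistic
    is referred to ``k - 1`` df. Invariant to any within-subject monotone
    transformation of the values. Every subject fully tied yields
    ``Q = 0, p = 1``.
    """
    y = matrix.values
    n, k = y.shape
    ranks = stats.rankdata(y, axis=1)
    rank_sums = ranks.sum(axis=0)
    q = 12.0 / (n * k * (k + 1)) * (rank_sums**2).sum() - 3.0 * n * (k + 1)
    ties = 0.0
    for row in y:
        _, counts = np.unique(row, return_counts=True)
        ties += (counts**3 - counts).sum()
    correction = 1.0 - ties / (n * k * (k**2 - 1))
    if correction <= 0:  # every subject fully tied
        return FriedmanResult(Q=0.0, df=k - 1, p=1.0)
    q /= correction
    q = max(q, 0.0)
    return FriedmanResult(Q=float(q), df=k - 1, p=float(stats.chi2.sf(q, k - 1)))


def shapiro_residuals(matrix: SubjectBySessionMatrix) -> NormalityResult:
    """Shapiro-Wilk on doubly-centred residuals.

    Residuals remove subject and session means, so the test targets the
    noise term of the two-way model rather than subject heterogeneity or
    site offsets. Zero-variance residuals (perfectly additive data) are
    flagged not-estimable.
    """
    y = matrix.values
    grand = y.mean()
    resid = (y - y.mean(axis=1, keepdims=True) - y.mean(axis=0, keepdims=True) + grand).ravel()
    scale = max(np.ptp(y), 1e-300)
    if resid.size < 3 or np.ptp(resid) <= 1e-10 * scale or not np.all(np.isfinite(resid)):
        return NormalityResult(statistic=np.nan, p=np.nan, estimable=False)
    stat, p = stats.shapiro(resid)
    return NormalityResult(statistic=float(stat), p=float(p))


def fdr_adjust(p_values, classes=None, q: float = 0.05):
    """Benjamini-Hochberg step-up within each phenotype class.

    Parameters
    ----------
    p_values : array-like
        Raw p-values; NaNs (skipped phenotypes) are passed through
        unadjusted and never rejected.
    classes : array-like of str, optional
        Class label per p-value; adjustment is applied independently within
        each class. Omitted -> one pooled family.
    q : float
        FDR level.

    Returns
    -------
    (reject, p_adjusted) : ndarray of bool, ndarray of float
    """
    p = np.asarray(p_values, dtype=float)
    if classes is None:
        classes = np.zeros(p.shape, dtype=int)
    classes = np.asarray(classes)
    reject = np.zeros(p.shape, dtype=bool)
    p_adj = np.full(p.shape, np.nan)
    for label in np.unique(classes):
        sel = (classes == label) & np.isfinite(p)
        if not sel.any():
            continue
        rej, adj, _, _ = multipletests(p[sel], alpha=q, method="fdr_bh")
        reject[sel] = rej
        p_adj[sel] = adj
    return reject, p_adj


@dataclass(frozen=True)
class SiteEffectResults:
    """Fitted site-effect battery for one phenotype matrix."""

    matrix: SubjectBySessionMatrix
    anova: AnovaResult
    sphericity: SphericityResult
    normality: NormalityResult
    friedman: FriedmanResult

    def summary(self) -> str:
        m, a, s, nr, fr = self.matrix, self.anova, self.sphericity, self.normality, self.friedman
        lines = [
            f"Site-effect battery: {m.idp_name or '<matrix>'} "
            f"({m.n_subjects} subjects x {m.k_sessions} sessions)",
            "-" * 64,
            f"RM-ANOVA        F({a.df_effect:.3g}, {a.df_error:.3g}) = {a.F:.4g}, "
            f"p = {a.p_reported:.4g}"
            + (" [GG-corrected]" if a.gg_applied else "")
            + (" [degenerate]" if a.degenerate else ""),
            f"partial eta^2   {a.eta_squared:.4f}",
            f"Mauchly         W = {s.W:.4f}, X2({s.df}) = {s.chi_square:.4g}, "
            f"p = {s.p:.4g}, GG eps = {s.epsilon_gg:.4f}"
            if s.estimable
            else f"Mauchly         not estimable (GG eps floor {s.epsilon_gg:.4f})",
            f"Shapiro-Wilk    W = {nr.statistic:.4f}, p = {nr.p:.4g}"
            if nr.estimable
            else "Shapiro-Wilk    not estimable",
            f"Friedman        Q({fr.df}) = {fr.Q:.4g}, p = {fr.p:.4g}",
        ]
        return "\n".join(lines)


class SiteEffectModel:
    """Site-effect test battery for one phenotype.

    Parameters
    ----------
    matrix : SubjectBySessionMatrix
        Complete-case n x k matrix (n >= 3, k >= 2).

    ``fit`` runs the ANOVA, Mauchly/GG, Shapiro-Wilk and Friedman tests and
    returns a :class:`SiteEffectResults`.
    """

    def __init__(self, matrix: SubjectBySessionMatrix):
        if matrix.n_subjects < 3 or matrix.k_sessions < 2:
            raise InsufficientDataError(
                f"need n >= 3 and k >= 2, got {matrix.n_subjects} x {matrix.k_sessions}",
                n_complete=matrix.n_subjects,
            )
        self.matrix = matrix

    def fit(self, gg_alpha: float = 0.05, eta: str = "partial") -> SiteEffectResults:
        anova = rm_anova(self.matrix, eta=eta)
        sphericity = mauchly_test(self.matrix)
        anova = apply_gg(anova, sphericity, alpha_sphericity=gg_alpha)
        return SiteEffectResults(
            matrix=self.matrix,
            anova=anova,
            sphericity=sphericity,
            normality=shapiro_residuals(self.matrix),
            friedman=friedman_test(self.matrix),
        )


def site_effect_scan(
    table: IDPTable,
    sessions=None,
    q: float = 0.05,
    gg_alpha: float = 0.05,
    eta: str = "partial",
) -> pd.DataFrame:
    """Run the full battery for every phenotype in a table.

    Phenotypes failing the minimum-subject rule appear as skipped rows (with
    the reason) rather than vanishing. FDR flags (`significant`) come from
    Benjamini-Hochberg at level ``q`` within each phenotype class applied to
    the reported (GG-corrected where triggered) ANOVA p-values.
    """
    rows = []
    for idp in table.idp_names:
        base = {"idp_name": idp, "class_label": table.class_of(idp)}
        try:
            matrix = table.extract_matrix(idp, sessions=sessions)
        except InsufficientDataError as exc:
            rows.append({**base, "skipped": True, "skip_reason": str(exc)})
            continue
        res = SiteEffectModel(matrix).fit(gg_alpha=gg_alpha, eta=eta)
        a, s, nr, fr = res.anova, res.sphericity, res.normality, res.friedman
        rows.append(
            {
                **base,
                "skipped": False,
                "skip_reason": "",
                "n_subjects": matrix.n_subjects,
                "k_sessions": matrix.k_sessions,
                "F": a.F,
                "df_effect": a.df_effect,
                "df_error": a.df_error,
                "p_uncorrected": a.p_uncorrected,
                "p_reported": a.p_reported,
                "eta_squared": a.eta_squared,
                "gg_applied": a.gg_applied,
                "anova_degenerate": a.degenerate,
                "mauchly_W": s.W,
                "mauchly_p": s.p,
                "epsilon_gg": s.epsilon_gg,
                "sphericity_violated": bool(s.estimable and s.p < gg_alpha),
                "shapiro_W": nr.statistic,
                "shapiro_p": nr.p,
                "friedman_Q": fr.Q,
                "friedman_p": fr.p,
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    for col in ("p_reported", "skipped"):
        if col not in out:
            out[col] = np.nan
    p = out["p_reported"].to_numpy(dtype=float)
    reject, p_adj = fdr_adjust(p, out["class_label"].to_numpy(), q=q)
    out["p_fdr"] = p_adj
    out["significant"] = reject
    return out
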