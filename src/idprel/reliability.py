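"""Variance components and consistency ICC(3,1) per phenotype.

The headline reliability statistic is the "consistency" intraclass
correlation ICC(3,1): the two-way model ``y_ij = mu + beta_j + a_i + e_ij``
with the session (site) effect ``beta_j`` fixed and the subject effect
``a_i`` random. It quantifies preservation of subject ranking across
sessions and is, by construction, insensitive to additive per-session
offsets — the component of a site effect that is easy to model away.

Two estimators are provided and agree on balanced complete data:

* ``anova`` — the closed form from the two-way mean squares,
  ``ICC = (MS_subjects - MS_error) / (MS_subjects + (k-1) MS_error)``.
  Small-sample estimates can be negative; they are reported raw with a flag
  (silent truncation at 0 would bias class means upward at n = 8).
* ``reml`` — the restricted-maximum-likelihood fit of the same model. For
  the balanced one-random-factor layout REML has a closed-form profile
  solution: interior ``sigma2_e = MS_error``,
  ``sigma2_s = (MS_subjects - MS_error)/k``; when that subject component is
  negative the REML maximum sits on the boundary ``sigma2_s = 0`` with the
  pooled ``sigma2_e = (SS_subjects + SS_error) / ((n-1) k)``. REML variances
  are therefore never negative and the REML ICC is floored at 0.

ICC(2,1) "absolute agreement" — which *does* penalise session offsets — is
available as an optional extra because manufacturer offsets make the two
definitions diverge informatively.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._core import icc_consistency_from_ms, mean_squares, ss_decomposition
from .errors import InsufficientDataError
from .tables import IDPTable, SubjectBySessionMatrix

__all__ = [
    "VarianceComponents",
    "IccResults",
    "IccModel",
    "CorrelationMatrix",
    "icc_consistency",
    "pairwise_icc",
    "site_correlation_matrix",
    "class_icc_summary",
    "interpret_icc",
]

#: Conventional qualitative bands for reporting: 0.5-0.8 fair-to-good,
#: > 0.8 good, > 0.9 very good reliability.
ICC_BANDS = ((0.9, "very good"), (0.8, "good"), (0.5, "fair to good"))


def interpret_icc(icc: float) -> str:
    """Qualitative reliability band for an ICC value."""
    if not np.isfinite(icc):
        return "not estimable"
    for lo, label in ICC_BANDS:
        if icc >= lo:
            return label
    return "poor"


@dataclass(frozen=True)
class VarianceComponents:
    """Between-subject and residual variance with fixed session means.

    ``sigma2_subject`` from the ANOVA method is the raw moment estimator and
    may be negative; REML estimates are constrained >= 0.
    """

    sigma2_subject: float
    sigma2_error: float
    session_means: tuple
    method: str


@dataclass(frozen=True)
class IccResults:
    """Fitted consistency ICC with provenance.

    ``icc`` may exceed no upper bound of 1 and can be negative for the
    ANOVA method (small-sample noise); negativity is flagged, never silently
    truncated. ``degenerate`` marks ``MS_error == 0`` (ICC exactly 1).
    """

    icc: float
    n_subjects: int
    k_sessions: int
    method: str
    components: VarianceComponents
    degenerate: bool = False
    icc_absolute: float = np.nan

    @property
    def negative(self) -> bool:
        return bool(np.isfinite(self.icc) and self.icc < 0)

    def summary(self) -> str:
        c = self.components
        lines = [
            f"Consistency ICC(3,1) [{self.method}]  "
            f"{self.n_subjects} subjects x {self.k_sessions} sessions",
            "-" * 56,
            f"ICC             {self.icc:.4f}  ({interpret_icc(self.icc)})"
            + ("  [negative estimate]" if self.negative else "")
            + ("  [degenerate: MS_error = 0]" if self.degenerate else ""),
            f"sigma2_subject  {c.sigma2_subject:.6g}",
            f"sigma2_error    {c.sigma2_error:.6g}",
        ]
        if np.isfinite(self.icc_absolute):
            lines.append(f"ICC(2,1) abs.   {self.icc_absolute:.4f}")
        return "\n".join(lines)


class IccModel:
    """Consistency-ICC model for one phenotype matrix.

    ``fit(method="anova" | "reml", absolute=False)`` returns
    :class:`IccResults`. Both methods coincide whenever the interior REML
    solution applies (subject variance estimate positive).
    """

    def __init__(self, matrix: SubjectBySessionMatrix):
        if matrix.n_subjects < 3 or matrix.k_sessions < 2:
            raise InsufficientDataError(
                f"need n >= 3 and k >= 2, got {matrix.n_subjects} x {matrix.k_sessions}",
                n_complete=matrix.n_subjects,
            )
        self.matrix = matrix

    def fit(self, method: str = "anova", absolute: bool = False) -> IccResults:
        y = self.matrix.values
        n, k = y.shape
        ms_subj, ms_sess, ms_err = (float(m) for m in mean_squares(y))
        session_means = tuple(y.mean(axis=0))
        # MS_error at floating-error scale of the other terms counts as zero
        degenerate = ms_err <= 1e-12 * (ms_subj + ms_sess + ms_err)
        if degenerate:
            ms_err = 0.0

        if method == "anova":
            sigma2_e = ms_err
            sigma2_s = (ms_subj - ms_err) / k
            icc = float(icc_consistency_from_ms(ms_subj, ms_err, k))
        elif method == "reml":
            sigma2_s = (ms_subj - ms_err) / k
            if sigma2_s >= 0:
                sigma2_e = ms_err
            else:  # boundary solution
                ss_subj, _, ss_err = ss_decomposition(y)
                sigma2_s = 0.0
                sigma2_e = float((ss_subj + ss_err) / ((n - 1) * k))
            denom = sigma2_s + sigma2_e
            icc = 1.0 if degenerate else (sigma2_s / denom if denom > 0 else np.nan)
        else:
            raise ValueError(f"method must be 'anova' or 'reml', got {method!r}")

        icc_abs = np.nan
        if absolute:
            denom = ms_subj + (k - 1) * ms_err + k * (ms_sess - ms_err) / n
            icc_abs = (ms_subj - ms_err) / denom if denom != 0 else np.nan
            if degenerate and ms_sess == 0:
                icc_abs = 1.0

        return IccResults(
            icc=icc,
            n_subjects=n,
            k_sessions=k,
            method=method,
            components=VarianceComponents(
                sigma2_subject=float(sigma2_s),
                sigma2_error=float(sigma2_e),
                session_means=session_means,
                method={"anova": "ANOVA_CLOSED_FORM", "reml": "REML"}[method],
            ),
            degenerate=degenerate,
            icc_absolute=float(icc_abs) if np.isfinite(icc_abs) else np.nan,
        )


def icc_consistency(matrix: SubjectBySessionMatrix, method: str = "anova") -> IccResults:
    """Functional alias: ``IccModel(matrix).fit(method)``."""
    return IccModel(matrix).fit(method=method)


def pairwise_icc(table: IDPTable, idp_name: str, sessions=None, method: str = "anova"):
    """Consistency ICC for every unordered pair of the requested sessions.

    Returns a list of ``(pair, IccResults | None, reason)`` — pairs with
    fewer than 3 complete subjects are reported as skipped with the reason,
    not dropped.
    """
    if sessions is None:
        sessions = table.session_labels
    sessions = sorted(sessions)
    out = []
    for pair in itertools.combinations(sessions, 2):
        try:
            matrix = table.extract_matrix(idp_name, sessions=pair)
        except InsufficientDataError as exc:
            out.append((pair, None, str(exc)))
            continue
        out.append((pair, IccModel(matrix).fit(method=method), ""))
    return out


@dataclass(frozen=True)
class CorrelationMatrix:
    """k x k between-session correlations: Pearson above the diagonal,
    Spearman (mid-rank ties) below, 1 on the diagonal. Zero-variance
    sessions produce NaN entries, listed in ``undefined_sessions``."""

    matrix: np.ndarray
    session_labels: tuple
    undefined_sessions: tuple = ()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix, index=self.session_labels, columns=self.session_labels
        )


def site_correlation_matrix(matrix: SubjectBySessionMatrix) -> CorrelationMatrix:
    """Pairwise between-session Pearson/Spearman correlations of subjects."""
    y = matrix.values
    k = y.shape[1]
    out = np.eye(k)
    degenerate = [j for j in range(k) if np.ptp(y[:, j]) == 0]
    for i in range(k):
        for j in range(i + 1, k):
            if i in degenerate or j in degenerate:
                out[i, j] = out[j, i] = np.nan
                continue
            out[i, j] = stats.pearsonr(y[:, i], y[:, j]).statistic
            out[j, i] = stats.spearmanr(y[:, i], y[:, j]).statistic
    return CorrelationMatrix(
        matrix=out,
        session_labels=matrix.session_labels,
        undefined_sessions=tuple(matrix.session_labels[j] for j in degenerate),
    )


def class_icc_summary(icc_table: pd.DataFrame, truncate_negative: bool = False) -> pd.DataFrame:
    """Per-class mean and SD of ICC over estimable phenotypes.

    ``icc_table`` needs columns ``class_label`` and ``icc`` (NaN = skipped).
    ``truncate_negative`` floors negative estimates at 0 before averaging —
    a report-level option, off by default.
    """
    df = icc_table.copy()
    icc = df["icc"].to_numpy(dtype=float)
    if truncate_negative:
        icc = np.where(np.isfinite(icc), np.maximum(icc, 0.0), icc)
    df["icc"] = icc
    rows = []
    for label, grp in df.groupby("class_label", sort=True):
        ok = grp["icc"].dropna()
        rows.append(
            {
                "class_label": label,
                "mean_icc": ok.mean() if len(ok) else np.nan,
                "sd_icc": ok.std(ddof=1) if len(ok) > 1 else np.nan,
                "n_idps": int(len(ok)),
                "n_skipped": int(grp["icc"].isna().sum()),
                "band": interpret_icc(ok.mean()) if len(ok) else "not estimable",
            }
        )
    return pd.DataFrame(rows)


def icc_scan(
    table: IDPTable, sessions=None, method: str = "anova", absolute: bool = False
) -> pd.DataFrame:
    """Consistency ICC for every phenotype over a session subset.

    Skipped phenotypes (too few complete subjects) keep their row with NaN
    ICC and the reason.
    """
    rows = []
    for idp in table.idp_names:
        base = {"idp_name": idp, "class_label": table.class_of(idp)}
        try:
            matrix = table.extract_matrix(idp, sessions=sessions)
        except InsufficientDataError as exc:
            rows.append({**base, "icc": np.nan, "skip_reason": str(exc)})
            continue
        res = IccModel(matrix).fit(method=method, absolute=absolute)
        rows.append(
            {
                **base,
                "icc": res.icc,
                "icc_absolute": res.icc_absolute,
                "sigma2_subject": res.components.sigma2_subject,
                "sigma2_error": res.components.sigma2_error,
                "n_subjects": res.n_subjects,
                "k_sessions": res.k_sessions,
                "method": res.method,
                "negative": res.negative,
                "degenerate": res.degenerate,
                "skip_reason": "",
            }
        )
    return pd.DataFrame(rows)
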