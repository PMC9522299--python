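"""Vectorised two-way within-subject sums of squares and ICC kernels.

All functions accept arrays of shape ``(..., n, k)`` — any number of leading
batch axes over an ``n`` subjects by ``k`` sessions layout — so that
simulation-heavy callers (resampling, calibration studies) can evaluate
thousands of matrices in one call. The model classes wrap the single-matrix
case.
"""

from __future__ import annotations

import numpy as np


def ss_decomposition(y: np.ndarray):
    """Partition SS_total = SS_subjects + SS_sessions + SS_error.

    Returns ``(ss_subjects, ss_sessions, ss_error)`` with shapes equal to the
    batch shape of ``y``.
    """
    y = np.asarray(y, dtype=float)
    n, k = y.shape[-2], y.shape[-1]
    grand = y.mean(axis=(-2, -1), keepdims=True)
    row = y.mean(axis=-1, keepdims=True)
    col = y.mean(axis=-2, keepdims=True)
    ss_subj = (k * (row - grand) ** 2).sum(axis=(-2, -1))
    ss_sess = (n * (col - grand) ** 2).sum(axis=(-2, -1))
    resid = y - row - col + grand
    ss_err = (resid**2).sum(axis=(-2, -1))
    return ss_subj, ss_sess, ss_err


def mean_squares(y: np.ndarray):
    """``(ms_subjects, ms_sessions, ms_error)`` of the two-way layout."""
    n, k = y.shape[-2], y.shape[-1]
    ss_subj, ss_sess, ss_err = ss_decomposition(y)
    return ss_subj / (n - 1), ss_sess / (k - 1), ss_err / ((n - 1) * (k - 1))


def anova_f(y: np.ndarray):
    """Session-effect F ratio and partial eta squared, batched.

    Returns ``(F, eta_sq_partial)``; where ``SS_error == 0`` the F is +inf
    (perfectly additive data) with eta_sq 1, or nan when the session SS is
    zero too.
    """
    n, k = y.shape[-2], y.shape[-1]
    _, ss_sess, ss_err = ss_decomposition(y)
    ms_sess = ss_sess / (k - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(ms_err > 0, ms_sess / np.where(ms_err > 0, ms_err, 1.0), np.inf)
        f = np.where((ss_err == 0) & (ss_sess == 0), np.nan, f)
        denom = ss_sess + ss_err
        eta = np.where(denom > 0, ss_sess / np.where(denom > 0, denom, 1.0), 0.0)
    return f, eta


def icc_consistency_from_ms(ms_subj, ms_err, k: int):
    """ICC(3,1) from mean squares: (MSs - MSe) / (MSs + (k-1) MSe).

    Degenerate ``MS_error == 0`` maps to ICC 1 (columns reproduce each
    subject exactly up to session offsets).
    """
    ms_subj = np.asarray(ms_subj, dtype=float)
    ms_err = np.asarray(ms_err, dtype=float)
    denom = ms_subj + (k - 1) * ms_err
    with np.errstate(divide="ignore", invalid="ignore"):
        icc = np.where(
            ms_err == 0,
            np.where(ms_subj > 0, 1.0, np.nan),
            (ms_subj - ms_err) / np.where(denom != 0, denom, np.nan),
        )
    return icc


def icc_consistency(y: np.ndarray):
    """Batched consistency ICC(3,1) over the trailing (n, k) axes."""
    ms_subj, _, ms_err = mean_squares(y)
    return icc_consistency_from_ms(ms_subj, ms_err, y.shape[-1])
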