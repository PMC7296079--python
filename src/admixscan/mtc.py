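"""Storey-Tibshirani q values and FDR threshold lines.

The q value of a test is the minimum false-discovery rate at which it
would be called significant:

    q_i = min_{p_j >= p_i} pi0 * m * p_j / rank(p_j),

where ``pi0`` estimates the proportion of true nulls.  With ``pi0`` fixed
at 1 this reduces to the Benjamini-Hochberg step-up procedure.  The
default ``pi0`` estimate is the natural-cubic-spline smoother of
``pi0(lambda) = #{p > lambda} / (m (1 - lambda))`` over a lambda grid,
evaluated at the largest grid point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = ["QValueSet", "qvalues", "fdr_threshold_line"]


@dataclass
class QValueSet:
    p: np.ndarray
    q: np.ndarray
    pi0: float
    lambda_grid: np.ndarray


def _pi0_smoother(p: np.ndarray, lambda_grid: np.ndarray) -> float:
    m = len(p)
    pi0_lam = np.array(
        [np.count_nonzero(p > lam) / (m * (1.0 - lam)) for lam in lambda_grid]
    )
    if len(lambda_grid) < 4:
        return float(np.clip(pi0_lam[-1], 1.0 / m, 1.0))
    spline = CubicSpline(lambda_grid, pi0_lam, bc_type="natural")
    pi0 = float(spline(lambda_grid[-1]))
    return float(np.clip(pi0, 1.0 / m, 1.0))


def qvalues(
    p: np.ndarray,
    lambda_grid: np.ndarray | None = None,
    pi0: float | None = None,
) -> QValueSet:
    """Q values for a set of p values.

    Parameters
    ----------
    p
        P values in (0, 1].
    lambda_grid
        Grid for the pi0 smoother; default 0.05, 0.10, ..., 0.95.
    pi0
        Fix the null proportion instead of estimating it (``pi0=1`` gives
        Benjamini-Hochberg).
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("need a non-empty 1-D array of p values")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p values must lie in (0, 1]")
    if lambda_grid is None:
        lambda_grid = np.arange(0.05, 0.96, 0.05)
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    if pi0 is None:
        pi0 = _pi0_smoother(p, lambda_grid)
    if not 0 < pi0 <= 1:
        raise ValueError("pi0 must lie in (0, 1]")

    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    raw = pi0 * m * ranked / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(raw[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return QValueSet(p=p, q=q, pi0=float(pi0), lambda_grid=lambda_grid)


def fdr_threshold_line(qset: QValueSet, level: float) -> float | None:
    """-log10 p of the least-significant test passing the FDR level.

    Returns the -log10 of the largest p value whose q value is at most
    ``level``, or ``None`` when no test passes (the caller then draws no
    threshold line).
    """
    passing = qset.q <= level
    if not passing.any():
        return None
    return float(-np.log10(np.max(qset.p[passing])))
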