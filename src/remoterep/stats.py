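"""Rank and regression statistics used by the session-level analyses.

The Mann-Whitney U test is implemented from the rank formula (with tie
correction and a normal approximation) and by exhaustive enumeration of group
assignments for small samples, so that per-rat session comparisons do not
depend on any particular library's two-sided convention.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["mann_whitney", "MannWhitneyResult", "linear_trend", "zscore"]

EXACT_MAX_N = 8  # per-group size up to which the exact enumeration runs


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float          # U statistic of the first group
    p: float          # two-sided p-value
    method: str       # "exact" or "normal"


def _u_from_ranks(ranks_x: np.ndarray, nx: int) -> float:
    return float(ranks_x.sum() - nx * (nx + 1) / 2.0)


def mann_whitney(x, y, exact_max_n: int = EXACT_MAX_N) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    For ``max(len(x), len(y)) <= exact_max_n`` the null distribution of U is
    enumerated exhaustively over all group assignments (ties handled by
    mid-ranks), and the two-sided p-value is ``P(U <= u_lo) + P(U >= u_hi)``
    with ``u_lo = min(u, nx*ny - u)``. Larger samples use the normal
    approximation with the tie-corrected variance. All values tied gives
    p = 1 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx == 0 or ny == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)
    u = _u_from_ranks(ranks[:nx], nx)

    if np.ptp(combined) == 0:
        return MannWhitneyResult(u=u, p=1.0, method="degenerate")

    if max(nx, ny) <= exact_max_n:
        n = nx + ny
        u_lo = min(u, nx * ny - u)
        u_hi = nx * ny - u_lo
        count = 0
        total = math.comb(n, nx)
        idx = np.arange(n)
        for subset in itertools.combinations(idx, nx):
            up = _u_from_ranks(ranks[list(subset)], nx)
            if up <= u_lo + 1e-12 or up >= u_hi - 1e-12:
                count += 1
        return MannWhitneyResult(u=u, p=min(1.0, count / total), method="exact")

    # normal approximation with tie correction
    n = nx + ny
    mu = nx * ny / 2.0
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
    sigma2 = nx * ny / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return MannWhitneyResult(u=u, p=1.0, method="degenerate")
    z = (u - mu) / math.sqrt(sigma2)
    p = 2.0 * sps.norm.sf(abs(z))
    return MannWhitneyResult(u=u, p=min(1.0, float(p)), method="normal")


def zscore(values) -> np.ndarray:
    """Z-score a series; a constant series maps to zeros."""
    v = np.asarray(values, dtype=float)
    sd = v.std(ddof=0)
    if sd == 0:
        return np.zeros_like(v)
    return (v - v.mean()) / sd


def linear_trend(values, index=None, z: bool = False):
    """OLS of ``values`` (optionally z-scored) against a session index.

    Returns ``(slope, p)`` where ``p`` is the two-sided t-test on the slope.
    A constant series returns ``(0.0, 1.0)`` by convention.
    """
    v = np.asarray(values, dtype=float)
    if index is None:
        index = np.arange(len(v), dtype=float)
    else:
        index = np.asarray(index, dtype=float)
    if len(v) < 3:
        raise ValueError("need at least 3 points for a trend")
    if z:
        v = zscore(v)
    if np.ptp(v) == 0:
        return 0.0, 1.0
    res = sps.linregress(index, v)
    p = res.pvalue
    if np.isnan(p):  # perfectly collinear
        p = 0.0
    return float(res.slope), float(p)
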