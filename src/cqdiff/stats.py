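"""Robust two-sample statistics: trimmed means, Winsorized variance, the
Yuen-Welch statistic, its permutation null, and Benjamini-Hochberg FDR.

The Yuen-Welch test compares gamma-trimmed means of two independent groups
using Winsorized-variance standard errors (Yuen 1974):

    T = (tmean(x) - tmean(y)) / sqrt(d_x + d_y),
    d_j = (n_j - 1) * s2w_j / (h_j * (h_j - 1)),   h_j = n_j - 2*g_j,

with g_j = floor(gamma * n_j) observations trimmed from each tail of group j
and s2w_j the Winsorized sample variance (divisor n_j - 1). Significance is
assessed by permuting group labels without replacement and recomputing the
studentized statistic; the two-sided p-value uses the add-one estimator
p = (1 + #{|T*| >= |T_obs|}) / (B + 1), which is never zero.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

__all__ = [
    "trimmed_mean",
    "winsorized_variance",
    "yuen_welch_statistic",
    "permutation_yuen_test",
    "exhaustive_permutation_test",
    "bh_adjust",
    "PermutationTestResult",
]


def _as_clean_1d(x, name: str) -> np.ndarray:
    a = np.asarray(x, dtype=float).ravel()
    if a.size == 0:
        raise ValueError(f"{name} is empty")
    if np.isnan(a).any():
        raise ValueError(f"{name} contains NaN; pass complete cases only")
    return a


def _ntrim(n: int, trim: float) -> int:
    if not (0 <= trim < 0.5):
        raise ValueError("trim proportion must satisfy 0 <= gamma < 0.5")
    return int(math.floor(trim * n))


def trimmed_mean(x, trim: float) -> float:
    """Mean of the central order statistics after removing floor(gamma*n)
    observations from each tail."""
    a = np.sort(_as_clean_1d(x, "x"))
    g = _ntrim(a.size, trim)
    if a.size - 2 * g < 1:
        raise ValueError(f"trimming gamma={trim} leaves no observations from n={a.size}")
    return float(a[g : a.size - g].mean())


def winsorized_variance(x, trim: float) -> float:
    """Sample variance (divisor n-1) after replacing each tail's g values by
    the nearest retained order statistic."""
    a = np.sort(_as_clean_1d(x, "x"))
    n = a.size
    g = _ntrim(n, trim)
    if n < 2 or n - 2 * g < 2:
        raise ValueError(f"need at least 2 retained observations (n={n}, gamma={trim})")
    w = np.clip(a, a[g], a[n - g - 1])
    return float(w.var(ddof=1))


def _yuen_parts(a: np.ndarray, trim: float) -> tuple[float, float, int]:
    """(trimmed mean, Yuen squared-SE term d, retained count h) for one group."""
    a = np.sort(a)
    n = a.size
    g = _ntrim(n, trim)
    h = n - 2 * g
    if h < 2:
        raise ValueError(f"group too small after trimming (n={n}, gamma={trim})")
    tm = a[g : n - g].mean()
    w = np.clip(a, a[g], a[n - g - 1])
    s2w = w.var(ddof=1)
    d = (n - 1) * s2w / (h * (h - 1))
    return float(tm), float(d), h


def yuen_welch_statistic(x, y, trim: float = 0.10) -> float:
    """Yuen-Welch studentized difference of trimmed means.

    With ``trim=0`` this reduces exactly to the Welch unequal-variance t
    statistic. A zero standard error with equal trimmed means returns 0;
    with unequal trimmed means it is a degenerate-variance error.
    """
    ax = _as_clean_1d(x, "x")
    ay = _as_clean_1d(y, "y")
    tmx, dx, _ = _yuen_parts(ax, trim)
    tmy, dy, _ = _yuen_parts(ay, trim)
    num = tmx - tmy
    den = math.sqrt(dx + dy)
    if den == 0.0:
        if num == 0.0:
            return 0.0
        raise ValueError("degenerate variance: zero Winsorized spread with unequal trimmed means")
    return num / den


def _yuen_batch(xs: np.ndarray, ys: np.ndarray, trim: float) -> np.ndarray:
    """Vectorized Yuen-Welch statistics for stacked groups.

    ``xs`` is (B, n_x), ``ys`` is (B, n_y). Degenerate rows (zero pooled SE)
    yield 0 when the trimmed means tie and +/-inf otherwise, so they compare
    as maximally extreme in the permutation tail count.
    """
    stats = []
    for a in (xs, ys):
        a = np.sort(a, axis=1)
        n = a.shape[1]
        g = _ntrim(n, trim)
        h = n - 2 * g
        if h < 2:
            raise ValueError(f"group too small after trimming (n={n}, gamma={trim})")
        tm = a[:, g : n - g].mean(axis=1)
        w = np.clip(a, a[:, g][:, None], a[:, n - g - 1][:, None])
        s2w = w.var(axis=1, ddof=1)
        d = (n - 1) * s2w / (h * (h - 1))
        stats.append((tm, d))
    (tmx, dx), (tmy, dy) = stats
    num = tmx - tmy
    den = np.sqrt(dx + dy)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = num / den
    t[(den == 0) & (num == 0)] = 0.0
    t[(den == 0) & (num > 0)] = np.inf
    t[(den == 0) & (num < 0)] = -np.inf
    return t


@dataclass
class PermutationTestResult:
    """Outcome of a (Monte-Carlo or exhaustive) permutation Yuen-Welch test."""

    statistic: float
    pvalue: float
    n_permutations: int
    n_x: int
    n_y: int
    trim: float
    seed: int | None = None
    exhaustive: bool = False


def _rng(random_state) -> np.random.Generator:
    if isinstance(random_state, np.random.Generator):
        return random_state
    return np.random.default_rng(random_state)


def permutation_yuen_test(
    x,
    y,
    trim: float = 0.10,
    n_permutations: int = 1000,
    random_state=None,
) -> PermutationTestResult:
    """Two-sided Monte-Carlo permutation test of the Yuen-Welch statistic.

    Pools the observations, draws ``n_permutations`` random relabelings
    preserving group sizes, and counts relabeled statistics at least as
    extreme as the observed one: p = (1 + count) / (B + 1).
    """
    ax = _as_clean_1d(x, "x")
    ay = _as_clean_1d(y, "y")
    if ax.size + ay.size < 4:
        raise ValueError("need at least 4 pooled observations")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    seed = random_state if isinstance(random_state, (int, np.integer)) else None
    pooled = np.concatenate([ax, ay])
    n, n_x = pooled.size, ax.size

    if np.ptp(pooled) == 0.0:
        return PermutationTestResult(0.0, 1.0, n_permutations, n_x, ay.size, trim, seed)

    t_obs = _yuen_batch(ax[None, :], ay[None, :], trim)[0]
    rng = _rng(random_state)
    # B independent label permutations via row-wise argsort of random keys
    order = np.argsort(rng.random((n_permutations, n)), axis=1)
    perm = pooled[order]
    t_star = _yuen_batch(perm[:, :n_x], perm[:, n_x:], trim)
    count = int(np.count_nonzero(np.abs(t_star) >= abs(t_obs)))
    p = (1 + count) / (n_permutations + 1)
    return PermutationTestResult(float(t_obs), float(p), n_permutations, n_x, ay.size, trim, seed)


def exhaustive_permutation_test(
    x,
    y,
    trim: float = 0.10,
    max_combinations: int = 10**6,
) -> PermutationTestResult:
    """Exact two-sided permutation p by full enumeration of relabelings.

    p = #{|T*| >= |T_obs|} / C(n, n_x); the identity relabeling is part of
    the enumeration, so p >= 1/C(n, n_x). Intended as the small-n oracle for
    :func:`permutation_yuen_test`.
    """
    ax = _as_clean_1d(x, "x")
    ay = _as_clean_1d(y, "y")
    n, n_x = ax.size + ay.size, ax.size
    ncomb = math.comb(n, n_x)
    if ncomb > max_combinations:
        raise ValueError(
            f"C({n},{n_x}) = {ncomb} exceeds cap {max_combinations}; use permutation_yuen_test"
        )
    pooled = np.concatenate([ax, ay])
    if np.ptp(pooled) == 0.0:
        return PermutationTestResult(0.0, 1.0, ncomb, n_x, ay.size, trim, exhaustive=True)
    t_obs = _yuen_batch(ax[None, :], ay[None, :], trim)[0]
    idx = np.fromiter(
        itertools.chain.from_iterable(itertools.combinations(range(n), n_x)),
        dtype=np.intp,
    ).reshape(ncomb, n_x)
    mask = np.ones((ncomb, n), dtype=bool)
    np.put_along_axis(mask, idx, False, axis=1)
    xs = pooled[idx]
    ys = pooled[np.nonzero(mask)[1].reshape(ncomb, n - n_x)]
    t_star = _yuen_batch(xs, ys, trim)
    count = int(np.count_nonzero(np.abs(t_star) >= abs(t_obs)))
    return PermutationTestResult(float(t_obs), count / ncomb, ncomb, n_x, ay.size, trim, exhaustive=True)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Missing entries (NaN) are excluded from the family size m and returned
    as NaN; any value outside [0, 1] is an error.
    """
    p = np.asarray(pvalues, dtype=float).ravel()
    mask = ~np.isnan(p)
    if ((p[mask] < 0) | (p[mask] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out
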