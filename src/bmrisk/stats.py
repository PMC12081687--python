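"""Statistical primitives used across the analyses.

Implemented once here so every module cites the same definitions:
two-tailed Welch's t test, Wilcoxon signed-rank (exact for small n),
1-D Wasserstein (earth mover's) distance between binned histograms,
and the 95% t-interval over per-site values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "SiteSamples",
    "welch_t_test",
    "wilcoxon_signed_rank",
    "wasserstein_1d",
    "ci95_over_sites",
    "benjamini_hochberg",
]

#: threshold below which the Wilcoxon null distribution is enumerated exactly
WILCOXON_EXACT_N = 25


@dataclass(frozen=True)
class SiteSamples:
    """One scalar quantity measured at each contributing site."""

    values: tuple[float, ...]
    sites: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.sites and len(self.sites) != len(self.values):
            raise ValueError("sites and values length mismatch")
        if self.sites and len(set(self.sites)) != len(self.sites):
            raise ValueError("duplicate site identifiers")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("site values must be finite")


def _as_array(x) -> np.ndarray:
    if isinstance(x, SiteSamples):
        return np.asarray(x.values, dtype=float)
    return np.asarray(x, dtype=float)


def welch_t_test(a, b) -> tuple[float, float, float]:
    """Two-tailed Welch's t test with Satterthwaite degrees of freedom.

    Returns ``(t, df, p_two_sided)``.
    """
    a, b = _as_array(a), _as_array(b)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least two values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if np.allclose(a.mean(), b.mean()):
            return 0.0, float(a.size + b.size - 2), 1.0
        raise ValueError("zero variance in both samples with unequal means")
    res = sps.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def _signed_rank_exact_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p for the signed-rank statistic by convolution.

    Midranked ties give half-integer ranks; doubling makes every rank an
    integer so the null distribution is a polynomial convolution over
    2^n equiprobable sign assignments.
    """
    r2 = np.rint(2 * ranks).astype(np.int64)
    total = int(r2.sum())
    # dist[w] = number of sign assignments with doubled W+ equal to w
    dist = np.zeros(total + 1, dtype=np.float64)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = dist + shifted
    dist /= dist.sum()
    w2 = int(np.rint(2 * w_plus))
    p_le = dist[: w2 + 1].sum()
    p_ge = dist[w2:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_signed_rank(diffs) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zeros are dropped, ties midranked.  For n <= 25 the null distribution
    is enumerated exactly; above that a normal approximation with tie and
    continuity corrections is used.  Returns ``(W_plus, p)``; if every
    difference is zero, returns ``(0.0, nan)`` with a warning.
    """
    d = _as_array(diffs)
    d = d[d != 0]
    n = d.size
    if n == 0:
        warnings.warn("all differences zero; Wilcoxon p undefined", stacklevel=2)
        return 0.0, float("nan")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= WILCOXON_EXACT_N:
        return w_plus, _signed_rank_exact_p(ranks, w_plus)
    mean = n * (n + 1) / 4.0
    # variance with tie correction over the midranked |d|
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = (counts**3 - counts).sum() / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    z = (w_plus - mean - 0.5 * np.sign(w_plus - mean)) / np.sqrt(var)
    return w_plus, float(2 * sps.norm.sf(abs(z)))


def wasserstein_1d(h1, h2, bin_width: float) -> float:
    """Earth mover's distance between two histograms on a common binning.

    Equals the sum of absolute CDF differences times the bin width, in the
    units of the support.  Unnormalized inputs are renormalized with a
    warning.
    """
    h1, h2 = _as_array(h1), _as_array(h2)
    if h1.shape != h2.shape:
        raise ValueError("histograms must share a binning")
    if np.any(h1 < 0) or np.any(h2 < 0):
        raise ValueError("histogram masses must be non-negative")
    s1, s2 = h1.sum(), h2.sum()
    if s1 <= 0 or s2 <= 0:
        raise ValueError("empty histogram")
    if not (np.isclose(s1, 1.0) and np.isclose(s2, 1.0)):
        warnings.warn("histograms not normalized; renormalizing", stacklevel=2)
    c1, c2 = np.cumsum(h1 / s1), np.cumsum(h2 / s2)
    return float(np.abs(c1 - c2).sum() * bin_width)


def ci95_over_sites(s) -> tuple[float, float, float]:
    """Mean and 95% t-interval of per-site values: mean +/- t_{0.975,n-1} SE."""
    x = _as_array(s)
    n = x.size
    if n < 2:
        raise ValueError("confidence interval needs at least two sites")
    m = float(x.mean())
    half = float(sps.t.ppf(0.975, n - 1) * x.std(ddof=1) / np.sqrt(n))
    return m, m - half, m + half


def benjamini_hochberg(pvals) -> np.ndarray:
    """BH-adjusted p-values (optional; analyses report raw p by default)."""
    p = _as_array(pvals)
    n = p.size
    order = np.argsort(p)
    adj = np.empty(n)
    prev = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        k = n - rank_from_end
        prev = min(prev, p[idx] * n / k)
        adj[idx] = prev
    return adj
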