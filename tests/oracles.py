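"""Independent brute-force oracles used only by the test suite.

Each function recomputes a quantity by the most literal method available
(flood fill, exhaustive scan, linear programming, full enumeration) and
stays independent of the library code paths it checks.
"""

from __future__ import annotations

from collections import deque
from itertools import product

import numpy as np
from scipy.optimize import linprog


def bfs_label_26(mask: np.ndarray) -> int:
    """Number of 26-connected components by breadth-first flood fill."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    offsets = [d for d in product((-1, 0, 1), repeat=3) if d != (0, 0, 0)]
    n_comp = 0
    for start in zip(*np.nonzero(mask)):
        if seen[start]:
            continue
        n_comp += 1
        queue = deque([start])
        seen[start] = True
        while queue:
            v = queue.popleft()
            for d in offsets:
                w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
                if all(0 <= w[i] < mask.shape[i] for i in range(3)):
                    if mask[w] and not seen[w]:
                        seen[w] = True
                        queue.append(w)
    return n_comp


def exhaustive_distance_map(target: np.ndarray, spacing_mm: float) -> np.ndarray:
    """O(n^2) nearest-target-voxel Euclidean distance, in mm."""
    target = np.asarray(target, dtype=bool)
    tgt = np.argwhere(target).astype(float)
    out = np.empty(target.shape)
    for idx in np.ndindex(target.shape):
        d2 = ((tgt - np.asarray(idx, dtype=float)) ** 2).sum(axis=1)
        out[idx] = np.sqrt(d2.min()) * spacing_mm
    return out


def exhaustive_dilation(mask: np.ndarray, spacing_mm: float, margin_mm: float) -> np.ndarray:
    """Euclidean dilation by direct distance check against every mask voxel."""
    mask = np.asarray(mask, dtype=bool)
    src = np.argwhere(mask).astype(float)
    out = np.zeros_like(mask)
    for idx in np.ndindex(mask.shape):
        d2 = ((src - np.asarray(idx, dtype=float)) ** 2).sum(axis=1)
        out[idx] = np.sqrt(d2.min()) * spacing_mm <= margin_mm
    return out


def lp_transport_distance(h1: np.ndarray, h2: np.ndarray, bin_width: float) -> float:
    """1-D earth mover's distance as an explicit optimal-transport LP."""
    h1 = np.asarray(h1, dtype=float) / np.sum(h1)
    h2 = np.asarray(h2, dtype=float) / np.sum(h2)
    n = h1.size
    cost = np.abs(np.subtract.outer(np.arange(n), np.arange(n))).ravel() * bin_width
    a_eq = []
    for i in range(n):  # row sums = h1
        row = np.zeros(n * n)
        row[i * n : (i + 1) * n] = 1
        a_eq.append(row)
    for j in range(n):  # column sums = h2
        col = np.zeros(n * n)
        col[j::n] = 1
        a_eq.append(col)
    res = linprog(cost, A_eq=np.asarray(a_eq), b_eq=np.concatenate([h1, h2]), method="highs")
    assert res.success
    return float(res.fun)


def enumerate_signed_rank_p(diffs: np.ndarray) -> float:
    """Exact two-sided signed-rank p by enumerating all 2^n sign patterns."""
    from scipy.stats import rankdata

    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = np.zeros(2**n)
    for bits in range(2**n):
        picked = [(bits >> k) & 1 for k in range(n)]
        ws[bits] = (ranks * np.asarray(picked)).sum()
    p_le = np.mean(ws <= w_obs + 1e-12)
    p_ge = np.mean(ws >= w_obs - 1e-12)
    return min(1.0, 2 * min(p_le, p_ge))
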