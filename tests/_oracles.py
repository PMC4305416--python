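"""Independent brute-force oracles used by the test suite.

Each oracle deliberately avoids the code paths it checks: plain double loops
instead of k-d trees, linear programming instead of Qhull, exhaustive
enumeration instead of normal approximations.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy.optimize import linprog

QUARTIC_PEAK = 3.0 / np.pi


def brute_force_density(cancer_xy: np.ndarray, h: float, queries: np.ndarray) -> np.ndarray:
    """Double-loop quartic kernel sum, h⁻² Σ_i K((p−x_i)/h)."""
    out = np.zeros(len(queries))
    for qi, p in enumerate(queries):
        total = 0.0
        for x in cancer_xy:
            r2 = ((p[0] - x[0]) / h) ** 2 + ((p[1] - x[1]) / h) ** 2
            if r2 <= 1.0:
                total += QUARTIC_PEAK * (1.0 - r2) ** 2
        out[qi] = total / h**2
    return out


def brute_force_dmin(cancer_xy: np.ndarray, lymph_xy: np.ndarray) -> np.ndarray:
    """Exhaustive nearest-cancer distance."""
    out = np.empty(len(lymph_xy))
    for i, p in enumerate(lymph_xy):
        out[i] = min(float(np.hypot(p[0] - x[0], p[1] - x[1])) for x in cancer_xy)
    return out


def _is_extreme(points: np.ndarray, i: int) -> bool:
    """Is points[i] outside the convex hull of the other points? (LP test)"""
    others = np.delete(points, i, axis=0)
    m = len(others)
    if m == 0:
        return True
    # feasibility of points[i] = Σ λ_j · others_j, λ ≥ 0, Σ λ = 1
    A_eq = np.vstack([others.T, np.ones(m)])
    b_eq = np.array([points[i, 0], points[i, 1], 1.0])
    res = linprog(np.zeros(m), A_eq=A_eq, b_eq=b_eq, bounds=[(0, None)] * m,
                  method="highs")
    return not res.success


def oracle_hull_vertex_centroid(points: np.ndarray) -> np.ndarray:
    """Mean of extreme points, via the LP membership scan."""
    pts = np.unique(points, axis=0)
    if len(pts) == 1:
        return pts[0]
    extremes = [i for i in range(len(pts)) if _is_extreme(pts, i)]
    return pts[extremes].mean(axis=0)


def oracle_k_nearest(cancer_xy: np.ndarray, point: np.ndarray, k: int) -> np.ndarray:
    """k nearest cancer cells, ties to the lowest index (stable sort)."""
    d2 = ((cancer_xy - point) ** 2).sum(axis=1)
    order = np.lexsort((np.arange(len(cancer_xy)), d2))
    return order[:k]


def oracle_dcentroid(cancer_xy: np.ndarray, lymph_xy: np.ndarray, k: int = 5) -> np.ndarray:
    out = np.empty(len(lymph_xy))
    for i, p in enumerate(lymph_xy):
        idx = oracle_k_nearest(cancer_xy, p, k)
        c = oracle_hull_vertex_centroid(cancer_xy[idx])
        out[i] = float(np.hypot(p[0] - c[0], p[1] - c[1]))
    return out


def jt_statistic_naive(groups: list) -> float:
    stat = 0.0
    for gi, gj in combinations(groups, 2):
        for a in gi:
            for b in gj:
                if a < b:
                    stat += 1.0
                elif a == b:
                    stat += 0.5
    return stat


def jt_exact_enumeration(groups: list) -> tuple[float, float, float]:
    """(statistic, one-sided p≥, one-sided p≤) by exhaustive assignment."""
    observed = jt_statistic_naive(groups)
    pooled = np.concatenate(groups)
    sizes = [len(g) for g in groups]
    ge = le = total = 0

    def rec(avail: tuple, gi: int, built: list):
        nonlocal ge, le, total
        if gi == len(sizes) - 1:
            grp = built + [pooled[list(avail)]]
            s = jt_statistic_naive([np.asarray(g) for g in grp])
            total += 1
            ge += s >= observed - 1e-12
            le += s <= observed + 1e-12
            return
        for comb in combinations(avail, sizes[gi]):
            rest = tuple(i for i in avail if i not in set(comb))
            rec(rest, gi + 1, built + [pooled[list(comb)]])

    rec(tuple(range(len(pooled))), 0, [])
    return observed, ge / total, le / total


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up, straight from the definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj
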