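"""Physical-distance characterization of lymphocyte classes.

Two per-lymphocyte metrics complement the kernel proximity value:

* ``d_min`` — Euclidean distance to the nearest cancer cell;
* ``d_centroid`` — distance to the centroid of the convex hull of the k = 5
  nearest cancer cells, where the centroid is the arithmetic mean of the
  hull *vertices* (extreme points).  A lymphocyte surrounded by cancer sits
  near that centroid; one with all nearby cancer to one side is far from it,
  so d_centroid measures the spatial arrangement of the surroundings rather
  than mere closeness.

Degenerate neighbourhoods are handled explicitly: coincident cancer points
are deduplicated before hull construction, a fully collinear set contributes
its two endpoints (centroid = their midpoint), and a single distinct point is
its own centroid.  Ties in the k-nearest selection break to the lowest cell
index.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError, cKDTree
from scipy.stats import ttest_ind

from .cell_tables import CellMap


def nearest_cancer_distance(cell_map: CellMap) -> np.ndarray:
    """d_min: Euclidean distance from each lymphocyte to the closest cancer cell."""
    cancer = cell_map.cancer_xy
    if cancer.shape[0] == 0:
        raise ValueError(f"{cell_map.tumour_id}: no cancer cells")
    lymph = cell_map.lymphocyte_xy
    if lymph.shape[0] == 0:
        return np.empty(0)
    d, _ = cKDTree(cancer).query(lymph, k=1)
    return np.asarray(d, dtype=float)


def _k_nearest_indices(cancer: np.ndarray, tree: cKDTree, point: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k nearest cancer cells, ties broken by lowest index."""
    d, idx = tree.query(point, k=k)
    d = np.atleast_1d(d)
    idx = np.atleast_1d(idx)
    dk = d[-1]
    # pull in every cell at the k-th distance so the tie rule is deterministic
    cand = np.asarray(tree.query_ball_point(point, dk * (1 + 1e-12) + 1e-12), dtype=np.intp)
    if cand.size < k:
        cand = idx
    d2 = ((cancer[cand] - point) ** 2).sum(axis=1)
    order = np.lexsort((cand, d2))
    return cand[order[:k]]


def _hull_vertex_centroid(points: np.ndarray) -> np.ndarray:
    """Mean of the extreme points of a small 2-D point set.

    Coincident points are deduplicated first.  Collinear sets contribute
    their two endpoints; a single distinct point is its own centroid.
    """
    pts = np.unique(points, axis=0)
    if pts.shape[0] == 1:
        return pts[0]
    if pts.shape[0] == 2:
        return pts.mean(axis=0)
    try:
        hull = ConvexHull(pts)
        return pts[hull.vertices].mean(axis=0)
    except QhullError:
        # collinear: the extreme points are the endpoints of the segment
        i, j = max(
            combinations(range(pts.shape[0]), 2),
            key=lambda ij: ((pts[ij[0]] - pts[ij[1]]) ** 2).sum(),
        )
        return 0.5 * (pts[i] + pts[j])


def hull_centroid_distance(cell_map: CellMap, k: int = 5) -> np.ndarray:
    """d_centroid for every lymphocyte, from its k nearest cancer cells."""
    cancer = cell_map.cancer_xy
    if cancer.shape[0] < k:
        raise ValueError(
            f"{cell_map.tumour_id}: need ≥{k} cancer cells for the hull, "
            f"have {cancer.shape[0]}"
        )
    lymph = cell_map.lymphocyte_xy
    tree = cKDTree(cancer)
    out = np.empty(lymph.shape[0])
    for i, p in enumerate(lymph):
        idx = _k_nearest_indices(cancer, tree, p, k)
        centroid = _hull_vertex_centroid(cancer[idx])
        out[i] = float(np.hypot(*(p - centroid)))
    return out


def arrangement_table(
    cell_map: CellMap, labels: np.ndarray | None = None, k: int = 5
) -> pd.DataFrame:
    """Per-lymphocyte table of d_min, d_centroid and (optionally) class."""
    d_min = nearest_cancer_distance(cell_map)
    d_cen = hull_centroid_distance(cell_map, k=k)
    df = pd.DataFrame(
        {"lymph_id": cell_map.lymphocyte_index, "d_min": d_min, "d_centroid": d_cen}
    )
    if labels is not None:
        df["til_class"] = np.asarray(labels, dtype=object)
    return df


def class_difference_tests(
    values: np.ndarray,
    labels: np.ndarray,
    classes: tuple = ("ITL", "ATL", "DTL"),
    equal_var: bool = False,
) -> pd.DataFrame:
    """Pairwise t-tests of a distance metric between lymphocyte classes.

    Welch's unequal-variance t-test by default (class variances differ
    markedly in practice); ``equal_var=True`` gives the classic pooled test.
    Reports per-class medians and interquartile ranges alongside each
    comparison.  Two identical constant groups are reported as t = 0, p = 1.
    Pairs with an absent class are skipped with a warning.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=object)
    rows = []
    for a, b in combinations(classes, 2):
        va, vb = values[labels == a], values[labels == b]
        if len(va) < 2 or len(vb) < 2:
            warnings.warn(f"class pair ({a}, {b}) skipped: too few observations", stacklevel=2)
            continue
        if np.ptp(va) == 0 and np.ptp(vb) == 0 and va[0] == vb[0]:
            t, p = 0.0, 1.0
        else:
            t, p = ttest_ind(va, vb, equal_var=equal_var)
        qa, qb = np.percentile(va, [25, 50, 75]), np.percentile(vb, [25, 50, 75])
        rows.append(
            {
                "class_a": a, "class_b": b,
                "t": float(t), "p": float(p),
                "n_a": len(va), "n_b": len(vb),
                "median_a": qa[1], "iqr_a_low": qa[0], "iqr_a_high": qa[2],
                "median_b": qb[1], "iqr_b_low": qb[0], "iqr_b_high": qb[2],
            }
        )
    return pd.DataFrame(rows)
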