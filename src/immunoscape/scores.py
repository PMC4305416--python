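"""Per-tumour infiltration scores and trend tests against ordered categories.

The intratumour lymphocyte ratio

    ITLR = n_ITL / n_cancer

is the headline score; ATLR and DTLR are the analogous ratios for the other
two classes, and Lym = (n_ITL + n_ATL + n_DTL)/n_cancer is the older
class-agnostic lymphocyte abundance, so ITLR + ATLR + DTLR = Lym by
construction.  The class composition (p_ITL, p_ATL, p_DTL) sums to one and is
the per-tumour datum behind ternary composition plots.

Association between a score and an ordered clinical category (for example
pathologist infiltration graded absent < mild < severe) is tested with the
Jonckheere–Terpstra trend test, implemented here with exact enumeration for
tiny samples and a tie-corrected normal approximation otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import norm

from .mixture import ClassifiedLymphocytes


@dataclass
class InfiltrationScores:
    """One tumour's lymphocyte-class counts and ratio scores."""

    tumour_id: str
    n_cancer: int
    n_itl: int
    n_atl: int
    n_dtl: int

    @property
    def n_lymph(self) -> int:
        return self.n_itl + self.n_atl + self.n_dtl

    @property
    def itlr(self) -> float:
        return self.n_itl / self.n_cancer

    @property
    def atlr(self) -> float:
        return self.n_atl / self.n_cancer

    @property
    def dtlr(self) -> float:
        return self.n_dtl / self.n_cancer

    @property
    def lym(self) -> float:
        return self.n_lymph / self.n_cancer

    @property
    def composition(self) -> tuple[float, float, float]:
        """(p_ITL, p_ATL, p_DTL); sums to 1 when any lymphocytes exist."""
        m = self.n_lymph
        if m == 0:
            return (float("nan"),) * 3
        return (self.n_itl / m, self.n_atl / m, self.n_dtl / m)

    def to_dict(self) -> dict:
        p = self.composition
        return {
            "tumour_id": self.tumour_id,
            "n_cancer": self.n_cancer,
            "n_itl": self.n_itl,
            "n_atl": self.n_atl,
            "n_dtl": self.n_dtl,
            "itlr": self.itlr,
            "atlr": self.atlr,
            "dtlr": self.dtlr,
            "lym": self.lym,
            "p_itl": p[0],
            "p_atl": p[1],
            "p_dtl": p[2],
        }


def compute_scores(
    labels: ClassifiedLymphocytes | np.ndarray,
    n_cancer: int,
    tumour_id: str = "",
) -> InfiltrationScores:
    """Class counts → ITLR/ATLR/DTLR/Lym for one tumour.

    ``labels`` may be a :class:`ClassifiedLymphocytes` or a plain array of
    ITL/ATL/DTL labels; ``n_cancer`` must be positive (the ratios are
    undefined otherwise).
    """
    if n_cancer <= 0:
        raise ValueError("n_cancer must be positive: infiltration ratios are undefined")
    arr = labels.labels if isinstance(labels, ClassifiedLymphocytes) else np.asarray(labels)
    counts = {c: int((arr == c).sum()) for c in ("ITL", "ATL", "DTL")}
    if sum(counts.values()) != arr.size:
        raise ValueError("labels contain values outside {ITL, ATL, DTL}")
    return InfiltrationScores(tumour_id, int(n_cancer), counts["ITL"], counts["ATL"], counts["DTL"])


def scores_table(score_list: list[InfiltrationScores]) -> pd.DataFrame:
    return pd.DataFrame([s.to_dict() for s in score_list])


# ---------------------------------------------------------------------------
# Jonckheere–Terpstra trend test
# ---------------------------------------------------------------------------

def _jt_statistic(groups: list[np.ndarray]) -> float:
    """JT = Σ_{i<j} Mann–Whitney count of pairs (a < b) with ties as ½."""
    stat = 0.0
    for gi, gj in combinations(groups, 2):
        a = gi[:, None]
        b = gj[None, :]
        stat += float((a < b).sum()) + 0.5 * float((a == b).sum())
    return stat


def _jt_exact(groups: list[np.ndarray], observed: float) -> tuple[float, float]:
    """Exact one-sided p-values by full enumeration of group assignments."""
    pooled = np.concatenate(groups)
    sizes = [len(g) for g in groups]
    n = pooled.size
    ge = le = total = 0

    def rec(available: tuple[int, ...], gi: int, chosen: list[np.ndarray]):
        nonlocal ge, le, total
        if gi == len(sizes) - 1:
            grp = [*chosen, pooled[list(available)]]
            s = _jt_statistic(grp)
            total += 1
            if s >= observed - 1e-12:
                ge += 1
            if s <= observed + 1e-12:
                le += 1
            return
        for comb in combinations(available, sizes[gi]):
            rest = tuple(i for i in available if i not in set(comb))
            rec(rest, gi + 1, chosen + [pooled[list(comb)]])

    rec(tuple(range(n)), 0, [])
    return ge / total, le / total


def jt_trend_test(
    scores: np.ndarray,
    categories: np.ndarray,
    order: list | None = None,
    exact_max_n: int = 10,
) -> dict:
    """Jonckheere–Terpstra test for a monotone trend across ordered groups.

    ``categories`` are ordered by ``order`` (default: sorted unique values).
    Exact p by full enumeration when the total sample size is ≤
    ``exact_max_n``; otherwise a normal approximation with the standard tie
    correction.  Returns the statistic with one-sided (increasing trend) and
    two-sided p-values.
    """
    scores = np.asarray(scores, dtype=float)
    categories = np.asarray(categories)
    if order is None:
        order = sorted(pd.unique(categories))
    groups = [scores[categories == c] for c in order]
    groups = [g for g in groups if len(g)]
    if len(groups) < 2:
        raise ValueError("need at least 2 non-empty ordered categories")
    stat = _jt_statistic(groups)
    n = sum(len(g) for g in groups)

    if n <= exact_max_n:
        p_ge, p_le = _jt_exact(groups, stat)
        return {
            "statistic": stat,
            "p_one_sided": p_ge,
            "p_two_sided": min(1.0, 2.0 * min(p_ge, p_le)),
            "method": "exact",
        }

    sizes = np.array([len(g) for g in groups], dtype=float)
    pooled = np.concatenate(groups)
    _, tie_counts = np.unique(pooled, return_counts=True)
    t = tie_counts.astype(float)
    N = float(n)
    mean = (N**2 - (sizes**2).sum()) / 4.0
    term1 = (
        N * (N - 1) * (2 * N + 5)
        - (sizes * (sizes - 1) * (2 * sizes + 5)).sum()
        - (t * (t - 1) * (2 * t + 5)).sum()
    ) / 72.0
    term2 = (
        (sizes * (sizes - 1) * (sizes - 2)).sum()
        * (t * (t - 1) * (t - 2)).sum()
        / (36.0 * N * (N - 1) * (N - 2))
    )
    term3 = (
        (sizes * (sizes - 1)).sum() * (t * (t - 1)).sum() / (8.0 * N * (N - 1))
    )
    var = term1 + term2 + term3
    if var <= 0:
        raise ValueError("degenerate trend test (zero variance)")
    z = (stat - mean) / np.sqrt(var)
    p_up = float(norm.sf(z))
    p_down = float(norm.cdf(z))
    return {
        "statistic": stat,
        "z": float(z),
        "p_one_sided": p_up,
        "p_two_sided": min(1.0, 2.0 * min(p_up, p_down)),
        "method": "normal",
    }
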