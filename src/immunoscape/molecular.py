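"""Molecular correlates of the infiltration score.

Gene expression (genes × samples) is related to a per-sample score by
Pearson correlation with t-distribution p-values, controlled for multiple
testing with Storey-type q-values: the null proportion π₀ is estimated from
the p-values falling in the top quarter of the unit interval (λ = 0.75) and
multiplies the Benjamini–Hochberg step-up quantity, so forcing π₀ = 1
recovers BH exactly.

Co-expression modules among the score-associated genes are found by average
-linkage hierarchical clustering of the gene–gene correlation matrix (using
1 − r as the distance, which keeps anticorrelated genes apart; positively
and negatively score-associated pools are clustered separately), cutting the
tree into 100 clusters and keeping clusters with mean pairwise |r| > 0.75
and at least 6 members.

Gene-set enrichment of a hit list against a GMT collection uses the
upper-tail hypergeometric test, with BH adjustment across sets reported
alongside the raw p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import hypergeom
from scipy.stats import t as t_dist

from .survival import cox_model


# ---------------------------------------------------------------------------
# correlation and q-values
# ---------------------------------------------------------------------------

def correlate_genes(
    score: pd.Series, expr: pd.DataFrame, q_threshold: float = 0.05
) -> pd.DataFrame:
    """Per-gene Pearson correlation of expression with a per-sample score.

    ``score`` is indexed by sample id; ``expr`` has genes in rows and samples
    in columns.  Samples are matched on shared ids (≥ 3 required).  Returns a
    table with r, p (two-sided t transform), Storey q, a significance flag at
    ``q < q_threshold``, and the direction of significant correlations.
    Zero-variance genes are emitted with ``flag='zero_variance'`` and excluded
    from testing.
    """
    shared = [c for c in expr.columns if c in score.index]
    if len(shared) < 3:
        raise ValueError("need at least 3 matched samples")
    z = score.loc[shared].to_numpy(dtype=float)
    X = expr[shared].to_numpy(dtype=float)
    n = len(shared)

    zc = z - z.mean()
    Xc = X - X.mean(axis=1, keepdims=True)
    z_ss = float(zc @ zc)
    x_ss = (Xc**2).sum(axis=1)
    if z_ss == 0:
        raise ValueError("score has zero variance")
    ok = x_ss > 0
    r = np.full(X.shape[0], np.nan)
    r[ok] = (Xc[ok] @ zc) / np.sqrt(x_ss[ok] * z_ss)
    r = np.clip(r, -1.0, 1.0)

    p = np.full(X.shape[0], np.nan)
    with np.errstate(divide="ignore"):
        tstat = r[ok] * np.sqrt((n - 2) / np.maximum(1.0 - r[ok] ** 2, 1e-300))
    p[ok] = 2.0 * t_dist.sf(np.abs(tstat), df=n - 2)
    p[ok & (np.abs(r) >= 1.0)] = 0.0

    q = np.full(X.shape[0], np.nan)
    q[ok], pi0 = estimate_qvalues(p[ok])

    out = pd.DataFrame(
        {
            "gene": expr.index,
            "r": r,
            "p": p,
            "q": q,
            "flag": np.where(ok, "", "zero_variance"),
        }
    )
    sig = (out["q"] < q_threshold) & ok
    out["significant"] = sig
    out["direction"] = np.where(
        sig, np.where(out["r"] > 0, "positive", "negative"), ""
    )
    out.attrs["pi0"] = pi0
    out.attrs["n_samples"] = n
    return out


def estimate_qvalues(
    p: np.ndarray, lam: float = 0.75, pi0: float | None = None
) -> tuple[np.ndarray, float]:
    """Storey q-values with π₀ estimated from p-values above ``lam``.

    π₀ = #{p > λ} / (m·(1 − λ)), clipped to (0, 1] (floored at 1/m so a
    fully-signal input does not zero every q).  With ``pi0=1`` the result is
    exactly the Benjamini–Hochberg step-up adjustment.  q is monotone
    non-decreasing in p.
    """
    p = np.asarray(p, dtype=float).ravel()
    m = p.size
    if m == 0:
        raise ValueError("empty p-value array")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if pi0 is None:
        pi0 = (p > lam).sum() / (m * (1.0 - lam))
        pi0 = float(min(1.0, max(pi0, 1.0 / m)))
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / (np.arange(m) + 1.0)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1] * pi0
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q, pi0


# ---------------------------------------------------------------------------
# gene modules
# ---------------------------------------------------------------------------

@dataclass
class GeneModule:
    """A tightly co-expressed gene cluster."""

    module_id: str
    genes: list
    mean_abs_r: float
    sign: str = ""  # "positive"/"negative" score-association pool

    @property
    def size(self) -> int:
        return len(self.genes)


def find_modules(
    expr: pd.DataFrame,
    n_clusters: int = 100,
    r_min: float = 0.75,
    min_size: int = 6,
    method: str = "average",
    features: str = "profile",
    sign: str = "",
) -> list[GeneModule]:
    """Tightly connected modules among score-associated genes.

    Hierarchically clusters the gene–gene Pearson correlation matrix of
    ``expr`` (genes × samples), cuts the tree into
    ``min(n_clusters, n_genes)`` clusters, and keeps clusters whose mean
    pairwise |r| exceeds ``r_min`` with at least ``min_size`` members ("size
    exceeding five" read strictly).  Fewer than ``min_size`` input genes
    yield an empty list with a warning.

    ``features`` controls what is clustered.  ``"profile"`` (default) treats
    each gene's row of correlations as its feature vector (Euclidean
    distance): co-module genes share near-identical profiles while unrelated
    genes concentrate at a common background distance, which keeps modules
    pure even among many uncorrelated genes.  ``"distance"`` clusters the
    condensed 1 − r matrix directly; with a fixed cluster-count cut this is
    prone to absorbing unrelated genes into tight modules and is retained
    for comparison.
    """
    genes = list(expr.index)
    n_genes = len(genes)
    if n_genes < min_size:
        warnings.warn(f"only {n_genes} genes; no module can reach size {min_size}", stacklevel=2)
        return []
    corr = np.corrcoef(expr.to_numpy(dtype=float))
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    if features == "profile":
        Z = linkage(corr, method=method)
    elif features == "distance":
        dist = 1.0 - corr
        np.fill_diagonal(dist, 0.0)
        Z = linkage(squareform(dist, checks=False), method=method)
    else:
        raise ValueError(f"unknown features mode {features!r}")
    labels = fcluster(Z, t=min(n_clusters, n_genes), criterion="maxclust")
    modules = []
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        if idx.size < min_size:
            continue
        sub = np.abs(corr[np.ix_(idx, idx)])
        mean_abs = float((sub.sum() - idx.size) / (idx.size * (idx.size - 1)))
        if mean_abs > r_min:
            modules.append(
                GeneModule("", [genes[i] for i in idx], mean_abs, sign)
            )
    modules.sort(key=lambda mo: -mo.size)
    prefix = {"positive": "P", "negative": "N"}.get(sign, "M")
    for i, mo in enumerate(modules, start=1):
        mo.module_id = f"{prefix}{i}"
    return modules


def find_modules_by_sign(
    correlations: pd.DataFrame, expr: pd.DataFrame, **kwargs
) -> list[GeneModule]:
    """Cluster positively and negatively score-associated genes separately."""
    modules = []
    for sign in ("positive", "negative"):
        pool = correlations.loc[correlations["direction"] == sign, "gene"]
        pool = [g for g in pool if g in expr.index]
        if not pool:
            continue
        modules.extend(find_modules(expr.loc[pool], sign=sign, **kwargs))
    return modules


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

def read_gmt(path) -> dict:
    """Parse a GMT gene-set file: one tab-separated set per line
    (name, description, genes...)."""
    sets = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def hypergeom_enrichment(
    hits: list, gene_sets: dict, universe: list
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of a hit list per gene set.

    p = P(overlap ≥ observed) drawing |hits| genes from a universe of size M
    containing the (universe-intersected) set.  BH-adjusted p across sets is
    reported alongside the raw value.
    """
    universe_set = set(universe)
    hit_set = set(hits)
    if not universe_set:
        raise ValueError("empty universe")
    if not hit_set:
        raise ValueError("empty hit list")
    if not hit_set <= universe_set:
        raise ValueError("hits must be a subset of the universe")
    M, N = len(universe_set), len(hit_set)
    rows = []
    for name, genes in gene_sets.items():
        in_universe = set(genes) & universe_set
        k = len(in_universe & hit_set)
        n = len(in_universe)
        p = float(hypergeom.sf(k - 1, M, n, N)) if n else 1.0
        rows.append(
            {"set": name, "set_size": n, "overlap": k, "p": min(p, 1.0)}
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adj"], _ = estimate_qvalues(out["p"].to_numpy(), pi0=1.0)
    return out


# ---------------------------------------------------------------------------
# ITLR vs single-gene stratification
# ---------------------------------------------------------------------------

def _gene_grouping(values: np.ndarray, scheme: str) -> np.ndarray:
    """Rank-based patient grouping from one gene's expression."""
    order = np.argsort(np.argsort(values, kind="mergesort"), kind="mergesort")
    n = values.size
    if scheme == "median2":
        return (order >= n // 2).astype(int)
    if scheme == "p25_50_25":
        lo = n // 4
        hi = n - lo
        return np.where(order < lo, 0, np.where(order < hi, 1, 2))
    raise ValueError(f"unknown grouping scheme {scheme!r}")


def compare_score_vs_gene(
    score_group: np.ndarray,
    expr: pd.DataFrame,
    clinical: pd.DataFrame,
    genes: list | None = None,
    gene_grouping: str = "median2",
) -> pd.DataFrame:
    """Paired Cox models: dichotomized score versus single-gene stratification.

    For each gene a multivariate Cox model contains the score group (high
    coded 1) and a rank-based gene grouping (``median2`` halves or
    ``p25_50_25`` lower-quarter/middle-half/upper-quarter ordinal).  Reports
    HR, p and −log10 p per term; a gene grouping identical to the score
    grouping (collinear design) is flagged and skipped, as are
    non-convergent fits.
    """
    score_group = np.asarray(score_group, dtype=int)
    if genes is None:
        genes = list(expr.index)
    rows = []
    for gene in genes:
        gvals = expr.loc[gene].to_numpy(dtype=float)
        ggrp = _gene_grouping(gvals, gene_grouping)
        if len(np.unique(ggrp)) < 2 or np.all(ggrp == score_group) or np.all(
            ggrp == 1 - score_group
        ):
            rows.append(
                {"gene": gene, "collinear": True, "converged": False,
                 "hr_score": np.nan, "p_score": np.nan,
                 "hr_gene": np.nan, "p_gene": np.nan}
            )
            continue
        df = clinical.assign(score_high=score_group, gene_group=ggrp)
        res = cox_model(df, ["score_high", "gene_group"])
        if not res["converged"]:
            rows.append(
                {"gene": gene, "collinear": False, "converged": False,
                 "hr_score": np.nan, "p_score": np.nan,
                 "hr_gene": np.nan, "p_gene": np.nan}
            )
            continue
        tab = res["table"].set_index("term")
        rows.append(
            {
                "gene": gene,
                "collinear": False,
                "converged": True,
                "hr_score": float(tab.loc["score_high", "hr"]),
                "p_score": float(tab.loc["score_high", "p"]),
                "hr_gene": float(tab.loc["gene_group", "hr"]),
                "p_gene": float(tab.loc["gene_group", "p"]),
            }
        )
    out = pd.DataFrame(rows)
    with np.errstate(divide="ignore"):
        out["neglog10_p_score"] = -np.log10(out["p_score"])
        out["neglog10_p_gene"] = -np.log10(out["p_gene"])
    return out
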