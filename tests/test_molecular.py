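import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom, pearsonr

from immunoscape.molecular import (
    compare_score_vs_gene,
    correlate_genes,
    estimate_qvalues,
    find_modules,
    find_modules_by_sign,
    hypergeom_enrichment,
    read_gmt,
)
from immunoscape.synthetic import ExprSimParams, simulate_expression


def _toy_expression(seed=0, n=10, n_genes=6):
    rng = np.random.default_rng(seed)
    samples = [f"S{i}" for i in range(n)]
    score = pd.Series(rng.normal(size=n), index=samples)
    X = rng.normal(size=(n_genes, n))
    expr = pd.DataFrame(X, index=[f"g{i}" for i in range(n_genes)], columns=samples)
    return score, expr


def test_correlation_identities():
    score, expr = _toy_expression()
    expr.loc["g0"] = score.to_numpy()
    expr.loc["g1"] = -score.to_numpy()
    expr.loc["g2"] = 7.0  # constant gene
    out = correlate_genes(score, expr).set_index("gene")
    assert out.loc["g0", "r"] == pytest.approx(1.0)
    assert out.loc["g1", "r"] == pytest.approx(-1.0)
    assert out.loc["g0", "p"] == 0.0
    assert out.loc["g2", "flag"] == "zero_variance"
    assert np.isnan(out.loc["g2", "r"])


def test_correlation_matches_scipy_pearsonr():
    score, expr = _toy_expression(seed=1)
    out = correlate_genes(score, expr).set_index("gene")
    for g in expr.index:
        r_ref, p_ref = pearsonr(expr.loc[g].to_numpy(), score.to_numpy())
        assert out.loc[g, "r"] == pytest.approx(r_ref, abs=1e-12)
        assert out.loc[g, "p"] == pytest.approx(p_ref, abs=1e-12)


def test_correlation_requires_matched_samples():
    score, expr = _toy_expression()
    with pytest.raises(ValueError, match="matched"):
        correlate_genes(score.iloc[:2], expr[expr.columns[:2]])


def test_qvalues_with_pi0_one_equal_bh():
    from _oracles import bh_adjust

    rng = np.random.default_rng(2)
    p = rng.uniform(size=500)
    q, pi0 = estimate_qvalues(p, pi0=1.0)
    assert pi0 == 1.0
    np.testing.assert_allclose(q, bh_adjust(p), atol=1e-15)


def test_qvalues_monotone_in_p():
    rng = np.random.default_rng(3)
    p = np.concatenate([rng.uniform(0, 1e-3, 50), rng.uniform(size=500)])
    q, _ = estimate_qvalues(p)
    order = np.argsort(p)
    assert (np.diff(q[order]) >= -1e-15).all()


def test_qvalues_null_yields_no_discoveries():
    rng = np.random.default_rng(4)
    q, pi0 = estimate_qvalues(rng.uniform(size=10_000))
    assert (q >= 0.05).all()
    assert 0.9 < pi0 <= 1.0


def test_qvalues_validate_input():
    with pytest.raises(ValueError, match="empty"):
        estimate_qvalues(np.array([]))
    with pytest.raises(ValueError, match="0, 1"):
        estimate_qvalues(np.array([0.5, 1.5]))


def test_planted_gene_recovery_sensitivity_and_fdp():
    rng = np.random.default_rng(5)
    scores = rng.lognormal(-4, 1, 181)
    expr, truth = simulate_expression(
        scores,
        ExprSimParams(n_genes=2000, n_correlated=60, n_negative=40,
                      r_target=0.6, seed=55),
    )
    score = pd.Series(scores, index=expr.columns)
    out = correlate_genes(score, expr)
    hits = set(out.loc[out["significant"], "gene"])
    planted = set(truth["positive_genes"]) | set(truth["negative_genes"])
    sensitivity = len(hits & planted) / len(planted)
    fdp = len(hits - planted) / max(len(hits), 1)
    assert sensitivity >= 0.9
    assert fdp <= 0.1
    # direction split mirrors the planted signs
    pos = set(out.loc[out["direction"] == "positive", "gene"])
    assert set(truth["positive_genes"]) & hits <= pos


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------

def _planted_block_expression(seed=6, block_rho=0.85, sizes=(8, 10, 12), n_null=470):
    rng = np.random.default_rng(seed)
    scores = rng.normal(size=181)
    expr, truth = simulate_expression(
        scores,
        ExprSimParams(
            n_genes=sum(sizes) + n_null,
            n_correlated=0,
            module_spec=[(s, block_rho) for s in sizes],
            seed=seed + 1,
        ),
    )
    return expr, truth


def test_planted_blocks_recovered_exactly():
    expr, truth = _planted_block_expression()
    modules = find_modules(expr)
    found = sorted([frozenset(m.genes) for m in modules], key=len)
    want = sorted([frozenset(g) for g in truth["modules"]], key=len)
    assert found == want  # Jaccard 1 against the planted truth


def test_small_or_weak_blocks_rejected():
    expr, truth = _planted_block_expression(seed=7, sizes=(5, 10))
    # size-5 block at high correlation: excluded by the "size exceeding five" rule
    modules = find_modules(expr)
    assert frozenset(truth["modules"][0]) not in {frozenset(m.genes) for m in modules}
    assert frozenset(truth["modules"][1]) in {frozenset(m.genes) for m in modules}
    # size-10 block at |r| ≈ 0.6: excluded by the correlation rule
    expr2, truth2 = _planted_block_expression(seed=8, block_rho=0.6, sizes=(10,))
    assert all(
        frozenset(truth2["modules"][0]) != frozenset(m.genes)
        for m in find_modules(expr2)
    )


def test_modules_invariant_to_gene_order():
    expr, _ = _planted_block_expression(seed=9, sizes=(8, 10), n_null=100)
    rng = np.random.default_rng(10)
    shuffled = expr.iloc[rng.permutation(len(expr))]
    a = {frozenset(m.genes) for m in find_modules(expr)}
    b = {frozenset(m.genes) for m in find_modules(shuffled)}
    assert a == b


def test_too_few_genes_warns_empty():
    expr, _ = _planted_block_expression(seed=11, sizes=(8,), n_null=0)
    with pytest.warns(UserWarning, match="no module"):
        assert find_modules(expr.iloc[:3]) == []


def test_find_modules_by_sign_pools_separately():
    rng = np.random.default_rng(12)
    scores = rng.lognormal(-4, 1, 181)
    expr, truth = simulate_expression(
        scores,
        ExprSimParams(n_genes=100, n_correlated=20, n_negative=20,
                      r_target=0.9, seed=60),
    )
    score = pd.Series(scores, index=expr.columns)
    corr = correlate_genes(score, expr)
    modules = find_modules_by_sign(corr, expr, n_clusters=5, r_min=0.5, min_size=6)
    signs = {m.sign for m in modules}
    assert signs <= {"positive", "negative"}
    for m in modules:  # no module mixes the two pools
        pool = truth["positive_genes"] if m.sign == "positive" else truth["negative_genes"]
        assert set(m.genes) <= set(pool)


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

def test_hypergeometric_closed_form():
    universe = [f"u{i}" for i in range(20)]
    gene_set = {"setA": universe[:5]}
    out = hypergeom_enrichment(universe[:5], gene_set, universe)
    from math import comb

    assert out.iloc[0]["p"] == pytest.approx(1 / comb(20, 5))
    # zero overlap → P(X ≥ 0) = 1
    out0 = hypergeom_enrichment(universe[5:10], {"setA": universe[:5]}, universe)
    assert out0.iloc[0]["p"] == 1.0


def test_hypergeometric_pmf_normalized():
    total = sum(hypergeom.pmf(k, 20, 5, 5) for k in range(6))
    assert total == pytest.approx(1.0, abs=1e-12)


def test_enrichment_validates_inputs():
    with pytest.raises(ValueError, match="universe"):
        hypergeom_enrichment(["a"], {}, [])
    with pytest.raises(ValueError, match="subset"):
        hypergeom_enrichment(["zzz"], {}, ["a", "b"])


def test_read_gmt_roundtrip(tmp_path):
    path = tmp_path / "sets.gmt"
    path.write_text("setA\tdesc\tg1\tg2\tg3\nsetB\tdesc\tg2\tg4\n")
    sets = read_gmt(path)
    assert sets == {"setA": ["g1", "g2", "g3"], "setB": ["g2", "g4"]}


# ---------------------------------------------------------------------------
# ITLR vs gene stratification
# ---------------------------------------------------------------------------

def test_grouping_sizes_quartile_scheme():
    from immunoscape.molecular import _gene_grouping

    rng = np.random.default_rng(13)
    g = _gene_grouping(rng.normal(size=180), "p25_50_25")
    counts = np.bincount(g)
    assert list(counts) == [45, 90, 45]
    g2 = _gene_grouping(rng.normal(size=180), "median2")
    assert list(np.bincount(g2)) == [90, 90]


def test_score_term_beats_noise_gene():
    from immunoscape.synthetic import SurvSimParams, simulate_survival

    rng = np.random.default_rng(14)
    scores = rng.lognormal(-4, 1, 180)
    clin = simulate_survival(
        scores, SurvSimParams(n_patients=180, hazard_ratio=0.25, censor_rate=0.002, seed=70)
    )
    expr = pd.DataFrame(
        rng.normal(size=(3, 180)), index=["noise1", "noise2", "noise3"],
        columns=clin["sample_id"],
    )
    out = compare_score_vs_gene(
        clin["true_group_high"].to_numpy(), expr, clin, gene_grouping="median2"
    )
    assert (out["p_score"] < 0.05).sum() >= 2  # planted effect detected
    assert (out["p_gene"] > 0.05).sum() >= 2  # noise genes stay null


def test_collinear_gene_grouping_flagged():
    rng = np.random.default_rng(15)
    from immunoscape.synthetic import SurvSimParams, simulate_survival

    scores = rng.lognormal(-4, 1, 60)
    clin = simulate_survival(
        scores,
        SurvSimParams(n_patients=60, hazard_ratio=0.3, low_fraction=0.5, seed=71),
    )
    group = clin["true_group_high"].to_numpy()  # balanced → median2 twin grouping

    # a gene whose expression is exactly the score grouping
    expr = pd.DataFrame([group.astype(float)], index=["twin"], columns=clin["sample_id"])
    out = compare_score_vs_gene(group, expr, clin, gene_grouping="median2")
    assert bool(out.iloc[0]["collinear"])
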