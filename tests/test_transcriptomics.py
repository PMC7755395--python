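import math

import numpy as np
import pandas as pd
import pytest

from neuroscales.spatial import inverse_distance_weights, msr_nulls
from neuroscales.synthetic import (
    generate_expression_matrix,
    generate_sa_map,
    generate_toy_ontology,
)
from neuroscales.transcriptomics import (
    ExpressionMatrix,
    GeneAnnotation,
    correlate_genes_with_map,
    cross_scale_comparison,
    expression_pca,
    fisher_exact_pvalues,
    go_enrichment,
    null_pls_gene_selection,
    pls1_weights,
    residualize,
    select_brain_specific,
)


@pytest.fixture(scope="module")
def map_and_nulls(geometry, smooth_map):
    W = inverse_distance_weights(geometry.parcel_distance)
    return smooth_map, msr_nulls(smooth_map, W, n_null=300, seed=77)


# -- selection ---------------------------------------------------------------

def test_brain_specific_strict_fourfold_rule():
    df = pd.DataFrame(
        {
            "brain": [8.0, 9.0, 1.0],
            "t1": [2.0, 2.0, 1.0],
            "t2": [2.0, 2.0, 1.0],
            "t3": [2.0, 2.0, 1.0],
        },
        index=["boundary", "enriched", "flat"],
    )
    got = select_brain_specific(df, ["brain"])
    assert got == ["enriched"]  # 8 = 4 x 2 is excluded by strict inequality


def test_brain_specific_planted_fixture(rng):
    n = 200
    base = rng.uniform(1, 3, (n, 6))
    planted = rng.choice(n, 40, replace=False)
    df = pd.DataFrame(base, columns=[f"t{i}" for i in range(5)] + ["brain"],
                      index=[f"g{i}" for i in range(n)])
    med = df.median(axis=1)
    # 20x the pre-modification median stays >4x even after the brain column
    # itself shifts the per-gene median
    df.loc[df.index[planted], "brain"] = 20.0 * med.iloc[planted]
    got = set(select_brain_specific(df, ["brain"]))
    assert got == {f"g{i}" for i in planted}


def test_brain_specific_zero_median_kept_iff_positive():
    df = pd.DataFrame(
        {"brain": [1.0, 0.0], "t1": [0.0, 0.0], "t2": [0.0, 0.0]},
        index=["on", "off"],
    )
    assert select_brain_specific(df, ["brain"]) == ["on"]


# -- PCA -----------------------------------------------------------------------

def test_pca_rank_one(rng):
    grad = rng.standard_normal(40)
    X = np.outer(rng.uniform(0.5, 2.0, 30), grad)
    X = (X - X.mean(1, keepdims=True)) / X.std(1, keepdims=True)
    expr = ExpressionMatrix(X, np.arange(30), normalized=True)
    res = expression_pca(expr, 3)
    assert res.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-10)


def test_pca_gene_order_invariance_and_descending_evr(geometry, smooth_map, rng):
    expr, _ = generate_expression_matrix(geometry, smooth_map, 120, 30, 1.0, 0.5, seed=4)
    norm = expr.normalize()
    res = expression_pca(norm, 5)
    perm = rng.permutation(expr.n_genes)
    shuffled = ExpressionMatrix(norm.X[perm], norm.gene_ids[perm], normalized=True)
    res_p = expression_pca(shuffled, 5)
    np.testing.assert_allclose(res_p.components, res.components, atol=1e-8)
    evr = res.explained_variance_ratio
    assert np.all(np.diff(evr) <= 1e-12) and evr.sum() <= 1.0 + 1e-12


def test_pca_recovers_planted_gradient(geometry, smooth_map):
    from scipy.stats import spearmanr

    expr, _ = generate_expression_matrix(geometry, smooth_map, 400, 120, 1.5, 0.5, seed=5)
    res = expression_pca(expr.normalize(), 2)
    rho = spearmanr(res.components[:, 0], smooth_map.values).statistic
    assert abs(rho) >= 0.95


def test_pca_full_reconstruction(rng):
    X = rng.standard_normal((25, 12))
    X = (X - X.mean(1, keepdims=True)) / X.std(1, keepdims=True)
    expr = ExpressionMatrix(X, np.arange(25), normalized=True)
    res = expression_pca(expr, 12)
    np.testing.assert_allclose(res.scores @ res.components.T, X, atol=1e-8)


def test_pca_requires_normalization_and_valid_k(rng):
    expr = ExpressionMatrix(rng.standard_normal((10, 8)), np.arange(10))
    with pytest.raises(ValueError, match="normalized"):
        expression_pca(expr, 2)
    with pytest.raises(ValueError, match="rank"):
        expression_pca(expr.normalize(), 9)


# -- per-gene correlation ------------------------------------------------------

def test_correlate_genes_identity_and_calibration(geometry, map_and_nulls, rng):
    smooth_map, nulls = map_and_nulls
    X = rng.standard_normal((50, 180))
    X[0] = smooth_map.values
    expr = ExpressionMatrix(X, np.arange(50))
    out = correlate_genes_with_map(expr, smooth_map.values, nulls)
    assert out.loc[0, "rho"] == pytest.approx(1.0)
    assert out.loc[0, "p_sa"] == pytest.approx(1.0 / (nulls.n_null + 1))


def test_correlate_genes_planted_dominate(geometry, smooth_map, map_and_nulls):
    _, nulls = map_and_nulls
    expr, truth = generate_expression_matrix(geometry, smooth_map, 300, 40, 1.0, 0.5, seed=6)
    out = correlate_genes_with_map(expr, smooth_map.values, nulls)
    planted = out["gene_id"].isin(truth.associated_genes)
    assert out.loc[planted, "rho"].abs().median() > out.loc[~planted, "rho"].abs().median()


# -- residualization -----------------------------------------------------------

def test_residualize_exact_and_orthogonal_cases(rng):
    x = rng.standard_normal(80)
    y = 2.0 * x + 3.0
    np.testing.assert_allclose(residualize(y, x), 0.0, atol=1e-12)
    y2 = rng.standard_normal(80)
    y2 -= np.polyval(np.polyfit(x, y2, 1), x)  # orthogonalize
    res = residualize(y2 + 5.0, x)
    np.testing.assert_allclose(res, y2 - y2.mean(), atol=1e-10)
    assert abs(np.corrcoef(residualize(y2 + x, x), x)[0, 1]) < 1e-10
    with pytest.raises(ValueError, match="constant"):
        residualize(y, np.ones(80))


def test_residualize_construction_check(geometry, smooth_map, rng):
    from neuroscales.synthetic import sa_field

    noise = sa_field(geometry.parcel_distance, 20.0, rng)
    y = smooth_map.values + noise
    r = residualize(y, smooth_map.values)
    assert abs(np.corrcoef(r, smooth_map.values)[0, 1]) < 1e-10
    assert np.corrcoef(r, noise)[0, 1] > 0.6


# -- PLS -----------------------------------------------------------------------

def test_pls1_weights_covariance_direction(rng):
    y = rng.standard_normal(60)
    X = rng.standard_normal((30, 60))
    w = pls1_weights(X, y)
    yc = y - y.mean()
    cov = (X - X.mean(1, keepdims=True)) @ yc
    np.testing.assert_allclose(w, cov / np.linalg.norm(cov), rtol=1e-12)
    assert np.linalg.norm(w) == pytest.approx(1.0, rel=1e-12)


def test_pls1_self_predictor_dominates_and_invariances(rng):
    y = rng.standard_normal(60)
    X = rng.standard_normal((20, 60))
    X[7] = y
    w = pls1_weights(X, y)
    assert np.argmax(np.abs(w)) == 7
    np.testing.assert_allclose(pls1_weights(X, 3.7 * y), w, rtol=1e-12)
    perm = rng.permutation(20)
    np.testing.assert_allclose(pls1_weights(X[perm], y), w[perm], rtol=1e-12)
    with pytest.raises(ValueError, match="variance"):
        pls1_weights(X, np.ones(60))


def test_pls1_matches_sklearn_first_component(rng):
    from sklearn.cross_decomposition import PLSRegression

    X = rng.standard_normal((40, 25))  # genes x parcels
    y = rng.standard_normal(25)
    w = pls1_weights(X, y)
    pls = PLSRegression(n_components=1, scale=False).fit(X.T, y)
    w_sk = pls.x_weights_[:, 0]
    if np.dot(w_sk, w) < 0:
        w_sk = -w_sk
    np.testing.assert_allclose(w, w_sk, rtol=1e-8)


def test_null_pls_selection_recovery_small(geometry, smooth_map, map_and_nulls):
    _, nulls = map_and_nulls
    expr, truth = generate_expression_matrix(geometry, smooth_map, 300, 30, 1.0, 0.5, seed=8)
    sel = null_pls_gene_selection(expr.normalize().X, smooth_map.values, nulls,
                                  gene_ids=expr.gene_ids)
    planted = sel["gene_id"].isin(truth.associated_genes)
    assert sel.loc[planted, "significant"].mean() >= 0.8
    assert sel.loc[~planted, "significant"].mean() <= 0.1


def test_null_pls_small_ensemble_warns(geometry, smooth_map, rng, caplog):
    import logging

    from neuroscales.spatial import NullMapEnsemble

    X = rng.standard_normal((20, 180))
    tiny = NullMapEnsemble(nulls=rng.standard_normal((50, 180)),
                           source_map_id="m", seed=0)
    with caplog.at_level(logging.WARNING):
        null_pls_gene_selection(X, smooth_map.values, tiny)
    assert any("unstable" in r.message for r in caplog.records)


# -- enrichment ----------------------------------------------------------------

def test_fisher_matches_scipy_on_random_tables(rng):
    from scipy import stats

    for _ in range(150):
        N = int(rng.integers(2, 70))
        n = int(rng.integers(0, N + 1))
        B = int(rng.integers(0, N + 1))
        kmin, kmax = max(0, n + B - N), min(n, B)
        b = int(rng.integers(kmin, kmax + 1))
        mine = fisher_exact_pvalues(N, n, B)[b - kmin]
        ref = stats.fisher_exact([[b, n - b], [B - b, N - n - B + b]])[1]
        assert mine == pytest.approx(ref, abs=1e-12)


def toy_annotation():
    genes = [f"g{i}" for i in range(20)]
    ann = GeneAnnotation(
        {"T:1": set(genes[:4]), "T:all": set(genes), "T:out": set(genes[10:18])},
        {"T:1": ("term one", "BP"), "T:all": ("everything", "CC"),
         "T:out": ("disjoint", "MF")},
    )
    return genes, ann


def test_enrichment_toy_table_and_directions():
    genes, ann = toy_annotation()
    study = genes[:3] + [genes[5], genes[6]]  # n=5, overlap with T:1 is b=3
    out = go_enrichment(study, genes, ann).set_index("term_id")
    row = out.loc["T:1"]
    assert row["enrichment_ratio"] == pytest.approx(3.0)
    assert (row["N"], row["n"], row["B"], row["b"]) == (20, 5, 4, 3)
    # saturating term: every study gene annotated -> ratio 1
    assert out.loc["T:all", "enrichment_ratio"] == pytest.approx(1.0)
    assert out.loc["T:all", "p"] == pytest.approx(1.0)
    # disjoint term: purified direction
    assert out.loc["T:out", "b"] == 0
    assert out.loc["T:out", "enrichment_ratio"] == 0.0


def test_enrichment_study_equals_reference():
    genes, ann = toy_annotation()
    out = go_enrichment(genes, genes, ann)
    assert np.allclose(out["enrichment_ratio"], 1.0)
    assert np.allclose(out["p"], 1.0)


def test_enrichment_input_validation():
    genes, ann = toy_annotation()
    with pytest.raises(ValueError, match="empty"):
        go_enrichment([], genes, ann)
    with pytest.raises(ValueError, match="subset"):
        go_enrichment(["nope"], genes, ann)


def test_bh_qvalues_monotone(rng):
    genes = [f"g{i}" for i in range(40)]
    ann = generate_toy_ontology(genes, n_terms=25, term_size_range=(3, 20), seed=2)
    out = go_enrichment(genes[:10], genes, ann)
    q_sorted = out.sort_values("p")["q"].to_numpy()
    assert np.all(np.diff(q_sorted) >= -1e-12)
    assert np.all(out["q"] >= out["p"] - 1e-12)


def test_planted_term_attains_smallest_p(geometry, smooth_map, map_and_nulls):
    _, nulls = map_and_nulls
    expr, truth = generate_expression_matrix(geometry, smooth_map, 300, 30, 1.0, 0.5, seed=9)
    sel = null_pls_gene_selection(expr.normalize().X, smooth_map.values, nulls,
                                  gene_ids=expr.gene_ids)
    study = sel.loc[sel["significant"], "gene_id"].tolist()
    ann = generate_toy_ontology(
        expr.gene_ids, n_terms=20, term_size_range=(5, 40), seed=10,
        extra_terms={"TOY:PLANTED": (set(truth.associated_genes), "planted", "BP")},
    )
    out = go_enrichment(study, expr.gene_ids, ann)
    assert out.iloc[0]["term_id"] == "TOY:PLANTED"


# -- cross-scale ---------------------------------------------------------------

def cross_scale_inputs(rng, n=200):
    macro_rho = rng.uniform(-0.9, 0.9, n)
    macro = pd.DataFrame(
        {"gene_id": [f"g{i}" for i in range(n)], "rho": macro_rho,
         "p_sa": np.full(n, 0.01)}
    )
    return macro


def test_cross_scale_identity_and_null(rng):
    macro = cross_scale_inputs(rng)
    micro = pd.Series(macro["rho"].to_numpy(), index=macro["gene_id"])
    res = cross_scale_comparison(micro, macro)
    assert res["rho"] == pytest.approx(1.0)
    assert all(r == pytest.approx(1.0) for r in res["per_quantile_rho"])
    indep = pd.Series(rng.standard_normal(len(macro)), index=macro["gene_id"])
    res0 = cross_scale_comparison(indep, macro)
    assert abs(res0["rho"]) < 0.15


def test_cross_scale_quantile_trend(rng):
    macro = cross_scale_inputs(rng, n=600)
    rank = macro["rho"].abs().rank(pct=True).to_numpy()
    noise_sd = np.where(rank > 0.8, 0.05, np.where(rank > 0.6, 0.3, 1.8))
    micro = pd.Series(
        macro["rho"].to_numpy() + rng.standard_normal(600) * noise_sd,
        index=macro["gene_id"],
    )
    res = cross_scale_comparison(micro, macro)
    per_q = res["per_quantile_rho"]
    assert per_q[-1] > per_q[0]
    assert per_q[-1] > 0.8


def test_cross_scale_respects_significance_filter_and_min_join(rng):
    macro = cross_scale_inputs(rng, n=30)
    macro.loc[5:, "p_sa"] = 0.5  # only 5 significant genes remain
    micro = pd.Series(rng.standard_normal(30), index=macro["gene_id"])
    with pytest.raises(ValueError, match="joined"):
        cross_scale_comparison(micro, macro)
    res = cross_scale_comparison(micro, macro, restrict_significant=False)
    assert res["n_genes"] == 30
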