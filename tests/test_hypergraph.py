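import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from txhyper import (
    CorrelationMatrix,
    IncidenceMatrix,
    TranscriptomeHypergraph,
    binarize,
    build_correlation,
    clique_reduction,
    degree_rank,
)
from txhyper.hypergraph import CliqueReduction, HypergraphError

from conftest import make_adata


def inc(B):
    B = np.asarray(B, dtype=np.int8)
    return IncidenceMatrix(
        B=B,
        nodes=[f"n{i}" for i in range(B.shape[0])],
        edges=[f"e{j}" for j in range(B.shape[1])],
        tau=0.1,
    )


def brute_force_shared_edges(B):
    n = B.shape[0]
    M = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(n):
            M[i, j] = sum(int(B[i, e] and B[j, e]) for e in range(B.shape[1]))
    return M


# ---------------------------------------------------------------- correlation


def test_pearson_hand_example_and_copy_edge():
    norm = np.array(
        [
            [1.0, 1.0, 1.0],
            [2.0, 1.0, 2.0],
            [3.0, 4.0, 3.0],
            [4.0, 4.0, 4.0],
        ]
    )  # genes: node n, edge e, edge copy-of-n
    adata = make_adata(np.zeros_like(norm, int), gene_ids=["n", "e", "ncopy"], normalized=norm)
    corr = build_correlation(adata, ["n"], edge_genes=["e", "ncopy"])
    assert corr.values[0, 0] == pytest.approx(6 / (np.sqrt(5) * 3))
    assert corr.values[0, 1] == pytest.approx(1.0)
    # reference implementation cross-check
    assert corr.values[0, 0] == pytest.approx(np.corrcoef(norm[:, 0], norm[:, 1])[0, 1])


def test_constant_edge_gene_is_flagged_with_zero_correlation():
    norm = np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]])
    adata = make_adata(np.zeros_like(norm, int), gene_ids=["n", "flat"], normalized=norm)
    corr = build_correlation(adata, ["n"], edge_genes=["flat"])
    assert corr.values[0, 0] == 0.0
    assert corr.flagged_edges == ["flat"]


def test_correlation_input_validation():
    norm = np.ones((4, 3))
    adata = make_adata(np.zeros((4, 3), int), gene_ids=["a", "b", "c"], normalized=norm)
    with pytest.raises(HypergraphError, match="absent"):
        build_correlation(adata, ["missing"])
    with pytest.raises(HypergraphError, match="both node and edge"):
        build_correlation(adata, ["a"], edge_genes=["a", "b"])
    two_cells = make_adata(np.zeros((2, 3), int), gene_ids=["a", "b", "c"], normalized=np.ones((2, 3)))
    with pytest.raises(HypergraphError, match="at least 3 cells"):
        build_correlation(two_cells, ["a"])


# ------------------------------------------------------------------ binarize


def corr_from(values):
    values = np.asarray(values, float)
    return CorrelationMatrix(
        values=values,
        nodes=[f"n{i}" for i in range(values.shape[0])],
        edges=[f"e{j}" for j in range(values.shape[1])],
        method="pearson",
    )


def test_binarize_threshold_is_population_sd_of_entries():
    corr = corr_from([[0.9, 0.1], [-0.8, 0.2]])
    out = binarize(corr)
    assert out.tau == pytest.approx(np.std([0.9, 0.1, -0.8, 0.2]))
    assert out.tau == pytest.approx(0.60415, abs=1e-4)
    np.testing.assert_array_equal(out.B, [[1, 0], [1, 0]])


def test_binarize_degenerate_all_zero():
    out = binarize(corr_from(np.zeros((3, 4))))
    assert out.tau == 0.0
    assert out.B.sum() == 0  # strict inequality: |0| > 0 is false


def test_binarize_is_sign_symmetric():
    rng = np.random.default_rng(3)
    values = np.clip(rng.normal(0, 0.4, (6, 9)), -1, 1)
    np.testing.assert_array_equal(binarize(corr_from(values)).B, binarize(corr_from(-values)).B)


# ---------------------------------------------------------- clique reduction


def test_clique_reduction_worked_examples():
    np.testing.assert_array_equal(clique_reduction(inc(np.eye(3))).M, np.eye(3, dtype=int))
    B = [[1, 1, 0], [1, 0, 1], [0, 1, 1]]
    np.testing.assert_array_equal(
        clique_reduction(inc(B)).M, [[2, 1, 1], [1, 2, 1], [1, 1, 2]]
    )
    zero_row = [[0, 0, 0], [1, 1, 0], [0, 1, 1]]
    M = clique_reduction(inc(zero_row)).M
    assert M[0].sum() == 0 and M[:, 0].sum() == 0


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    st.integers(1, 12),
    st.integers(1, 18),
    st.integers(0, 2**31 - 1),
)
def test_clique_reduction_matches_bruteforce_counting(n, e, seed):
    B = np.random.default_rng(seed).integers(0, 2, (n, e))
    M = clique_reduction(inc(B)).M
    np.testing.assert_array_equal(M, brute_force_shared_edges(B))
    # conservation and bound invariants
    assert np.diag(M).sum() == B.sum()
    assert (M <= np.minimum.outer(np.diag(M), np.diag(M))).all()
    assert M.sum() == (B.sum(axis=0) ** 2).sum()


# -------------------------------------------------------------- degree ranks


def test_average_split_ranks_worked_example():
    # rowsums [5, 3, 5, 1] -> descending ranks [1.5, 3, 1.5, 4]
    B = np.array(
        [
            [1, 1, 1, 1, 1],
            [1, 1, 1, 0, 0],
            [1, 1, 1, 1, 1],
            [1, 0, 0, 0, 0],
        ]
    )
    table = degree_rank(inc(B), clique_reduction(inc(B)))
    np.testing.assert_array_equal(table["incidence_rowsum"], [5, 3, 5, 1])
    np.testing.assert_array_equal(table["rank_incidence"], [1.5, 3, 1.5, 4])


def test_full_tie_ranks_and_rank_sum_invariant():
    B = np.array([[1, 1, 0], [1, 0, 1], [0, 1, 1]])
    table = degree_rank(inc(B), clique_reduction(inc(B)))
    np.testing.assert_array_equal(table["incidence_rowsum"], [2, 2, 2])
    np.testing.assert_array_equal(table["clique_rowsum"], [2, 2, 2])
    assert (table["rank_incidence"] == 2).all()
    rng = np.random.default_rng(7)
    for _ in range(10):
        R = rng.integers(0, 2, (rng.integers(2, 15), rng.integers(1, 20)))
        t = degree_rank(inc(R), clique_reduction(inc(R)))
        n = len(t)
        assert t["rank_incidence"].sum() == pytest.approx(n * (n + 1) / 2)
        assert t["rank_clique"].sum() == pytest.approx(n * (n + 1) / 2)


# ------------------------------------------------------------- model objects


def test_model_fit_builds_consistent_results(small_sim):
    nodes = list(small_sim.var_names[:40])
    fit = TranscriptomeHypergraph(small_sim, nodes, cells="tissue == 'FT'").fit(k=2)
    assert fit.incidence.B.shape == (40, small_sim.n_vars - 40)
    assert fit.clique.M.shape == (40, 40)
    np.testing.assert_array_equal(fit.clique.M, fit.clique.M.T)
    np.testing.assert_array_equal(np.diag(fit.clique.M), fit.incidence.B.sum(axis=1))
    assert set(fit.central.members) <= set(nodes)
    assert fit.central.mean_member_rowsum >= fit.central.mean_nonmember_rowsum
    text = fit.summary()
    assert "tau" in text and "central cluster" in text


def test_spearman_option_is_rank_based(small_sim):
    nodes = list(small_sim.var_names[:5])
    edges = list(small_sim.var_names[5:25])
    pear = build_correlation(small_sim, nodes, edge_genes=edges, method="pearson")
    spear = build_correlation(small_sim, nodes, edge_genes=edges, method="spearman")
    assert spear.method == "spearman"
    assert not np.allclose(pear.values, spear.values)
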