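from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from txhyper import rank_sum_de, select_nodes
from txhyper.de import DEError

from conftest import make_adata


def u_statistic(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    return float(sum((x > y) + 0.5 * (x == y) for x in a for y in b))


def exact_p_enumeration(a, b):
    """Brute-force two-sided exact rank-sum p over all group assignments."""
    pooled = list(a) + list(b)
    na = len(a)
    obs = u_statistic(a, b)
    us = []
    for comb in combinations(range(len(pooled)), na):
        chosen = set(comb)
        ga = [pooled[i] for i in comb]
        gb = [pooled[i] for i in range(len(pooled)) if i not in chosen]
        us.append(u_statistic(ga, gb))
    us = np.array(us)
    return min(1.0, 2.0 * min((us <= obs).mean(), (us >= obs).mean()))


def de_adata(xa, xb):
    """AnnData with one gene per column of xa/xb, groups by tissue."""
    xa, xb = np.asarray(xa, float), np.asarray(xb, float)
    if xa.ndim == 1:
        xa = xa[:, None]
    if xb.ndim == 1:
        xb = xb[:, None]
    values = np.vstack([xa, xb])
    return make_adata(
        np.zeros_like(values, dtype=int),
        tissue=["FT"] * len(xa) + ["endometrium"] * len(xb),
        normalized=values,
    )


def test_exact_p_for_separated_samples_matches_enumeration():
    adata = de_adata(np.array([[1.0], [2.0], [3.0]]), np.array([[4.0], [5.0], [6.0]]))
    table = rank_sum_de(adata, "tissue == 'FT'", "tissue == 'endometrium'")
    assert table["U"].iloc[0] == 0
    assert table["p_value"].iloc[0] == pytest.approx(0.1)
    assert table["p_value"].iloc[0] == pytest.approx(
        exact_p_enumeration([1, 2, 3], [4, 5, 6])
    )
    assert table["direction"].iloc[0] == -1


def test_identical_groups_give_p_one():
    x = np.array([[1.0], [2.0], [3.0]])
    adata = de_adata(x, x)
    table = rank_sum_de(adata, "tissue == 'FT'", "tissue == 'endometrium'")
    assert table["p_value"].iloc[0] == pytest.approx(1.0)
    assert table["z"].iloc[0] == 0.0


def test_swapping_groups_preserves_p_and_flips_direction(small_sim):
    a, b = "tissue == 'FT'", "tissue == 'endometrium'"
    t1 = rank_sum_de(small_sim, a, b)
    t2 = rank_sum_de(small_sim, b, a)
    np.testing.assert_allclose(t1["p_value"], t2.loc[t1.index, "p_value"], rtol=1e-10)
    nonzero = t1["direction"] != 0
    assert (t1.loc[nonzero, "direction"] == -t2.loc[t1.index, "direction"][nonzero]).all()


def test_asymptotic_p_matches_scipy_with_ties(small_sim):
    """Cross-check the vectorized tie-corrected approximation against scipy."""
    table = rank_sum_de(small_sim, "tissue == 'FT'", "tissue == 'endometrium'")
    dense = small_sim.layers["normalized"].toarray()
    mask_a = np.asarray(small_sim.obs.eval("tissue == 'FT'"))
    mask_b = np.asarray(small_sim.obs.eval("tissue == 'endometrium'"))
    rng = np.random.default_rng(0)
    for j in rng.choice(small_sim.n_vars, 25, replace=False):
        gene = small_sim.var_names[j]
        ref = stats.mannwhitneyu(
            dense[mask_a, j], dense[mask_b, j], alternative="two-sided",
            method="asymptotic", use_continuity=True,
        )
        assert table.loc[gene, "p_value"] == pytest.approx(ref.pvalue, rel=1e-6, abs=1e-12)


def test_group_validation_errors():
    adata = de_adata(np.ones((3, 1)), np.ones((3, 1)))
    with pytest.raises(DEError, match="overlap"):
        rank_sum_de(adata, "tissue == 'FT'", "tissue == 'FT'")
    with pytest.raises(DEError, match="at least 2"):
        rank_sum_de(adata, "cell_id == 'r1'", "tissue == 'endometrium'")


def test_bh_adjustment_is_monotone_and_bounded(small_sim):
    table = rank_sum_de(small_sim, "tissue == 'FT'", "tissue == 'endometrium'")
    assert (table["p_adjusted"] >= table["p_value"] - 1e-15).all()
    ordered = table.sort_values("p_value")["p_adjusted"].to_numpy()
    assert (np.diff(ordered) >= -1e-12).all()
    assert table["p_value"].is_monotonic_increasing


def deg_table_from_scores(y):
    p = 10.0 ** (-np.asarray(y, float))
    return pd.DataFrame(
        {
            "p_value": p,
            "p_adjusted": p,
            "neg_log10_p": np.asarray(y, float),
            "direction": 1,
        },
        index=pd.Index([f"g{i}" for i in range(len(y))], name="gene"),
    )


def test_fixed_n_selection_and_clamp():
    table = deg_table_from_scores([9, 8, 7, 6, 5])
    assert select_nodes(table, n=3).genes == ["g0", "g1", "g2"]
    clamped = select_nodes(table, n=10)
    assert clamped.n_selected == 5
    with pytest.raises(DEError):
        select_nodes(table, n=0)


def test_inflection_cut_matches_bruteforce_chord_deviation():
    y = [100.0, 50.0, 4.0, 3.0, 2.0, 1.0]
    table = deg_table_from_scores(y)
    nodes = select_nodes(table, mode="inflection")
    # brute-force vertical deviation below the chord at every rank
    ranks = np.arange(1, 7)
    chord = y[0] + (y[-1] - y[0]) * (ranks - 1) / 5
    dev = chord - np.array(y)
    assert np.argmax(dev) + 1 == 3
    assert nodes.n_selected == 3
    assert nodes.genes == ["g0", "g1", "g2"]
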