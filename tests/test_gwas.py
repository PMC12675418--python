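import numpy as np
import pandas as pd
import pytest

from txhyper import map_and_intersect, rank_lookup, simulate_gwas_tables
from txhyper.cluster import CentralCluster
from txhyper.gwas import GwasError, validate_gwas_summary


def toy_tables():
    gwas = pd.DataFrame({"rsid": ["rs1", "rs2"], "p_value": [1e-9, 1e-3]})
    eqtl = pd.DataFrame(
        {"rsid": ["rs1", "rs2"], "gene": ["GENEA", "GENEB"], "tissue": ["FT", "FT"]}
    )
    return gwas, eqtl


def test_toy_mapping_and_node_intersection():
    gwas, eqtl = toy_tables()
    report = map_and_intersect(gwas, eqtl, ["GENEA", "GENEC"], n_lowest=10)
    assert report.n_genes_mapped == 2
    assert report.n_genes_in_nodes == 1
    assert report.table.loc["GENEA", "in_nodes"]
    assert report.table.loc["GENEA", "best_p"] == pytest.approx(1e-9)


def test_empty_eqtl_gives_zero_counts_without_error():
    gwas, _ = toy_tables()
    empty = pd.DataFrame(columns=["rsid", "gene", "tissue"])
    report = map_and_intersect(gwas, empty, ["GENEA"], n_lowest=10)
    assert report.n_genes_mapped == 0
    assert report.n_genes_in_nodes == 0
    assert report.n_rsids_mapped_to_nodes == 0


def test_report_is_invariant_to_input_row_order():
    tables = simulate_gwas_tables([f"G{i:03d}" for i in range(60)], n_variants=500, n_overlap=7, seed=3)
    nodes = [f"G{i:03d}" for i in range(60)]
    r1 = map_and_intersect(tables.gwas_summary, tables.eqtl_map, nodes, n_lowest=100)
    shuffled_g = tables.gwas_summary.sample(frac=1, random_state=1).reset_index(drop=True)
    shuffled_e = tables.eqtl_map.sample(frac=1, random_state=2).reset_index(drop=True)
    r2 = map_and_intersect(shuffled_g, shuffled_e, nodes, n_lowest=100)
    assert r1.counts() == r2.counts()
    pd.testing.assert_frame_equal(r1.table, r2.table)


def test_duplicate_rsids_keep_smallest_p_and_boundary_ties_included():
    gwas = pd.DataFrame(
        {"rsid": ["rs1", "rs1", "rs2", "rs3"], "p_value": [0.5, 1e-6, 1e-4, 1e-4]}
    )
    cleaned = validate_gwas_summary(gwas)
    assert len(cleaned) == 3
    assert cleaned.set_index("rsid").loc["rs1", "p_value"] == pytest.approx(1e-6)
    eqtl = pd.DataFrame(
        {"rsid": ["rs2", "rs3"], "gene": ["A", "B"], "tissue": ["FT", "FT"]}
    )
    # n_lowest=2 selects rs1 and the tied pair rs2/rs3 (boundary ties included)
    report = map_and_intersect(gwas, eqtl, ["A", "B"], n_lowest=2)
    assert report.n_genes_in_nodes == 2


def test_excluded_tissue_filtering_and_unknown_label_warning():
    gwas, eqtl = toy_tables()
    eqtl.loc[1, "tissue"] = "nervous_system"
    report = map_and_intersect(gwas, eqtl, ["GENEA", "GENEB"], n_lowest=10)
    assert report.n_genes_mapped == 1  # GENEB row excluded with its tissue
    with pytest.warns(UserWarning, match="not present"):
        map_and_intersect(gwas, eqtl, ["GENEA"], n_lowest=10, tissue_exclude=("no_such",))


def test_invalid_p_values_rejected():
    bad = pd.DataFrame({"rsid": ["rs1"], "p_value": [0.0]})
    with pytest.raises(GwasError, match="p-values"):
        validate_gwas_summary(bad)


def degree_table(rowsums):
    from scipy.stats import rankdata

    arr = np.asarray(rowsums, float)
    return pd.DataFrame(
        {
            "incidence_rowsum": arr,
            "clique_rowsum": arr,
            "rank_incidence": rankdata(-arr, method="average"),
            "rank_clique": rankdata(-arr, method="average"),
        },
        index=pd.Index([f"G{i}" for i in range(len(arr))], name="gene"),
    )


def test_rank_lookup_attaches_ranks_with_average_ties():
    gwas = pd.DataFrame({"rsid": ["rs1", "rs2", "rs3"], "p_value": [1e-8, 1e-7, 1e-6]})
    eqtl = pd.DataFrame(
        {
            "rsid": ["rs1", "rs2", "rs3"],
            "gene": ["G0", "G1", "OUTSIDE"],
            "tissue": ["FT"] * 3,
        }
    )
    report = map_and_intersect(gwas, eqtl, ["G0", "G1", "G2"], n_lowest=5)
    deg = degree_table([9, 9, 1])  # G0 and G1 tied at the top
    out = rank_lookup(report, {"ft": deg})
    assert out.table.loc["G0", "rank_clique_ft"] == pytest.approx(1.5)
    assert out.table.loc["G1", "rank_clique_ft"] == pytest.approx(1.5)
    assert np.isnan(out.table.loc["OUTSIDE", "rank_clique_ft"])


def test_central_membership_implies_node_membership():
    gwas, eqtl = toy_tables()
    cluster = CentralCluster(
        members=["GENEB"], linkage="ward", k=2,
        mean_member_rowsum=1.0, mean_nonmember_rowsum=0.0,
    )
    # GENEB is central but NOT a node gene: must not be flagged central
    report = map_and_intersect(gwas, eqtl, ["GENEA"], clusters={"ft": cluster}, n_lowest=10)
    assert not report.table.loc["GENEB", "in_central_ft"]
    assert report.n_genes_in_central == 0


def test_simulated_tables_plant_exact_overlap_and_are_deterministic():
    nodes = [f"N{i:04d}" for i in range(600)]
    t1 = simulate_gwas_tables(nodes, n_variants=3000, n_overlap=13, seed=11)
    t2 = simulate_gwas_tables(nodes, n_variants=3000, n_overlap=13, seed=11)
    pd.testing.assert_frame_equal(t1.gwas_summary, t2.gwas_summary)
    pd.testing.assert_frame_equal(t1.eqtl_map, t2.eqtl_map)
    assert len(t1.planted_overlap) == 13
    report = map_and_intersect(t1.gwas_summary, t1.eqtl_map, nodes, n_lowest=300)
    assert report.n_genes_in_nodes == 13
    assert sorted(report.table.index[report.table["in_nodes"]]) == t1.planted_overlap

    none = simulate_gwas_tables(nodes, n_variants=1000, n_overlap=0, seed=1)
    r0 = map_and_intersect(none.gwas_summary, none.eqtl_map, nodes, n_lowest=100)
    assert r0.n_genes_in_nodes == 0

    with pytest.raises(ValueError, match="n_overlap"):
        simulate_gwas_tables(["A"], n_variants=100, n_overlap=2, seed=0)
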