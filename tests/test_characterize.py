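import pytest

from pepgraph import (
    DigestConfig,
    ProteinRecord,
    classify_components,
    digest_database,
    isoform_crosstab,
    node_count_distributions,
    summarize,
    uniqueness_breakdown,
)
from pepgraph.characterize import ISO_COLS, ISO_ROWS
from helpers import star_component


def test_summary_counts_by_hand(smallest_component, m_component):
    comps = [smallest_component, m_component]
    classes = classify_components(comps)
    s = summarize(comps, classes)
    assert (s.graphs, s.graphs_one_protein) == (2, 1)
    assert (s.protein_nodes, s.peptide_nodes, s.edges) == (3, 4, 5)
    assert s.isomorphism_classes == 2
    assert s.largest_graph == (2, 3, 4)
    assert s.second_largest_graph == (1, 1, 1)


def test_summary_single_and_empty(smallest_component):
    classes = classify_components([smallest_component])
    s = summarize([smallest_component], classes)
    assert s.largest_graph == (1, 1, 1)
    assert s.second_largest_graph == (0, 0, 0)
    empty = summarize([], [])
    assert empty.graphs == 0 and empty.largest_graph == (0, 0, 0)


def test_summary_totals_match_component_sums(m_component, n_component, w_component):
    comps = [m_component, n_component, w_component]
    s = summarize(comps, classify_components(comps))
    assert s.protein_nodes == sum(c.n_protein_nodes for c in comps)
    assert s.peptide_nodes == sum(c.n_peptide_nodes for c in comps)
    assert s.edges == sum(c.n_edges for c in comps)


def test_summary_uses_map_totals_when_given(m_component):
    pmap = digest_database(
        [ProteinRecord("A", "AAAAKVVVVK"), ProteinRecord("B", "CCCCKVVVVK")],
        DigestConfig(min_len=5, max_missed=0),
    )
    s = summarize([m_component], classify_components([m_component]), pmap)
    assert s.protein_accessions == 2
    assert s.peptide_sequences == 3


def test_node_count_distributions(
    smallest_component, m_component, n_component
):
    hists = node_count_distributions(
        [smallest_component, m_component, n_component]
    )
    assert hists["protein_nodes"][1] == pytest.approx(1 / 3)
    assert hists["protein_nodes"][2] == pytest.approx(2 / 3)
    for hist in hists.values():
        assert sum(hist.values()) == pytest.approx(1.0, abs=1e-9)
    only_m = node_count_distributions([m_component])
    assert only_m["shared_peptide_nodes"][1] == pytest.approx(1.0)
    smalls = node_count_distributions([smallest_component] * 4)
    assert smalls["unique_peptide_nodes"][1] == pytest.approx(1.0)
    assert smalls["shared_peptide_nodes"][0] == pytest.approx(1.0)


def test_distribution_caps_at_ten():
    hists = node_count_distributions([star_component(12, True)])
    assert hists["peptide_nodes"]["10+"] == pytest.approx(1.0)
    with pytest.raises(ValueError):
        node_count_distributions([])


@pytest.mark.parametrize(
    "fixture,expected",
    [
        ("m_component", dict(both=100.0, lacking=0.0)),
        ("n_component", dict(only_shared=50.0, both=50.0, lacking=100.0)),
        ("w_component", dict(only_shared=100.0, pep_shared=100.0)),
    ],
)
def test_uniqueness_breakdown_fixtures(request, fixture, expected):
    b = uniqueness_breakdown([request.getfixturevalue(fixture)])
    if "both" in expected:
        assert b.protein_nodes_both_pct == pytest.approx(expected["both"])
    if "only_shared" in expected:
        assert b.protein_nodes_only_shared_pct == pytest.approx(
            expected["only_shared"]
        )
    if "lacking" in expected:
        assert b.graphs_with_node_lacking_unique_pct == pytest.approx(
            expected["lacking"]
        )
    if "pep_shared" in expected:
        assert b.peptide_nodes_shared_pct == pytest.approx(expected["pep_shared"])
    assert b.peptide_nodes_unique_pct + b.peptide_nodes_shared_pct == pytest.approx(
        100.0
    )
    assert (
        b.protein_nodes_only_unique_pct
        + b.protein_nodes_both_pct
        + b.protein_nodes_only_shared_pct
    ) == pytest.approx(100.0)


def test_breakdown_all_singletons(smallest_component):
    b = uniqueness_breakdown([smallest_component] * 5)
    assert b.protein_nodes_only_unique_pct == 100.0
    assert b.peptide_nodes_shared_pct == 0.0
    assert b.graphs_with_node_lacking_unique_pct == 0.0


CFG = DigestConfig(min_len=5, max_missed=0)


def iso_db():
    canonical = [
        ProteinRecord("P1", "AAAAKVVVVKDDDDK"),
        ProteinRecord("P2", "CCCCKVVVVK"),
    ]
    # isoform of P1 missing the DDDDK block
    iso = canonical + [ProteinRecord("P1-2", "AAAAKVVVVK")]
    return digest_database(canonical, CFG), digest_database(iso, CFG)


def test_isoform_crosstab_cells():
    map_c, map_i = iso_db()
    tab = isoform_crosstab(map_c, map_i)
    # AAAAK: P1 + P1-2 only -> isoform-unique; was unique in canonical
    assert tab.counts[("isoform-unique", "unique")] == 1
    # VVVVK: shared across base accessions in both maps
    assert tab.counts[("shared", "shared")] == 1
    # DDDDK unique to P1, CCCCK unique to P2 in both maps
    assert tab.counts[("unique", "unique")] == 2
    assert tab.grand_total == len(map_i.entries)
    assert tab.canonical_only == 0


def test_isoform_crosstab_new_isoform_only_peptide():
    map_c = digest_database([ProteinRecord("P1", "AAAAKVVVVK")], CFG)
    map_i = digest_database(
        [
            ProteinRecord("P1", "AAAAKVVVVK"),
            ProteinRecord("P1-2", "AAAAKWWWWK"),
        ],
        CFG,
    )
    tab = isoform_crosstab(map_c, map_i)
    assert tab.counts[("unique", "not existing")] == 1  # WWWWK only in P1-2
    assert tab.counts[("isoform-unique", "unique")] == 1  # AAAAK
    assert tab.counts[("unique", "unique")] == 1  # VVVVK stays unique to P1


def test_crosstab_impossible_cell_stays_zero():
    # when canonical accessions are a subset of the isoform database, a
    # peptide unique there cannot have been shared before
    map_c, map_i = iso_db()
    tab = isoform_crosstab(map_c, map_i)
    assert tab.counts.get(("unique", "shared"), 0) == 0
    df = tab.to_dataframe()
    assert df.loc["sum", "sum"] == tab.grand_total
    assert list(df.columns) == list(ISO_COLS) + ["sum"]
    assert list(df.index) == list(ISO_ROWS) + ["sum"]


def test_crosstab_config_mismatch_errors():
    map_c, _ = iso_db()
    other = digest_database(
        [ProteinRecord("P1", "AAAAKVVVVK")], DigestConfig(min_len=7, max_missed=0)
    )
    with pytest.raises(ValueError, match="config"):
        isoform_crosstab(map_c, other)
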