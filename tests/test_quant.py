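import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pepgraph import (
    DigestConfig,
    ProteinRecord,
    QuantTable,
    aggregate_ptm_rows,
    aggregate_replicates,
    compute_ratios,
    digest_database,
    enumerate_comparisons,
    filter_quant_peptides,
    map_quant_peptides,
    read_maxquant_peptides,
    read_quant_table,
)

DESIGN = {
    "A_1": ("A", 1), "A_2": ("A", 2), "A_3": ("A", 3),
    "B_1": ("B", 1), "B_2": ("B", 2), "B_3": ("B", 3),
}


def make_table(rows, index=None, decoy=None):
    df = pd.DataFrame(rows, columns=list(DESIGN), index=index, dtype=float)
    decoy_s = None
    if decoy is not None:
        decoy_s = pd.Series(decoy, index=df.index)
    return QuantTable(df, dict(DESIGN), decoy_s)


def test_ptm_rows_summed_per_sample():
    idx = pd.MultiIndex.from_tuples(
        [("PEPTIDEK", "mod1"), ("PEPTIDEK", "mod2"), ("OTHERK", "")],
        names=["sequence", "modification"],
    )
    table = make_table(
        [
            [10, np.nan, 1, 1, 1, 1],
            [5, np.nan, 2, 2, 2, 2],
            [7, 7, 7, 7, 7, 7],
        ],
        index=idx,
    )
    out = aggregate_ptm_rows(table)
    assert out.intensities.loc["PEPTIDEK", "A_1"] == 15
    # all variants missing in a sample -> stays missing, not zero
    assert math.isnan(out.intensities.loc["PEPTIDEK", "A_2"])
    assert out.intensities.loc["OTHERK", "A_1"] == 7


def test_filter_drops_decoys_short_sequences_and_zeros():
    table = make_table(
        [[1, 2, 3, 4, 5, 6], [1, 2, 3, 4, 5, 6], [0, 2, 3, 4, 5, 6]],
        index=pd.Index(["AAAAAAK", "DECOYPEPK", "SHRT"], name="sequence"),
        decoy=[False, True, False],
    )
    out = filter_quant_peptides(table, DigestConfig(min_len=7, max_len=50))
    assert list(out.intensities.index) == ["AAAAAAK"]
    long_table = make_table(
        [[0, 2, 3, 4, 5, 6]], index=pd.Index(["AAAAAAAK"], name="sequence")
    )
    out2 = filter_quant_peptides(long_table, DigestConfig(min_len=7))
    assert math.isnan(out2.intensities.iloc[0, 0])  # zero became missing


def test_map_quant_peptides_substring_semantics():
    records = [
        ProteinRecord("A", "AAAAKVVVVK"),
        ProteinRecord("B", "CCCCKVVVVK"),
        ProteinRecord("D", "VVVVKWWWWW", is_decoy=True),
    ]
    pmap = map_quant_peptides(["VVVVK", "WWWWW", "AAAAKVVVVK"], records)
    assert sorted(pmap.entries["VVVVK"]) == ["A", "B"]  # decoy D not matched
    assert "WWWWW" not in pmap.entries  # unmapped peptides are excluded
    assert pmap.entries["AAAAKVVVVK"] == frozenset({"A"})  # equality counts


def test_quant_map_agrees_with_digest_for_tryptic_peptides():
    records = [
        ProteinRecord("A", "AAAAKVVVVKDDDDK"),
        ProteinRecord("B", "CCCCKVVVVK"),
    ]
    dmap = digest_database(records, DigestConfig(min_len=5, max_missed=0))
    qmap = map_quant_peptides(sorted(dmap.entries), records)
    assert qmap.entries == dmap.entries


@pytest.mark.parametrize(
    "values,min_valid,expected",
    [
        ((10, 20, math.nan), 2, 15),
        ((10, math.nan, math.nan), 2, math.nan),
        ((10, 10, 10), 2, 10),
        ((math.nan,), 1, math.nan),
        ((4,), 1, 4),
    ],
)
def test_replicate_aggregation_rule(values, min_valid, expected):
    got = aggregate_replicates(values, min_valid)
    assert math.isnan(got) if math.isnan(expected) else got == expected


def test_replicate_aggregation_validation():
    with pytest.raises(ValueError):
        aggregate_replicates((1, 2, 3), min_valid=0)
    with pytest.raises(ValueError):
        aggregate_replicates(())


def test_ratio_rules():
    table = make_table(
        [
            [20, 20, np.nan, 10, 10, 10],   # mean 20 / mean 10
            [5, np.nan, np.nan, 1, 1, 1],   # state A mean missing
            [3, 3, 3, 3, 3, 3],
        ],
        index=pd.Index(["RATIOTWOK", "INVALIDK", "EQUALK"], name="sequence"),
    )
    ratios = compute_ratios(table, "A", "B")
    assert ratios.comparison == ("A", "B")
    assert ratios.ratios["RATIOTWOK"] == 2.0
    assert math.isnan(ratios.ratios["INVALIDK"])
    assert ratios.ratios["EQUALK"] == 1.0
    assert ratios.valid_peptides == ["RATIOTWOK", "EQUALK"]
    with pytest.raises(ValueError, match="unknown state"):
        compute_ratios(table, "A", "Z")


@given(st.lists(
    st.one_of(st.floats(min_value=0.5, max_value=1e6), st.just(math.nan)),
    min_size=3, max_size=3,
))
def test_swapping_states_inverts_ratios(vals_a):
    vals_b = [7.0, 8.0, 9.0]
    table = make_table([vals_a + vals_b], index=pd.Index(["PEPK"], name="sequence"))
    ab = compute_ratios(table, "A", "B").ratios["PEPK"]
    ba = compute_ratios(table, "B", "A").ratios["PEPK"]
    if math.isnan(ab):
        assert math.isnan(ba)
    else:
        assert ab == pytest.approx(1.0 / ba)


def test_replicate_relabeling_invariance():
    rng = np.random.default_rng(0)
    vals = rng.uniform(1, 100, size=6).tolist()
    t1 = make_table([vals], index=pd.Index(["PEPK"], name="sequence"))
    # permute replicates within each state
    perm = [vals[2], vals[0], vals[1], vals[4], vals[5], vals[3]]
    t2 = make_table([perm], index=pd.Index(["PEPK"], name="sequence"))
    assert compute_ratios(t1, "A", "B").ratios.equals(
        compute_ratios(t2, "A", "B").ratios
    )


def test_enumerate_comparisons_orders_pairs():
    assert enumerate_comparisons(["S3", "S1", "S2"]) == [
        ("S1", "S2"), ("S1", "S3"), ("S2", "S3")
    ]
    five = [f"S{i}" for i in range(1, 6)]
    assert len(enumerate_comparisons(five)) == 10


def test_generic_reader_and_maxquant_preset(tmp_path):
    generic = tmp_path / "quant.csv"
    generic.write_text(
        "sequence,modification,A_1,A_2,A_3,B_1,B_2,B_3\n"
        "PEPTIDEK,,1,2,3,4,5,6\n"
        "PEPTIDEK,ox,1,1,1,1,1,1\n"
    )
    table = read_quant_table(generic, DESIGN, modification_col="modification")
    assert isinstance(table.intensities.index, pd.MultiIndex)
    agg = aggregate_ptm_rows(table)
    assert agg.intensities.loc["PEPTIDEK", "A_1"] == 2

    mq = tmp_path / "peptides.txt"
    mq.write_text(
        "Sequence\tReverse\tIntensity A_1\tIntensity A_2\tIntensity A_3\t"
        "Intensity B_1\tIntensity B_2\tIntensity B_3\n"
        "AAAAAAK\t\t1\t2\t3\t4\t5\t6\n"
        "CCCCCCK\t+\t1\t2\t3\t4\t5\t6\n"
    )
    table = read_maxquant_peptides(mq, DESIGN)
    assert list(table.decoy_only) == [False, True]
    with pytest.raises(ValueError, match="not in table"):
        read_quant_table(generic, {"X_1": ("X", 1)})
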