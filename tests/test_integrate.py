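"""Criterion intersection, Venn partitioning, curation and reporting."""

import itertools

import pandas as pd
import pytest

from chrscreen.integrate import (
    PARTITION_ORDER,
    CurationEntry,
    annotate_cell_cycle,
    apply_curation,
    intersect_criteria,
    load_table1_fixture,
    partition_counts,
    round_half_up_pct,
    summarize_venn,
)
from conftest import make_records


def all_pattern_records():
    """One gene per (repressed, dream, chr) pattern, ids g0..g7."""
    rows = [
        (f"g{i}", *pattern)
        for i, pattern in enumerate(itertools.product([False, True], repeat=3))
    ]
    return make_records([(gid, r, d, c) for gid, r, d, c in rows])


def test_each_pattern_lands_in_its_partition():
    records = all_pattern_records().set_index("gene_id")
    assert records.loc["g7", "partition"] == "all_three"  # T,T,T
    assert records.loc["g7", "in_final_list"]
    assert records.loc["g6", "partition"] == "repressed_dream"  # T,T,F
    assert records.loc["g5", "partition"] == "repressed_chr"  # T,F,T
    assert records.loc["g3", "partition"] == "dream_chr"  # F,T,T
    assert records.loc["g0", "partition"] == "none"
    assert not records.loc["g6", "in_final_list"]


def test_partitions_are_disjoint_and_complete():
    records = all_pattern_records()
    counts = partition_counts(records)
    assert sum(counts.values()) == len(records)
    assert set(counts) == set(PARTITION_ORDER)
    assert records["partition"].isin(PARTITION_ORDER).all()


def test_marginal_identity_dream_and_repressed():
    records = make_records(
        [("a", True, True, True)] * 0
        + [(f"x{i}", True, True, True) for i in range(4)]
        + [(f"y{i}", True, True, False) for i in range(3)]
        + [(f"z{i}", False, True, False) for i in range(2)]
    )
    counts = partition_counts(records)
    n_rep_dream = int((records["repressed"] & records["dream_bound"]).sum())
    assert n_rep_dream == counts["all_three"] + counts["repressed_dream"]


def test_duplicate_gene_id_in_one_input_rejected():
    scores = pd.DataFrame(
        {"gene_id": ["a", "a"], "score": [-4, -4], "repressed": [True, True]}
    )
    dream = pd.DataFrame({"gene_id": ["a"], "n_components": [3], "bound": [True]})
    chrc = pd.DataFrame({"gene_id": ["a"], "conserved_chr": [True]})
    with pytest.raises(ValueError, match="duplicate"):
        intersect_criteria(scores, dream, chrc)


def test_gene_missing_from_an_input_is_false_and_flagged():
    scores = pd.DataFrame(
        {"gene_id": ["a", "b"], "score": [-4, -5], "repressed": [True, True]}
    )
    dream = pd.DataFrame({"gene_id": ["a"], "n_components": [4], "bound": [True]})
    chrc = pd.DataFrame({"gene_id": ["a", "b"], "conserved_chr": [True, True]})
    records = intersect_criteria(scores, dream, chrc).set_index("gene_id")
    assert records.loc["b", "missing_evidence"] == "dream"
    assert not records.loc["b", "dream_bound"]
    assert records.loc["b", "partition"] == "repressed_chr"
    assert records.loc["a", "missing_evidence"] == ""
    assert len(records) == 2  # universe preserved, nothing dropped


def test_manual_include_overrides_failed_screen():
    # a validated DREAM target detected with only two components is
    # rescued by curation, with provenance recorded
    records = make_records([("gas2l3", True, False, True), ("ok", True, True, True)])
    curated = apply_curation(
        records, [CurationEntry(symbol="GAS2L3", action="include", reason="known target")]
    ).set_index("gene_id")
    assert curated.loc["gas2l3", "in_final_list"]
    assert curated.loc["gas2l3", "curation"] == "manual_include"
    assert curated.loc["ok", "curation"] == "screen"


def test_manual_exclude_and_audit_trail():
    records = make_records([("a", True, True, True), ("b", True, True, True)])
    curated = apply_curation(records, [CurationEntry(symbol="b", action="exclude")])
    curated = curated.set_index("gene_id")
    assert not curated.loc["b", "in_final_list"]
    assert curated.loc["b", "curation"] == "manual_exclude"
    # removing manual overrides recovers the raw screen output
    raw = curated[curated["curation"] == "screen"]
    assert raw["in_final_list"].all() and list(raw.index) == ["a"]


def test_empty_curation_is_identity():
    records = make_records([("a", True, True, True)])
    assert apply_curation(records, []).equals(records)


def test_conflicting_curation_rejected():
    records = make_records([("a", True, True, True)])
    with pytest.raises(ValueError, match="both included and excluded"):
        apply_curation(
            records,
            [
                CurationEntry(symbol="A", action="include"),
                CurationEntry(symbol="a", action="exclude"),
            ],
        )


def test_unknown_curated_symbol_warns_not_fails():
    records = make_records([("a", True, True, True)])
    with pytest.warns(UserWarning, match="GHOST"):
        out = apply_curation(records, [CurationEntry(symbol="GHOST", action="include")])
    assert out["in_final_list"].equals(records["in_final_list"])


@pytest.mark.parametrize(
    "numerator, denominator, expected",
    [
        (358, 870, 41.1),  # repressed among DREAM-bound
        (158, 210, 75.2),  # cell-cycle regulated among final candidates
        (0, 5, 0.0),
        (1, 3, 33.3),
        (1, 8, 12.5),
        (205, 2000, 10.3),  # 10.25 rounds half-up, not to even
    ],
)
def test_percentages_round_half_up_to_one_decimal(numerator, denominator, expected):
    assert round_half_up_pct(numerator, denominator) == expected


def test_zero_denominator_percentage_is_undefined():
    assert round_half_up_pct(5, 0) is None


def test_venn_summary_counts_and_denominators():
    records = make_records(
        [(f"a{i}", True, True, True) for i in range(3)]
        + [(f"b{i}", True, True, False) for i in range(2)]
        + [(f"c{i}", False, True, False) for i in range(5)]
    )
    summary = summarize_venn(records).set_index("set")
    assert summary.loc["dream_bound", "count"] == 10
    assert summary.loc["repressed&dream_bound", "count"] == 5
    assert summary.loc["repressed&dream_bound", "percent"] == 50.0
    assert summary.loc["all_three", "count"] == 3
    assert summary.loc["all_three", "percent"] == 30.0
    assert summary.loc["final_list", "count"] == 3


def test_cell_cycle_annotation_fraction_and_flags():
    final = make_records([(f"g{i}", True, True, True) for i in range(4)])
    annotation = pd.DataFrame(
        {
            "symbol": ["g0", "g1", "g2"],
            "cell_cycle_regulated": [True, True, False],
            "peak_phase": ["G2", "M", ""],
        }
    )
    fraction, joined = annotate_cell_cycle(final, annotation)
    assert fraction == 50.0  # 2 of 4; g3 unmatched counts as not annotated
    joined = joined.set_index("gene_id")
    assert not joined.loc["g3", "cc_annotated"]
    assert joined.loc["g0", "peak_phase"] == "G2"


def test_cell_cycle_fraction_of_constructed_cohort():
    final = make_records([(f"g{i}", True, True, True) for i in range(100)])
    annotation = pd.DataFrame(
        {
            "symbol": [f"g{i}" for i in range(100)],
            "cell_cycle_regulated": [i < 79 for i in range(100)],
        }
    )
    fraction, _ = annotate_cell_cycle(final, annotation)
    assert fraction == 79.0


def test_cell_cycle_of_empty_final_list_is_undefined():
    final = make_records([("a", True, True, False)])
    fraction, _ = annotate_cell_cycle(
        final[final["in_final_list"]],
        pd.DataFrame({"symbol": ["a"], "cell_cycle_regulated": [True]}),
    )
    assert fraction is None


def test_peak_phase_requires_cell_cycle_regulation():
    final = make_records([("a", True, True, True)])
    bad = pd.DataFrame(
        {"symbol": ["a"], "cell_cycle_regulated": [False], "peak_phase": ["G2"]}
    )
    with pytest.raises(ValueError, match="peak_phase"):
        annotate_cell_cycle(final, bad)


def test_packaged_candidate_list_has_210_distinct_symbols():
    symbols = load_table1_fixture()
    assert len(symbols) == 210
    assert len(set(symbols)) == 210
    for known in ("CCNB2", "KIF23", "PLK4", "GAS2L3", "MYBL2"):
        assert known in symbols
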