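"""Concordance tables, sensitivity/specificity, densities, unions, extrapolation."""

from __future__ import annotations

import pytest

from capsnv.calling import VariantCall
from capsnv.evaluate import (
    ConcordanceTable,
    build_concordance,
    extrapolate_multicopy_sensitivity,
    sensitivity,
    snv_density,
    specificity,
    union_snvs,
)


def _call(position, vaf, region="R", status="passed"):
    depth = 50
    alt = int(round(vaf / 100 * depth))
    fwd = alt // 2
    return VariantCall(
        region=region, position=position, ref_allele="A", alt_allele="C",
        depth=depth, alt_count=alt, alt_forward=fwd, alt_reverse=alt - fwd,
        vaf=vaf, status=status,
    )


def test_concordance_assigns_each_truth_site_once():
    calls = [_call(10, 50.0), _call(20, 98.0), _call(40, 50.0, status="filtered")]
    truth = [
        ("R", 10, "het"),       # called het -> concordant
        ("R", 20, "het"),       # called homvar -> discordant
        ("R", 30, "het"),       # nothing called -> no_hcdiff
        ("R", 40, "het"),       # only a filtered call -> no_hcdiff
        ("R", 50, "homref"),    # nothing called -> concordant homref
    ]
    table = build_concordance(calls, truth, depth=None)
    assert table["het", "het"] == 1
    assert table["het", "homvar"] == 1
    assert table["het", "no_hcdiff"] == 2
    assert table["homref", "no_hcdiff"] == 1
    assert table.truth_total("het") == 4


def test_concordance_low_depth_is_not_covered():
    calls = [_call(10, 50.0)]
    truth = [("R", 10, "het"), ("R", 20, "het")]
    depth_of = lambda region, position: 0 if position == 20 else 50
    table = build_concordance(calls, truth, depth=depth_of, min_depth=6)
    assert table["het", "het"] == 1
    assert table["het", "not_covered"] == 1


def test_concordance_duplicate_truth_rejected():
    with pytest.raises(ValueError, match="duplicate"):
        build_concordance([], [("R", 10, "het"), ("R", 10, "het")], depth=None)


def test_concordance_row_sums_conserved():
    calls = [_call(10, 50.0)]
    truth = [("R", 10, "het"), ("R", 30, "homvar"), ("R", 50, "homref")]
    table = build_concordance(calls, truth, depth=None)
    for cls in ("het", "homvar", "homref"):
        assert table.truth_total(cls) == 1


def test_perfect_table_gives_100_percent():
    table = ConcordanceTable.from_counts(
        {
            "homref": {"no_hcdiff": 50},
            "het": {"het": 30},
            "homvar": {"homvar": 20},
        }
    )
    assert sensitivity(table, "het") == 100.0
    assert specificity(table, "het") == 100.0
    assert sensitivity(table, "homref") == 100.0


def test_diagonal_table_from_error_free_simulation(clean_dataset):
    from capsnv.calling import call_all
    from capsnv.io import build_region_pileups

    ds = clean_dataset
    piles = build_region_pileups(ds.reads, ds.reference.sequences)
    calls = call_all(piles)
    table = build_concordance(calls, ds.truth, piles)
    # without sequencing errors no discordant genotype cell is populated
    assert table["het", "homref"] == 0
    assert table["het", "homvar"] == 0
    assert table["homvar", "het"] == 0
    assert table["homvar", "homref"] == 0
    # and nearly all well-covered sites are concordant
    assert table["het", "het"] + table["het", "not_covered"] == table.truth_total("het")
    assert (
        table["homvar", "homvar"] + table["homvar", "not_covered"]
        == table.truth_total("homvar")
    )


def test_sensitivity_zero_denominator():
    table = ConcordanceTable.from_counts(
        {"homref": {}, "het": {"het": 1}, "homvar": {}}
    )
    with pytest.raises(ValueError):
        sensitivity(table, "homvar")
    with pytest.raises(ValueError):
        specificity(table, "homvar")


@pytest.mark.parametrize(
    "count, kb, expected",
    [
        (1157, 234 - 69, 7.0),
        (1919, 850, 2.3),
        (0, 100, 0.0),
    ],
)
def test_snv_density(count, kb, expected):
    assert snv_density(count, kb) == expected


def test_snv_density_validates_length():
    with pytest.raises(ValueError):
        snv_density(10, 0)


def test_union_disjoint_sets():
    a = [("R", i, "C", False) for i in range(3)]
    b = [("R", 100 + i, "C", False) for i in range(4)]
    result = union_snvs({"s1": a, "s2": b})
    assert result.n_unique == 7
    assert result.n_novel == 7


def test_union_idempotent_on_identical_sets():
    a = [("R", i, "C", True) for i in range(5)]
    result = union_snvs({"s1": a, "s2": list(a)})
    assert result.n_unique == 5
    assert result.n_known == 5


def test_union_overlapping_sets():
    a = [("R", 1, "C", False), ("R", 2, "C", False)]
    b = [("R", 2, "C", False), ("R", 3, "C", False)]
    assert union_snvs({"s1": a, "s2": b}).n_unique == 3


def test_union_allele_aware_mode():
    a = [("R", 1, "C", False)]
    b = [("R", 1, "T", False)]
    assert union_snvs({"s1": a, "s2": b}).n_unique == 1
    assert union_snvs({"s1": a, "s2": b}, match_allele=True).n_unique == 2


def test_union_known_wins_over_novel():
    a = [("R", 1, "C", False)]
    b = [("R", 1, "C", True)]
    result = union_snvs({"s1": a, "s2": b})
    assert result.n_known == 1 and result.n_novel == 0


def test_extrapolation_published_numbers():
    result = extrapolate_multicopy_sensitivity(673, 0.98, 3, 1157)
    assert result.expected_single_copy == 687
    assert result.expected_total == 2061
    assert result.sensitivity_percent == 56


def test_extrapolation_identity_case():
    assert extrapolate_multicopy_sensitivity(100, 1.0, 1, 100).sensitivity_percent == 100


def test_extrapolation_validates_inputs():
    with pytest.raises(ValueError):
        extrapolate_multicopy_sensitivity(100, 0.0, 1, 100)
    with pytest.raises(ValueError):
        extrapolate_multicopy_sensitivity(0, 1.0, 1, 0)
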