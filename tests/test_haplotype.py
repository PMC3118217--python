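"""Haplotyping windows, tallies, integer ratios and copy-number estimates."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy import stats

from capsnv.haplotype import (
    HaplotypeTally,
    aggregate_cn,
    cn_from_ratio,
    find_htcrs,
    integer_ratio,
    pooled_ratio,
    select_combinations,
    tally_haplotypes,
)

from conftest import make_read


# ---------------------------------------------------------------------------
# HTCR selection
# ---------------------------------------------------------------------------

def test_dense_kilobase_becomes_one_htcr():
    positions = [("R", 100 + 100 * i) for i in range(10)]  # 10 SNVs in ~0.9 kb
    htcrs = find_htcrs(positions, min_density=9)
    assert len(htcrs) == 1
    assert htcrs[0].snv_positions == tuple(p for _, p in positions)
    assert htcrs[0].density >= 9


def test_sparse_kilobase_is_rejected():
    positions = [("R", 100 + 200 * i) for i in range(5)]  # 5 SNVs / kb
    assert find_htcrs(positions, min_density=9) == []


def test_desert_separates_two_htcrs():
    """Two dense blocks with a 5-kb SNV desert give two windows (sliding oracle)."""
    block1 = [1000 + 90 * i for i in range(10)]
    block2 = [8000 + 90 * i for i in range(12)]
    positions = [("R", p) for p in block1 + block2]
    htcrs = find_htcrs(positions, min_density=9)
    assert len(htcrs) == 2
    assert htcrs[0].snv_positions == tuple(block1)
    assert htcrs[1].snv_positions == tuple(block2)
    # oracle: every reported window's anchored 1-kb sub-window is dense
    arr = np.array(block1 + block2)
    for htcr in htcrs:
        first = htcr.snv_positions[0]
        inside = ((arr >= first) & (arr < first + 1000)).sum()
        assert inside >= 9


def test_combinations_respect_span_and_size():
    positions = tuple(1000 + 60 * i for i in range(20))
    htcrs = find_htcrs([("R", p) for p in positions], min_density=9)
    combos = select_combinations(htcrs[0], max_span=200, max_snvs=7)
    seen = set()
    for combo in combos:
        assert 2 <= len(combo) <= 7
        assert combo[-1] - combo[0] <= 200
        assert not (set(combo) & seen), "combinations must not overlap"
        seen |= set(combo)


# ---------------------------------------------------------------------------
# Tallies
# ---------------------------------------------------------------------------

def _hap_reads(hap_counts, positions=(101, 151), region="R", length=120, start=50):
    """Reads spanning ``positions`` carrying given allele tuples."""
    reads = []
    i = 0
    for alleles, count in hap_counts.items():
        for _ in range(count):
            seq = ["A"] * length
            for pos, base in zip(positions, alleles):
                seq[pos - 1 - start] = base
            reads.append(
                make_read(region, start, "".join(seq), read_id=f"r{i}")
            )
            i += 1
    return reads


def test_tally_published_two_haplotype_row():
    """17 vs 34 reads over two tuples tally to 51 total."""
    reads = _hap_reads({("C", "G"): 17, ("T", "A"): 34})
    tally = tally_haplotypes(reads, (101, 151), min_total=30)
    assert tally is not None
    assert tally.total_reads == 51
    assert sorted(tally.counts.values()) == [17, 34]


def test_tally_drops_rare_haplotypes():
    reads = _hap_reads({("C", "G"): 17, ("T", "A"): 34, ("C", "A"): 4})
    tally = tally_haplotypes(reads, (101, 151), min_total=30)
    assert tally is not None
    assert len(tally.counts) == 2
    assert all(v >= 5 for v in tally.counts.values())


def test_tally_below_total_threshold_returns_none():
    reads = _hap_reads({("C", "G"): 12, ("T", "A"): 13})  # 25 < 30
    assert tally_haplotypes(reads, (101, 151), min_total=30) is None


def test_tally_requires_full_span_and_quality():
    reads = _hap_reads({("C", "G"): 10, ("T", "A"): 10})
    short = make_read("R", 50, "A" * 40, read_id="short")  # ends before 2nd SNV
    lowq = make_read("R", 50, "C" * 120, quality=10, read_id="lowq")
    tally = tally_haplotypes(reads + [short, lowq], (101, 151), min_total=10)
    assert tally is not None
    assert tally.total_reads == 20


def test_tally_from_counts_convenience():
    tally = HaplotypeTally.from_counts({"A": 17, "B": 34})
    assert tally.total_reads == 51
    assert tally.count_vector() == (17, 34)


# ---------------------------------------------------------------------------
# Integer ratios
# ---------------------------------------------------------------------------

def _oracle_ratio(counts, alpha):
    """Independent exhaustive oracle: all positive vectors per total,
    scored with scipy.stats.chisquare, smallest acceptable total wins."""
    counts = np.asarray(counts, float)
    k = len(counts)
    for total in range(k, 17):
        best = None
        for parts in itertools.product(range(1, total + 1), repeat=k):
            if sum(parts) != total:
                continue
            expected = counts.sum() * np.asarray(parts) / total
            chi, pval = stats.chisquare(counts, expected)
            if best is None or chi < best[1]:
                best = (parts, chi, pval)
        if best is not None and best[2] >= alpha:
            return best[0]
    return None


@pytest.mark.parametrize(
    "counts, expected",
    [
        ((17, 34), (1, 2)),
        ((10, 10), (1, 1)),
        ((16, 62, 11), (1, 4, 1)),  # published three-haplotype locus
        ((10, 26, 9), (1, 2, 1)),
    ],
)
def test_integer_ratio_examples(counts, expected):
    fit = integer_ratio(counts)
    assert fit.ratio == expected
    assert fit.total == sum(expected)


def test_integer_ratio_matches_exhaustive_oracle():
    rng = np.random.default_rng(21)
    for _ in range(40):
        k = int(rng.integers(2, 5))
        true = rng.integers(1, 5, size=k)
        n = int(rng.integers(30, 120))
        counts = rng.multinomial(n, true / true.sum()) + 1
        fit = integer_ratio(tuple(int(c) for c in counts), alpha=0.3)
        oracle = _oracle_ratio(counts, alpha=0.3)
        assert oracle is not None
        assert fit.ratio == tuple(oracle)


def test_integer_ratio_exact_proportionality():
    """Exactly proportional counts recover the generating vector (up to the
    smallest-total preference when a smaller total also fits the noise)."""
    for c in [(1, 2), (1, 1, 4), (2, 3), (1, 2, 3), (1, 1, 1, 3)]:
        for k in (30, 50):
            counts = tuple(k * x for x in c)
            fit = integer_ratio(counts)
            # the returned vector must be proportion-identical or a
            # statistically indistinguishable smaller total; with k >= 20
            # the exact vector always wins
            assert fit.ratio == c, (counts, fit)


def test_integer_ratio_validates_input():
    with pytest.raises(ValueError):
        integer_ratio((10,))
    with pytest.raises(ValueError):
        integer_ratio((10, 0))
    with pytest.raises(ValueError):
        integer_ratio((10, -3))


# ---------------------------------------------------------------------------
# Copy numbers
# ---------------------------------------------------------------------------

def test_cn_three_haplotypes_sum():
    est = cn_from_ratio((1, 4, 1), counts=(16, 62, 11))
    assert est.diploid_cn == 6
    assert not est.ambiguous_flag


def test_cn_two_haplotypes_with_external_scale():
    est = cn_from_ratio((1, 2), haploid_scale=2, counts=(17, 34))
    assert est.diploid_cn == 6
    assert not est.ambiguous_flag


def test_cn_two_haplotypes_default_scale_flagged():
    est = cn_from_ratio((1, 1), counts=(10, 10))
    assert est.diploid_cn == 2
    assert est.ambiguous_flag


def test_cn_invalid_scale():
    with pytest.raises(ValueError):
        cn_from_ratio((1, 2), haploid_scale=0)


def test_aggregate_constant_estimates():
    ests = [cn_from_ratio((1, 1), haploid_scale=1, counts=(10, 10)) for _ in range(5)]
    summary = aggregate_cn(ests)
    assert summary.count == 5
    assert summary.mean == 2.0
    assert summary.sd == 0.0


def test_aggregate_empty_is_error():
    with pytest.raises(ValueError):
        aggregate_cn([])


@pytest.mark.parametrize(
    "pairs, expected",
    [
        ([(172, 173)], 0.99),
        ([(104, 97)], 1.07),
        ([(100, 100), (72, 73)], 0.99),
    ],
)
def test_pooled_two_haplotype_ratio(pairs, expected):
    assert pooled_ratio(pairs) == expected
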