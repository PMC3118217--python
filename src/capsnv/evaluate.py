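"""Concordance with reference genotypes, sensitivity/specificity,
SNV densities, cross-sample unions, and the multi-copy sensitivity
extrapolation.

Conventions follow the published comparison table for 2-copy loci:
sensitivity for a genotype class is the number of concordant calls of that
class divided by the truth-class total (in percent); "specificity" follows
the same table's arithmetic — concordant calls over all calls of that class
at truth-annotated sites — which is a precision-style measure, kept under
its historical name rather than replaced by the textbook true-negative
definition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Optional, Sequence

import pandas as pd

from ._util import round_half_up
from .calling import VariantCall
from .classify import classify_vaf
from .io import RegionPileup
from .simulate import TruthRecord

TRUTH_CLASSES = ("homref", "het", "homvar")
CALL_CATEGORIES = ("no_hcdiff", "homref", "het", "homvar", "not_covered")

#: default coverage floor below which a truth site counts as "not covered"
DEFAULT_MIN_DEPTH = 6


class ConcordanceTable:
    """Truth-class x called-category count matrix.

    Rows are truth genotype classes (homref / het / homvar), columns the
    called categories: ``no_hcdiff`` (no call at a covered site),
    homref / het / homvar VAF-band calls, and ``not_covered`` (local depth
    below the coverage floor, or alignment problems).
    """

    def __init__(self, frame: pd.DataFrame):
        missing = set(TRUTH_CLASSES) - set(frame.index)
        if missing:
            raise ValueError(f"concordance table missing truth rows {sorted(missing)}")
        self.frame = frame.reindex(index=list(TRUTH_CLASSES), columns=list(CALL_CATEGORIES)).fillna(0).astype(int)

    @classmethod
    def from_counts(cls, counts: Mapping[str, Mapping[str, int]]) -> "ConcordanceTable":
        """Build from nested {truth_class: {called_category: count}}."""
        return cls(pd.DataFrame(counts).T)

    def truth_total(self, truth_class: str) -> int:
        return int(self.frame.loc[truth_class].sum())

    def __getitem__(self, key: tuple[str, str]) -> int:
        truth_class, called = key
        return int(self.frame.loc[truth_class, called])

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index_label="truth_class")


def _truth_class(record: TruthRecord | tuple) -> tuple[str, int, str, Optional[str]]:
    """Normalise a truth entry to (region, position, class, alt or None)."""
    if isinstance(record, TruthRecord):
        if record.copies_variant == 0:
            cls = "homref"
        elif record.copies_variant == record.copies_total:
            cls = "homvar"
        else:
            cls = "het"
        return record.region, record.position, cls, record.alt_allele
    region, position, cls = record[:3]
    if cls not in TRUTH_CLASSES:
        raise ValueError(f"unknown truth class {cls!r}")
    alt = record[3] if len(record) > 3 else None
    return region, int(position), cls, alt


def build_concordance(
    calls: Sequence[VariantCall],
    truth: Sequence[TruthRecord | tuple],
    depth: Mapping[str, RegionPileup] | Callable[[str, int], int] | None,
    min_depth: int = DEFAULT_MIN_DEPTH,
    diploid_cn: int = 2,
) -> ConcordanceTable:
    """Assign every truth site to exactly one called category.

    Sites with local depth below ``min_depth`` are "not covered" whatever
    was called there; covered sites take the genotype band of the passed
    call at that position, or ``no_hcdiff`` when there is none. Only calls
    with status 'passed' (or 'raw', for unfiltered comparisons) count.
    """
    call_index: dict[tuple[str, int], VariantCall] = {}
    for call in calls:
        if call.status in ("masked", "filtered"):
            continue
        call_index[(call.region, call.position)] = call

    if depth is None:
        depth_of = lambda region, position: min_depth  # treat all as covered
    elif callable(depth):
        depth_of = depth
    else:
        piles = depth
        depth_of = lambda region, position: int(piles[region].depth[position - 1])

    counts = {t: {c: 0 for c in CALL_CATEGORIES} for t in TRUTH_CLASSES}
    seen: set[tuple[str, int]] = set()
    for record in truth:
        region, position, truth_cls, _alt = _truth_class(record)
        if (region, position) in seen:
            raise ValueError(f"duplicate truth position {region}:{position}")
        seen.add((region, position))
        if depth_of(region, position) < min_depth:
            counts[truth_cls]["not_covered"] += 1
            continue
        call = call_index.get((region, position))
        if call is None:
            counts[truth_cls]["no_hcdiff"] += 1
        else:
            counts[truth_cls][classify_vaf(call, diploid_cn).label] += 1
    return ConcordanceTable.from_counts(counts)


def sensitivity(table: ConcordanceTable, truth_class: str) -> float:
    """Concordant calls of a class over the truth-class total, in percent.

    For homref truth, both ``no_hcdiff`` and an explicit homref-band call
    count as concordant.
    """
    total = table.truth_total(truth_class)
    if total == 0:
        raise ValueError(f"no truth sites of class {truth_class!r}")
    concordant = table[truth_class, truth_class]
    if truth_class == "homref":
        concordant += table[truth_class, "no_hcdiff"]
    return round_half_up(100.0 * concordant / total, 1)


def specificity(table: ConcordanceTable, call_class: str) -> float:
    """Concordant calls over all same-class calls at truth-annotated sites.

    This is the precision-style measure of the published comparison table,
    in percent to one decimal.
    """
    column = int(table.frame[call_class].sum())
    if column == 0:
        raise ValueError(f"no calls of class {call_class!r} at truth sites")
    return round_half_up(100.0 * table[call_class, call_class] / column, 1)


def snv_density(snv_count: int, effective_length_kb: float) -> float:
    """SNVs per kb over the effective (unmasked) length, one decimal."""
    if effective_length_kb <= 0:
        raise ValueError("effective length must be > 0 kb")
    if snv_count < 0:
        raise ValueError("snv_count must be >= 0")
    return round_half_up(snv_count / effective_length_kb, 1)


@dataclass
class UnionResult:
    """Cross-sample SNV union with known/novel accounting."""

    keys: set[tuple]
    n_unique: int
    n_known: int
    n_novel: int
    per_region: pd.DataFrame  # region x (known, novel)


def _call_key_flag(item, match_allele: bool) -> tuple[tuple, bool]:
    if isinstance(item, VariantCall):
        known = item.known_flag == "known"
        key = (item.region, item.position, item.alt_allele) if match_allele else (
            item.region, item.position)
        return key, known
    region, position, alt, known = item
    known = known in (True, "known")
    key = (region, int(position), alt) if match_allele else (region, int(position))
    return key, known


def union_snvs(
    call_sets: Mapping[str, Iterable],
    match_allele: bool = False,
) -> UnionResult:
    """Union of per-sample SNV sets, partitioned known/novel per region.

    Items may be :class:`VariantCall` objects or
    (region, position, alt, known_flag) tuples. A position listed as known
    in any sample counts as known in the union.
    """
    if not call_sets:
        raise ValueError("need at least one sample call set")
    known_by_key: dict[tuple, bool] = {}
    for _sample, items in call_sets.items():
        for item in items:
            key, known = _call_key_flag(item, match_allele)
            known_by_key[key] = known_by_key.get(key, False) or known
    per_region: dict[str, dict[str, int]] = {}
    n_known = 0
    for key, known in known_by_key.items():
        region = key[0]
        bucket = per_region.setdefault(region, {"known": 0, "novel": 0})
        if known:
            bucket["known"] += 1
            n_known += 1
        else:
            bucket["novel"] += 1
    frame = pd.DataFrame(per_region).T.fillna(0).astype(int).sort_index()
    return UnionResult(
        keys=set(known_by_key),
        n_unique=len(known_by_key),
        n_known=n_known,
        n_novel=len(known_by_key) - n_known,
        per_region=frame,
    )


@dataclass(frozen=True)
class Extrapolation:
    """Multi-copy sensitivity extrapolated from the single-copy regime."""

    expected_single_copy: int  # observed / single-copy sensitivity, rounded
    expected_total: int  # x copy multiple
    sensitivity_percent: int


def extrapolate_multicopy_sensitivity(
    observed_single_copy: int,
    single_copy_sensitivity: float,
    copy_multiple: int,
    observed_multicopy: int,
) -> Extrapolation:
    """Detection sensitivity in a high-copy region, by extrapolation.

    The SNV count observed in the 2-copy sample is corrected for the
    single-copy detection sensitivity, multiplied by the haploid copy
    multiple to give the expected count in the high-copy sample, and the
    observed high-copy count is expressed as an integer percentage of it.
    """
    if not 0 < single_copy_sensitivity <= 1:
        raise ValueError("single_copy_sensitivity must lie in (0, 1]")
    if copy_multiple < 1:
        raise ValueError("copy_multiple must be >= 1")
    expected_single = int(round_half_up(observed_single_copy / single_copy_sensitivity))
    expected_total = expected_single * copy_multiple
    if expected_total == 0:
        raise ValueError("expected SNV count is zero")
    percent = int(round_half_up(100.0 * observed_multicopy / expected_total))
    return Extrapolation(expected_single, expected_total, percent)
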