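"""Read-backed haplotyping and copy-number estimation from haplotype ratios.

In windows dense enough in SNVs (>= 9 per kb), single long reads span
several variant positions, so the ordered tuple of alleles a read carries —
a read-backed haplotype — can be observed directly. At a locus present in
C copies per diploid genome, each distinct haplotype occupies an integer
number of copies, and read counts per haplotype are (up to sampling noise)
proportional to those integers. Recovering the smallest integer vector
compatible with the observed counts and summing it therefore estimates C.

The integer-ratio search formalises what used to be done by eye: totals T
are tried from the number of distinct haplotypes upward; for each T the
best assignment of T copies to haplotypes (every haplotype >= 1 copy) is
found by exact search over integer compositions, scored by a chi-square
goodness-of-fit against expected counts total * c_i / T; the smallest T
not rejected at level alpha wins. Two-haplotype loci are fundamentally
scale-ambiguous (1:1 fits 2, 4, 6 ... copies); the haploid multiplicity
scale must then be supplied externally and the estimate is flagged when it
was defaulted.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import gcd
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._util import round_half_up
from .calling import VariantCall
from .io import AlignedRead, string_to_phred

DEFAULT_MIN_DENSITY = 9.0  # SNVs per kb
DEFAULT_MIN_READS_PER_HAP = 5
DEFAULT_ALPHA = 0.3
DEFAULT_MAX_TOTAL = 16


@dataclass(frozen=True)
class Htcr:
    """A haplotyping candidate region: a window of high SNV density."""

    region: str
    start: int  # 0-based half-open genomic window
    end: int
    snv_positions: tuple[int, ...]  # 1-based, ordered
    density: float  # SNVs per kb

    def __post_init__(self):
        if len(self.snv_positions) < 2:
            raise ValueError("an HTCR needs at least 2 SNVs")


@dataclass
class HaplotypeTally:
    """Read counts per allele tuple over one SNV combination."""

    snv_combination: tuple[int, ...]  # 1-based positions, 2..7 SNVs
    counts: dict[tuple[str, ...], int]
    total_reads: int

    @classmethod
    def from_counts(
        cls, counts: Mapping[tuple[str, ...] | str, int],
        snv_combination: Sequence[int] = (),
    ) -> "HaplotypeTally":
        """Build a tally directly from haplotype -> read-count pairs."""
        norm = {
            (k if isinstance(k, tuple) else (k,)): int(v) for k, v in counts.items()
        }
        return cls(tuple(snv_combination), norm, sum(norm.values()))

    def count_vector(self) -> tuple[int, ...]:
        """Counts in insertion (observation) order."""
        return tuple(self.counts.values())


@dataclass(frozen=True)
class RatioFit:
    """Result of the integer-ratio search."""

    ratio: tuple[int, ...]
    total: int
    chisq: float
    pvalue: float
    alpha: float
    ambiguous: bool  # ratio reducible (scalar multiple of a smaller vector)


@dataclass
class CnEstimate:
    """One locus' diploid copy-number estimate."""

    ratio: tuple[int, ...]
    haploid_scale: int
    diploid_cn: int
    reads_used: int
    ambiguous_flag: bool
    counts: Optional[tuple[int, ...]] = None
    snv_combination: tuple[int, ...] = ()
    region: str = ""


@dataclass
class CnSummary:
    count: int
    mean: float
    min: int
    max: int
    sd: float
    pooled_two_hap_ratio: Optional[float]


# ---------------------------------------------------------------------------
# HTCR selection
# ---------------------------------------------------------------------------

def find_htcrs(
    calls: Sequence[VariantCall] | Sequence[tuple[str, int]],
    min_density: float = DEFAULT_MIN_DENSITY,
    min_snvs: int = 2,
    window: int = 1000,
) -> list[Htcr]:
    """Select maximal high-SNV-density windows from passed calls.

    A window of ``window`` bases anchored at an SNV qualifies when it holds
    at least ``min_density`` SNVs (densities are per kb with window = 1 kb);
    overlapping qualifying windows merge into one maximal HTCR, trimmed to
    its first and last SNV. Dense blocks separated by SNV deserts wider
    than the window therefore yield separate HTCRs.
    """
    sites: dict[str, list[int]] = {}
    for c in calls:
        if isinstance(c, VariantCall):
            sites.setdefault(c.region, []).append(c.position)
        else:
            region, position = c
            sites.setdefault(region, []).append(position)
    min_count = int(np.ceil(min_density * window / 1000.0))
    out: list[Htcr] = []
    for region in sorted(sites):
        pos = np.array(sorted(set(sites[region])), dtype=np.int64)
        if pos.size < max(min_count, min_snvs):
            continue
        # count of SNVs in [p_i, p_i + window)
        upper = np.searchsorted(pos, pos + window, side="left")
        counts = upper - np.arange(pos.size)
        anchors = np.flatnonzero(counts >= min_count)
        if anchors.size == 0:
            continue
        # merge overlapping qualifying windows
        merged: list[list[int]] = []
        for i in anchors:
            s, e = int(pos[i]), int(pos[i]) + window
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        for s, e in merged:
            inside = pos[(pos >= s) & (pos < e)]
            if inside.size < max(min_count, min_snvs):
                continue
            span = int(inside[-1] - inside[0] + 1)
            density = inside.size / (max(span, window) / 1000.0)
            out.append(
                Htcr(
                    region=region,
                    start=int(inside[0]) - 1,
                    end=int(inside[-1]),
                    snv_positions=tuple(int(p) for p in inside),
                    density=density,
                )
            )
    return out


def select_combinations(
    htcr: Htcr,
    max_span: int = 200,
    max_snvs: int = 7,
    min_snvs: int = 2,
) -> list[tuple[int, ...]]:
    """Greedy non-overlapping consecutive SNV runs a single read can span.

    Runs grow while the genomic span stays within ``max_span`` (which must
    be well below the read length for enough reads to cover the whole
    combination) and the run holds at most ``max_snvs`` SNVs.
    """
    combos: list[tuple[int, ...]] = []
    positions = htcr.snv_positions
    i = 0
    while i < len(positions):
        j = i + 1
        while (
            j < len(positions)
            and j - i < max_snvs
            and positions[j] - positions[i] <= max_span
        ):
            j += 1
        if j - i >= min_snvs:
            combos.append(positions[i:j])
        i = j if j > i + 1 else i + 1
    return combos


# ---------------------------------------------------------------------------
# Tallying
# ---------------------------------------------------------------------------

def tally_haplotypes(
    reads: Iterable[AlignedRead],
    combination: Sequence[int],
    min_reads_per_hap: int = DEFAULT_MIN_READS_PER_HAP,
    min_total: int = 10,
    min_q: int = 20,
) -> Optional[HaplotypeTally]:
    """Count read-backed haplotypes over an SNV combination.

    Only reads spanning *every* position of the combination with an
    unambiguous, quality-passing base are counted. Haplotypes seen on
    fewer than ``min_reads_per_hap`` reads are dropped; the tally is
    returned only if the surviving total reaches ``min_total`` (10 is the
    working threshold for a 2-copy locus, 30 for a 6-copy one).
    """
    combination = tuple(int(p) for p in combination)
    if len(combination) < 2:
        raise ValueError("a combination needs at least 2 SNV positions")
    counts: dict[tuple[str, ...], int] = {}
    lo, hi = combination[0] - 1, combination[-1]  # 0-based half-open span
    for read in reads:
        if read.start > lo or read.end < hi:
            continue
        quals = string_to_phred(read.quality)
        alleles = []
        for position in combination:
            off = position - 1 - read.start
            base = read.sequence[off]
            if base == "N" or quals[off] < min_q:
                alleles = None
                break
            alleles.append(base)
        if alleles is None:
            continue
        key = tuple(alleles)
        counts[key] = counts.get(key, 0) + 1
    kept = {k: v for k, v in counts.items() if v >= min_reads_per_hap}
    total = sum(kept.values())
    if not kept or total < min_total:
        return None
    return HaplotypeTally(combination, kept, total)


# ---------------------------------------------------------------------------
# Integer ratios and copy numbers
# ---------------------------------------------------------------------------

def _best_assignment(counts: np.ndarray, total: int) -> tuple[tuple[int, ...], float] | None:
    """Best (min chi-square) assignment of ``total`` copies, each haplotype >= 1.

    Exact search over positive integer compositions; k <= 7 and total <= 16
    keep this trivially small.
    """
    k = counts.size
    if total < k:
        return None
    best: tuple[int, ...] | None = None
    best_chi = np.inf
    s = counts.sum()
    # compositions of total into k positive parts via strictly increasing cuts
    for cuts in combinations(range(1, total), k - 1):
        bounds = (0,) + cuts + (total,)
        parts = [bounds[i + 1] - bounds[i] for i in range(k)]
        expected = s * np.array(parts, dtype=float) / total
        chi = float(((counts - expected) ** 2 / expected).sum())
        if chi < best_chi - 1e-12:
            best_chi = chi
            best = tuple(parts)
    if best is None:
        return None
    return best, best_chi


def integer_ratio(
    counts: Sequence[int],
    alpha: float = DEFAULT_ALPHA,
    max_total: int = DEFAULT_MAX_TOTAL,
) -> RatioFit:
    """Smallest integer copy vector consistent with haplotype read counts.

    Searches totals T upward from the number of haplotypes; for each T the
    best positive-integer assignment (exact composition search) is scored
    by chi-square goodness of fit (df = k - 1) against expected counts
    sum(counts) * c_i / T, and the first T not rejected at ``alpha`` is
    accepted. If no T up to ``max_total`` is acceptable the best-fitting
    assignment overall is returned (its p-value exposes the poor fit).
    """
    arr = np.asarray(list(counts), dtype=np.int64)
    if arr.size < 2:
        raise ValueError("need at least 2 haplotype counts")
    if (arr <= 0).any():
        raise ValueError("all haplotype counts must be positive")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    farr = arr.astype(float)
    df = arr.size - 1
    fallback: RatioFit | None = None
    for total in range(arr.size, max_total + 1):
        found = _best_assignment(farr, total)
        if found is None:
            continue
        parts, chi = found
        pvalue = float(stats.chi2.sf(chi, df))
        fit = RatioFit(
            ratio=parts,
            total=total,
            chisq=chi,
            pvalue=pvalue,
            alpha=alpha,
            ambiguous=gcd(*parts) > 1,
        )
        if pvalue >= alpha:
            return fit
        if fallback is None or fit.pvalue > fallback.pvalue:
            fallback = fit
    assert fallback is not None
    return fallback


def cn_from_ratio(
    ratio: Sequence[int] | RatioFit,
    haploid_scale: Optional[int] = None,
    ploidy: int = 2,
    counts: Optional[Sequence[int]] = None,
    reads_used: Optional[int] = None,
    snv_combination: Sequence[int] = (),
    region: str = "",
) -> CnEstimate:
    """Diploid copy number from an integer haplotype ratio.

    With three or more distinct haplotypes the ratio itself fixes the copy
    number: CN = sum(ratio) (scale 1). With exactly two haplotypes the
    ratio only fixes CN up to an integer multiple; ``haploid_scale`` (the
    haploid-multiplicity annotation, e.g. 2 for a "3n" locus under
    ploidy 2) must come from external knowledge, and the estimate is
    flagged ambiguous when it was left at the default of 1.
    """
    if isinstance(ratio, RatioFit):
        ratio = ratio.ratio
    ratio = tuple(int(r) for r in ratio)
    ambiguous = False
    if len(ratio) == 2:
        if haploid_scale is None:
            haploid_scale = 1
            ambiguous = True
    else:
        if haploid_scale is None:
            haploid_scale = 1
    if haploid_scale < 1:
        raise ValueError("haploid_scale must be >= 1")
    diploid_cn = sum(ratio) * haploid_scale
    return CnEstimate(
        ratio=ratio,
        haploid_scale=haploid_scale,
        diploid_cn=diploid_cn,
        reads_used=int(reads_used) if reads_used is not None else (
            int(sum(counts)) if counts is not None else 0
        ),
        ambiguous_flag=ambiguous,
        counts=tuple(int(c) for c in counts) if counts is not None else None,
        snv_combination=tuple(int(p) for p in snv_combination),
        region=region,
    )


def pooled_ratio(pairs: Iterable[tuple[int, int]]) -> float:
    """Pooled two-haplotype read ratio: sum of first counts over second.

    Summing counts over all two-haplotype loci before taking the ratio
    suppresses per-locus sampling noise (e.g. pooled 172:173 -> 0.99).
    """
    a = b = 0
    for x, y in pairs:
        a += int(x)
        b += int(y)
    if b == 0:
        raise ValueError("second pooled count is zero")
    return round_half_up(a / b, 2)


def aggregate_cn(estimates: Sequence[CnEstimate]) -> CnSummary:
    """Summary statistics over diploid CN estimates plus the pooled
    two-haplotype read ratio (None when no two-haplotype locus is present).
    """
    if not estimates:
        raise ValueError("no CN estimates to aggregate")
    values = np.array([e.diploid_cn for e in estimates], dtype=float)
    pairs = [e.counts for e in estimates if e.counts is not None and len(e.counts) == 2]
    return CnSummary(
        count=len(estimates),
        mean=float(values.mean()),
        min=int(values.min()),
        max=int(values.max()),
        sd=float(values.std(ddof=1)) if len(estimates) > 1 else 0.0,
        pooled_two_hap_ratio=pooled_ratio(pairs) if pairs else None,
    )


def estimate_copy_numbers(
    reads: Sequence[AlignedRead],
    htcrs: Sequence[Htcr],
    min_total: int = 30,
    min_reads_per_hap: int = DEFAULT_MIN_READS_PER_HAP,
    max_span: int = 200,
    alpha: float = DEFAULT_ALPHA,
    min_q: int = 20,
) -> list[CnEstimate]:
    """Full haplotype-CN stage: combinations -> tallies -> ratios -> CNs.

    Two-haplotype tallies yield scale-ambiguous estimates (flagged); callers
    typically exclude those from CN averaging unless external scale
    information is available.
    """
    by_region: dict[str, list[AlignedRead]] = {}
    for read in reads:
        by_region.setdefault(read.region, []).append(read)
    estimates: list[CnEstimate] = []
    for htcr in htcrs:
        region_reads = by_region.get(htcr.region, [])
        # pre-restrict to reads overlapping the window
        window_reads = [
            r for r in region_reads if r.end > htcr.start and r.start < htcr.end
        ]
        for combo in select_combinations(htcr, max_span=max_span):
            tally = tally_haplotypes(
                window_reads, combo,
                min_reads_per_hap=min_reads_per_hap,
                min_total=min_total, min_q=min_q,
            )
            if tally is None or len(tally.counts) < 2:
                continue
            fit = integer_ratio(tally.count_vector(), alpha=alpha)
            estimates.append(
                cn_from_ratio(
                    fit,
                    counts=tally.count_vector(),
                    reads_used=tally.total_reads,
                    snv_combination=combo,
                    region=htcr.region,
                )
            )
    return estimates


def estimates_to_frame(estimates: Sequence[CnEstimate]) -> pd.DataFrame:
    """Tabular view mirroring the published per-locus CN table."""
    rows = []
    for e in estimates:
        rows.append(
            {
                "region": e.region,
                "snv_positions": ",".join(str(p) for p in e.snv_combination),
                "reads": e.reads_used,
                "counts": ":".join(str(c) for c in (e.counts or ())),
                "ratio": ":".join(str(r) for r in e.ratio),
                "haploid_scale": e.haploid_scale,
                "ambiguous": e.ambiguous_flag,
                "diploid_cn": e.diploid_cn,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "region", "snv_positions", "reads", "counts", "ratio",
            "haploid_scale", "ambiguous", "diploid_cn",
        ],
    )
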