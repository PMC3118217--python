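"""Candidate SNV detection from pileups.

A site is called when the most-supported non-reference base meets the
minimal-evidence rule used for high-confidence differences: at least 3
variant-supporting reads with Phred >= Q20 in each orientation, or at least
5 such reads in a single orientation. The one-orientation clause is applied
as max(forward, reverse) >= 5, which keeps calling monotone in added variant
evidence (a site never becomes uncalled because an extra supporting read
arrived on the other strand).

Depth n counts every read spanning the site regardless of base quality; the
Phred gate applies only to variant support inside the rule, so n stays
consistent with the local coverage used by the binomial error model. The
variant allele frequency (VAF) is computed from *all* variant-supporting
reads over depth, and calls below a 10 % VAF floor are suppressed,
mirroring the 10-100 % reporting range of the upstream mapping software.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from ._util import BASES, round_half_up
from .io import PileupColumn, RegionPileup

#: call statuses, in pipeline order
STATUSES = ("raw", "masked", "filtered", "passed")


@dataclass
class VariantCall:
    """One candidate single-nucleotide variant."""

    region: str
    position: int  # 1-based
    ref_allele: str
    alt_allele: str
    depth: int  # n: all reads spanning the site
    alt_count: int  # d: all reads supporting the alternate allele
    alt_forward: int
    alt_reverse: int
    vaf: float  # percent, full precision
    error_prob: Optional[float] = None
    status: str = "raw"
    known_flag: Optional[str] = None  # None (unset) / 'known' / 'novel'
    genotype_class: Optional[str] = None

    def __post_init__(self):
        if self.alt_forward + self.alt_reverse != self.alt_count:
            raise ValueError("alt_count must equal alt_forward + alt_reverse")
        if self.alt_count > self.depth:
            raise ValueError("alt_count cannot exceed depth")

    @property
    def vaf_rounded(self) -> float:
        """VAF to one decimal (reporting style, half-up)."""
        return round_half_up(self.vaf, 1)

    def key(self, with_allele: bool = True):
        if with_allele:
            return (self.region, self.position, self.alt_allele)
        return (self.region, self.position)


def _decide(
    region: str,
    position: int,
    ref_base: str,
    depth: int,
    alt_fwd: np.ndarray,
    alt_rev: np.ndarray,
    q_fwd: np.ndarray,
    q_rev: np.ndarray,
    min_support_both: int = 3,
    min_support_single: int = 5,
    vaf_floor: float = 10.0,
) -> Optional[VariantCall]:
    """Shared calling decision from per-allele count vectors (A,C,G,T)."""
    ref_idx = BASES.index(ref_base) if ref_base in BASES else -1
    totals = alt_fwd + alt_rev
    candidates = [i for i in range(4) if i != ref_idx and totals[i] > 0]
    if not candidates:
        return None
    # most-supported alternate; ties broken by base order A<C<G<T
    best = min(candidates, key=lambda i: (-totals[i], i))
    qf, qr = int(q_fwd[best]), int(q_rev[best])
    both = qf >= min_support_both and qr >= min_support_both
    single = max(qf, qr) >= min_support_single
    if not (both or single):
        return None
    alt_count = int(totals[best])
    vaf = 100.0 * alt_count / depth
    if vaf < vaf_floor:
        return None
    return VariantCall(
        region=region,
        position=position,
        ref_allele=ref_base,
        alt_allele=BASES[best],
        depth=int(depth),
        alt_count=alt_count,
        alt_forward=int(alt_fwd[best]),
        alt_reverse=int(alt_rev[best]),
        vaf=vaf,
    )


def call_site(column: PileupColumn, min_q: int = 20, vaf_floor: float = 10.0) -> Optional[VariantCall]:
    """Apply the calling rule to a single pileup column."""
    if column.depth < 1:
        return None
    alt_fwd = np.zeros(4, dtype=np.int64)
    alt_rev = np.zeros(4, dtype=np.int64)
    q_fwd = np.zeros(4, dtype=np.int64)
    q_rev = np.zeros(4, dtype=np.int64)
    for obs in column.observations:
        if obs.base == "N":
            continue  # N carries depth but never variant support
        i = BASES.index(obs.base)
        if obs.orientation == "+":
            alt_fwd[i] += 1
            if obs.quality >= min_q:
                q_fwd[i] += 1
        else:
            alt_rev[i] += 1
            if obs.quality >= min_q:
                q_rev[i] += 1
    return _decide(
        column.region, column.position, column.ref_allele,
        column.depth, alt_fwd, alt_rev, q_fwd, q_rev, vaf_floor=vaf_floor,
    )


def _call_region(pile: RegionPileup, vaf_floor: float) -> list[VariantCall]:
    """Vectorised candidate scan over a RegionPileup.

    Any call requires >= 5 quality-passing supporting reads, hence >= 5
    supporting reads overall, so positions where no non-reference allele
    reaches 5 total supporting reads are screened out in bulk and the exact
    per-column rule is applied to the survivors.
    """
    totals = pile.alt_fwd + pile.alt_rev
    non_ref = totals.copy()
    ref_ok = pile.ref_codes < 4
    rows = np.flatnonzero(ref_ok)
    non_ref[rows, pile.ref_codes[rows]] = 0
    candidates = np.flatnonzero(non_ref.max(axis=1) >= 5)
    calls = []
    for pos0 in candidates:
        ref_base = BASES[pile.ref_codes[pos0]] if pile.ref_codes[pos0] < 4 else "N"
        call = _decide(
            pile.region, int(pos0) + 1, ref_base, int(pile.depth[pos0]),
            pile.alt_fwd[pos0], pile.alt_rev[pos0],
            pile.q_fwd[pos0], pile.q_rev[pos0], vaf_floor=vaf_floor,
        )
        if call is not None:
            calls.append(call)
    return calls


def call_all(
    pileups: Mapping[str, RegionPileup] | Iterable[PileupColumn],
    min_q: int = 20,
    vaf_floor: float = 10.0,
) -> list[VariantCall]:
    """Call every pileup column; deterministic, (region, position)-sorted.

    Accepts either the dense per-region pileups (fast path) or an iterable
    of :class:`PileupColumn`. With dense pileups ``min_q`` must match the
    gate the pileup was built with.
    """
    calls: list[VariantCall] = []
    if isinstance(pileups, Mapping):
        for region in sorted(pileups):
            pile = pileups[region]
            if pile.min_q != min_q:
                raise ValueError(
                    f"pileup for {region} was built with min_q={pile.min_q}, "
                    f"calling requested min_q={min_q}"
                )
            calls.extend(_call_region(pile, vaf_floor))
    else:
        for column in pileups:
            call = call_site(column, min_q=min_q, vaf_floor=vaf_floor)
            if call is not None:
                calls.append(call)
    calls.sort(key=lambda c: (c.region, c.position))
    return calls


# ---------------------------------------------------------------------------
# Call set I/O
# ---------------------------------------------------------------------------

CALL_TSV_COLUMNS = [
    "region", "position", "ref_allele", "alt_allele", "depth", "alt_count",
    "alt_forward", "alt_reverse", "vaf", "error_prob", "status", "known_flag",
    "genotype_class",
]


def calls_to_frame(calls: Sequence[VariantCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        row = {k: getattr(c, k) for k in CALL_TSV_COLUMNS}
        row["vaf"] = c.vaf_rounded
        rows.append(row)
    return pd.DataFrame(rows, columns=CALL_TSV_COLUMNS)


def write_calls_tsv(calls: Sequence[VariantCall], path: str | Path) -> None:
    calls_to_frame(calls).to_csv(path, sep="\t", index=False, na_rep=".")


def read_calls_tsv(path: str | Path) -> list[VariantCall]:
    df = pd.read_csv(path, sep="\t", na_values=["."])
    out = []
    for row in df.itertuples(index=False):
        out.append(
            VariantCall(
                region=row.region,
                position=int(row.position),
                ref_allele=row.ref_allele,
                alt_allele=row.alt_allele,
                depth=int(row.depth),
                alt_count=int(row.alt_count),
                alt_forward=int(row.alt_forward),
                alt_reverse=int(row.alt_reverse),
                vaf=float(row.vaf),
                error_prob=None if pd.isna(row.error_prob) else float(row.error_prob),
                status=row.status,
                known_flag=None if pd.isna(row.known_flag) else row.known_flag,
                genotype_class=None
                if pd.isna(row.genotype_class)
                else row.genotype_class,
            )
        )
    return out


def write_calls_vcf(calls: Sequence[VariantCall], path: str | Path) -> None:
    """Write calls as a minimal VCF with DP/AD/VAF/P/STATUS INFO keys."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for region in sorted({c.region for c in calls}):
            fh.write(f"##contig=<ID={region}>\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##INFO=<ID=AD,Number=1,Type=Integer,Description="Alternate-supporting reads">\n')
        fh.write('##INFO=<ID=VAF,Number=1,Type=Float,Description="Variant allele frequency, percent">\n')
        fh.write('##INFO=<ID=P,Number=1,Type=Float,Description="Binomial posterior error probability">\n')
        fh.write('##INFO=<ID=STATUS,Number=1,Type=String,Description="raw/masked/filtered/passed">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in calls:
            p = "." if c.error_prob is None else f"{c.error_prob:.6g}"
            ident = "." if c.known_flag is None else c.known_flag
            filt = "PASS" if c.status == "passed" else c.status
            fh.write(
                f"{c.region}\t{c.position}\t{ident}\t{c.ref_allele}\t{c.alt_allele}\t.\t{filt}\t"
                f"DP={c.depth};AD={c.alt_count};VAF={c.vaf_rounded};P={p};STATUS={c.status}\n"
            )
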