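"""Alignment and interval I/O plus per-site pileups.

Reads are represented gap-free (substitution-only analyses; indels are out of
scope) with explicit alignment coordinates, so a pileup column at reference
position ``p`` collects ``read.sequence[p - read.start]`` from every read
spanning ``p``. Coordinates are 0-based half-open internally; emitted variant
tables and the read TSV use 1-based starts, BED stays half-open on disk.

Two pileup representations are provided:

* :func:`build_pileups` yields one :class:`PileupColumn` per covered position,
  carrying the individual read observations (base, orientation, quality) —
  convenient for inspection and small data.
* :class:`RegionPileup` holds the same evidence as dense per-position count
  arrays for a whole region, which is what genome-scale calling uses.

Both are built from the same reads and agree column by column.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from ._util import BASE_TO_CODE, encode_bases, string_to_phred

logger = logging.getLogger(__name__)

READ_TSV_COLUMNS = ["read_id", "region", "start", "strand", "sequence", "quality"]


@dataclass(frozen=True)
class ReadObservation:
    """One read's evidence at one reference position."""

    base: str
    orientation: str  # '+' or '-'
    quality: int
    read_id: str

    def __post_init__(self):
        if self.base not in BASE_TO_CODE:
            raise ValueError(f"invalid base {self.base!r}")
        if self.orientation not in "+-":
            raise ValueError(f"invalid orientation {self.orientation!r}")
        if self.quality < 0:
            raise ValueError("quality must be >= 0")


@dataclass
class PileupColumn:
    """All read evidence at a single 1-based reference position."""

    region: str
    position: int  # 1-based
    ref_allele: str
    observations: list[ReadObservation] = field(default_factory=list)

    @property
    def depth(self) -> int:
        return len(self.observations)


@dataclass(frozen=True)
class AlignedRead:
    """A gap-free aligned read; ``sequence`` is in reference orientation."""

    read_id: str
    region: str
    start: int  # 0-based leftmost reference position
    strand: str  # '+' or '-'
    sequence: str
    quality: str  # Phred+33

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")
        if len(self.quality) != len(self.sequence):
            raise ValueError(
                f"read {self.read_id}: quality length {len(self.quality)} "
                f"!= sequence length {len(self.sequence)}"
            )
        if self.start < 0:
            raise ValueError("start must be >= 0")

    @property
    def end(self) -> int:
        """0-based exclusive end on the reference."""
        return self.start + len(self.sequence)


class IntervalSet:
    """Half-open intervals per region with point-membership queries."""

    def __init__(self, intervals: Iterable[tuple[str, int, int]]):
        per_region: dict[str, list[tuple[int, int]]] = {}
        for region, start, end in intervals:
            if not start < end:
                raise ValueError(f"interval start {start} must be < end {end}")
            per_region.setdefault(region, []).append((int(start), int(end)))
        self._merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for region, ivs in per_region.items():
            ivs.sort()
            merged: list[list[int]] = []
            for s, e in ivs:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            starts = np.array([m[0] for m in merged], dtype=np.int64)
            ends = np.array([m[1] for m in merged], dtype=np.int64)
            self._merged[region] = (starts, ends)

    @classmethod
    def from_bed(cls, path: str | Path) -> "IntervalSet":
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            usecols=[0, 1, 2], names=["region", "start", "end"],
        )
        return cls(df.itertuples(index=False, name=None))

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for region, start, end in self.intervals():
                fh.write(f"{region}\t{start}\t{end}\n")

    def intervals(self) -> list[tuple[str, int, int]]:
        out = []
        for region in sorted(self._merged):
            starts, ends = self._merged[region]
            out.extend((region, int(s), int(e)) for s, e in zip(starts, ends))
        return out

    def regions(self) -> list[str]:
        return sorted(self._merged)

    def contains(self, region: str, pos: int) -> bool:
        """Membership of 0-based position ``pos`` (end coordinate excluded)."""
        if region not in self._merged:
            return False
        starts, ends = self._merged[region]
        i = bisect_right(starts, pos) - 1
        return i >= 0 and pos < ends[i]

    def total_length(self, region: str | None = None) -> int:
        if region is not None:
            if region not in self._merged:
                return 0
            starts, ends = self._merged[region]
            return int((ends - starts).sum())
        return sum(self.total_length(r) for r in self._merged)

    def mask_array(self, region: str, length: int) -> np.ndarray:
        """Boolean membership array over positions 0..length-1."""
        out = np.zeros(length, dtype=bool)
        if region in self._merged:
            starts, ends = self._merged[region]
            for s, e in zip(starts, ends):
                out[max(0, s):min(length, e)] = True
        return out


# ---------------------------------------------------------------------------
# Read set I/O
# ---------------------------------------------------------------------------

def write_alignments_tsv(reads: Iterable[AlignedRead], path: str | Path) -> None:
    """Write the 6-column read TSV (start emitted 1-based, SAM-like)."""
    with open(path, "w") as fh:
        fh.write("\t".join(READ_TSV_COLUMNS) + "\n")
        for r in reads:
            fh.write(
                f"{r.read_id}\t{r.region}\t{r.start + 1}\t{r.strand}\t"
                f"{r.sequence}\t{r.quality}\n"
            )


def _read_alignments_tsv(path: str | Path) -> list[AlignedRead]:
    reads: list[AlignedRead] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != READ_TSV_COLUMNS:
            raise ValueError(
                f"{path}: line 1: expected header {READ_TSV_COLUMNS}, got {header}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise ValueError(f"{path}: line {lineno}: expected 6 columns")
            read_id, region, start, strand, seq, qual = fields
            try:
                reads.append(
                    AlignedRead(read_id, region, int(start) - 1, strand, seq, qual)
                )
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    return reads


def _read_alignments_sam(path: str | Path) -> list[AlignedRead]:
    """Load primary, mapped, gap-free records from a SAM file.

    Unmapped/secondary/supplementary records and records whose CIGAR contains
    anything besides matches and soft clips are skipped with a logged count —
    only fully aligned substitution-style evidence enters the pileup.
    """
    reads: list[AlignedRead] = []
    skipped = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                skipped += 1
                continue
            if rec.cigartuples and any(op not in (0, 4, 7, 8) for op, _ in rec.cigartuples):
                skipped += 1
                continue
            seq = rec.query_alignment_sequence
            quals = rec.query_alignment_qualities
            if seq is None or quals is None:
                skipped += 1
                continue
            reads.append(
                AlignedRead(
                    rec.query_name,
                    rec.reference_name,
                    rec.reference_start,
                    "-" if rec.is_reverse else "+",
                    seq.upper(),
                    "".join(chr(q + 33) for q in quals),
                )
            )
    if skipped:
        logger.info("skipped %d unusable SAM records", skipped)
    return reads


def read_alignments(path: str | Path, fmt: str | None = None) -> list[AlignedRead]:
    """Read aligned reads from SAM or the documented 6-column TSV."""
    path = Path(path)
    if fmt is None:
        fmt = "sam" if path.suffix.lower() == ".sam" else "tsv"
    if fmt == "sam":
        return _read_alignments_sam(path)
    if fmt == "tsv":
        return _read_alignments_tsv(path)
    raise ValueError(f"unknown alignment format {fmt!r}")


def write_alignments_sam(
    reads: Iterable[AlignedRead], path: str | Path, region_lengths: Mapping[str, int]
) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": int(length)} for name, length in region_lengths.items()],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for r in reads:
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.read_id
            a.query_sequence = r.sequence
            a.reference_name = r.region
            a.reference_start = r.start
            a.mapping_quality = 60
            a.cigartuples = [(0, len(r.sequence))]
            a.flag = 16 if r.strand == "-" else 0
            a.query_qualities = pysam.qualitystring_to_array(r.quality)
            out.write(a)


# ---------------------------------------------------------------------------
# Pileups
# ---------------------------------------------------------------------------

class RegionPileup:
    """Dense per-position pileup counts for one region.

    Arrays (length L = region length):

    ``depth``     reads spanning each position (any base, any quality);
    ``alt_fwd`` / ``alt_rev``   per-base (A,C,G,T) counts from forward/reverse
                  reads, regardless of base quality (N excluded);
    ``q_fwd`` / ``q_rev``       same, restricted to bases with Phred >= min_q.

    ``depth`` deliberately counts low-quality and N bases so that it matches
    the local coverage n used by the binomial error model; the Phred gate
    applies only to variant *support* in the calling rule.
    """

    def __init__(self, region: str, ref_codes: np.ndarray, min_q: int = 20):
        self.region = region
        self.ref_codes = ref_codes
        self.min_q = min_q
        L = len(ref_codes)
        self.depth = np.zeros(L, dtype=np.int32)
        self.alt_fwd = np.zeros((L, 4), dtype=np.int32)
        self.alt_rev = np.zeros((L, 4), dtype=np.int32)
        self.q_fwd = np.zeros((L, 4), dtype=np.int32)
        self.q_rev = np.zeros((L, 4), dtype=np.int32)

    @property
    def length(self) -> int:
        return len(self.ref_codes)

    def add_read(self, read: AlignedRead) -> None:
        codes = encode_bases(read.sequence)
        quals = string_to_phred(read.quality)
        if read.end > self.length:
            raise ValueError(
                f"read {read.read_id} extends past region {self.region} "
                f"({read.end} > {self.length})"
            )
        idx = np.arange(read.start, read.end)
        self.depth[read.start:read.end] += 1
        real = codes < 4  # N carries depth but never allele support
        fwd = read.strand == "+"
        tgt_all = self.alt_fwd if fwd else self.alt_rev
        tgt_q = self.q_fwd if fwd else self.q_rev
        np.add.at(tgt_all, (idx[real], codes[real]), 1)
        qok = real & (quals >= self.min_q)
        np.add.at(tgt_q, (idx[qok], codes[qok]), 1)

    @classmethod
    def build(
        cls, region: str, ref_codes: np.ndarray, reads: Iterable[AlignedRead],
        min_q: int = 20,
    ) -> "RegionPileup":
        pile = cls(region, ref_codes, min_q=min_q)
        for read in reads:
            if read.region != region:
                raise ValueError(f"read {read.read_id} maps to {read.region}, not {region}")
            pile.add_read(read)
        return pile


def build_region_pileups(
    reads: Sequence[AlignedRead],
    reference: Mapping[str, str] | Mapping[str, np.ndarray],
    min_q: int = 20,
) -> dict[str, RegionPileup]:
    """Build one :class:`RegionPileup` per reference region."""
    by_region: dict[str, list[AlignedRead]] = {}
    for read in reads:
        if read.region not in reference:
            raise ValueError(f"read {read.read_id} references unknown region {read.region!r}")
        by_region.setdefault(read.region, []).append(read)
    out = {}
    for region, seq in reference.items():
        codes = seq if isinstance(seq, np.ndarray) else encode_bases(seq)
        out[region] = RegionPileup.build(region, codes, by_region.get(region, []), min_q=min_q)
    return out


def build_pileups(
    reads: Sequence[AlignedRead],
    reference: Mapping[str, str],
    intervals: IntervalSet | None = None,
) -> Iterator[PileupColumn]:
    """Yield per-position pileup columns for every covered position.

    Columns are emitted in (region, position) order and only inside
    ``intervals`` when given. The result does not depend on read input order.
    """
    by_region: dict[str, list[AlignedRead]] = {}
    for read in reads:
        if read.region not in reference:
            raise ValueError(f"read {read.read_id} references unknown region {read.region!r}")
        by_region.setdefault(read.region, []).append(read)

    for region in sorted(by_region):
        ref = reference[region]
        columns: dict[int, list[ReadObservation]] = {}
        for read in sorted(by_region[region], key=lambda r: (r.start, r.read_id)):
            quals = string_to_phred(read.quality)
            for offset, base in enumerate(read.sequence):
                pos0 = read.start + offset
                if pos0 >= len(ref):
                    raise ValueError(
                        f"read {read.read_id} extends past region {region}"
                    )
                if intervals is not None and not intervals.contains(region, pos0):
                    continue
                columns.setdefault(pos0, []).append(
                    ReadObservation(base, read.strand, int(quals[offset]), read.read_id)
                )
        for pos0 in sorted(columns):
            yield PileupColumn(region, pos0 + 1, ref[pos0], columns[pos0])


def coverage_summary(
    pileups: Mapping[str, RegionPileup],
    intervals: IntervalSet | None = None,
    min_depth: int = 2,
) -> pd.DataFrame:
    """Per-region mean depth and fraction of bases covered >= ``min_depth``.

    When ``intervals`` is given, statistics are restricted to interval bases;
    otherwise the whole region counts.
    """
    rows = []
    for region in sorted(pileups):
        pile = pileups[region]
        if intervals is not None:
            mask = intervals.mask_array(region, pile.length)
        else:
            mask = np.ones(pile.length, dtype=bool)
        depths = pile.depth[mask]
        if depths.size == 0:
            continue
        rows.append(
            {
                "region": region,
                "bases": int(depths.size),
                "mean_depth": float(depths.mean()),
                f"frac_ge_{min_depth}": float((depths >= min_depth).mean()),
            }
        )
    return pd.DataFrame(rows)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA file into an ordered name -> sequence dict."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
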