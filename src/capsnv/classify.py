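"""Paralog masking, error-probability filtering, VAF genotype bands and
known/novel annotation.

Candidate calls pass two successive filters. First, calls inside masked
intervals (near-identical segmental duplications whose paralogs co-enrich
with the target and confound allele assignment) are excluded. Second, each
surviving call receives the binomial posterior error probability P for its
depth and alternate-read count; calls with P above the model threshold
(default 1e-3) are discarded as error-prone.

Surviving calls are genotyped from their VAF. For a 2-copy locus the bands
are the classical ones: [10, 25) ambiguous/homozygous-reference band,
[25, 75] heterozygous, (75, 100] homozygous variant. For a 6-copy locus the
six "k of 6" bands are [10,25), [25,43), [43,59), [59,76), [76,93),
[93,100]. For any other copy number the bands are generated from midpoints
between consecutive expected VAFs 100*k/cn, floored at the 10 % reporting
limit (an extension beyond the two documented cases).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .calling import VariantCall
from .error_model import ErrorModel, binomial_tail
from .io import IntervalSet


@dataclass(frozen=True)
class GenotypeClass:
    """A VAF band and its genotype label."""

    label: str
    low: float  # percent
    high: float  # percent
    high_inclusive: bool = False
    low_inclusive: bool = True

    def contains(self, vaf: float) -> bool:
        if vaf < self.low or (vaf == self.low and not self.low_inclusive):
            return False
        return vaf <= self.high if self.high_inclusive else vaf < self.high

    @property
    def band(self) -> tuple[float, float]:
        return (self.low, self.high)


_TWO_COPY_BANDS = (
    GenotypeClass("homref", 10.0, 25.0),
    GenotypeClass("het", 25.0, 75.0, high_inclusive=True),  # het owns 75 exactly
    GenotypeClass("homvar", 75.0, 100.0, high_inclusive=True, low_inclusive=False),
)

_SIX_COPY_EDGES = (10.0, 25.0, 43.0, 59.0, 76.0, 93.0, 100.0)


def vaf_bands(diploid_cn: int) -> tuple[GenotypeClass, ...]:
    """Genotype bands partitioning [10, 100] for a given diploid copy number."""
    if diploid_cn < 2:
        raise ValueError("diploid_cn must be >= 2")
    if diploid_cn == 2:
        return _TWO_COPY_BANDS
    if diploid_cn == 6:
        bands = []
        for k in range(6):
            bands.append(
                GenotypeClass(
                    f"{k + 1}_of_6",
                    _SIX_COPY_EDGES[k],
                    _SIX_COPY_EDGES[k + 1],
                    high_inclusive=(k == 5),
                )
            )
        return tuple(bands)
    # generalized scheme: midpoints between expected VAFs 100*k/cn,
    # k = 0..cn; bands below the 10 % floor collapse away
    boundaries = [100.0 * (2 * k - 1) / (2 * diploid_cn) for k in range(1, diploid_cn + 1)]
    edges = [10.0]
    labels = []
    k_low = 0
    for k, b in enumerate(boundaries):
        if b <= 10.0:
            k_low = k + 1
            continue
        edges.append(min(b, 100.0))
        labels.append(k_low)
        k_low = k + 1
    edges.append(100.0)
    labels.append(k_low)
    bands = []
    for i, k in enumerate(labels):
        bands.append(
            GenotypeClass(
                f"{k}_of_{diploid_cn}",
                edges[i],
                edges[i + 1],
                high_inclusive=(i == len(labels) - 1),
            )
        )
    return tuple(bands)


def classify_vaf(call_or_vaf: VariantCall | float, diploid_cn: int) -> GenotypeClass:
    """Assign a call (or a bare VAF percentage) to its genotype band."""
    vaf = call_or_vaf.vaf if isinstance(call_or_vaf, VariantCall) else float(call_or_vaf)
    if not 10.0 <= vaf <= 100.0:
        raise ValueError(f"VAF {vaf} outside the reportable range [10, 100]")
    bands = vaf_bands(diploid_cn)
    for band in bands:
        if band.contains(vaf):
            return band
    raise AssertionError("bands must partition [10, 100]")  # pragma: no cover


def classify_calls(calls: Iterable[VariantCall], diploid_cn: int) -> list[VariantCall]:
    """Set genotype_class on passed calls (masked/filtered left untouched)."""
    out = list(calls)
    for call in out:
        if call.status in ("masked", "filtered"):
            continue
        call.genotype_class = classify_vaf(call, diploid_cn).label
    return out


def apply_region_mask(calls: Iterable[VariantCall], mask: IntervalSet) -> list[VariantCall]:
    """Mark calls inside mask intervals as masked (half-open convention).

    Idempotent; calls outside every mask interval are untouched.
    """
    out = list(calls)
    for call in out:
        if mask.contains(call.region, call.position - 1):
            call.status = "masked"
    return out


def apply_error_filter(calls: Iterable[VariantCall], model: ErrorModel) -> list[VariantCall]:
    """Store P on every call and set filtered/passed status.

    A call is filtered when P > threshold, passed otherwise. Masked calls
    keep their status (a masked call is never resurrected) but still get P
    recorded. Idempotent.
    """
    out = list(calls)
    for call in out:
        call.error_prob = binomial_tail(call.depth, call.alt_count, model.p)
        if call.status == "masked":
            continue
        call.status = "filtered" if call.error_prob > model.threshold else "passed"
    return out


class SnpTable:
    """Known-SNP positions, optionally allele-aware."""

    def __init__(self, entries: Iterable[tuple[str, int, Optional[str], Optional[str]]]):
        self._positions: set[tuple[str, int]] = set()
        self._alleles: set[tuple[str, int, str]] = set()
        self._ids: dict[tuple[str, int], str] = {}
        n = 0
        for region, position, alt, ident in entries:
            n += 1
            self._positions.add((region, int(position)))
            if alt is not None and not pd.isna(alt):
                self._alleles.add((region, int(position), str(alt)))
            if ident is not None and not pd.isna(ident):
                self._ids[(region, int(position))] = str(ident)
        self.n_entries = n

    def __len__(self) -> int:
        return len(self._positions)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SnpTable":
        """Load from a TSV with columns region, position[, alt][, id]."""
        df = pd.read_csv(path, sep="\t")
        cols = {c.lower(): c for c in df.columns}
        if "region" not in cols or "position" not in cols:
            raise ValueError(f"{path}: SNP table needs 'region' and 'position' columns")
        alt_col = cols.get("alt") or cols.get("alt_allele")
        id_col = cols.get("id")
        return cls(
            (
                row[cols["region"]],
                int(row[cols["position"]]),
                row[alt_col] if alt_col else None,
                row[id_col] if id_col else None,
            )
            for _, row in df.iterrows()
        )

    @classmethod
    def from_vcf(cls, path: str | Path) -> "SnpTable":
        """Load positions/alleles from a VCF (uncompressed or bgzipped)."""
        import pysam

        entries = []
        with pysam.VariantFile(str(path)) as vcf:
            for rec in vcf:
                for alt in rec.alts or (None,):
                    entries.append((rec.chrom, rec.pos, alt, rec.id))
        return cls(entries)

    def contains(self, region: str, position: int, alt: str | None = None) -> bool:
        if alt is None:
            return (region, position) in self._positions
        return (region, position, alt) in self._alleles


def annotate_known(
    calls: Iterable[VariantCall], table: SnpTable, match_allele: bool = False
) -> list[VariantCall]:
    """Flag each call known/novel against the SNP table.

    By default matching is positional; with ``match_allele`` the listed
    alternate allele must also agree.
    """
    out = list(calls)
    for call in out:
        hit = table.contains(
            call.region, call.position, call.alt_allele if match_allele else None
        )
        call.known_flag = "known" if hit else "novel"
    return out
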