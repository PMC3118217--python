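"""Synthetic 454-style capture data for copy-number-variable target regions.

The generator emulates the study conditions this pipeline was designed for:
hybridisation-captured genomic regions, some present at elevated copy number
(the diploid copy number is a per-region parameter), shotgun-sequenced with
long single-end reads. Defaults follow the real experiment: mean read length
330 bp (the platform's 300-350 bp range), a global per-site substitution
error rate of 2.3 %, capture depth proportional to copy number (optionally
damped by a saturation factor to mimic probe saturation at high copy
numbers), and designated high-SNV-density windows (>= 9 SNVs/kb) inside
which single reads span several variant positions — the raw material for
read-backed haplotyping.

Only substitution errors are simulated (the downstream analysis discards
indels and complex events); error substitutions are uniform over the three
non-reference bases, matching the single aggregate error rate of the
binomial error model. Every draw flows from one integer seed, and identical
configurations produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import BASES, decode_bases, encode_bases, phred_to_string
from .io import AlignedRead, IntervalSet, write_alignments_tsv, write_fasta

TRUTH_COLUMNS = [
    "region", "position", "ref_allele", "alt_allele",
    "copies_variant", "copies_total", "known_flag",
]


@dataclass(frozen=True)
class RegionSpec:
    """One simulated target region.

    Parameters
    ----------
    name : str
        Region label (FASTA record id).
    length : int
        Region length in bases.
    diploid_copy_number : int
        Copies per diploid genome; 2 for single-copy loci, 6 mimics the
        high-copy defensin cluster case.
    snv_density : float
        Planted variants per kb outside high-density windows.
    htcr_fraction : float
        Fraction of the region laid out as 1-kb high-SNV-density
        (haplotyping candidate) windows.
    htcr_snv_density : float
        Variants per kb inside those windows (>= 9 per the haplotyping
        selection rule; ~16/kb matches the selected windows of the study).
    """

    name: str
    length: int
    diploid_copy_number: int = 2
    snv_density: float = 0.0
    htcr_fraction: float = 0.0
    htcr_snv_density: float = 16.0

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError(f"region {self.name}: length must be > 0")
        if self.diploid_copy_number < 1:
            raise ValueError(f"region {self.name}: diploid_copy_number must be >= 1")
        if self.snv_density < 0 or self.htcr_snv_density < 0:
            raise ValueError(f"region {self.name}: SNV density must be >= 0")
        if not 0 <= self.htcr_fraction <= 1:
            raise ValueError(f"region {self.name}: htcr_fraction must be in [0, 1]")


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one synthetic capture experiment."""

    regions: tuple[RegionSpec, ...]
    mean_read_length: float = 330.0
    read_length_sd: float = 30.0
    min_read_length: int = 50
    per_site_error: float = 0.023
    target_depth_per_copy: float = 25.0
    base_quality: int = 30
    known_fraction: float = 0.9
    #: optional per-region capture-saturation factor multiplying depth
    #: (e.g. {"DEFB": 2.5/3} mimics probe saturation at high copy number).
    saturation: Mapping[str, float] | None = None
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "regions", tuple(self.regions))
        if not 0 <= self.per_site_error < 1:
            raise ValueError("per_site_error must lie in [0, 1)")
        if self.target_depth_per_copy <= 0:
            raise ValueError("target_depth_per_copy must be > 0")
        if self.mean_read_length <= 0:
            raise ValueError("mean_read_length must be > 0")

    def region(self, name: str) -> RegionSpec:
        for spec in self.regions:
            if spec.name == name:
                return spec
        raise KeyError(name)


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one planted SNV."""

    region: str
    position: int  # 1-based
    ref_allele: str
    alt_allele: str
    copies_variant: int
    copies_total: int
    known_flag: bool
    #: indices of the haploid copies carrying the alternate allele
    alt_copies: tuple[int, ...] = ()

    def __post_init__(self):
        if not 0 <= self.copies_variant <= self.copies_total:
            raise ValueError("copies_variant must lie in [0, copies_total]")


@dataclass
class Reference:
    """Simulated reference: sequences plus the target interval table."""

    sequences: dict[str, str]
    intervals: IntervalSet
    htcr_windows: IntervalSet


@dataclass
class Dataset:
    """Everything one simulation run produces, in memory."""

    config: SimulationConfig
    reference: Reference
    truth: list[TruthRecord]
    haplotypes: dict[str, np.ndarray]  # region -> (copies, length) uint8 codes
    reads: list[AlignedRead]

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {k: getattr(t, k) for k in TRUTH_COLUMNS}
                for t in self.truth
            ],
            columns=TRUTH_COLUMNS,
        )

    def known_snp_frame(self) -> pd.DataFrame:
        """The known-SNP table an annotation database would supply."""
        df = self.truth_frame()
        df = df[df["known_flag"].astype(bool)]
        return df[["region", "position", "alt_allele"]].rename(
            columns={"alt_allele": "alt"}
        ).assign(id=[f"sim{i}" for i in range(len(df))])


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    """Independent deterministic stream per pipeline stage."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(stage,))
    )


def _htcr_layout(spec: RegionSpec, window: int = 1000) -> list[tuple[int, int]]:
    """Evenly spaced non-overlapping 1-kb high-density windows."""
    n_windows = int(round(spec.htcr_fraction * spec.length / window))
    n_windows = min(n_windows, spec.length // window)
    if n_windows == 0:
        return []
    stride = spec.length // n_windows
    offset = (stride - window) // 2
    return [(i * stride + offset, i * stride + offset + window) for i in range(n_windows)]


def generate_reference(config: SimulationConfig) -> Reference:
    """Draw uniform-random reference sequences and the interval tables."""
    rng = _rng(config, 0)
    sequences: dict[str, str] = {}
    intervals = []
    htcrs = []
    for spec in config.regions:
        codes = rng.integers(0, 4, size=spec.length, dtype=np.uint8)
        sequences[spec.name] = decode_bases(codes)
        intervals.append((spec.name, 0, spec.length))
        htcrs.extend((spec.name, s, e) for s, e in _htcr_layout(spec))
    return Reference(
        sequences=sequences,
        intervals=IntervalSet(intervals),
        htcr_windows=IntervalSet(htcrs) if htcrs else IntervalSet([]),
    )


def plant_variants(
    reference: Reference, config: SimulationConfig
) -> tuple[list[TruthRecord], dict[str, np.ndarray]]:
    """Plant SNVs and build per-copy haplotype sequences.

    The number of variants per segment is Poisson with mean
    density x length; positions are unique within a region. Each variant is
    assigned a copies_variant drawn uniformly from 1..copies_total and placed
    on a uniform random subset of haploid copies, so adjacent variants inside
    a high-density window induce a multi-copy haplotype structure.
    """
    rng = _rng(config, 1)
    truth: list[TruthRecord] = []
    haplotypes: dict[str, np.ndarray] = {}
    for spec in config.regions:
        seq = reference.sequences[spec.name]
        ref_codes = encode_bases(seq)
        cn = spec.diploid_copy_number
        copies = np.tile(ref_codes, (cn, 1))

        htcr_windows = _htcr_layout(spec)
        in_htcr = np.zeros(spec.length, dtype=bool)
        for s, e in htcr_windows:
            in_htcr[s:e] = True

        segments: list[tuple[np.ndarray, float]] = []
        background = np.flatnonzero(~in_htcr)
        if background.size:
            segments.append((background, spec.snv_density))
        dense = np.flatnonzero(in_htcr)
        if dense.size:
            segments.append((dense, spec.htcr_snv_density))

        taken: set[int] = set()
        for candidates, density in segments:
            mean = density * candidates.size / 1000.0
            if mean <= 0:
                continue
            n = int(rng.poisson(mean))
            n = min(n, candidates.size)
            picked = rng.choice(candidates, size=n, replace=False)
            for pos0 in sorted(int(p) for p in picked):
                if pos0 in taken:  # cannot happen across disjoint segments
                    continue
                taken.add(pos0)
                ref_base = seq[pos0]
                alt_base = BASES[(ref_codes[pos0] + 1 + rng.integers(0, 3)) % 4]
                cv = int(rng.integers(1, cn + 1))
                alt_copies = tuple(
                    int(c) for c in sorted(rng.choice(cn, size=cv, replace=False))
                )
                for c in alt_copies:
                    copies[c, pos0] = BASES.index(alt_base)
                truth.append(
                    TruthRecord(
                        region=spec.name,
                        position=pos0 + 1,
                        ref_allele=ref_base,
                        alt_allele=alt_base,
                        copies_variant=cv,
                        copies_total=cn,
                        known_flag=bool(rng.random() < config.known_fraction),
                        alt_copies=alt_copies,
                    )
                )
        haplotypes[spec.name] = copies
    truth.sort(key=lambda t: (t.region, t.position))
    return truth, haplotypes


def simulate_reads(
    haplotypes: Mapping[str, np.ndarray], config: SimulationConfig
) -> list[AlignedRead]:
    """Simulate shotgun reads uniformly from every haploid copy.

    Per-site coverage approximates target_depth_per_copy x copy number
    (times the region's saturation factor if configured). Read lengths are
    normal (truncated below at min_read_length and at the region length);
    substitution errors are i.i.d. per base at per_site_error, uniform over
    the three non-reference bases; orientation is Bernoulli(1/2). Alignment
    coordinates are emitted directly — no mapper is involved.
    """
    rng = _rng(config, 2)
    reads: list[AlignedRead] = []
    qual_cache: dict[int, str] = {}
    for spec in config.regions:
        copies = haplotypes[spec.name]
        cn, L = copies.shape
        factor = 1.0
        if config.saturation:
            factor = float(config.saturation.get(spec.name, 1.0))
        depth = config.target_depth_per_copy * factor
        mean_len = min(config.mean_read_length, L)
        for copy_idx in range(cn):
            n_reads = int(round(L * depth / mean_len))
            lengths = rng.normal(config.mean_read_length, config.read_length_sd, n_reads)
            lengths = np.clip(np.rint(lengths), config.min_read_length, L).astype(np.int64)
            starts = (rng.random(n_reads) * (L - lengths + 1)).astype(np.int64)
            strands = rng.random(n_reads) < 0.5
            for i in range(n_reads):
                ln = int(lengths[i])
                s = int(starts[i])
                frag = copies[copy_idx, s:s + ln].copy()
                if config.per_site_error > 0:
                    err = np.flatnonzero(rng.random(ln) < config.per_site_error)
                    if err.size:
                        shift = rng.integers(1, 4, size=err.size, dtype=np.uint8)
                        frag[err] = (frag[err] + shift) % 4
                qual = qual_cache.get(ln)
                if qual is None:
                    qual = phred_to_string(np.full(ln, config.base_quality))
                    qual_cache[ln] = qual
                reads.append(
                    AlignedRead(
                        read_id=f"{spec.name}_c{copy_idx}_r{i}",
                        region=spec.name,
                        start=s,
                        strand="+" if strands[i] else "-",
                        sequence=decode_bases(frag),
                        quality=qual,
                    )
                )
    reads.sort(key=lambda r: (r.region, r.start, r.read_id))
    return reads


def simulate_dataset(config: SimulationConfig) -> Dataset:
    """Run the three generator stages and bundle the results."""
    reference = generate_reference(config)
    truth, haplotypes = plant_variants(reference, config)
    reads = simulate_reads(haplotypes, config)
    return Dataset(config, reference, truth, haplotypes, reads)


def write_dataset(dataset: Dataset, outdir: str | Path) -> dict[str, Path]:
    """Write FASTA / BED / TSV artifacts; returns name -> path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "reference": outdir / "reference.fasta",
        "regions": outdir / "regions.bed",
        "htcr_windows": outdir / "htcr_windows.bed",
        "reads": outdir / "reads.tsv",
        "truth": outdir / "truth.tsv",
        "known_snps": outdir / "known_snps.tsv",
    }
    write_fasta(dataset.reference.sequences, paths["reference"])
    dataset.reference.intervals.to_bed(paths["regions"])
    dataset.reference.htcr_windows.to_bed(paths["htcr_windows"])
    write_alignments_tsv(dataset.reads, paths["reads"])
    dataset.truth_frame().to_csv(paths["truth"], sep="\t", index=False)
    dataset.known_snp_frame().to_csv(paths["known_snps"], sep="\t", index=False)
    return paths


def load_truth(path: str | Path) -> list[TruthRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        TruthRecord(
            region=row.region,
            position=int(row.position),
            ref_allele=row.ref_allele,
            alt_allele=row.alt_allele,
            copies_variant=int(row.copies_variant),
            copies_total=int(row.copies_total),
            known_flag=bool(row.known_flag),
        )
        for row in df.itertuples(index=False)
    ]


def config_from_dict(data: Mapping) -> SimulationConfig:
    """Build a SimulationConfig from a parsed YAML/JSON mapping."""
    data = dict(data)
    regions = tuple(RegionSpec(**r) for r in data.pop("regions"))
    fields = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(data) - fields
    if unknown:
        raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
    return SimulationConfig(regions=regions, **data)
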