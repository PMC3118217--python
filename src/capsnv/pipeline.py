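"""End-to-end orchestration: simulate -> pileup -> call -> calibrate ->
filter -> classify -> haplotype -> evaluate, driven by one YAML config.

Every stage is a pure function of its inputs and the config; a run writes
all stage artifacts plus a machine-readable manifest (parameter values,
seed, SHA-256 of every artifact), so re-running the same config reproduces
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Optional

import yaml

from . import __version__
from .calling import call_all, write_calls_tsv, write_calls_vcf
from .classify import (
    SnpTable,
    annotate_known,
    apply_error_filter,
    apply_region_mask,
    classify_calls,
)
from .error_model import DEFAULT_THRESHOLD, ErrorModel, estimate_error_rate
from .evaluate import DEFAULT_MIN_DEPTH, build_concordance, sensitivity, snv_density
from .haplotype import (
    DEFAULT_ALPHA,
    DEFAULT_MIN_DENSITY,
    aggregate_cn,
    estimate_copy_numbers,
    estimates_to_frame,
    find_htcrs,
)
from .io import IntervalSet, build_region_pileups, coverage_summary
from .simulate import SimulationConfig, config_from_dict, simulate_dataset, write_dataset

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs.

    The defaults are the working parameters of the analysis this pipeline
    reimplements: error threshold P <= 1e-3, Q20 support gate, 10 % VAF
    floor, >= 9 SNVs/kb haplotyping windows, >= 5 reads per haplotype and
    >= 10 / >= 30 read totals for 2- / 6-copy loci.
    """

    simulation: SimulationConfig
    min_q: int = 20
    vaf_floor: float = 10.0
    error_threshold: float = DEFAULT_THRESHOLD
    min_depth: int = DEFAULT_MIN_DEPTH
    htcr_min_density: float = DEFAULT_MIN_DENSITY
    haplotype_alpha: float = DEFAULT_ALPHA
    haplotype_max_span: int = 200
    min_reads_per_hap: int = 5
    min_total_two_copy: int = 10
    min_total_multi_copy: int = 30
    match_allele: bool = False
    mask_bed: Optional[str] = None
    snp_table: Optional[str] = None  # path; None -> simulated known-SNP table
    outdir: str = "capsnv_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "PipelineConfig":
        data = dict(data)
        sim = config_from_dict(data.pop("simulation"))
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - fields
        if unknown:
            raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")
        return cls(simulation=sim, **data)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["simulation"]["regions"] = [
            dataclasses.asdict(r) for r in self.simulation.regions
        ]
        return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: PipelineConfig, outdir: str | Path | None = None) -> dict[str, Path]:
    """Run every stage; returns artifact name -> path."""
    outdir = Path(outdir if outdir is not None else config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    # --- simulate -----------------------------------------------------
    dataset = simulate_dataset(config.simulation)
    paths.update(write_dataset(dataset, outdir))
    logger.info("simulated %d reads, %d truth SNVs", len(dataset.reads), len(dataset.truth))

    # --- pileup -------------------------------------------------------
    pileups = build_region_pileups(
        dataset.reads, dataset.reference.sequences, min_q=config.min_q
    )
    cov = coverage_summary(pileups, dataset.reference.intervals, min_depth=2)
    paths["coverage"] = outdir / "coverage.tsv"
    cov.to_csv(paths["coverage"], sep="\t", index=False)

    # --- call ---------------------------------------------------------
    calls = call_all(pileups, min_q=config.min_q, vaf_floor=config.vaf_floor)
    paths["calls_raw"] = outdir / "calls_raw.tsv"
    write_calls_tsv(calls, paths["calls_raw"])
    logger.info("raw candidate calls: %d", len(calls))

    # --- calibrate ----------------------------------------------------
    control = [
        (t.region, t.position, t.alt_allele)
        for t in dataset.truth
        if t.copies_total == 2 and t.copies_variant == t.copies_total
    ]
    if not control:
        raise RuntimeError(
            "error-model calibration needs homozygous-variant control sites in a "
            "2-copy region; add a 2-copy region with snv_density > 0"
        )
    model = estimate_error_rate(pileups, control, threshold=config.error_threshold)
    paths["error_model"] = outdir / "error_model.yaml"
    model.to_yaml(paths["error_model"])
    logger.info("error model: p=%.5f from %d control sites", model.p, model.source_sites)

    # --- filter -------------------------------------------------------
    if config.mask_bed:
        calls = apply_region_mask(calls, IntervalSet.from_bed(config.mask_bed))
    calls = apply_error_filter(calls, model)
    n_masked = sum(c.status == "masked" for c in calls)
    n_filtered = sum(c.status == "filtered" for c in calls)
    n_passed = sum(c.status == "passed" for c in calls)
    logger.info(
        "filter funnel: %d raw -> %d masked, %d filtered, %d passed",
        len(calls), n_masked, n_filtered, n_passed,
    )

    # --- classify -----------------------------------------------------
    cn_by_region = {r.name: r.diploid_copy_number for r in config.simulation.regions}
    for region, cn in cn_by_region.items():
        region_calls = [c for c in calls if c.region == region]
        classify_calls(region_calls, max(cn, 2))
    if config.snp_table:
        table = SnpTable.from_tsv(config.snp_table)
    else:
        known = dataset.known_snp_frame()
        table = SnpTable(
            (row.region, int(row.position), row.alt, row.id)
            for row in known.itertuples(index=False)
        )
    calls = annotate_known(calls, table, match_allele=config.match_allele)
    paths["calls"] = outdir / "calls.tsv"
    write_calls_tsv(calls, paths["calls"])
    paths["calls_vcf"] = outdir / "calls.vcf"
    write_calls_vcf(calls, paths["calls_vcf"])

    # --- haplotype ----------------------------------------------------
    passed = [c for c in calls if c.status == "passed"]
    multi_regions = {r for r, cn in cn_by_region.items() if cn > 2}
    htcrs = find_htcrs(
        [c for c in passed], min_density=config.htcr_min_density
    )
    estimates = []
    for group, min_total in (
        ([h for h in htcrs if h.region in multi_regions], config.min_total_multi_copy),
        ([h for h in htcrs if h.region not in multi_regions], config.min_total_two_copy),
    ):
        estimates.extend(
            estimate_copy_numbers(
                dataset.reads,
                group,
                min_total=min_total,
                min_reads_per_hap=config.min_reads_per_hap,
                max_span=config.haplotype_max_span,
                alpha=config.haplotype_alpha,
                min_q=config.min_q,
            )
        )
    paths["cn_estimates"] = outdir / "cn_estimates.tsv"
    estimates_to_frame(estimates).to_csv(paths["cn_estimates"], sep="\t", index=False)
    unambiguous = [e for e in estimates if not e.ambiguous_flag]
    cn_summary = None
    if unambiguous:
        cn_summary = aggregate_cn(unambiguous)
        paths["cn_summary"] = outdir / "cn_summary.json"
        with open(paths["cn_summary"], "w") as fh:
            json.dump(dataclasses.asdict(cn_summary), fh, indent=2)
        logger.info(
            "CN estimates: %d loci, mean %.2f (range %d-%d)",
            cn_summary.count, cn_summary.mean, cn_summary.min, cn_summary.max,
        )

    # --- evaluate -----------------------------------------------------
    two_copy_truth = [t for t in dataset.truth if t.copies_total == 2]
    evaluation: dict[str, Any] = {"n_raw": len(calls), "n_masked": n_masked,
                                  "n_filtered": n_filtered, "n_passed": n_passed}
    if two_copy_truth:
        table_calls = [c for c in passed if cn_by_region.get(c.region) == 2]
        conc = build_concordance(
            table_calls, two_copy_truth, pileups, min_depth=config.min_depth
        )
        paths["concordance"] = outdir / "concordance.tsv"
        conc.to_tsv(paths["concordance"])
        for cls in ("het", "homvar"):
            try:
                evaluation[f"sensitivity_{cls}"] = sensitivity(conc, cls)
            except ValueError:
                pass
    for region, cn in cn_by_region.items():
        n = sum(1 for c in passed if c.region == region)
        length_kb = config.simulation.region(region).length / 1000.0
        evaluation[f"density_{region}"] = snv_density(n, length_kb)
    paths["evaluation"] = outdir / "evaluation.json"
    with open(paths["evaluation"], "w") as fh:
        json.dump(evaluation, fh, indent=2)

    # --- manifest -----------------------------------------------------
    manifest = {
        "package_version": __version__,
        "seed": config.simulation.seed,
        "parameters": config.to_dict(),
        "artifacts": {name: _sha256(p) for name, p in sorted(paths.items())},
    }
    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    paths["manifest"] = manifest_path
    return paths
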