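"""Shared fixtures and small builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from capsnv.io import AlignedRead, PileupColumn, ReadObservation
from capsnv.simulate import RegionSpec, SimulationConfig, simulate_dataset


def make_column(
    region: str = "R",
    position: int = 100,
    ref: str = "A",
    alt: str = "C",
    n_ref: int = 0,
    alt_fwd: int = 0,
    alt_rev: int = 0,
    quality: int = 30,
    ref_quality: int = 30,
) -> PileupColumn:
    """Pileup column with a given ref/alt observation mix."""
    obs = []
    for i in range(n_ref):
        obs.append(ReadObservation(ref, "+" if i % 2 == 0 else "-", ref_quality, f"ref{i}"))
    for i in range(alt_fwd):
        obs.append(ReadObservation(alt, "+", quality, f"af{i}"))
    for i in range(alt_rev):
        obs.append(ReadObservation(alt, "-", quality, f"ar{i}"))
    return PileupColumn(region, position, ref, obs)


def make_read(
    region: str,
    start: int,
    sequence: str,
    strand: str = "+",
    quality: int = 30,
    read_id: str = "r0",
) -> AlignedRead:
    return AlignedRead(
        read_id=read_id,
        region=region,
        start=start,
        strand=strand,
        sequence=sequence,
        quality=chr(quality + 33) * len(sequence),
    )


@pytest.fixture(scope="session")
def small_dataset():
    """A 2-copy 20-kb region at ~50x with default error rate."""
    config = SimulationConfig(
        regions=(RegionSpec("CTRL", 20_000, diploid_copy_number=2, snv_density=2.0),),
        seed=7,
    )
    return simulate_dataset(config)


@pytest.fixture(scope="session")
def clean_dataset():
    """Error-free reads over a 2-copy region with planted SNVs."""
    config = SimulationConfig(
        regions=(RegionSpec("CTRL", 10_000, diploid_copy_number=2, snv_density=3.0),),
        per_site_error=0.0,
        seed=3,
    )
    return simulate_dataset(config)
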