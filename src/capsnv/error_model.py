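"""Binomial error model for candidate-variant filtering.

Sequencing and mapping errors accumulate at particular positions and can
mimic novel alleles. The model pools read evidence at control sites whose
genotype is known to be homozygous for a variant allele: every read not
showing the expected allele is an error, and the pooled mismatch fraction
is the global per-site error frequency p (2.3 % in the experiment this
pipeline reimplements).

Given local depth n and d reads supporting one specific alternate allele,
the posterior probability that d identical deviations arise from error
alone is the inclusive upper binomial tail

    P = sum_{k=d}^{n} C(n, k) p^k (1 - p)^(n - k)

computed via the survival function for numerical stability. Candidates
with P above a threshold (default 1e-3) are considered error-prone and
discarded by :func:`capsnv.classify.apply_error_filter`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml
from scipy import stats

from ._util import BASES
from .io import PileupColumn, RegionPileup

DEFAULT_THRESHOLD = 1e-3
DEFAULT_FLOOR = 1e-4


@dataclass(frozen=True)
class ErrorModel:
    """Global per-site error frequency and the filtering threshold."""

    p: float
    source_sites: int = 0
    threshold: float = DEFAULT_THRESHOLD

    def __post_init__(self):
        if not 0 < self.p < 1:
            raise ValueError("p must lie strictly between 0 and 1")
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {"p": float(self.p), "source_sites": int(self.source_sites),
                 "threshold": float(self.threshold)},
                fh,
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ErrorModel":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


def estimate_error_rate(
    pileups: Mapping[str, RegionPileup] | Iterable[PileupColumn],
    control_sites: Sequence[tuple[str, int, str]],
    threshold: float = DEFAULT_THRESHOLD,
    floor: float = DEFAULT_FLOOR,
) -> ErrorModel:
    """Estimate p from homozygous-variant control sites.

    Parameters
    ----------
    pileups : per-region dense pileups, or an iterable of PileupColumn
    control_sites : (region, 1-based position, expected allele) triples;
        every site must be truth-homozygous for the expected allele, so any
        read showing a different base is an error. N bases are excluded
        from both numerator and denominator (a no-call is not a deviation).
    floor : substituted (with a warning) when no mismatch is observed, so
        the binomial test stays defined.
    """
    total = 0
    mismatch = 0
    if isinstance(pileups, Mapping):
        for region, position, allele in control_sites:
            pile = pileups[region]
            pos0 = position - 1
            counts = pile.alt_fwd[pos0] + pile.alt_rev[pos0]
            site_total = int(counts.sum())
            total += site_total
            mismatch += site_total - int(counts[BASES.index(allele)])
    else:
        wanted = {(r, p): a for r, p, a in control_sites}
        for column in pileups:
            allele = wanted.get((column.region, column.position))
            if allele is None:
                continue
            for obs in column.observations:
                if obs.base == "N":
                    continue
                total += 1
                if obs.base != allele:
                    mismatch += 1
    if total == 0:
        raise ValueError("control sites have zero total depth")
    p = mismatch / total
    if p == 0.0:
        warnings.warn(
            f"no mismatching reads at {len(control_sites)} control sites; "
            f"substituting error-rate floor {floor}",
            stacklevel=2,
        )
        p = floor
    return ErrorModel(p=p, source_sites=len(control_sites), threshold=threshold)


def binomial_tail(n: int, d: int, p: float) -> float:
    """Inclusive upper binomial tail P(X >= d), X ~ Binomial(n, p).

    Numerically stable for n up to at least 1e4 (survival-function
    evaluation via the regularised incomplete beta function).
    """
    if d < 0 or n < 0:
        raise ValueError("n and d must be non-negative")
    if d > n:
        raise ValueError(f"d ({d}) cannot exceed n ({n})")
    if not 0 < p < 1:
        raise ValueError("p must lie strictly between 0 and 1")
    if d == 0:
        return 1.0
    tail = float(stats.binom.sf(d - 1, n, p))
    if tail < 1e-250:
        # sf underflows long before float range ends; re-sum the tail in
        # log space so deep tails keep full relative accuracy
        from scipy.special import logsumexp

        k = np.arange(d, n + 1)
        tail = float(np.exp(logsumexp(stats.binom.logpmf(k, n, p))))
    return tail


@dataclass
class VafSimulation:
    """Simulated VAF distribution for one genotype under the error model."""

    vafs: np.ndarray  # percent, one per replicate
    hist: np.ndarray
    bin_edges: np.ndarray

    @property
    def mean(self) -> float:
        return float(self.vafs.mean())


def simulate_vaf_distribution(
    model: ErrorModel,
    depths: Sequence[int] | np.ndarray,
    genotype: tuple[int, int],
    replicates: int = 10_000,
    seed: int | None = None,
    bins: int | Sequence[float] = 20,
) -> VafSimulation:
    """Simulate the VAF distribution expected for a genotype.

    Each replicate draws a depth n from the supplied empirical depth
    distribution (sampled with replacement) and a variant-read count from
    Binomial(n, q), where for copies_variant/copies_total = f

        q = f (1 - p) + (1 - f) p / 3

    i.e. true variant alleles may be misread away (rate p) and reads from
    the other copies may be misread toward the variant base (p/3 each of
    the three non-reference bases).
    """
    depths = np.asarray(depths, dtype=np.int64)
    if depths.size == 0:
        raise ValueError("empty depth distribution")
    if (depths < 1).any():
        raise ValueError("depths must be >= 1")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    cv, ct = genotype
    if not 0 <= cv <= ct or ct < 1:
        raise ValueError("genotype must satisfy 0 <= copies_variant <= copies_total")
    f = cv / ct
    q = f * (1.0 - model.p) + (1.0 - f) * model.p / 3.0
    rng = np.random.default_rng(seed)
    n = rng.choice(depths, size=replicates, replace=True)
    d = rng.binomial(n, q)
    vafs = 100.0 * d / n
    hist, edges = np.histogram(vafs, bins=bins, range=(0.0, 100.0) if np.isscalar(bins) else None)
    return VafSimulation(vafs=vafs, hist=hist, bin_edges=edges)
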