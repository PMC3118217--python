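"""Error model: rate estimation, binomial tail correctness, VAF simulation."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from capsnv.error_model import (
    ErrorModel,
    binomial_tail,
    estimate_error_rate,
    simulate_vaf_distribution,
)
from capsnv.io import PileupColumn, ReadObservation


def brute_force_tail(n: int, d: int, p: float) -> float:
    """Independent oracle: pmf by multiplicative recurrence, summed from the top."""
    pmf = np.empty(n + 1)
    pmf[0] = (1.0 - p) ** n
    ratio = p / (1.0 - p)
    for k in range(n):
        pmf[k + 1] = pmf[k] * (n - k) / (k + 1) * ratio
    return float(pmf[d:][::-1].sum())


def _control_columns(matches_and_depths, allele="G", ref="A"):
    cols = []
    for i, (matches, depth) in enumerate(matches_and_depths):
        obs = [ReadObservation(allele, "+", 30, f"m{j}") for j in range(matches)]
        obs += [ReadObservation("T", "-", 30, f"x{j}") for j in range(depth - matches)]
        cols.append(PileupColumn("R", i + 1, ref, obs))
    return cols


def test_estimate_simple_arithmetic():
    """98 of 100 reads matching the expected allele gives p = 0.02."""
    cols = _control_columns([(98, 100)])
    model = estimate_error_rate(cols, [("R", 1, "G")])
    assert model.p == pytest.approx(0.02)
    assert model.source_sites == 1


def test_estimate_pools_over_sites():
    cols = _control_columns([(50, 50), (48, 50)])
    model = estimate_error_rate(cols, [("R", 1, "G"), ("R", 2, "G")])
    assert model.p == pytest.approx(2 / 100)


def test_estimate_zero_mismatch_floors_with_warning():
    cols = _control_columns([(100, 100)])
    with pytest.warns(UserWarning, match="floor"):
        model = estimate_error_rate(cols, [("R", 1, "G")])
    assert model.p == pytest.approx(1e-4)


def test_estimate_zero_depth_is_an_error():
    cols = _control_columns([(0, 0)])
    with pytest.raises(ValueError, match="zero total depth"):
        estimate_error_rate(cols, [("R", 1, "G")])


def test_estimate_recovers_simulated_error_rate():
    """248 control sites at depth 50 drawn at p = 0.023: estimate within 0.005."""
    rng = np.random.default_rng(12)
    sites = []
    for mism in rng.binomial(50, 0.023, size=248):
        sites.append((50 - int(mism), 50))
    cols = _control_columns(sites)
    control = [("R", i + 1, "G") for i in range(248)]
    model = estimate_error_rate(cols, control)
    assert abs(model.p - 0.023) <= 0.005


def test_estimate_from_simulated_dataset(small_dataset):
    """Homozygous-variant truth sites of a real simulation recover p~=2.3%."""
    from capsnv.io import build_region_pileups

    ds = small_dataset
    piles = build_region_pileups(ds.reads, ds.reference.sequences)
    control = [
        (t.region, t.position, t.alt_allele)
        for t in ds.truth
        if t.copies_variant == t.copies_total
    ]
    assert control
    model = estimate_error_rate(piles, control)
    assert abs(model.p - 0.023) <= 0.01


@pytest.mark.parametrize(
    "n, d, p, expected",
    [
        (10, 0, 0.023, 1.0),
        (1, 1, 0.023, 0.023),
        (50, 2, 0.023, None),  # closed form below
    ],
)
def test_tail_trivial_values(n, d, p, expected):
    if expected is None:
        expected = 1 - (1 - p) ** 50 - 50 * p * (1 - p) ** 49
    assert binomial_tail(n, d, p) == pytest.approx(expected, rel=1e-12)


def test_tail_passes_the_published_depth104_site():
    """14 deviant reads of 104 at p=0.023 survive the 1e-3 threshold."""
    assert binomial_tail(104, 14, 0.023) < 1e-3


def test_tail_validates_arguments():
    with pytest.raises(ValueError):
        binomial_tail(10, 11, 0.023)
    with pytest.raises(ValueError):
        binomial_tail(10, 2, 0.0)
    with pytest.raises(ValueError):
        binomial_tail(-1, 0, 0.5)


def test_tail_matches_brute_force_grid():
    """Survival-function tail equals direct pmf summation to 1e-12 relative."""
    for p in (0.001, 0.023, 0.1):
        for n in (1, 2, 5, 17, 50, 104, 200):
            for d in range(0, n + 1, max(1, n // 7)):
                exact = brute_force_tail(n, d, p)
                got = binomial_tail(n, d, p)
                assert got == pytest.approx(exact, rel=1e-12, abs=1e-300)


@settings(max_examples=150, deadline=None, derandomize=True)
@given(
    n=st.integers(1, 200),
    p=st.sampled_from([0.001, 0.023, 0.1]),
    data=st.data(),
)
def test_tail_monotone_in_d_and_p(n, p, data):
    d = data.draw(st.integers(0, n))
    tail = binomial_tail(n, d, p)
    if d > 0:
        assert binomial_tail(n, d - 1, p) >= tail
    assert binomial_tail(n, d, min(0.5, p * 2)) >= tail


def test_tail_stable_at_large_n():
    assert 0.0 <= binomial_tail(10_000, 400, 0.023) <= 1.0
    assert binomial_tail(10_000, 400, 0.023) < 1e-12


def test_vaf_simulation_homvar_without_error():
    model = ErrorModel(p=1e-12)
    sim = simulate_vaf_distribution(model, [50], (2, 2), replicates=500, seed=0)
    assert (sim.vafs == 100.0).all()


def test_vaf_simulation_het_centred_at_half():
    model = ErrorModel(p=1e-12)
    sim = simulate_vaf_distribution(model, [1000], (1, 2), replicates=4000, seed=1)
    # per-draw SD = 100*sqrt(0.25/1000) ~= 1.58; SE of the mean ~= 0.025
    se_mean = 100 * np.sqrt(0.25 / 1000) / np.sqrt(4000)
    assert abs(sim.mean - 50.0) <= 3 * se_mean


def test_vaf_simulation_one_of_six_band():
    """1-of-6 genotype at depth 100: mass concentrates in the 10-25% band."""
    model = ErrorModel(p=0.023)
    sim = simulate_vaf_distribution(model, [100], (1, 6), replicates=5000, seed=2)
    in_band = ((sim.vafs >= 10) & (sim.vafs <= 25)).mean()
    assert in_band > 0.9
    assert abs(sim.mean - 16.67) < 2.0


def test_vaf_simulation_validates_inputs():
    model = ErrorModel(p=0.023)
    with pytest.raises(ValueError, match="empty depth"):
        simulate_vaf_distribution(model, [], (1, 2))
    with pytest.raises(ValueError):
        simulate_vaf_distribution(model, [50], (3, 2))


def test_model_yaml_round_trip(tmp_path):
    model = ErrorModel(p=0.0231, source_sites=248)
    path = tmp_path / "model.yaml"
    model.to_yaml(path)
    assert ErrorModel.from_yaml(path) == model
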