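"""Ping-pong 5'-5' overlap profile and strand coverage."""

import dataclasses
import math

import numpy as np
import pytest

import pirnakit as pk
from pirnakit.errors import DataError

from conftest import small_ref_sizes


def _oracle_profile(five_primes, k_max=20):
    """Brute-force double loop over all (plus, minus) hit pairs."""
    pair = np.zeros(k_max)
    plus = [(p, w) for s, p, w in five_primes if s == "+"]
    minus = [(q, w) for s, q, w in five_primes if s == "-"]
    for p, wp in plus:
        for q, wq in minus:
            k = q - p + 1
            if 1 <= k <= k_max:
                pair[k - 1] += wp * wq
    total = pair.sum()
    pct = 100 * pair / total if total > 0 else pair
    return pct, total


def test_single_pair_concentrates_at_offset_ten():
    fives = [("+", 0, 1.0), ("-", 9, 1.0)]
    profile = pk.pingpong_profile(fives, 20)
    assert profile.percentages[9] == pytest.approx(100.0)
    assert profile.percentages.sum() == pytest.approx(100.0)
    assert profile.total_pair_weight == pytest.approx(1.0)


def test_single_strand_yields_zero_profile():
    fives = [("+", i, 2.0) for i in range(30)]
    profile = pk.pingpong_profile(fives, 20)
    assert profile.total_pair_weight == 0.0
    assert (profile.percentages == 0).all()


def test_empty_input_is_not_an_error():
    profile = pk.pingpong_profile([], 20)
    assert profile.total_pair_weight == 0.0


def test_profile_equals_pair_oracle_on_small_instances():
    rng = np.random.default_rng(17)
    for _ in range(10):
        n = int(rng.integers(2, 200))
        fives = [
            (
                "+" if rng.random() < 0.5 else "-",
                int(rng.integers(0, 300)),
                float(rng.integers(1, 5)),
            )
            for _ in range(n)
        ]
        profile = pk.pingpong_profile(fives, 20)
        expected_pct, expected_total = _oracle_profile(fives, 20)
        assert profile.total_pair_weight == pytest.approx(expected_total)
        assert profile.percentages == pytest.approx(expected_pct)


def test_percentages_sum_to_100_whenever_pairs_exist():
    fives = [("+", 3, 2.0), ("-", 12, 1.0), ("-", 20, 4.0), ("+", 15, 1.0)]
    profile = pk.pingpong_profile(fives, 20)
    assert profile.total_pair_weight > 0
    assert profile.percentages.sum() == pytest.approx(100.0)


def test_zscore_degenerate_cases_are_undefined():
    flat = pk.pingpong_profile([], 20)
    assert math.isnan(pk.pingpong_zscore(flat))
    spike = pk.pingpong_profile([("+", 0, 1.0), ("-", 9, 1.0)], 20)
    # all other offsets are exactly zero -> sd 0 -> undefined
    assert math.isnan(pk.pingpong_zscore(spike))


def test_zscore_of_planted_signal_peaks_at_focal_offset():
    rng = np.random.default_rng(23)
    fives = [("+", int(p), 1.0) for p in rng.integers(0, 500, size=150)]
    fives += [("-", int(q), 1.0) for q in rng.integers(0, 500, size=150)]
    fives += [("+", 100, 30.0), ("-", 109, 30.0)]  # strong pairs at k=10
    profile = pk.pingpong_profile(fives, 20)
    z10 = pk.pingpong_zscore(profile, 10)
    assert profile.offsets[profile.percentages.argmax()] == 10
    for k in range(1, 21):
        if k != 10:
            assert z10 > pk.pingpong_zscore(profile, k)


def test_reflection_invariance():
    """Reverse-complementing the element (position -> L-1-pos, strands
    swapped) leaves the profile unchanged and reflects the coverage."""
    rng = np.random.default_rng(29)
    length = 400
    fives = [
        (
            "+" if rng.random() < 0.5 else "-",
            int(rng.integers(0, length)),
            float(rng.integers(1, 4)),
        )
        for _ in range(120)
    ]
    reflected = [
        ("-" if s == "+" else "+", length - 1 - p, w) for s, p, w in fives
    ]
    a = pk.pingpong_profile(fives, 20)
    b = pk.pingpong_profile(reflected, 20)
    assert a.percentages == pytest.approx(b.percentages)
    assert a.total_pair_weight == pytest.approx(b.total_pair_weight)

    cov_a = pk.strand_coverage(fives, length, "none", 1.0)
    cov_b = pk.strand_coverage(reflected, length, "none", 1.0)
    assert cov_b.sense == pytest.approx(cov_a.antisense[::-1])
    assert cov_b.antisense == pytest.approx(cov_a.sense[::-1])


def test_strand_coverage_increments_and_normalizes():
    cov = pk.strand_coverage([("+", 5, 2.0)], 10, "total_reads", 2.0)
    assert cov.sense[5] == pytest.approx(1.0)
    assert cov.sense.sum() == pytest.approx(1.0)
    assert (cov.antisense == 0).all()


def test_strand_coverage_scale_invariant_when_depth_and_normalizer_double():
    fives = [("+", 2, 3.0), ("-", 7, 1.0)]
    doubled = [(s, p, 2 * w) for s, p, w in fives]
    a = pk.strand_coverage(fives, 10, "total_reads", 4.0)
    b = pk.strand_coverage(doubled, 10, "total_reads", 8.0)
    assert a.sense == pytest.approx(b.sense)
    assert a.antisense == pytest.approx(b.antisense)


def test_strand_coverage_zero_normalizer_errors():
    with pytest.raises(DataError):
        pk.strand_coverage([], 10, "total_reads", 0)


def _element_five_primes(config):
    catalog = pk.build_reference_catalog(config)
    reads, _ = pk.simulate_library(config, catalog)
    pre = pk.preprocess_library(reads, pk.PreprocessParams(adapter=config.adapter))
    element = catalog.find(catalog.element_name)
    element_index = pk.SeedIndex(
        pk.ReferenceCatalog([("element", {catalog.element_name: element})])
    )
    pairs = pk.align_library(pre.collapsed, element_index, 1)
    return pk.collect_five_primes(pairs, catalog.element_name)


def test_offset10_share_monotone_in_planted_pingpong_fraction():
    shares = []
    for fraction in (0.1, 0.3, 0.6):
        config = pk.SimConfig(
            seed=31, n_mirna=0, n_mili=0, n_miwi=1500, error_rate=0.0,
            pingpong_fraction=fraction, element_fraction=1.0,
            ref_sizes=small_ref_sizes(),
        )
        profile = pk.pingpong_profile(_element_five_primes(config), 20)
        shares.append(profile.percentages[9])
    assert shares == sorted(shares)
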