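"""Generator behaviour: determinism, planted structure, ground truth."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import pirnakit as pk
from pirnakit.errors import ConfigurationError

from conftest import small_ref_sizes


def test_catalog_deterministic_under_fixed_seed(small_config):
    a = pk.build_reference_catalog(small_config)
    b = pk.build_reference_catalog(small_config)
    assert list(a.iter_refs()) == list(b.iter_refs())
    cluster = a["piRNA_cluster"]["cluster_01"]
    assert len(cluster) == small_config.ref_sizes["piRNA_cluster"][0]
    assert set(cluster) <= set("ACGT")


def test_catalog_differs_by_seed_but_not_in_structure(small_config):
    import dataclasses

    other = dataclasses.replace(small_config, seed=small_config.seed + 1)
    a = pk.build_reference_catalog(small_config)
    b = pk.build_reference_catalog(other)
    assert a.category_names == b.category_names
    assert [(c, n, len(s)) for c, n, s in a.iter_refs()] == [
        (c, n, len(s)) for c, n, s in b.iter_refs()
    ]
    assert any(sa != sb for (_, _, sa), (_, _, sb) in
               zip(a.iter_refs(), b.iter_refs()))


def test_zero_reference_size_rejected():
    sizes = small_ref_sizes()
    sizes["piRNA_cluster"] = [1200, 0]
    config = pk.SimConfig(ref_sizes=sizes)
    with pytest.raises(ConfigurationError):
        pk.build_reference_catalog(config)


def test_library_bit_identical_across_runs(small_config, small_catalog):
    reads_a, truth_a = pk.simulate_library(small_config, small_catalog)
    reads_b, truth_b = pk.simulate_library(small_config, small_catalog)
    assert reads_a == reads_b
    pd.testing.assert_frame_equal(truth_a, truth_b)


def test_record_count_matches_configured_totals(small_config, small_library):
    reads, truth = small_library
    expected = small_config.n_mirna + small_config.n_mili + small_config.n_miwi
    assert len(reads) == expected
    assert len(truth) == expected
    assert truth.read_id.is_unique


def test_zero_pingpong_fraction_yields_no_responders(small_config, small_catalog):
    import dataclasses

    config = dataclasses.replace(small_config, pingpong_fraction=0.0)
    _, truth = pk.simulate_library(config, small_catalog)
    assert truth.is_pingpong_responder.sum() == 0


def test_responders_reference_existing_partners(small_library):
    _, truth = small_library
    responders = truth[truth.is_pingpong_responder]
    assert len(responders) > 0
    ids = set(truth.read_id)
    assert set(responders.partner_id) <= ids
    partners = truth.set_index("read_id").loc[list(responders.partner_id)]
    assert (partners.strand == "+").all()
    assert (partners.source_ref == responders.source_ref.iloc[0]).all()


def test_full_u1_forcing_without_errors_starts_every_primary_with_t(
    small_config, small_catalog
):
    import dataclasses

    config = dataclasses.replace(small_config, u1_fraction=1.0)
    _, truth = pk.simulate_library(config, small_catalog)
    primaries = truth[
        truth.population.isin(["mili", "miwi"]) & ~truth.is_pingpong_responder
    ]
    assert (primaries.insert_seq.str[0] == "T").all()


def test_error_free_reads_are_insert_plus_adapter(small_config, small_library):
    reads, truth = small_library
    by_id = {r.read_id: r.sequence for r in reads}
    for row in truth.itertuples():
        assert by_id[row.read_id] == row.insert_seq + small_config.adapter


def test_truth_coordinates_match_reference_except_forced_positions(
    small_config, small_catalog, small_library
):
    """With no sequencing errors the insert equals the reference window
    (reverse-complemented on the minus strand) at every position except the
    forced first base of primaries and position 10 of responders."""
    _, truth = small_library
    for row in truth.itertuples():
        ref = small_catalog.find(row.source_ref)
        window = ref[row.source_start : row.source_start + row.insert_len]
        expected = window if row.strand == "+" else pk.revcomp(window)
        forced = set()
        if row.population in ("mili", "miwi"):
            forced = {9} if row.is_pingpong_responder else {0}
        diffs = {
            i for i, (a, b) in enumerate(zip(row.insert_seq, expected)) if a != b
        }
        assert diffs <= forced, row.read_id


def test_responder_overlap_with_initiator_is_exactly_the_offset(
    small_config, small_library
):
    _, truth = small_library
    indexed = truth.set_index("read_id")
    responders = truth[truth.is_pingpong_responder]
    for row in responders.itertuples():
        partner = indexed.loc[row.partner_id]
        q = row.source_start + row.insert_len - 1  # minus-strand 5' end
        p = partner.source_start  # plus-strand 5' end
        assert q - p + 1 == small_config.pingpong_offset


def test_mili_length_histogram_within_binomial_ci(small_catalog):
    config = pk.SimConfig(
        seed=11, n_mirna=0, n_mili=1000, n_miwi=0, error_rate=0.0,
        pingpong_fraction=0.0, element_fraction=0.0,
        ref_sizes=small_ref_sizes(),
    )
    catalog = pk.build_reference_catalog(config)
    _, truth = pk.simulate_library(config, catalog)
    counts = truth.insert_len.value_counts()
    lo, hi = stats.binom.interval(0.99, 1000, 0.25)
    for length in (25, 26, 27, 28):
        assert lo <= counts[length] <= hi


def test_empirical_u1_fraction_converges(small_catalog):
    config = pk.SimConfig(
        seed=13, n_mirna=0, n_mili=5000, n_miwi=0, error_rate=0.0,
        pingpong_fraction=0.0, element_fraction=0.0, u1_fraction=0.6,
        ref_sizes=small_ref_sizes(),
    )
    catalog = pk.build_reference_catalog(config)
    _, truth = pk.simulate_library(config, catalog)
    n_u = (truth.insert_seq.str[0] == "T").sum()
    lo, hi = stats.binom.interval(0.99, 5000, 0.6)
    assert lo <= n_u <= hi


def test_invalid_fractions_rejected():
    with pytest.raises(ConfigurationError):
        pk.SimConfig(u1_fraction=1.5).validate()
    with pytest.raises(ConfigurationError):
        pk.SimConfig(pingpong_offset=0).validate()
    with pytest.raises(ConfigurationError):
        pk.SimConfig(n_mili=-1).validate()


def test_element_too_short_for_pingpong_is_a_configuration_error():
    sizes = small_ref_sizes()
    sizes["element"] = 30  # < max read length + offset
    config = pk.SimConfig(
        n_mirna=0, n_mili=100, n_miwi=100, pingpong_fraction=0.5,
        ref_sizes=sizes,
    )
    catalog = pk.build_reference_catalog(config)
    with pytest.raises(ConfigurationError):
        pk.simulate_library(config, catalog)
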