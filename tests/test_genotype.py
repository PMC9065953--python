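"""Genotype-likelihood kernel against brute-force oracles, calling
behaviour, and symmetry/consistency properties."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from invertype.genotype import (GenotypeConfig, NO_CALL, calls_to_frame,
                                genotype_all, genotype_inversion,
                                site_log_likelihoods)
from invertype.synth import SimulationConfig, make_panel, simulate_cohort

CFG = GenotypeConfig(damage_mode="ignore")


def brute_force_likelihoods(reads, allele_a, allele_b, e):
    """Independent oracle: plain product over reads, no logs until the end.

    reads: list of (base, ) observed bases.
    """
    def p(obs, allele):
        return 1.0 - e if obs == allele else e / 3.0

    l_aa = l_ab = l_bb = 1.0
    for obs in reads:
        l_aa *= p(obs, allele_a)
        l_bb *= p(obs, allele_b)
        l_ab *= 0.5 * p(obs, allele_a) + 0.5 * p(obs, allele_b)
    return np.log([l_aa, l_ab, l_bb])


def obs_frame(rows):
    return pd.DataFrame(
        rows, columns=["specimen", "chrom", "pos", "base", "dist5", "dist3",
                       "read_len"]
    )


def panel_frame(rows):
    return pd.DataFrame(
        rows, columns=["inversion_id", "chrom", "pos", "allele_A", "allele_B"]
    )


def test_no_reads_gives_flat_loglik():
    np.testing.assert_array_equal(
        site_log_likelihoods([], "A", "C", CFG), np.zeros(3)
    )


def test_single_read_matches_direct_formula():
    e = 0.01
    ll = site_log_likelihoods(["A"], "A", "C", GenotypeConfig(error_rate=e))
    assert math.exp(ll[0]) == pytest.approx(0.99)
    assert math.exp(ll[2]) == pytest.approx(e / 3)
    assert math.exp(ll[1]) == pytest.approx(0.5 * 0.99 + 0.5 * e / 3)


def test_five_reads_match_bruteforce_product():
    reads = ["A", "A", "A", "C", "C"]
    expected = brute_force_likelihoods(reads, "A", "C", 0.01)
    got = site_log_likelihoods(reads, "A", "C", GenotypeConfig(error_rate=0.01))
    np.testing.assert_allclose(got, expected, atol=1e-12, rtol=0)


def test_invalid_inputs_raise():
    with pytest.raises(ValueError):
        site_log_likelihoods(["N"], "A", "C", CFG)
    with pytest.raises(ValueError):
        site_log_likelihoods(["A"], "A", "A", CFG)


@settings(deadline=None, derandomize=True, max_examples=50)
@given(
    st.lists(st.sampled_from("ACGT"), min_size=0, max_size=40),
    st.sampled_from([("A", "C"), ("C", "T"), ("G", "A"), ("T", "G")]),
    st.floats(min_value=1e-4, max_value=0.2),
)
def test_posterior_normalises_and_matches_oracle(bases, alleles, e):
    """For arbitrary observations the three posteriors sum to 1 within
    1e-12 and the total likelihood equals the brute-force product."""
    a, b = alleles
    cfg = GenotypeConfig(error_rate=e, damage_mode="ignore", min_sites=0)
    panel = panel_frame([("LG1", "c", 10, a, b)])
    rows = [("S", "c", 10, base, 5, 30, 36) for base in bases]
    call = genotype_inversion(obs_frame(rows), panel, cfg, specimen="S")
    assert sum(call.posterior) == pytest.approx(1.0, abs=1e-12)
    if bases:
        expected = brute_force_likelihoods(bases, a, b, e)
        w = np.exp(expected - expected.max())
        np.testing.assert_allclose(call.posterior, w / w.sum(), atol=1e-12,
                                   rtol=0)


def test_zero_observations_is_uniform_no_call():
    panel = panel_frame([("LG1", "c", 10, "A", "C")])
    call = genotype_inversion(obs_frame([]), panel, CFG, specimen="S")
    assert call.hard_call == NO_CALL
    assert call.posterior == pytest.approx((1 / 3, 1 / 3, 1 / 3))
    assert call.n_sites_used == 0 and call.n_reads_used == 0


def test_uniform_b_reads_give_confident_bb():
    """3x coverage of the B allele over 50 sites -> BB above 0.999."""
    rng = np.random.default_rng(0)
    panel = panel_frame([("LG1", "c", i + 1, "A", "C") for i in range(50)])
    rows = [("S", "c", i + 1, "C", 10, 25, 36)
            for i in range(50) for _ in range(3)]
    call = genotype_inversion(obs_frame(rows), panel, CFG, specimen="S")
    assert call.hard_call == "BB"
    assert call.posterior[2] > 0.999


def test_simulated_genotypes_recovered_including_heterozygote(strong_freqs):
    """100 sites at 1x with e=0.01: every simulated specimen's hard calls
    match its true genotypes, including heterozygous inversions."""
    panel = make_panel(100, seed=51)
    freqs = pd.DataFrame(
        [("P", inv, 0.5) for inv in ("LG1", "LG2", "LG7", "LG12")],
        columns=["population", "inversion_id", "freq_B"],
    )
    cfg = SimulationConfig(coverage_mean=1.0, error_rate=0.01,
                           damage_amplitude=0.0, seed=52)
    pops = [(f"S{i}", "P") for i in range(12)]
    truth, obs = simulate_cohort(pops, panel, freqs, cfg)
    calls = genotype_all(obs, panel, GenotypeConfig(damage_mode="ignore"))
    truth_map = {(r.specimen, r.inversion_id): r.genotype
                 for r in truth.itertuples(index=False)}
    genotypes_seen = set()
    for c in calls:
        if c.hard_call != NO_CALL:
            assert c.hard_call == truth_map[(c.specimen, c.inversion_id)]
            genotypes_seen.add(c.hard_call)
    assert "AB" in genotypes_seen


def test_posterior_concentrates_at_high_coverage(strong_freqs):
    """Consistency: 30x coverage over 50 sites puts >=0.999 on the truth."""
    panel = make_panel(50, seed=61)
    cfg = SimulationConfig(coverage_mean=30.0, error_rate=0.01,
                           damage_amplitude=0.0, seed=62)
    truth, obs = simulate_cohort([("S0", "NEAC")], panel, strong_freqs, cfg)
    calls = genotype_all(obs, panel, GenotypeConfig(damage_mode="ignore"))
    truth_map = {(r.specimen, r.inversion_id): r.genotype
                 for r in truth.itertuples(index=False)}
    for c in calls:
        idx = {"AA": 0, "AB": 1, "BB": 2}[truth_map[(c.specimen, c.inversion_id)]]
        assert c.posterior[idx] >= 0.999


def test_allele_label_symmetry(strong_freqs):
    """Swapping allele_A <-> allele_B mirrors every posterior exactly."""
    panel = make_panel(30, seed=71)
    cfg = SimulationConfig(coverage_mean=1.0, seed=72)
    _, obs = simulate_cohort([("S0", "Lofoten_Coastal")], panel, strong_freqs,
                             cfg)
    swapped = panel.rename(columns={"allele_A": "allele_B",
                                    "allele_B": "allele_A"})
    gcfg = GenotypeConfig(damage_mode="ignore", min_sites=0)
    for orig, mirr in zip(genotype_all(obs, panel, gcfg),
                          genotype_all(obs, swapped, gcfg)):
        assert orig.posterior == tuple(reversed(mirr.posterior))


def test_genotype_all_counts_and_partial_coverage():
    panel = pd.concat([
        panel_frame([(inv, inv, i + 1, "A", "C") for i in range(6)])
        for inv in ("LG1", "LG2", "LG7", "LG12")
    ], ignore_index=True)
    rows = [("S", "LG1", i + 1, "C", 10, 20, 31) for i in range(6)]
    calls = genotype_all(obs_frame(rows), panel, CFG)
    assert len(calls) == 4
    by_inv = {c.inversion_id: c for c in calls}
    assert by_inv["LG1"].hard_call == "BB"
    for inv in ("LG2", "LG7", "LG12"):
        assert by_inv[inv].hard_call == NO_CALL
    frame = calls_to_frame(calls)
    assert list(frame["inversion_id"]) == ["LG1", "LG2", "LG7", "LG12"]


def test_damage_filter_drops_terminal_ambiguous_reads():
    """At a C/T site, terminal T observations (dist5 < window) are excluded
    under damage_mode='filter' but kept under 'ignore'."""
    panel = panel_frame([("LG1", "c", 1, "C", "T")])
    rows = [
        ("S", "c", 1, "T", 0, 40, 41),   # terminal T: filtered
        ("S", "c", 1, "T", 2, 38, 41),   # terminal T: filtered
        ("S", "c", 1, "T", 20, 20, 41),  # interior T: kept
        ("S", "c", 1, "C", 1, 39, 41),   # C never filtered
    ]
    obs = obs_frame(rows)
    kept = genotype_inversion(obs, panel,
                              GenotypeConfig(damage_mode="filter",
                                             damage_window=5, min_sites=0),
                              specimen="S")
    ignored = genotype_inversion(obs, panel,
                                 GenotypeConfig(damage_mode="ignore",
                                                min_sites=0), specimen="S")
    assert kept.n_reads_used == 2
    assert ignored.n_reads_used == 4
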