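"""Population assignment: HWE kernel, hand and enumeration oracles,
symmetry properties, cohort summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest

from invertype.assign import (AssignConfig, UNASSIGNED, assign_ecotype,
                              classify_cohort, genotype_prob_under_pop)
from invertype.genotype import GENOTYPE_STATES, NO_CALL, InversionGenotypeCall


def freq_frame(values):
    rows = [(pop, inv, f) for pop, per_inv in values.items()
            for inv, f in per_inv.items()]
    return pd.DataFrame(rows, columns=["population", "inversion_id", "freq_B"])


def call(inv, hard, posterior=None, specimen="S"):
    if posterior is None:
        posterior = tuple(1.0 if g == hard else 0.0 for g in GENOTYPE_STATES)
    return InversionGenotypeCall(
        specimen=specimen, inversion_id=inv, posterior=tuple(posterior),
        hard_call=hard, n_sites_used=10, n_reads_used=20,
    )


def enumeration_oracle(calls, freqs, prior):
    """Independent soft-mode oracle: sum over every genotype configuration."""
    pops = list(dict.fromkeys(freqs["population"]))
    table = {(r.population, r.inversion_id): r.freq_B
             for r in freqs.itertuples(index=False)}
    out = {}
    for pop in pops:
        total = 0.0
        for config in itertools.product(range(3), repeat=len(calls)):
            term = 1.0
            for c, gi in zip(calls, config):
                g = GENOTYPE_STATES[gi]
                term *= c.posterior[gi] * genotype_prob_under_pop(
                    g, table[(pop, c.inversion_id)])
            total += term
        out[pop] = prior[pop] * total
    z = sum(out.values())
    return {p: v / z for p, v in out.items()}


@pytest.mark.parametrize(
    "genotype,f,expected",
    [("AB", 0.5, 0.5), ("BB", 1.0, 1.0), ("AA", 1.0, 0.0), ("BB", 0.9, 0.81),
     ("AA", 0.3, 0.49)],
)
def test_hwe_genotype_probability(genotype, f, expected):
    assert genotype_prob_under_pop(genotype, f) == pytest.approx(expected)


def test_hwe_rejects_bad_inputs():
    with pytest.raises(ValueError):
        genotype_prob_under_pop("XX", 0.5)
    with pytest.raises(ValueError):
        genotype_prob_under_pop("AA", 1.5)


def test_two_population_hand_oracle():
    """One BB call, f_B 0.9 vs 0.1: posterior (0.81, 0.01)/0.82."""
    freqs = freq_frame({"hi": {"LG1": 0.9}, "lo": {"LG1": 0.1}})
    a = assign_ecotype([call("LG1", "BB")], freqs,
                       AssignConfig(threshold=0.6))
    assert a.posterior["hi"] == pytest.approx(0.81 / 0.82, abs=1e-12)
    assert a.posterior["lo"] == pytest.approx(0.01 / 0.82, abs=1e-12)
    assert a.label == "hi"


def test_identical_frequencies_return_prior_unassigned():
    freqs = freq_frame({p: {"LG1": 0.4, "LG2": 0.4}
                        for p in ("a", "b", "c")})
    a = assign_ecotype([call("LG1", "AB"), call("LG2", "BB")], freqs,
                       AssignConfig(threshold=0.95))
    for p in ("a", "b", "c"):
        assert a.posterior[p] == pytest.approx(1 / 3, abs=1e-12)
    assert a.label == UNASSIGNED


def test_soft_mode_matches_exhaustive_enumeration():
    """4 inversions x 3 populations with random frequencies and random
    genotype posteriors: soft-mode posterior equals the 3^4-configuration
    enumeration to 1e-12."""
    rng = np.random.default_rng(123)
    invs = ["LG1", "LG2", "LG7", "LG12"]
    pops = ["NEAC", "Lofoten_Coastal", "West_Coastal"]
    for _ in range(20):
        freqs = freq_frame({p: {i: rng.uniform(0.05, 0.95) for i in invs}
                            for p in pops})
        calls = []
        for inv in invs:
            post = rng.dirichlet([1.0, 1.0, 1.0])
            hard = GENOTYPE_STATES[int(np.argmax(post))]
            calls.append(call(inv, hard, posterior=post))
        a = assign_ecotype(calls, freqs, AssignConfig(mode="soft"))
        prior = {p: 1 / 3 for p in pops}
        expected = enumeration_oracle(calls, freqs, prior)
        for p in pops:
            assert a.posterior[p] == pytest.approx(expected[p], abs=1e-12)


def test_soft_with_degenerate_posteriors_equals_hard():
    rng = np.random.default_rng(5)
    invs = ["LG1", "LG2", "LG7", "LG12"]
    freqs = freq_frame({p: {i: rng.uniform(0.1, 0.9) for i in invs}
                        for p in ("x", "y", "z")})
    calls = [call(i, rng.choice(GENOTYPE_STATES)) for i in invs]
    hard = assign_ecotype(calls, freqs, AssignConfig(mode="hard"))
    soft = assign_ecotype(calls, freqs, AssignConfig(mode="soft"))
    for p in ("x", "y", "z"):
        assert hard.posterior[p] == pytest.approx(soft.posterior[p], abs=1e-15)


def test_population_order_invariance():
    base = {"a": {"LG1": 0.9, "LG2": 0.2}, "b": {"LG1": 0.1, "LG2": 0.7},
            "c": {"LG1": 0.5, "LG2": 0.5}}
    calls = [call("LG1", "BB"), call("LG2", "AB")]
    f1 = freq_frame(base)
    f2 = freq_frame({k: base[k] for k in ("c", "a", "b")})
    a1 = assign_ecotype(calls, f1)
    a2 = assign_ecotype(calls, f2)
    assert a1.posterior == pytest.approx(a2.posterior)
    assert a1.label == a2.label


def test_uninformative_inversion_leaves_posterior_unchanged():
    informative = {"a": {"LG1": 0.9}, "b": {"LG1": 0.1}}
    with_extra = {"a": {"LG1": 0.9, "LG2": 0.33},
                  "b": {"LG1": 0.1, "LG2": 0.33}}
    a1 = assign_ecotype([call("LG1", "BB")], freq_frame(informative),
                        AssignConfig(threshold=0.6))
    a2 = assign_ecotype([call("LG1", "BB"), call("LG2", "AB")],
                        freq_frame(with_extra), AssignConfig(threshold=0.6))
    for p in ("a", "b"):
        assert a1.posterior[p] == pytest.approx(a2.posterior[p], abs=1e-12)


def test_fixed_frequency_survives_one_discordant_call():
    """The probability floor keeps a population with f_B=1 alive after a
    single discordant (possibly erroneous) call."""
    freqs = freq_frame({"fixed": {"LG1": 1.0, "LG2": 1.0},
                        "other": {"LG1": 0.6, "LG2": 0.6}})
    calls = [call("LG1", "BB"), call("LG2", "AB")]  # AB impossible under f=1
    a = assign_ecotype(calls, freqs, AssignConfig(threshold=0.95))
    assert a.posterior["fixed"] > 0.0
    assert a.label == "other"


def test_no_calls_returns_prior_and_unassigned():
    freqs = freq_frame({"a": {"LG1": 0.9}, "b": {"LG1": 0.1}})
    a = assign_ecotype([call("LG1", NO_CALL, posterior=(1/3, 1/3, 1/3))],
                       freqs, AssignConfig(threshold=0.95))
    assert a.label == UNASSIGNED
    assert a.n_inversions_used == 0
    assert a.posterior == {"a": 0.5, "b": 0.5}


def test_missing_frequency_raises_lookup_error():
    freqs = freq_frame({"a": {"LG1": 0.9}, "b": {"LG1": 0.1}})
    with pytest.raises(KeyError):
        assign_ecotype([call("LG2", "BB")], freqs)


def test_cohort_two_of_five_is_forty_percent():
    """A cohort labelled [NEAC, NEAC, coastal, coastal, coastal] has a
    migratory fraction of exactly 40%."""
    labels = ["NEAC", "NEAC", "coastal", "coastal", "coastal"]
    assignments = [
        # minimal assignment stubs carrying the label of interest
        type("A", (), {"posterior": {"NEAC": 0.0, "coastal": 0.0},
                       "label": lab})()
        for lab in labels
    ]
    summary = classify_cohort(assignments)
    assert summary.counts["NEAC"] == 2
    assert summary.fractions["NEAC"] == pytest.approx(0.40)
    assert summary.n == 5


def test_cohort_all_unassigned_has_zero_population_counts():
    assignments = [
        type("A", (), {"posterior": {"NEAC": 0.5, "coastal": 0.5},
                       "label": UNASSIGNED})()
        for _ in range(3)
    ]
    summary = classify_cohort(assignments)
    assert summary.counts["NEAC"] == 0
    assert summary.counts["coastal"] == 0
    assert summary.counts[UNASSIGNED] == 3
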