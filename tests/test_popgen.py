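import itertools
import math

import numpy as np
import pytest
from scipy.stats import chi2, fisher_exact

from breedsnp.popgen import (
    ChainSettings,
    allele_frequencies,
    exact_table_test,
    fisher_combined,
    genic_differentiation,
    genotypic_differentiation,
    hwe_exact,
    locus_allele_counts,
    _feasible_heterozygote_counts,
    _log_array_prob,
    _log_table_prob,
)
from breedsnp.simulate import simulate_genotype_panel


# ------------------------------------------------------------------- HWE

@pytest.mark.parametrize(
    "counts,expected",
    [
        # full enumeration by hand: arrays (1,0,1) P=1/3 and (0,2,0) P=2/3
        ((1, 0, 1), 1 / 3),
        ((0, 2, 0), 1.0),
    ],
)
def test_hwe_probability_test_hand_enumerated(counts, expected):
    res = hwe_exact(counts, method="enum")
    assert res.p_value == pytest.approx(expected, rel=1e-12)
    assert res.method == "enumeration" and res.mc_std_error == 0.0


def test_hwe_monomorphic_flag():
    res = hwe_exact((5, 0, 0))
    assert res.p_value == 1.0 and res.monomorphic


def test_hwe_rejects_invalid_counts():
    with pytest.raises(ValueError):
        hwe_exact((0, 0, 0))
    with pytest.raises(ValueError):
        hwe_exact((-1, 2, 0))


def test_conditional_array_probabilities_sum_to_one():
    rng = np.random.default_rng(0)
    for _ in range(200):
        n = int(rng.integers(1, 60))
        n_a = int(rng.integers(0, 2 * n + 1))
        total = sum(
            math.exp(_log_array_prob((n_a - ab) // 2, ab, (2 * n - n_a - ab) // 2))
            for ab in _feasible_heterozygote_counts(n, n_a)
        )
        assert total == pytest.approx(1.0, rel=1e-9)


def test_hwe_markov_chain_agrees_with_enumeration():
    chain = ChainSettings(dememorization=1000, batches=20, iterations_per_batch=2000)
    rng = np.random.default_rng(42)
    for trial in range(12):
        n_aa, n_ab, n_bb = (int(rng.integers(0, 15)) for _ in range(3))
        if n_aa + n_ab + n_bb == 0:
            continue
        enum = hwe_exact((n_aa, n_ab, n_bb), method="enum")
        mc = hwe_exact((n_aa, n_ab, n_bb), method="mc", chain=chain, seed=trial)
        if mc.monomorphic or enum.monomorphic:
            assert mc.p_value == enum.p_value == 1.0
            continue
        slack = max(3 * mc.mc_std_error, 3 / (chain.batches * chain.iterations_per_batch))
        assert abs(mc.p_value - enum.p_value) <= slack


def test_hwe_markov_chain_deterministic_for_fixed_seed():
    a = hwe_exact((6, 3, 6), method="mc", seed=11)
    b = hwe_exact((6, 3, 6), method="mc", seed=11)
    assert a.p_value == b.p_value and a.mc_std_error == b.mc_std_error


def test_hwe_type_one_error_conservative_under_null():
    # HWE-true genotypes: rejection rate at alpha=0.05 must not exceed the
    # nominal level beyond binomial noise (exact tests are conservative)
    n_loci, n, q = 400, 50, 0.3
    freqs = {f"L{j}": {"X": q} for j in range(n_loci)}
    gm = simulate_genotype_panel({"X": n}, freqs, seed=3)
    rejections = sum(
        hwe_exact(gm.genotype_counts(locus, "X")).p_value <= 0.05
        for locus in gm.loci
    )
    bound = 0.05 + 3 * math.sqrt(0.05 * 0.95 / n_loci)
    assert rejections / n_loci <= bound


# ------------------------------------------------- contingency-table tests

def enumerate_2x2_pvalue(table):
    """Independent oracle: hypergeometric enumeration over the free cell."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def log_prob(k):
        return (
            math.lgamma(r1 + 1) + math.lgamma(r2 + 1)
            + math.lgamma(c1 + 1) + math.lgamma(n - c1 + 1) - math.lgamma(n + 1)
            - math.lgamma(k + 1) - math.lgamma(r1 - k + 1)
            - math.lgamma(c1 - k + 1) - math.lgamma(r2 - c1 + k + 1)
        )

    lp_obs = log_prob(a)
    total = 0.0
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        lp = log_prob(k)
        if lp <= lp_obs + 1e-9:
            total += math.exp(lp)
    return min(total, 1.0)


def test_fixed_allele_table_probability():
    # 2 breeds, complete fixation: only the two extreme tables are as improbable
    res = exact_table_test(np.array([[10, 0], [0, 10]]), method="enum")
    assert res.p_value == pytest.approx(2 / 184_756, rel=1e-9)


def test_modal_table_has_p_one():
    res = exact_table_test(np.array([[5, 5], [5, 5]]), method="enum")
    assert res.p_value == pytest.approx(1.0, rel=1e-9)


def test_2x2_enumeration_matches_independent_oracle_and_scipy():
    rng = np.random.default_rng(7)
    for _ in range(25):
        table = rng.integers(0, 16, size=(2, 2))
        if table.sum(axis=1).min() == 0 or table.sum(axis=0).min() == 0:
            continue
        p = exact_table_test(table, method="enum").p_value
        assert p == pytest.approx(enumerate_2x2_pvalue(table), rel=1e-9)
        assert p == pytest.approx(fisher_exact(table)[1], rel=1e-7)


def test_3x3_enumeration_matches_direct_itertools_oracle():
    table = np.array([[3, 1, 0], [1, 2, 2], [0, 1, 3]])
    rows, cols = table.sum(axis=1), table.sum(axis=0)
    lp_obs = _log_table_prob(table)
    total = 0.0
    for c00, c01, c10, c11 in itertools.product(
        range(rows[0] + 1), range(rows[0] + 1),
        range(rows[1] + 1), range(rows[1] + 1),
    ):
        t = np.array([
            [c00, c01, rows[0] - c00 - c01],
            [c10, c11, rows[1] - c10 - c11],
            [cols[0] - c00 - c10, cols[1] - c01 - c11, 0],
        ])
        t[2, 2] = rows[2] - t[2, 0] - t[2, 1]
        if (t < 0).any():
            continue
        lp = _log_table_prob(t)
        if lp <= lp_obs + 1e-9:
            total += math.exp(lp)
    res = exact_table_test(table, method="enum")
    assert res.p_value == pytest.approx(min(total, 1.0), rel=1e-9)


def test_table_markov_chain_within_three_se_of_enumeration():
    chain = ChainSettings(dememorization=1000, batches=20, iterations_per_batch=2000)
    rng = np.random.default_rng(5)
    for trial in range(8):
        table = rng.integers(0, 8, size=(3, 3))
        if table.sum(axis=1).min() == 0 or table.sum(axis=0).min() == 0:
            continue
        enum = exact_table_test(table, method="enum")
        mc = exact_table_test(table, method="mc", chain=chain, seed=trial)
        slack = max(3 * mc.mc_std_error, 3 / (chain.batches * chain.iterations_per_batch))
        assert abs(mc.p_value - enum.p_value) <= slack


def test_differentiation_invariant_under_relabeling():
    table = np.array([[8, 2], [3, 7], [5, 5]])
    p = exact_table_test(table, method="enum").p_value
    assert exact_table_test(table[::-1], method="enum").p_value == pytest.approx(p, rel=1e-9)
    assert exact_table_test(table[:, ::-1], method="enum").p_value == pytest.approx(p, rel=1e-9)


def panel():
    freqs = {
        "L1": {"HF": 0.95, "Red": 0.10, "Her": 0.15},
        "L2": {"HF": 0.50, "Red": 0.50, "Her": 0.50},
    }
    return simulate_genotype_panel({"HF": 15, "Red": 15, "Her": 14}, freqs, seed=9)


def test_genic_and_genotypic_differentiation_on_panel():
    gm = panel()
    strongly = genic_differentiation(gm, "L1", method="enum")
    weakly = genic_differentiation(gm, "L2", method="enum")
    assert strongly.p_value < 1e-6 < weakly.p_value
    geno = genotypic_differentiation(gm, "L1", method="enum")
    assert geno.p_value < 1e-4


def test_genotypic_two_breed_extreme_table():
    # breeds fixed for opposite homozygotes: enumeration over (10+10 choose ...)
    table = np.array([[10, 0, 0], [0, 0, 10]])
    res = exact_table_test(table, method="enum")
    oracle = enumerate_2x2_pvalue([[10, 0], [0, 10]])  # middle column is empty
    assert res.p_value == pytest.approx(oracle, rel=1e-9)


# ----------------------------------------------------------- frequencies

def test_allele_frequencies_basic():
    gm = simulate_genotype_panel({"X": 1}, {"L0": {"X": 0.0}}, seed=0)
    gm.genotypes = [["AB"]]
    freq = allele_frequencies(gm)
    assert freq.loc["L0", "X"] == 0.5
    gm.genotypes = [["AA"]]
    assert allele_frequencies(gm).loc["L0", "X"] == 1.0
    gm.genotypes = [[None]]
    assert math.isnan(allele_frequencies(gm).loc["L0", "X"])


def test_allele_counts_complete_case():
    gm = panel()
    for breed, (n_a, n_b) in locus_allele_counts(gm, "L1").items():
        n_aa, n_ab, n_bb = gm.genotype_counts("L1", breed)
        assert n_a == 2 * n_aa + n_ab and n_b == 2 * n_bb + n_ab
        assert n_a + n_b == 2 * (n_aa + n_ab + n_bb)


# -------------------------------------------------------- Fisher combined

def test_fisher_combined_examples():
    res = fisher_combined([1.0, 1.0, 1.0])
    assert res.chi_square == 0.0 and res.p_value == pytest.approx(1.0)
    res = fisher_combined([0.5, 0.5])
    assert res.chi_square == pytest.approx(-2 * math.log(0.25), rel=1e-12)
    assert res.df == 4
    assert res.p_value == pytest.approx(chi2.sf(res.chi_square, 4), rel=1e-12)
    assert res.p_value == pytest.approx(0.5966, abs=5e-4)


@pytest.mark.parametrize("p", [0.9, 0.5, 0.1, 1e-4])
def test_fisher_combined_single_p_identity(p):
    # with one locus, -2 ln p against chi2(2) returns p itself
    assert fisher_combined([p]).p_value == pytest.approx(p, rel=1e-9)


def test_fisher_combined_floors_zeros_with_warning():
    with pytest.warns(UserWarning, match="floored"):
        res = fisher_combined([0.0, 0.5])
    assert res.n_floored == 1 and res.p_value < 1e-10
    with pytest.raises(ValueError):
        fisher_combined([])
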