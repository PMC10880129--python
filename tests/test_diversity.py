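import itertools
import math

import numpy as np
import pytest

from dayflower.datatypes import MISSING, GenotypeMatrix
from dayflower.diversity import (
    AlleleFreqTable,
    allele_frequencies,
    allelic_richness,
    diversity_table,
    expected_heterozygosity,
    hwe_exact_probabilities,
    hwe_exact_test,
    inbreeding_coefficient,
    multilocus_fis,
    observed_heterozygosity,
)


def _single_pop(calls):
    calls = np.asarray(calls, dtype=np.int8).reshape(len(calls), -1)
    inds = [f"i{k}" for k in range(calls.shape[0])]
    return GenotypeMatrix(
        inds, [f"L{j}" for j in range(calls.shape[1])], calls,
        {i: "p" for i in inds},
    )


def _freq_table(alt, total, het=None, pops=("p",)):
    alt = np.atleast_2d(alt)
    total = np.atleast_2d(total)
    het = np.zeros_like(alt) if het is None else np.atleast_2d(het)
    return AlleleFreqTable(
        list(pops), [f"L{j}" for j in range(alt.shape[1])],
        alt, total, het, total // 2,
    )


# ---------------------------------------------------------------------------
# Brute-force oracles
# ---------------------------------------------------------------------------

def rarefied_richness_bruteforce(counts, g):
    """Mean number of distinct alleles over all C(N, g) gene-copy subsamples."""
    copies = []
    for allele, n in enumerate(counts):
        copies += [allele] * n
    vals = [len(set(sub)) for sub in itertools.combinations(copies, g)]
    return sum(vals) / len(vals)


def unbiased_he_bruteforce(counts):
    """Probability two distinct gene copies differ, by pair enumeration."""
    copies = []
    for allele, n in enumerate(counts):
        copies += [allele] * n
    pairs = list(itertools.combinations(copies, 2))
    return sum(a != b for a, b in pairs) / len(pairs)


def hwe_probs_bruteforce(n_alt, n_diploids):
    """Exact conditional genotype-configuration probabilities by enumeration.

    Enumerate all (n_AA, n_Aa, n_aa) with the given allele counts; weight
    each by multinomial(n; ...) * 2^n_het, normalise.
    """
    weights = {}
    for n_het in range(n_alt % 2, min(n_alt, 2 * n_diploids - n_alt) + 1, 2):
        n_alt_hom = (n_alt - n_het) // 2
        n_ref_hom = n_diploids - n_het - n_alt_hom
        if n_ref_hom < 0:
            continue
        w = (math.factorial(n_diploids)
             // (math.factorial(n_alt_hom) * math.factorial(n_het)
                 * math.factorial(n_ref_hom))) * 2 ** n_het
        weights[n_het] = w
    total = sum(weights.values())
    return {h: w / total for h, w in weights.items()}


# ---------------------------------------------------------------------------
# Allele frequencies / H_O
# ---------------------------------------------------------------------------

class TestAlleleFrequencies:
    def test_basic_counts(self):
        g = _single_pop([[0], [1], [2]])
        f = allele_frequencies(g)
        assert f.freq_alt()[0, 0] == pytest.approx(0.5)
        assert f.total_copies[0, 0] == 6

    def test_all_missing_flagged_undefined(self):
        g = _single_pop([[MISSING], [MISSING]])
        f = allele_frequencies(g)
        assert not f.defined()[0, 0]
        assert np.isnan(f.freq_alt()[0, 0])

    def test_monomorphic(self):
        g = _single_pop([[0], [0], [0]])
        f = allele_frequencies(g)
        assert f.freq_alt()[0, 0] == 0.0


class TestObservedHeterozygosity:
    @pytest.mark.parametrize(
        "calls,expected",
        [([[1], [1], [0], [2], [0]], 0.4),
         ([[0], [2], [0]], 0.0),
         ([[1], [1], [1]], 1.0)],
    )
    def test_values(self, calls, expected):
        assert observed_heterozygosity(_single_pop(calls)).iloc[0, 0] == pytest.approx(expected)

    def test_no_calls_undefined(self):
        ho = observed_heterozygosity(_single_pop([[MISSING], [MISSING]]))
        assert np.isnan(ho.iloc[0, 0])


class TestExpectedHeterozygosity:
    def test_plain_maximum(self):
        f = _freq_table([5], [10])
        assert expected_heterozygosity(f, unbiased=False).iloc[0, 0] == pytest.approx(0.5)

    def test_fixed_locus_zero(self):
        f = _freq_table([0], [10])
        for unbiased in (True, False):
            assert expected_heterozygosity(f, unbiased=unbiased).iloc[0, 0] == 0.0

    def test_unbiased_matches_pair_enumeration(self):
        # counts (5,5): 2*5*5/(10*9) = 0.5556 exactly
        f = _freq_table([5], [10])
        he = expected_heterozygosity(f, unbiased=True).iloc[0, 0]
        assert he == pytest.approx(50 / 90, abs=1e-12)
        # all count vectors up to N = 12
        for n in range(2, 13):
            for alt in range(n + 1):
                got = expected_heterozygosity(_freq_table([alt], [n])).iloc[0, 0]
                assert got == pytest.approx(unbiased_he_bruteforce([alt, n - alt]),
                                            abs=1e-12)


# ---------------------------------------------------------------------------
# Allelic richness
# ---------------------------------------------------------------------------

class TestAllelicRichness:
    def test_hand_case(self):
        # counts (5,5), g = 2 -> 1 + 2*(1 - C(5,2)/C(10,2)) ... = 70/45
        f = _freq_table([5], [10])
        ar, _ = allelic_richness(f, 2)
        assert ar.iloc[0, 0] == pytest.approx(70 / 45, abs=1e-12)

    def test_matches_bruteforce_enumeration(self):
        """Hurdle formula equals the exhaustive-subsample mean for N <= 12."""
        for n in range(2, 13):
            for alt in range(n + 1):
                for g in range(1, min(n, 5) + 1):
                    got = allelic_richness(_freq_table([alt], [n]), g)[0].iloc[0, 0]
                    want = rarefied_richness_bruteforce([alt, n - alt], g)
                    assert got == pytest.approx(want, abs=1e-12)

    def test_monomorphic_is_one(self):
        f = _freq_table([0], [10])
        assert allelic_richness(f, 5)[0].iloc[0, 0] == pytest.approx(1.0)

    def test_full_sample_gives_observed_count(self):
        f = _freq_table([3], [10])
        assert allelic_richness(f, 10)[0].iloc[0, 0] == pytest.approx(2.0)

    def test_underpowered_loci_skipped(self):
        f = _freq_table([[3, 1]], [[10, 4]])
        ar, skipped = allelic_richness(f, 5)
        assert skipped == ["L1"]
        assert np.isnan(ar.iloc[0, 1]) and np.isfinite(ar.iloc[0, 0])

    def test_invalid_g(self):
        with pytest.raises(ValueError):
            allelic_richness(_freq_table([3], [10]), 0)


# ---------------------------------------------------------------------------
# F_IS
# ---------------------------------------------------------------------------

class TestInbreeding:
    @pytest.mark.parametrize("ho,he,expected",
                             [(0.3, 0.3, 0.0), (0.0, 0.4, 1.0), (0.2, 0.4, 0.5)])
    def test_single_locus(self, ho, he, expected):
        assert inbreeding_coefficient(ho, he) == pytest.approx(expected)

    def test_undefined_when_he_zero(self):
        assert np.isnan(inbreeding_coefficient(0.0, 0.0))

    def test_ratio_of_sums_aggregation(self):
        import pandas as pd
        ho = pd.DataFrame({"L0": [0.1], "L1": [0.3]}, index=["p"])
        he = pd.DataFrame({"L0": [0.2], "L1": [0.6]}, index=["p"])
        assert multilocus_fis(ho, he)["p"] == pytest.approx(1 - 0.4 / 0.8)


# ---------------------------------------------------------------------------
# HWE exact test
# ---------------------------------------------------------------------------

class TestHweExact:
    def test_probabilities_sum_to_one(self):
        for n in range(2, 9):
            for n_alt in range(1, 2 * n):
                probs = hwe_exact_probabilities(n_alt, n)
                assert sum(probs.values()) == pytest.approx(1.0, abs=1e-12)

    def test_matches_enumeration_oracle(self):
        """Exact conditional distribution equals brute-force enumeration, n <= 8."""
        for n in range(2, 9):
            for n_alt in range(1, 2 * n):
                got = hwe_exact_probabilities(n_alt, n)
                want = hwe_probs_bruteforce(n_alt, n)
                assert set(got) == set(want)
                for h in got:
                    assert got[h] == pytest.approx(want[h], abs=1e-12)

    def test_deficit_p_for_two_homozygote_classes(self):
        # counts (AA=2, Aa=0, aa=2): one-sided deficit p = 6/70
        g = _single_pop([[0], [0], [2], [2]])
        res = hwe_exact_test(g)["p"]
        assert res.p_deficit[0] == pytest.approx(6 / 70, abs=1e-12)
        assert res.homozygote_excess[0]

    def test_all_het_deficit_p_is_one(self):
        g = _single_pop([[1], [1], [1], [1]])
        res = hwe_exact_test(g)["p"]
        assert res.p_deficit[0] == pytest.approx(1.0)

    def test_hwe_proportions_not_rejected(self):
        # 25 AA, 50 Aa, 25 aa: observed count is the conditional mode
        calls = [[0]] * 25 + [[1]] * 50 + [[2]] * 25
        res = hwe_exact_test(_single_pop(calls))["p"]
        assert res.p_two_sided[0] > 0.5

    def test_monomorphic_flagged(self):
        g = _single_pop([[0], [0], [0]])
        res = hwe_exact_test(g)["p"]
        assert res.monomorphic[0] and res.p_two_sided[0] == 1.0


# ---------------------------------------------------------------------------
# Assembled table
# ---------------------------------------------------------------------------

def test_diversity_table_ranges(rng):
    from conftest import random_matrix
    g = random_matrix(rng, n_ind=30, n_loci=20, n_pops=3, missing_rate=0.1)
    tab = diversity_table(g, rarefaction_copies=2)
    assert set(tab.columns) == {"N_A", "A_R", "H_O", "H_E", "F_IS"}
    assert ((tab["H_O"] >= 0) & (tab["H_O"] <= 1)).all()
    assert ((tab["H_E"] >= 0) & (tab["H_E"] <= 1)).all()
    assert ((tab["A_R"] >= 1) & (tab["A_R"] <= 2)).all()
    assert ((tab["F_IS"] >= -1) & (tab["F_IS"] <= 1)).all()
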