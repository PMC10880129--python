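"""Per-population genetic-diversity statistics and Hardy-Weinberg testing.

All statistics operate on a filtered :class:`~dayflower.datatypes.GenotypeMatrix`
through an :class:`AlleleFreqTable`, which caches per-(population, locus)
allele counts, called-genotype counts and heterozygote counts.  Loci with no
called genotypes in a population are undefined there and are excluded from
that population's means (no imputation).

Statistics
----------
H_O     observed heterozygosity: het calls / called genotypes.
H_E     expected heterozygosity (gene diversity); the unbiased
        without-replacement estimator (2n/(2n-1)) * (1 - sum p^2) by default.
N_A     mean number of alleles per locus observed in the population.
A_R     rarefied allelic richness: expected distinct alleles in a random
        subsample of g gene copies (hurdle formula, exact hypergeometric).
F_IS    inbreeding coefficient 1 - H_O/H_E, aggregated across loci as a
        ratio of sums (sum H_O / sum H_E) for stability at low-diversity loci.

The Hardy-Weinberg test is the exact conditional test for biallelic
genotypes: the probability of the observed heterozygote count given the
allele counts, with a one-sided heterozygote-deficit p-value and a
two-sided p-value (sum of configurations no more probable than observed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .datatypes import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Allele frequencies
# ---------------------------------------------------------------------------

@dataclass
class AlleleFreqTable:
    """Per (population, locus) allele counts for a biallelic SNP table.

    Arrays are shaped (n_pops, n_loci).  ``total_copies`` is twice the number
    of called genotypes; entries with ``total_copies == 0`` are undefined and
    flagged by :meth:`defined`.
    """

    populations: list[str]
    locus_ids: list[str]
    alt_copies: np.ndarray
    total_copies: np.ndarray
    het_calls: np.ndarray
    called_genotypes: np.ndarray

    def defined(self) -> np.ndarray:
        return self.total_copies > 0

    def freq_alt(self) -> np.ndarray:
        """ALT allele frequency; NaN where undefined."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(
                self.total_copies > 0, self.alt_copies / self.total_copies, np.nan
            )

    def pop_index(self, pop: str) -> int:
        return self.populations.index(pop)


def allele_frequencies(g: GenotypeMatrix) -> AlleleFreqTable:
    """Count allele copies per population per locus over called genotypes only."""
    pops = g.populations
    idx = g.pop_indices()
    n_p, n_l = len(pops), g.n_loci
    alt = np.zeros((n_p, n_l), dtype=np.int64)
    tot = np.zeros((n_p, n_l), dtype=np.int64)
    het = np.zeros((n_p, n_l), dtype=np.int64)
    ngt = np.zeros((n_p, n_l), dtype=np.int64)
    for k, pop in enumerate(pops):
        sub = g.calls[idx[pop]]
        called = sub != MISSING
        ngt[k] = called.sum(axis=0)
        tot[k] = 2 * ngt[k]
        alt[k] = np.where(called, sub, 0).sum(axis=0)
        het[k] = (sub == 1).sum(axis=0)
    return AlleleFreqTable(pops, list(g.locus_ids), alt, tot, het, ngt)


# ---------------------------------------------------------------------------
# Heterozygosity
# ---------------------------------------------------------------------------

def observed_heterozygosity(g: GenotypeMatrix) -> pd.DataFrame:
    """H_O per (population, locus); NaN where a population has no calls."""
    f = allele_frequencies(g)
    with np.errstate(invalid="ignore", divide="ignore"):
        ho = np.where(f.called_genotypes > 0, f.het_calls / f.called_genotypes, np.nan)
    return pd.DataFrame(ho, index=f.populations, columns=f.locus_ids)


def expected_heterozygosity(f: AlleleFreqTable, *, unbiased: bool = True) -> pd.DataFrame:
    """H_E per (population, locus).

    Plain mode is 1 - sum(p^2).  Unbiased mode multiplies by 2n/(2n-1): the
    probability that two gene copies drawn *without replacement* differ,
    undefined when fewer than 2 copies were sampled.
    """
    p = f.freq_alt()
    he = 1.0 - (p ** 2 + (1.0 - p) ** 2)
    if unbiased:
        n2 = f.total_copies.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            he = np.where(n2 >= 2, n2 / (n2 - 1.0) * he, np.nan)
    return pd.DataFrame(he, index=f.populations, columns=f.locus_ids)


# ---------------------------------------------------------------------------
# Rarefied allelic richness
# ---------------------------------------------------------------------------

def _log_comb(n: np.ndarray, k: int) -> np.ndarray:
    n = np.asarray(n, dtype=float)
    with np.errstate(invalid="ignore"):
        out = gammaln(n + 1) - gammaln(np.maximum(n - k, 0) + 1) - gammaln(k + 1)
    return np.where(n >= k, out, -np.inf)


def allelic_richness(
    f: AlleleFreqTable, g_copies: int = 5
) -> tuple[pd.DataFrame, list[str]]:
    """Rarefied allelic richness per (population, locus).

    A_R = sum over alleles of [1 - C(N - N_i, g) / C(N, g)], the expected
    number of distinct alleles among g gene copies drawn without replacement
    from the N copies sampled in that population.  Loci where any population
    has fewer than g copies are skipped entirely (NaN for all populations)
    so values are comparable across populations; the skipped loci are
    returned and logged.
    """
    if g_copies < 1:
        raise ValueError("g_copies must be >= 1")
    N = f.total_copies.astype(float)
    min_copies = np.where(f.defined(), N, np.inf).min(axis=0)
    usable = min_copies >= g_copies
    skipped = [lid for lid, u in zip(f.locus_ids, usable) if not u]
    if skipped:
        log.info(
            "allelic_richness: skipped %d loci with < %d gene copies in some population",
            len(skipped), g_copies,
        )
    log_cn = _log_comb(N, g_copies)
    ar = np.zeros_like(N)
    for counts in (f.alt_copies, f.total_copies - f.alt_copies):
        with np.errstate(invalid="ignore"):
            term = 1.0 - np.exp(_log_comb(N - counts, g_copies) - log_cn)
        ar += np.where(counts > 0, term, 0.0)
    ar = np.where(usable[None, :] & f.defined(), ar, np.nan)
    return pd.DataFrame(ar, index=f.populations, columns=f.locus_ids), skipped


# ---------------------------------------------------------------------------
# Inbreeding coefficient
# ---------------------------------------------------------------------------

def inbreeding_coefficient(ho: float, he: float) -> float:
    """Single-locus F_IS = 1 - H_O/H_E; NaN when H_E is 0 or undefined."""
    if not np.isfinite(he) or he <= 0:
        return float("nan")
    return 1.0 - ho / he


def multilocus_fis(ho: pd.DataFrame, he: pd.DataFrame) -> pd.Series:
    """Per-population F_IS aggregated as 1 - sum(H_O)/sum(H_E) over defined loci."""
    out = {}
    for pop in ho.index:
        mask = he.loc[pop].notna() & ho.loc[pop].notna() & (he.loc[pop] > 0)
        se = he.loc[pop][mask].sum()
        out[pop] = 1.0 - ho.loc[pop][mask].sum() / se if se > 0 else float("nan")
    return pd.Series(out, name="F_IS")


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_probabilities(n_alt_copies: int, n_diploids: int) -> dict[int, float]:
    """P(n_het | allele counts) for every feasible heterozygote count.

    Conditional on the minor-allele copy count among 2n gene copies, the
    probability of observing n_het heterozygotes is
    multinomial(n; n_AA, n_het, n_aa) * 2^n_het / C(2n, n_alt).
    """
    n_a = min(n_alt_copies, 2 * n_diploids - n_alt_copies)  # minor copies
    probs: dict[int, float] = {}
    log_denom = _log_comb(np.array(2 * n_diploids), n_a)
    for n_het in range(n_a % 2, n_a + 1, 2):
        n_minor_hom = (n_a - n_het) // 2
        n_major_hom = n_diploids - n_het - n_minor_hom
        if n_major_hom < 0:
            continue
        log_num = (
            gammaln(n_diploids + 1)
            - gammaln(n_minor_hom + 1) - gammaln(n_het + 1) - gammaln(n_major_hom + 1)
            + n_het * np.log(2.0)
        )
        probs[n_het] = float(np.exp(log_num - log_denom))
    return probs


@dataclass
class HweResult:
    """Per-locus exact-test results for one population."""

    population: str
    locus_ids: list[str]
    p_two_sided: np.ndarray
    p_deficit: np.ndarray            # one-sided heterozygote-deficit
    homozygote_excess: np.ndarray    # True where observed het < HWE expectation
    monomorphic: np.ndarray
    alpha: float = 0.05

    @property
    def deviating_fraction(self) -> float:
        """Fraction of testable (polymorphic) loci with two-sided p < alpha."""
        testable = ~self.monomorphic & np.isfinite(self.p_two_sided)
        if not testable.any():
            return float("nan")
        return float((self.p_two_sided[testable] < self.alpha).mean())


def hwe_exact_test(g: GenotypeMatrix, alpha: float = 0.05) -> dict[str, HweResult]:
    """Exact HWE test per population per locus.

    Monomorphic loci get p = 1 by convention and are flagged; loci with
    fewer than 2 called genotypes are NaN.
    """
    f = allele_frequencies(g)
    results: dict[str, HweResult] = {}
    for k, pop in enumerate(f.populations):
        n_l = len(f.locus_ids)
        p2 = np.full(n_l, np.nan)
        pdef = np.full(n_l, np.nan)
        excess = np.zeros(n_l, dtype=bool)
        mono = np.zeros(n_l, dtype=bool)
        for j in range(n_l):
            n = int(f.called_genotypes[k, j])
            if n < 2:
                continue
            n_alt = int(f.alt_copies[k, j])
            n_het = int(f.het_calls[k, j])
            if n_alt == 0 or n_alt == 2 * n:
                mono[j] = True
                p2[j] = 1.0
                pdef[j] = 1.0
                continue
            probs = hwe_exact_probabilities(n_alt, n)
            p_obs = probs[n_het]
            p2[j] = min(1.0, sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12)))
            pdef[j] = min(1.0, sum(p for h, p in probs.items() if h <= n_het))
            # expected het count under HWE within-sample: compare to conditional mean
            mean_het = sum(h * p for h, p in probs.items())
            excess[j] = n_het < mean_het
        results[pop] = HweResult(pop, list(f.locus_ids), p2, pdef, excess, mono, alpha)
    return results


# ---------------------------------------------------------------------------
# Assembled diversity table
# ---------------------------------------------------------------------------

def diversity_table(
    g: GenotypeMatrix,
    *,
    rarefaction_copies: int = 5,
    unbiased_he: bool = True,
) -> pd.DataFrame:
    """Per-population N_A, A_R, H_O, H_E and F_IS (one row per population).

    Population values are means over loci defined in that population
    (F_IS is the ratio-of-sums aggregate).
    """
    f = allele_frequencies(g)
    ho = observed_heterozygosity(g)
    he = expected_heterozygosity(f, unbiased=unbiased_he)
    ar, _ = allelic_richness(f, rarefaction_copies)

    n_alleles = np.where(
        f.defined(),
        (f.alt_copies > 0).astype(int) + (f.alt_copies < f.total_copies).astype(int),
        np.nan,
    )
    na = pd.DataFrame(n_alleles, index=f.populations, columns=f.locus_ids)

    return pd.DataFrame(
        {
            "N_A": na.mean(axis=1, skipna=True),
            "A_R": ar.mean(axis=1, skipna=True),
            "H_O": ho.mean(axis=1, skipna=True),
            "H_E": he.mean(axis=1, skipna=True),
            "F_IS": multilocus_fis(ho, he),
        }
    )
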