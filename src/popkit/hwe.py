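"""Hardy–Weinberg equilibrium tests for di-allelic loci.

Every locus is treated as a codominant di-allelic system: with reference-allele
frequency *p* the HWE genotype proportions are (p^2, 2pq, q^2).  Two tests are
provided per locus × population:

* an asymptotic chi-square goodness-of-fit test (1 df, allele frequency
  estimated from the data), and
* a conditional exact test that enumerates all heterozygote counts compatible
  with the observed allele counts and sums the probabilities of configurations
  no more probable than the observed one (two-sided).

For the small subsamples common in reference panels the exact test is the
default for significance decisions; the chi-square is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import lgamma, log

import numpy as np
from scipy import stats

from .panel import GenotypeMatrix

__all__ = ["HweResult", "HweSummary", "hwe_chi_square", "hwe_exact", "hwe_scan"]


@dataclass(frozen=True)
class HweResult:
    pop_id: str
    locus_id: str
    n_AA: int
    n_Aa: int
    n_aa: int
    chi_sq: float
    p_chi: float
    p_exact: float


@dataclass(frozen=True)
class HweSummary:
    """Deviation counts against chance expectation over all tests run.

    ``n_significant`` counts exact-test p-values below ``alpha``;
    ``expected_significant`` is ``alpha * n_tests`` (the count expected by
    chance if every null holds); ``bonferroni_flags`` lists the
    (pop_id, locus_id) pairs significant after Bonferroni correction.
    """

    n_tests: int
    alpha: float
    n_significant: int
    expected_significant: float
    bonferroni_flags: tuple[tuple[str, str], ...]


def _check_counts(n_AA: int, n_Aa: int, n_aa: int) -> None:
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    if n_AA + n_Aa + n_aa < 1:
        raise ValueError("at least one genotype observation required")


def hwe_chi_square(n_AA: int, n_Aa: int, n_aa: int) -> tuple[float, float]:
    """Chi-square goodness-of-fit test of HWE proportions.

    Expected counts come from the observed allele frequency
    ``p_hat = (2 n_AA + n_Aa) / (2n)``; the statistic has 1 degree of freedom.
    A monomorphic sample (``p_hat`` 0 or 1) fits perfectly by construction and
    returns ``(0.0, 1.0)``.
    """
    _check_counts(n_AA, n_Aa, n_aa)
    n = n_AA + n_Aa + n_aa
    p_hat = (2 * n_AA + n_Aa) / (2 * n)
    if p_hat in (0.0, 1.0):
        return 0.0, 1.0
    q_hat = 1.0 - p_hat
    expected = np.array([n * p_hat**2, 2 * n * p_hat * q_hat, n * q_hat**2])
    observed = np.array([n_AA, n_Aa, n_aa], dtype=float)
    chi = float(np.sum((observed - expected) ** 2 / expected))
    return chi, float(stats.chi2.sf(chi, df=1))


def _log_het_prob(n: int, n_A: int, h: int) -> float:
    # log P(n_Aa = h | n diploids, n_A copies of allele A), h same parity as n_A
    a = (n_A - h) // 2
    b = (2 * n - n_A - h) // 2
    return (
        lgamma(n + 1) - lgamma(a + 1) - lgamma(h + 1) - lgamma(b + 1)
        + h * log(2)
        + lgamma(n_A + 1) + lgamma(2 * n - n_A + 1) - lgamma(2 * n + 1)
    )


def hwe_exact(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided conditional exact HWE test.

    Conditions on the observed allele counts and sums, over every possible
    heterozygote count, the probabilities of configurations whose probability
    does not exceed the observed one.  Monomorphic samples return 1.
    """
    _check_counts(n_AA, n_Aa, n_aa)
    n = n_AA + n_Aa + n_aa
    n_A = 2 * n_AA + n_Aa
    n_a = 2 * n - n_A
    if n_A == 0 or n_a == 0:
        return 1.0
    h_values = range(n_A % 2, min(n_A, n_a) + 1, 2)
    log_probs = {h: _log_het_prob(n, n_A, h) for h in h_values}
    obs = log_probs[n_Aa]
    # relative tolerance guards float ties in the probability ordering
    p = sum(np.exp(lp) for lp in log_probs.values() if lp <= obs + 1e-9)
    return float(min(p, 1.0))


def _genotype_counts(dosages: np.ndarray) -> tuple[int, int, int]:
    typed = dosages[~np.isnan(dosages)]
    return int(np.sum(typed == 2)), int(np.sum(typed == 1)), int(np.sum(typed == 0))


def hwe_scan(
    genotypes: GenotypeMatrix,
    alpha: float = 0.05,
    min_n: int = 5,
) -> tuple[list[HweResult], HweSummary]:
    """Test every locus × population combination with enough typed individuals.

    Combinations with fewer than ``min_n`` typed individuals are excluded.
    Returns per-combination results plus a :class:`HweSummary` contrasting the
    observed number of significant exact tests with the ``alpha * n_tests``
    expected by chance, and Bonferroni-adjusted flags.
    """
    by_pop: dict[str, list[int]] = {}
    for idx, (_, pop) in enumerate(genotypes.individuals):
        by_pop.setdefault(pop, []).append(idx)

    results: list[HweResult] = []
    for pop_id in sorted(by_pop):
        sub = genotypes.calls[by_pop[pop_id]]
        for j, locus_id in enumerate(genotypes.panel.locus_ids):
            n_AA, n_Aa, n_aa = _genotype_counts(sub[:, j])
            if n_AA + n_Aa + n_aa < min_n:
                continue
            chi, p_chi = hwe_chi_square(n_AA, n_Aa, n_aa)
            p_exact = hwe_exact(n_AA, n_Aa, n_aa)
            results.append(HweResult(pop_id, locus_id, n_AA, n_Aa, n_aa, chi, p_chi, p_exact))

    n_tests = len(results)
    n_sig = sum(r.p_exact < alpha for r in results)
    bonf = tuple(
        (r.pop_id, r.locus_id)
        for r in results
        if n_tests and r.p_exact < alpha / n_tests
    )
    summary = HweSummary(n_tests, alpha, n_sig, alpha * n_tests, bonf)
    return results, summary
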