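"""Random match probability (RMP) and most-common-genotype statistics.

For a population with reference-allele frequency *p* at a locus, the HWE
genotype frequencies are (p^2, 2pq, q^2).  Two panel-wide summaries follow:

* the *expected* random match probability — the probability that two
  individuals drawn from the population share a genotype at every locus,
  ``RMP = prod_l sum_g f_l(g)^2`` — a measure of the panel's average
  heterozygosity in that population;
* the *most common genotype* frequency — ``prod_l max_g f_l(g)``, the largest
  probability any single multi-locus genotype attains, an upper envelope for
  every individual match probability.

No correction is applied for within-population substructure; monomorphic loci
legitimately contribute 1 (no flooring here — flooring zero frequencies is
the ancestry-likelihood module's concern).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .panel import PopFrequencyTable

__all__ = [
    "MatchStats",
    "genotype_frequency",
    "locus_rmp",
    "population_rmp",
    "individual_rmp",
    "match_stats_table",
]


@dataclass(frozen=True)
class MatchStats:
    pop_id: str
    rmp: float
    log10_rmp: float
    mcg_freq: float
    log10_mcg: float


def _check_p(p: np.ndarray | float) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("allele frequency outside [0, 1]")
    return p


def genotype_frequency(p: np.ndarray | float, dosage: np.ndarray | float) -> np.ndarray:
    """HWE frequency of the genotype with the given reference-allele dosage:
    p^2 for dosage 2, 2pq for 1, q^2 for 0."""
    p = _check_p(p)
    dosage = np.asarray(dosage, dtype=float)
    q = 1.0 - p
    return np.choose(dosage.astype(int), [q * q, 2 * p * q, p * p])


def locus_rmp(p: np.ndarray | float) -> np.ndarray | float:
    """Single-locus expected match probability p^4 + 4 p^2 q^2 + q^4.

    Minimized at p = 0.5 (value 0.375); equals 1 at a monomorphic locus.
    """
    p = _check_p(p)
    q = 1.0 - p
    out = p**4 + 4 * p**2 * q**2 + q**4
    return float(out) if out.ndim == 0 else out


def _locus_mcg(p: np.ndarray) -> np.ndarray:
    q = 1.0 - p
    return np.max(np.stack([p * p, 2 * p * q, q * q]), axis=0)


def population_rmp(freqs: PopFrequencyTable, pop_id: str) -> MatchStats:
    """Panel-wide expected RMP and most-common-genotype frequency for one
    population, computed from its allele frequencies under HWE."""
    p = freqs.row(pop_id)
    log10_rmp = float(np.sum(np.log10(locus_rmp(p))))
    log10_mcg = float(np.sum(np.log10(_locus_mcg(p))))
    return MatchStats(pop_id, 10.0**log10_rmp, log10_rmp, 10.0**log10_mcg, log10_mcg)


def individual_rmp(
    profile: np.ndarray,
    freqs: PopFrequencyTable,
    pop_id: str,
    floor=None,
) -> float:
    """Match probability of one observed multi-locus genotype in a population:
    the product over typed loci of the HWE frequency of the individual's
    genotype.  Missing loci are skipped.  ``floor`` optionally applies the
    ancestry module's zero-frequency floor so the value agrees with the
    likelihood ranking for the same profile.
    """
    profile = np.asarray(profile, dtype=float)
    typed = ~np.isnan(profile)
    if not typed.any():
        raise ValueError("profile has no typed loci")
    p = freqs.row(pop_id)[typed]
    if floor is not None:
        from .likelihood import apply_floor

        p = apply_floor(p, freqs.population(pop_id).sample_2n, floor)
    g = genotype_frequency(p, profile[typed])
    return float(np.exp(np.sum(np.log(g))))


def match_stats_table(freqs: PopFrequencyTable):
    """Per-population match statistics for the whole table, as a DataFrame
    (the quantities shown in per-population RMP/MCG figures)."""
    import pandas as pd

    rows = [population_rmp(freqs, p) for p in freqs.pop_ids]
    return pd.DataFrame(
        {
            "pop_id": [r.pop_id for r in rows],
            "log10_rmp": [r.log10_rmp for r in rows],
            "log10_mcg": [r.log10_mcg for r in rows],
            "rmp": [r.rmp for r in rows],
            "mcg_freq": [r.mcg_freq for r in rows],
        }
    )
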