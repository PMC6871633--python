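"""Likelihood ranking of a query genotype against reference populations.

For each reference population the likelihood of a query profile is the product
over typed loci of the population-specific HWE genotype frequency (p^2, 2pq or
q^2).  Populations are ranked from highest to lowest log10 likelihood; because
reference samples are finite, a population whose likelihood is within one
order of magnitude of the best is flagged as not significantly different as a
potential origin (a second flag marks the two-order band).

Zero allele frequencies would send a likelihood to -inf, so frequencies are
floored before use.  The default floor is ``1/(2N + 2)`` — one unseen-allele
pseudo-observation given the population's sampled chromosome count — applied
symmetrically to both alleles of the pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .match import genotype_frequency
from .panel import GenotypeMatrix, PopFrequencyTable

__all__ = [
    "RankEntry",
    "LikelihoodRanking",
    "apply_floor",
    "genotype_log_likelihood",
    "rank_populations",
    "compare_top",
    "loo_frequencies",
]


@dataclass(frozen=True)
class RankEntry:
    pop_id: str
    log10_likelihood: float
    rank: int
    within_one_oom: bool
    within_two_oom: bool


@dataclass(frozen=True)
class LikelihoodRanking:
    """Populations ordered by decreasing log10 likelihood for one query.

    ``within_one_oom`` is inclusive: true iff the entry's log10 likelihood is
    at least the top value minus 1.0 (populations separated by *less than* one
    order of magnitude belong together, and the boundary joins the band);
    ``within_two_oom`` analogously at 2.0.
    """

    query_id: str
    entries: tuple[RankEntry, ...]

    @property
    def top(self) -> RankEntry:
        return self.entries[0]

    def entry(self, pop_id: str) -> RankEntry:
        for e in self.entries:
            if e.pop_id == pop_id:
                return e
        raise KeyError(pop_id)

    def to_dataframe(self, top: int | None = None) -> pd.DataFrame:
        entries = self.entries if top is None else self.entries[:top]
        return pd.DataFrame(
            {
                "rank": [e.rank for e in entries],
                "pop_id": [e.pop_id for e in entries],
                "log10_likelihood": [e.log10_likelihood for e in entries],
                "within_one_oom": [e.within_one_oom for e in entries],
                "within_two_oom": [e.within_two_oom for e in entries],
            }
        )


def apply_floor(p: np.ndarray, two_n: int, rule) -> np.ndarray:
    """Floor allele frequencies away from 0 and 1.

    ``rule`` is ``"none"`` (frequencies used as-is; zero frequencies may
    produce -inf likelihoods), ``"pseudo"`` (floor at ``1/(2N + 2)``, one
    pseudo-observation of the unseen allele), a float, or ``"fixed:<value>"``
    for a fixed floor.  The floor is applied to both alleles: frequencies are
    clipped into ``[f, 1 - f]``.
    """
    p = np.asarray(p, dtype=float)
    if rule is None or rule == "none":
        return p
    if rule == "pseudo":
        f = 1.0 / (two_n + 2)
    elif isinstance(rule, str) and rule.startswith("fixed:"):
        f = float(rule.split(":", 1)[1])
    elif isinstance(rule, (int, float)):
        f = float(rule)
    else:
        raise ValueError(f"unknown floor rule {rule!r}")
    if not 0.0 < f < 0.5:
        raise ValueError(f"floor value must be in (0, 0.5), got {f}")
    return np.clip(p, f, 1.0 - f)


def genotype_log_likelihood(
    profile: np.ndarray,
    pop_freqs_row: np.ndarray,
    two_n: int,
    floor="pseudo",
) -> float:
    """log10 likelihood of a dosage profile under one population's HWE
    genotype frequencies, summed over non-missing loci."""
    profile = np.asarray(profile, dtype=float)
    pop_freqs_row = np.asarray(pop_freqs_row, dtype=float)
    if profile.shape != pop_freqs_row.shape:
        raise ValueError(
            f"profile length {profile.shape} does not match frequency row "
            f"{pop_freqs_row.shape}"
        )
    typed = ~np.isnan(profile)
    if not typed.any():
        raise ValueError("profile has no typed loci")
    p = apply_floor(pop_freqs_row[typed], two_n, floor)
    g = genotype_frequency(p, profile[typed])
    with np.errstate(divide="ignore"):
        return float(np.sum(np.log10(g)))


def rank_populations(
    profile: np.ndarray,
    freqs: PopFrequencyTable,
    query_id: str = "query",
    floor="pseudo",
) -> LikelihoodRanking:
    """Rank every reference population by the likelihood of the query profile.

    Ties are broken by population id (presentation only).  Order-of-magnitude
    flags are relative to the rank-1 likelihood, inclusive at the band edge.
    """
    if not freqs.populations:
        raise ValueError("frequency table has no populations")
    scored = [
        (
            genotype_log_likelihood(profile, freqs.freq[i], pop.sample_2n, floor),
            pop.pop_id,
        )
        for i, pop in enumerate(freqs.populations)
    ]
    scored.sort(key=lambda t: (-t[0], t[1]))
    top = scored[0][0]
    entries = tuple(
        RankEntry(pop_id, ll, rank, ll >= top - 1.0, ll >= top - 2.0)
        for rank, (ll, pop_id) in enumerate(scored, start=1)
    )
    return LikelihoodRanking(query_id, entries)


def compare_top(ranking: LikelihoodRanking, k: int = 30) -> pd.DataFrame:
    """Report the top-k populations with likelihood ratios to rank 1.

    ``delta_log10`` is each entry's log10 likelihood minus the top one (0 for
    rank 1, negative below); the band flags mirror the ranking's.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    df = ranking.to_dataframe(top=k)
    df["delta_log10"] = df["log10_likelihood"] - ranking.top.log10_likelihood
    return df[
        ["rank", "pop_id", "log10_likelihood", "delta_log10", "within_one_oom", "within_two_oom"]
    ]


def loo_frequencies(
    freqs: PopFrequencyTable,
    genotypes: GenotypeMatrix,
    individual_id: str,
) -> PopFrequencyTable:
    """Leave-one-out copy of ``freqs``: the query individual's own population
    frequencies are recomputed from genotypes with the query removed.

    The self-inclusion bias of ranking a reference-sample member against the
    sample that contains them is tiny for realistic sample sizes, so this is
    an optional refinement, not the default.
    """
    idx = genotypes.individual_ids.index(individual_id)
    pop_id = genotypes.individuals[idx][1]
    members = [
        i for i, (_, p) in enumerate(genotypes.individuals) if p == pop_id and i != idx
    ]
    if not members:
        raise ValueError(f"population {pop_id!r} has no other members to re-estimate from")
    sub = genotypes.calls[members]
    n_typed = np.sum(~np.isnan(sub), axis=0)
    if (n_typed == 0).any():
        raise ValueError("leave-one-out leaves a locus with no typed individuals")
    new_row = np.nanmean(sub, axis=0) / 2.0
    freq = freqs.freq.copy()
    freq[freqs.pop_index(pop_id)] = new_row
    return PopFrequencyTable(freqs.panel, list(freqs.populations), freq)
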