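"""Data model and delimited-text I/O for ancestry-informative SNP panels.

The central objects are:

* :class:`AisnpPanel` — an ordered list of di-allelic loci with their
  reference/alternate alleles on the positive strand;
* :class:`PopFrequencyTable` — a population × locus matrix of
  reference-allele frequencies with per-population chromosome counts (2N);
* :class:`GenotypeMatrix` — individuals × loci reference-allele dosages
  (0/1/2, missing allowed).

All file formats are tab-separated UTF-8 text with ``.`` for missing values.
Because every locus is di-allelic, a single frequency column per locus (the
reference allele; alternate = 1 − ref) is sufficient and unambiguous.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Locus",
    "AisnpPanel",
    "Population",
    "PopFrequencyTable",
    "GenotypeMatrix",
    "ParseError",
    "StrandError",
    "read_panel",
    "write_panel",
    "default_panel",
    "read_frequency_table",
    "write_frequency_table",
    "read_genotypes",
    "write_genotypes",
    "normalize_strand",
    "frequencies_from_genotypes",
]

MISSING = "."
_BASES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class ParseError(ValueError):
    """A structured parse/validation error naming the offending row/column."""


class StrandError(ValueError):
    """Raised when an allele call cannot be reconciled with a locus' alleles."""


@dataclass(frozen=True)
class Locus:
    """One di-allelic SNP locus: identifier plus positive-strand alleles."""

    locus_id: str
    allele_ref: str
    allele_alt: str

    def __post_init__(self) -> None:
        if self.allele_ref not in _BASES or self.allele_alt not in _BASES:
            raise ValueError(
                f"locus {self.locus_id!r}: alleles must be in A/C/G/T, "
                f"got {self.allele_ref!r}/{self.allele_alt!r}"
            )
        if self.allele_ref == self.allele_alt:
            raise ValueError(f"locus {self.locus_id!r}: ref and alt alleles are equal")

    @property
    def strand_ambiguous(self) -> bool:
        """True for A/T and C/G loci, where the strand of a raw call cannot be
        inferred from the bases alone (the allele pair is its own reverse
        complement)."""
        return _COMPLEMENT[self.allele_ref] == self.allele_alt


@dataclass(frozen=True)
class AisnpPanel:
    """Ordered panel of di-allelic SNP loci.

    Locus identifiers must be unique; order is meaningful (frequency and
    genotype matrices are column-aligned to it).
    """

    loci: tuple[Locus, ...]

    def __post_init__(self) -> None:
        ids = [l.locus_id for l in self.loci]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate locus ids in panel: {dup}")

    def __len__(self) -> int:
        return len(self.loci)

    def __iter__(self):
        return iter(self.loci)

    @property
    def locus_ids(self) -> list[str]:
        return [l.locus_id for l in self.loci]

    def index_of(self, locus_id: str) -> int:
        try:
            return self.locus_ids.index(locus_id)
        except ValueError:
            raise KeyError(f"locus {locus_id!r} not in panel") from None


@dataclass(frozen=True)
class Population:
    """Reference population: full identifier, 3-character abbreviation, and
    sampled chromosome count 2N."""

    pop_id: str
    abbrev: str
    sample_2n: int

    def __post_init__(self) -> None:
        if self.sample_2n < 2:
            raise ValueError(
                f"population {self.pop_id!r}: sample_2n must be >= 2, got {self.sample_2n}"
            )


@dataclass
class PopFrequencyTable:
    """Population × locus matrix of reference-allele frequencies."""

    panel: AisnpPanel
    populations: list[Population]
    freq: np.ndarray  # shape (n_populations, n_loci), values in [0, 1]

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        if self.freq.shape != (len(self.populations), len(self.panel)):
            raise ValueError(
                f"frequency matrix shape {self.freq.shape} does not match "
                f"{len(self.populations)} populations x {len(self.panel)} loci"
            )
        if self.freq.size and (np.nanmin(self.freq) < 0 or np.nanmax(self.freq) > 1):
            bad = np.argwhere((self.freq < 0) | (self.freq > 1))[0]
            raise ParseError(
                f"frequency out of [0,1] for population "
                f"{self.populations[bad[0]].pop_id!r}, locus "
                f"{self.panel.locus_ids[bad[1]]!r}: {self.freq[tuple(bad)]}"
            )
        ids = [p.pop_id for p in self.populations]
        if len(set(ids)) != len(ids):
            raise ParseError("duplicate pop_id in frequency table")
        abbrevs = [p.abbrev for p in self.populations]
        if len(set(abbrevs)) != len(abbrevs):
            raise ParseError("duplicate population abbreviation in frequency table")

    @property
    def pop_ids(self) -> list[str]:
        return [p.pop_id for p in self.populations]

    def pop_index(self, pop_id: str) -> int:
        try:
            return self.pop_ids.index(pop_id)
        except ValueError:
            raise KeyError(f"population {pop_id!r} not in table") from None

    def row(self, pop_id: str) -> np.ndarray:
        """Reference-allele frequency row for one population."""
        return self.freq[self.pop_index(pop_id)]

    def population(self, pop_id: str) -> Population:
        return self.populations[self.pop_index(pop_id)]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.freq, index=self.pop_ids, columns=self.panel.locus_ids)


@dataclass
class GenotypeMatrix:
    """Individuals × loci reference-allele dosages.

    ``calls`` is a float matrix with values in {0, 1, 2} and NaN for missing.
    """

    panel: AisnpPanel
    individuals: list[tuple[str, str]]  # (individual_id, pop_id)
    calls: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=float)
        if self.calls.shape != (len(self.individuals), len(self.panel)):
            raise ValueError(
                f"call matrix shape {self.calls.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.panel)} loci"
            )
        ok = np.isnan(self.calls) | np.isin(self.calls, (0.0, 1.0, 2.0))
        if not ok.all():
            bad = np.argwhere(~ok)[0]
            raise ParseError(
                f"genotype call for individual {self.individuals[bad[0]][0]!r}, "
                f"locus {self.panel.locus_ids[bad[1]]!r} is not in {{0,1,2,missing}}: "
                f"{self.calls[tuple(bad)]}"
            )

    @property
    def individual_ids(self) -> list[str]:
        return [i for i, _ in self.individuals]

    @property
    def pop_of(self) -> dict[str, str]:
        return dict(self.individuals)

    def profile(self, individual_id: str) -> np.ndarray:
        idx = self.individual_ids.index(individual_id)
        return self.calls[idx]


# ---------------------------------------------------------------------------
# Panel files


def read_panel(path) -> AisnpPanel:
    """Read a panel definition TSV with columns locus_id, ref, alt."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"locus_id", "ref", "alt"}
    if not required.issubset(df.columns):
        raise ParseError(f"panel file must have columns {sorted(required)}, got {list(df.columns)}")
    loci = tuple(Locus(r.locus_id, r.ref, r.alt) for r in df.itertuples())
    return AisnpPanel(loci)


def write_panel(panel: AisnpPanel, path) -> None:
    pd.DataFrame(
        {"locus_id": panel.locus_ids,
         "ref": [l.allele_ref for l in panel],
         "alt": [l.allele_alt for l in panel]}
    ).to_csv(path, sep="\t", index=False)


def default_panel(n_loci: int = 55, seed: int = 55) -> AisnpPanel:
    """Deterministic synthetic 55-locus panel.

    This is a *synthetic* stand-in for a real ancestry-informative SNP panel:
    the locus identifiers (``snp01`` … ``snp55``) and ref/alt allele
    assignments are generated, not taken from any published assay, because
    per-locus allele/strand metadata for the real panel is not bundled with
    this package.  Strand-unambiguous allele pairs are used throughout so the
    default panel exercises no ambiguity handling.
    """
    rng = np.random.default_rng(seed)
    # unambiguous ordered pairs only (exclude A/T and C/G)
    pairs = [(a, b) for a in "ACGT" for b in "ACGT"
             if a != b and _COMPLEMENT[a] != b]
    width = len(str(n_loci))
    loci = []
    for i in range(n_loci):
        ref, alt = pairs[rng.integers(len(pairs))]
        loci.append(Locus(f"snp{i + 1:0{width}d}", ref, alt))
    return AisnpPanel(tuple(loci))


# ---------------------------------------------------------------------------
# Frequency tables


def read_frequency_table(path, panel: AisnpPanel) -> PopFrequencyTable:
    """Read a population frequency TSV and align its locus columns to ``panel``.

    Layout: header ``pop_id  abbrev  two_n  <locus_id> ...``; one row per
    population; frequencies are the reference-allele frequency in [0, 1].
    Columns may appear in any order; every panel locus must be present.
    """
    df = pd.read_csv(path, sep="\t", dtype={"pop_id": str, "abbrev": str})
    for col in ("pop_id", "abbrev", "two_n"):
        if col not in df.columns:
            raise ParseError(f"frequency table missing required column {col!r}")
    present = set(df.columns) - {"pop_id", "abbrev", "two_n"}
    missing = [l for l in panel.locus_ids if l not in present]
    if missing:
        raise ParseError(f"frequency table missing panel loci: {missing}")
    unknown = sorted(present - set(panel.locus_ids))
    if unknown:
        raise ParseError(f"frequency table has loci not in panel: {unknown}")

    populations = []
    for row in df.itertuples():
        populations.append(Population(str(row.pop_id), str(row.abbrev), int(row.two_n)))
    freq = df[panel.locus_ids].to_numpy(dtype=float)
    # locate the first offending cell for a friendly message
    bad = np.argwhere((freq < 0) | (freq > 1) | np.isnan(freq))
    if bad.size:
        i, j = bad[0]
        raise ParseError(
            f"frequency out of [0,1] for population {populations[i].pop_id!r}, "
            f"locus {panel.locus_ids[j]!r}: {df[panel.locus_ids].iat[i, j]}"
        )
    return PopFrequencyTable(panel, populations, freq)


def write_frequency_table(table: PopFrequencyTable, path, decimals: int = 6) -> None:
    """Write a frequency table TSV; round trips with :func:`read_frequency_table`
    to within ``0.5 * 10**-decimals``."""
    df = pd.DataFrame(
        {"pop_id": table.pop_ids,
         "abbrev": [p.abbrev for p in table.populations],
         "two_n": [p.sample_2n for p in table.populations]}
    )
    freq = pd.DataFrame(np.round(table.freq, decimals), columns=table.panel.locus_ids)
    pd.concat([df, freq], axis=1).to_csv(path, sep="\t", index=False, na_rep=MISSING)


# ---------------------------------------------------------------------------
# Genotypes and strand normalization


def _looks_like_dosage(values: pd.DataFrame) -> bool:
    flat = values.to_numpy().ravel()
    for v in flat:
        s = str(v).strip()
        if s in (MISSING, "", "nan"):
            continue
        try:
            f = float(s)
        except ValueError:
            return False
        if f not in (0.0, 1.0, 2.0):
            return False
    return True


def _parse_call(raw: str) -> tuple[str, str] | None:
    s = str(raw).strip().upper()
    if s in (MISSING, "", "NAN", "N/N"):
        return None
    if "/" in s:
        a, b = s.split("/", 1)
    elif len(s) == 2:
        a, b = s[0], s[1]
    else:
        raise StrandError(f"cannot parse genotype call {raw!r}")
    if a not in _BASES or b not in _BASES:
        raise StrandError(f"genotype call {raw!r} contains a non-ACGT base")
    return a, b


def normalize_strand(
    calls: pd.DataFrame,
    panel: AisnpPanel,
    individuals: list[tuple[str, str]] | None = None,
    ambiguous_strand: str = "reject",
) -> GenotypeMatrix:
    """Map raw base-pair calls (possibly reverse-strand) to reference dosages.

    ``calls`` is an individuals × loci DataFrame of strings like ``"A/G"``
    (columns = panel locus ids, any order).  For each call the base pair must
    match either the locus' (ref, alt) alleles or their reverse complements;
    reverse-complement calls are flipped to the positive strand before dosage
    coding.  Anything else raises :class:`StrandError`.

    A/T and C/G loci are their own reverse complement, so the strand of a raw
    call cannot be inferred; ``ambiguous_strand`` controls them:
    ``"reject"`` (default) raises, ``"trust"`` takes calls as already on the
    positive strand.

    Already-normalized dosage input (values in {0,1,2,missing}) is passed
    through unchanged, making the operation idempotent.
    """
    if ambiguous_strand not in ("reject", "trust"):
        raise ValueError("ambiguous_strand must be 'reject' or 'trust'")
    missing_cols = [l for l in panel.locus_ids if l not in calls.columns]
    if missing_cols:
        raise ParseError(f"genotype calls missing panel loci: {missing_cols}")
    calls = calls[panel.locus_ids]
    if individuals is None:
        individuals = [(str(i), "") for i in calls.index]

    if _looks_like_dosage(calls):
        mat = calls.replace(MISSING, np.nan).to_numpy(dtype=float)
        return GenotypeMatrix(panel, individuals, mat)

    ambiguous = [l.locus_id for l in panel if l.strand_ambiguous]
    if ambiguous and ambiguous_strand == "reject":
        raise StrandError(
            f"strand-ambiguous loci (A/T or C/G) present with ambiguous_strand='reject': "
            f"{ambiguous}; supply strand-resolved calls or set ambiguous_strand='trust'"
        )

    mat = np.full(calls.shape, np.nan)
    for j, locus in enumerate(panel):
        direct = {locus.allele_ref, locus.allele_alt}
        flipped = {_COMPLEMENT[locus.allele_ref], _COMPLEMENT[locus.allele_alt]}
        for i, raw in enumerate(calls.iloc[:, j]):
            pair = _parse_call(raw)
            if pair is None:
                continue
            a, b = pair
            if a in direct and b in direct:
                bases = (a, b)
            elif a in flipped and b in flipped:
                bases = (_COMPLEMENT[a], _COMPLEMENT[b])
            else:
                raise StrandError(
                    f"call {raw!r} at locus {locus.locus_id!r} "
                    f"(ref={locus.allele_ref}, alt={locus.allele_alt}) matches neither "
                    f"strand (individual {individuals[i][0]!r})"
                )
            mat[i, j] = sum(base == locus.allele_ref for base in bases)
    return GenotypeMatrix(panel, individuals, mat)


def read_genotypes(path, panel: AisnpPanel, ambiguous_strand: str = "reject") -> GenotypeMatrix:
    """Read a genotype TSV: ``individual_id  pop_id  <locus_id> ...``.

    Locus columns may hold base-pair calls (``A/G``) or dosages (0/1/2);
    the encoding is auto-detected and base calls are strand-normalized.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("individual_id", "pop_id"):
        if col not in df.columns:
            raise ParseError(f"genotype file missing required column {col!r}")
    individuals = [(str(r.individual_id), str(r.pop_id)) for r in df.itertuples()]
    calls = df.drop(columns=["individual_id", "pop_id"])
    return normalize_strand(calls, panel, individuals, ambiguous_strand=ambiguous_strand)


def write_genotypes(genotypes: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(genotypes.calls, columns=genotypes.panel.locus_ids)
    df = df.map(lambda v: MISSING if np.isnan(v) else str(int(v)))
    df.insert(0, "pop_id", [p for _, p in genotypes.individuals])
    df.insert(0, "individual_id", genotypes.individual_ids)
    df.to_csv(path, sep="\t", index=False)


def frequencies_from_genotypes(genotypes: GenotypeMatrix) -> PopFrequencyTable:
    """Estimate per-population reference-allele frequencies as mean dosage / 2.

    Loci with no typed individuals in a population get frequency NaN is not
    allowed in a table, so such loci raise; sample_2n is twice the population's
    individual count.
    """
    pops: dict[str, list[int]] = {}
    for idx, (_, pop) in enumerate(genotypes.individuals):
        pops.setdefault(pop, []).append(idx)
    populations, rows = [], []
    used = set()
    for pop_id, idxs in pops.items():
        sub = genotypes.calls[idxs]
        n_typed = np.sum(~np.isnan(sub), axis=0)
        if (n_typed == 0).any():
            j = int(np.argwhere(n_typed == 0)[0][0])
            raise ValueError(
                f"population {pop_id!r} has no typed individuals at locus "
                f"{genotypes.panel.locus_ids[j]!r}"
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            rows.append(np.nanmean(sub, axis=0) / 2.0)
        abbrev = _unique_abbrev(pop_id, used)
        populations.append(Population(pop_id, abbrev, 2 * len(idxs)))
    return PopFrequencyTable(genotypes.panel, populations, np.array(rows))


def _unique_abbrev(pop_id: str, used: set[str]) -> str:
    base = (pop_id.upper().replace(" ", "") + "XXX")[:3]
    cand, k = base, 0
    while cand in used:
        k += 1
        cand = (base[:2] + str(k))[:3]
    used.add(cand)
    return cand
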