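"""Synthetic reference panels with known truth.

The generator emulates the stated world of an ancestry panel study: di-allelic
SNP allele frequencies in P populations descended by pure genetic drift from
shared ancestral frequencies along a known tree, optionally perturbed by gene
flow, plus Hardy–Weinberg genotype sampling at stated sample sizes.

Drift along a branch with drift parameter tau moves a frequency p to a draw
from a Beta distribution with mean p and variance ``tau * p * (1 - p)``
(the Balding–Nichols parameterization), which keeps frequencies inside (0, 1)
without ad-hoc truncation.  Under this model the expected drift-normalized
squared frequency difference between two leaves approximates the sum of tau
along the connecting path for small tau — the additivity the tau distance and
the least-squares tree fit rely on.

Gene flow is modeled minimally as one-shot mixing of each leaf toward the
global mean frequency, ``p <- (1 - m) p + m p_bar``.  A single shared rate m
rescales every population's deviation from the mean by the same factor, so it
shrinks all pairwise distances while (approximately) preserving additivity.
To emulate the gene-flow signature that breaks the tree model — populations
more similar than any tree allows, surfacing as negative fitted segments —
supply *per-population* rates (``gene_flow_m`` as a dict): unequal admixture
is what distorts the distance geometry rather than merely rescaling it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .panel import (
    AisnpPanel,
    GenotypeMatrix,
    PopFrequencyTable,
    Population,
    default_panel,
)
from .tree import DistanceMatrix

__all__ = [
    "DriftNode",
    "DriftTree",
    "SynthConfig",
    "SynthTruth",
    "drift_tree_from_newick",
    "simulate_frequencies",
    "sample_genotypes",
]


@dataclass
class DriftNode:
    """Node of a rooted drift tree; ``tau`` is the drift on the branch above
    (ignored at the root)."""

    name: str | None
    tau: float
    children: list["DriftNode"] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.tau < 0:
            raise ValueError(f"negative drift tau {self.tau} on branch above {self.name!r}")

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class DriftTree:
    """Rooted tree over populations with per-branch drift (tau, in drift units)."""

    root: DriftNode

    def __post_init__(self) -> None:
        names = self.leaf_names
        if len(set(names)) != len(names):
            raise ValueError("leaf names must be unique")
        if len(names) < 2:
            raise ValueError("drift tree needs at least 2 leaves")

    @property
    def leaf_names(self) -> list[str]:
        out: list[str] = []

        def walk(n: DriftNode) -> None:
            if n.is_leaf:
                if n.name is None:
                    raise ValueError("every leaf must be named")
                out.append(n.name)
            for c in n.children:
                walk(c)

        walk(self.root)
        return out

    def path_tau(self) -> DistanceMatrix:
        """True pairwise drift distances: sum of branch tau on the path
        between each pair of leaves (the quantity tau distances estimate)."""
        names = sorted(self.leaf_names)
        n = len(names)
        d = np.zeros((n, n))
        for a, b in combinations(range(n), 2):
            d[a, b] = d[b, a] = _path_distance(self.root, names[a], names[b])
        return DistanceMatrix(names, d)

    def nontrivial_splits(self) -> frozenset:
        """Unrooted non-trivial splits of the topology, canonicalized to the
        side not containing the alphabetically first leaf (for Robinson–Foulds
        scoring of topology recovery)."""
        all_names = frozenset(self.leaf_names)
        ref = min(all_names)
        splits = set()

        def clade(n: DriftNode) -> frozenset:
            if n.is_leaf:
                return frozenset([n.name])
            s = frozenset().union(*(clade(c) for c in n.children))
            canon = all_names - s if ref in s else s
            if 1 < len(canon) < len(all_names) - 1:
                splits.add(canon)
            return s

        clade(self.root)
        return frozenset(splits)


def _path_distance(root: DriftNode, a: str, b: str) -> float:
    """Sum of tau on the path between leaves a and b."""

    def down(n: DriftNode, target: str) -> float | None:
        # tau-sum from n (exclusive of n's own branch) down to target leaf
        if n.is_leaf:
            return 0.0 if n.name == target else None
        for c in n.children:
            sub = down(c, target)
            if sub is not None:
                return sub + c.tau
        return None

    def lca(n: DriftNode) -> DriftNode | None:
        has_a, has_b = down(n, a) is not None, down(n, b) is not None
        if not (has_a and has_b):
            return None
        for c in n.children:
            deeper = lca(c)
            if deeper is not None:
                return deeper
        return n

    anc = lca(root)
    return down(anc, a) + down(anc, b)


def drift_tree_from_newick(text: str) -> DriftTree:
    """Read a rooted newick string whose branch lengths are drift tau values."""
    import dendropy

    dt = dendropy.Tree.get(data=text, schema="newick")

    def convert(nd) -> DriftNode:
        name = nd.taxon.label if nd.taxon is not None else None
        node = DriftNode(name, float(nd.edge.length or 0.0))
        node.children = [convert(c) for c in nd.child_nodes()]
        return node

    return DriftTree(convert(dt.seed_node))


@dataclass
class SynthConfig:
    """Stated world of the simulation.

    Defaults: 55 unlinked loci (the panel size the pipeline is built around);
    ancestral frequencies uniform on [0.1, 0.9] (ancestry-informative panels
    are ascertained for common, informative variants, so extreme ancestral
    frequencies are excluded); 2N = 200 chromosomes per population (a typical
    reference-sample size, ~100 individuals); no gene flow.
    """

    n_loci: int = 55
    f_min: float = 0.1
    f_max: float = 0.9
    sample_2n: int | dict[str, int] = 200
    gene_flow_m: float | dict[str, float] = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.f_min < self.f_max < 1.0):
            raise ValueError("need 0 < f_min < f_max < 1")
        rates = (
            self.gene_flow_m.values()
            if isinstance(self.gene_flow_m, dict)
            else [self.gene_flow_m]
        )
        if any(not 0.0 <= m <= 1.0 for m in rates):
            raise ValueError("gene_flow_m must be in [0, 1]")


@dataclass
class SynthTruth:
    """Ground truth accompanying a simulated table: the drift tree, the true
    pairwise path-tau distances, and the ancestral frequencies."""

    tree: DriftTree
    path_tau: DistanceMatrix
    ancestral_freq: np.ndarray


def _drift(rng: np.random.Generator, p: np.ndarray, tau: float) -> np.ndarray:
    if tau == 0.0:
        return p.copy()
    scale = (1.0 - tau) / tau
    out = rng.beta(np.maximum(p * scale, 1e-12), np.maximum((1.0 - p) * scale, 1e-12))
    return np.clip(out, 1e-12, 1.0 - 1e-12)  # numeric edge guard only


def simulate_frequencies(
    tree: DriftTree, config: SynthConfig
) -> tuple[PopFrequencyTable, SynthTruth]:
    """Simulate a reference frequency table by pure drift along ``tree``.

    Ancestral frequencies are drawn per locus, every branch applies a
    Balding–Nichols Beta step with its tau, and leaves optionally mix toward
    the global mean at rate ``gene_flow_m``.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    p0 = rng.uniform(config.f_min, config.f_max, size=config.n_loci)

    leaf_freq: dict[str, np.ndarray] = {}

    def walk(node: DriftNode, p: np.ndarray) -> None:
        p_here = _drift(rng, p, node.tau)
        if node.is_leaf:
            leaf_freq[node.name] = p_here
        for c in node.children:
            walk(c, p_here)

    for c in tree.root.children:
        walk(c, p0)

    names = sorted(leaf_freq)
    freq = np.array([leaf_freq[n] for n in names])
    if isinstance(config.gene_flow_m, dict):
        m = np.array([config.gene_flow_m.get(n, 0.0) for n in names])[:, None]
    else:
        m = config.gene_flow_m
    if np.any(np.asarray(m) > 0):
        freq = (1 - m) * freq + m * freq.mean(axis=0)

    panel = default_panel(config.n_loci)
    pops = []
    used: set[str] = set()
    for name in names:
        two_n = (
            config.sample_2n[name]
            if isinstance(config.sample_2n, dict)
            else config.sample_2n
        )
        abbrev = _abbrev(name, used)
        pops.append(Population(name, abbrev, two_n))
    table = PopFrequencyTable(panel, pops, freq)
    return table, SynthTruth(tree, tree.path_tau(), p0)


def _abbrev(name: str, used: set[str]) -> str:
    base = (name.upper().replace(" ", "") + "XXX")[:3]
    cand, k = base, 0
    while cand in used:
        k += 1
        cand = (base[:2] + str(k))[:3]
    used.add(cand)
    return cand


def sample_genotypes(
    freqs: PopFrequencyTable, n_individuals: int | dict[str, int], seed: int = 0
) -> GenotypeMatrix:
    """Sample HWE genotypes: each individual's reference-allele dosage at each
    locus is Binomial(2, p) with that population's frequency, loci independent
    (the panel's loci are unlinked).  Deterministic for a fixed seed."""
    rng = np.random.default_rng(seed)
    individuals: list[tuple[str, str]] = []
    rows: list[np.ndarray] = []
    for i, pop in enumerate(freqs.populations):
        n = n_individuals[pop.pop_id] if isinstance(n_individuals, dict) else n_individuals
        if n < 1:
            raise ValueError(f"need at least 1 individual per population, got {n}")
        draws = rng.binomial(2, freqs.freq[i], size=(n, len(freqs.panel)))
        for k in range(n):
            individuals.append((f"{pop.abbrev}_{k + 1:03d}", pop.pop_id))
            rows.append(draws[k].astype(float))
    return GenotypeMatrix(freqs.panel, individuals, np.array(rows))
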