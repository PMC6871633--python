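"""Shared fixtures and independent oracles.

The oracles here are deliberately implemented without using popkit's own
tree/HWE machinery, so tests compare two independent routes to the same
quantity:

* ``random_additive_matrix`` builds a random binary tree as nested tuples and
  computes leaf-to-leaf distances by explicit path summation — the ground
  truth for NJ recovery and least-squares fitting;
* ``hwe_exact_enumeration`` computes the exact conditional HWE p-value by
  direct enumeration of all genotype configurations with the observed allele
  counts, using raw integer combinatorics.
"""

from __future__ import annotations

from math import comb

import numpy as np
import pytest

from popkit import (
    AisnpPanel,
    Locus,
    PopFrequencyTable,
    Population,
)


# ---------------------------------------------------------------------------
# Small fixed objects


@pytest.fixture
def toy_panel() -> AisnpPanel:
    return AisnpPanel(
        (
            Locus("snpA", "A", "G"),
            Locus("snpB", "C", "T"),
            Locus("snpC", "G", "A"),
        )
    )


@pytest.fixture
def toy_table(toy_panel) -> PopFrequencyTable:
    pops = [
        Population("PopOne", "ON1", 100),
        Population("PopTwo", "TW2", 80),
    ]
    freq = np.array([[0.5, 0.5, 0.2], [0.1, 0.9, 0.6]])
    return PopFrequencyTable(toy_panel, pops, freq)


# ---------------------------------------------------------------------------
# Additive-matrix oracle (independent of popkit.tree)


def random_additive_matrix(
    leaf_names: list[str],
    rng: np.random.Generator,
    min_len: float = 0.3,
    max_len: float = 2.0,
):
    """Random binary tree with positive branch lengths; returns the
    path-sum distance matrix, the set of canonical non-trivial splits, and
    the set of true branch lengths of the unrooted tree (root child branches
    merged)."""
    names = sorted(leaf_names)
    all_names = frozenset(names)
    ref = min(names)

    def build(leaves: list[str]):
        if len(leaves) == 1:
            return ("leaf", leaves[0])
        k = int(rng.integers(1, len(leaves)))
        order = [leaves[i] for i in rng.permutation(len(leaves))]
        return ("node", build(sorted(order[:k])), build(sorted(order[k:])))

    root = build(names)
    n = len(names)
    index = {nm: i for i, nm in enumerate(names)}
    D = np.zeros((n, n))
    splits: set[frozenset] = set()
    branch_lengths: list[float] = []

    def canonical(clade: frozenset) -> frozenset:
        return all_names - clade if ref in clade else clade

    def walk(node, is_root_child_pair=False):
        """Return dict leaf -> distance from this node."""
        if node[0] == "leaf":
            return {node[1]: 0.0}
        parts = []
        for child in node[1:]:
            d = walk(child)
            ln = float(rng.uniform(min_len, max_len))
            branch_lengths.append(ln)
            clade = canonical(frozenset(d))
            if 1 < len(clade) < n - 1:
                splits.add(clade)
            parts.append({leaf: dist + ln for leaf, dist in d.items()})
        for a in parts[0]:
            for b in parts[1]:
                i, j = index[a], index[b]
                D[i, j] = D[j, i] = parts[0][a] + parts[1][b]
        return {**parts[0], **parts[1]}

    walk(root)
    return names, D, frozenset(splits)


@pytest.fixture
def additive_oracle():
    return random_additive_matrix


# ---------------------------------------------------------------------------
# HWE exact-test enumeration oracle (independent of popkit.hwe)


def hwe_exact_enumeration(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional HWE p by full enumeration with integer weights.

    Given n diploids and n_A copies of allele A, the conditional probability
    of h heterozygotes is proportional to the number of distinct ways to
    arrange the alleles: multinomial(n; a, h, b) * 2**h.  The two-sided p
    sums probabilities of all h whose probability is <= the observed one.
    """
    n = n_AA + n_Aa + n_aa
    n_A = 2 * n_AA + n_Aa
    n_a = 2 * n - n_A
    if n_A == 0 or n_a == 0:
        return 1.0
    weights = {}
    for h in range(n_A % 2, min(n_A, n_a) + 1, 2):
        a, b = (n_A - h) // 2, (n_a - h) // 2
        weights[h] = comb(n, a) * comb(n - a, h) * (2**h)
    total = sum(weights.values())
    obs = weights[n_Aa]
    return sum(w for w in weights.values() if w <= obs) / total


@pytest.fixture
def hwe_oracle():
    return hwe_exact_enumeration
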