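"""Drift-scale distances and additive population trees.

Pipeline: pairwise *tau* distances (drift-normalized squared frequency
differences, theoretically additive in units of random drift when populations
diverge by pure drift along a tree) → a Neighbor-Joining starting tree →
exact ordinary-least-squares branch lengths on any topology → a
nearest-neighbor-interchange hill-climb searching for an all-positive,
minimum-total-length solution.

Branch lengths fitted by unconstrained least squares may come out negative.
Negative drift cannot exist, so negative segments are a diagnostic, not a
nuisance: they indicate the additive pure-drift model is violated (e.g. by
gene flow), and this module counts and reports them rather than clipping
them.  A non-negative least-squares mode is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Iterator

import numpy as np

from .panel import PopFrequencyTable

__all__ = [
    "DistanceMatrix",
    "PopTree",
    "FitDiagnostics",
    "TreeSearchResult",
    "UnrootedTree",
    "tau_distance",
    "tau_matrix",
    "neighbor_joining",
    "ls_fit",
    "evaluate_lengths",
    "nni_neighbors",
    "search_topologies",
    "enumerate_topologies",
    "tree_report",
    "tree_to_newick",
    "tree_from_newick",
    "robinson_foulds",
]

_NEG_TOL = 1e-9  # lengths above -_NEG_TOL are treated as zero, not negative


# ---------------------------------------------------------------------------
# Distances


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix over named populations."""

    pop_ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.pop_ids)
        if self.d.shape != (n, n):
            raise ValueError(f"distance matrix shape {self.d.shape} != ({n}, {n})")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("distance matrix diagonal is not zero")
        if (self.d < -1e-12).any():
            raise ValueError("distance matrix has negative entries")

    def __getitem__(self, pair) -> float:
        i, j = pair
        if isinstance(i, str):
            i = self.pop_ids.index(i)
        if isinstance(j, str):
            j = self.pop_ids.index(j)
        return float(self.d[i, j])


def tau_distance(freqs: PopFrequencyTable, i: str, j: str) -> float:
    """Pairwise drift-scale distance between two populations.

    Mean over loci of ``(p_i - p_j)^2 / (p_bar (1 - p_bar))`` with
    ``p_bar = (p_i + p_j) / 2``.  Loci monomorphic in *both* populations
    (``p_bar`` 0 or 1) carry no drift information and are skipped; loci
    monomorphic in only one population are included.
    """
    pi, pj = freqs.row(i), freqs.row(j)
    pbar = (pi + pj) / 2.0
    denom = pbar * (1.0 - pbar)
    keep = denom > 0.0
    if not keep.any():
        raise ValueError(f"all loci monomorphic in both {i!r} and {j!r}; tau undefined")
    return float(np.mean((pi[keep] - pj[keep]) ** 2 / denom[keep]))


def tau_matrix(freqs: PopFrequencyTable, distance=tau_distance) -> DistanceMatrix:
    """All-pairs distance matrix; ``distance`` is pluggable (defaults to tau)."""
    ids = freqs.pop_ids
    n = len(ids)
    d = np.zeros((n, n))
    for a, b in combinations(range(n), 2):
        d[a, b] = d[b, a] = distance(freqs, ids[a], ids[b])
    return DistanceMatrix(ids, d)


# ---------------------------------------------------------------------------
# Unrooted trees

Edge = frozenset  # frozenset({u, v}) of node ids


class UnrootedTree:
    """Unrooted tree with named leaves; internal nodes unconstrained in id.

    A minimal adjacency structure supporting the operations the tree pipeline
    needs: split extraction (for least-squares design matrices and topology
    identity), NNI rearrangement, and newick serialization.
    """

    def __init__(self) -> None:
        self._adj: dict[int, set[int]] = {}
        self._leaf_name: dict[int, str] = {}
        self._next_id = 0

    # -- construction -------------------------------------------------------

    def add_node(self, leaf_name: str | None = None) -> int:
        nid = self._next_id
        self._next_id += 1
        self._adj[nid] = set()
        if leaf_name is not None:
            self._leaf_name[nid] = leaf_name
        return nid

    def add_edge(self, u: int, v: int) -> None:
        self._adj[u].add(v)
        self._adj[v].add(u)

    def remove_edge(self, u: int, v: int) -> None:
        self._adj[u].discard(v)
        self._adj[v].discard(u)

    def copy(self) -> "UnrootedTree":
        t = UnrootedTree()
        t._adj = {u: set(vs) for u, vs in self._adj.items()}
        t._leaf_name = dict(self._leaf_name)
        t._next_id = self._next_id
        return t

    # -- queries ------------------------------------------------------------

    @property
    def nodes(self) -> list[int]:
        return sorted(self._adj)

    @property
    def leaf_nodes(self) -> list[int]:
        return sorted(self._leaf_name)

    @property
    def leaf_names(self) -> list[str]:
        return sorted(self._leaf_name.values())

    def name_of(self, node: int) -> str | None:
        return self._leaf_name.get(node)

    def is_leaf(self, node: int) -> bool:
        return node in self._leaf_name

    def neighbors(self, node: int) -> set[int]:
        return self._adj[node]

    def edges(self) -> list[Edge]:
        es = {frozenset((u, v)) for u, vs in self._adj.items() for v in vs}
        return sorted(es, key=lambda e: self._split_signature(e))

    def side_leaves(self, edge: Edge, toward: int) -> frozenset[str]:
        """Leaf names in the component containing ``toward`` after cutting
        ``edge``."""
        u, v = tuple(edge)
        if toward == v:
            u, v = v, u
        seen, stack, names = {v}, [u], set()
        seen.add(u)
        while stack:
            x = stack.pop()
            if self.is_leaf(x):
                names.add(self._leaf_name[x])
            for y in self._adj[x] - seen:
                seen.add(y)
                stack.append(y)
        return frozenset(names)

    def canonical_split(self, edge: Edge) -> frozenset[str]:
        """The side of the bipartition NOT containing the alphabetically first
        leaf (a rooting-free canonical form)."""
        ref = min(self.leaf_names)
        u, v = tuple(edge)
        side = self.side_leaves(edge, u)
        return frozenset(self.leaf_names) - side if ref in side else side

    def _split_signature(self, edge: Edge):
        s = self.canonical_split(edge)
        return (len(s), tuple(sorted(s)))

    def topology_key(self) -> frozenset:
        """Canonical topology identity: the set of all edge splits (trivial
        splits are shared by every topology on the leaf set, so they do not
        disturb the identity)."""
        return frozenset(self.canonical_split(e) for e in self.edges())

    def nontrivial_splits(self) -> frozenset:
        n = len(self.leaf_names)
        return frozenset(
            s for e in self.edges()
            for s in (self.canonical_split(e),)
            if 1 < len(s) < n - 1
        )

    # -- newick -------------------------------------------------------------

    def to_newick(self, lengths: dict[Edge, float] | None = None, precision: int = 8) -> str:
        """Serialize rooted at the internal node next to the first leaf; child
        order is by smallest leaf name in each subtree, so equal topologies
        yield identical strings."""
        first_leaf = min(self._leaf_name, key=self._leaf_name.get)
        if len(self._adj) == 1:
            return f"{self._leaf_name[first_leaf]};"
        root = next(iter(self._adj[first_leaf]))

        def fmt(u: int, parent: int) -> tuple[str, str]:
            if self.is_leaf(u):
                label, mn = self._leaf_name[u], self._leaf_name[u]
            else:
                parts = sorted(
                    (fmt(v, u) for v in self._adj[u] if v != parent),
                    key=lambda t: t[1],
                )
                label = "(" + ",".join(p[0] for p in parts) + ")"
                mn = min(p[1] for p in parts)
            if lengths is not None and parent is not None:
                label += f":{lengths[frozenset((u, parent))]:.{precision}g}"
            return label, mn

        parts = sorted((fmt(v, root) for v in self._adj[root]), key=lambda t: t[1])
        return "(" + ",".join(p[0] for p in parts) + ");"


def tree_to_newick(tree: "PopTree", precision: int = 8) -> str:
    return tree.topology.to_newick(tree.lengths, precision=precision)


def tree_from_newick(text: str) -> tuple[UnrootedTree, dict[Edge, float]]:
    """Parse a newick string into an unrooted tree plus edge lengths.

    A basal bifurcation (rooted input) is suppressed: the root is removed and
    its two child edges merged with summed length.  Missing branch lengths
    default to 0.
    """
    import dendropy

    dt = dendropy.Tree.get(data=text, schema="newick")
    tree = UnrootedTree()
    lengths: dict[Edge, float] = {}
    node_map: dict = {}
    for nd in dt.preorder_node_iter():
        name = nd.taxon.label if nd.taxon is not None else None
        node_map[nd] = tree.add_node(name)
        if nd.parent_node is not None:
            u, v = node_map[nd.parent_node], node_map[nd]
            tree.add_edge(u, v)
            lengths[frozenset((u, v))] = float(nd.edge.length or 0.0)
    root = node_map[dt.seed_node]
    if len(tree.neighbors(root)) == 2 and not tree.is_leaf(root):
        a, b = tuple(tree.neighbors(root))
        merged = lengths.pop(frozenset((root, a))) + lengths.pop(frozenset((root, b)))
        tree.remove_edge(root, a)
        tree.remove_edge(root, b)
        tree.add_edge(a, b)
        lengths[frozenset((a, b))] = merged
        del tree._adj[root]
    return tree, lengths


# ---------------------------------------------------------------------------
# Fitted trees


@dataclass(frozen=True)
class FitDiagnostics:
    ssq: float
    total_length: float
    n_negative_internal: int
    n_negative_terminal: int

    @property
    def n_negative(self) -> int:
        return self.n_negative_internal + self.n_negative_terminal

    @property
    def all_positive(self) -> bool:
        return self.n_negative == 0


@dataclass
class PopTree:
    """A population tree: unrooted topology, per-segment lengths (drift units,
    possibly negative), and least-squares fit diagnostics."""

    topology: UnrootedTree
    lengths: dict[Edge, float]
    fit: FitDiagnostics | None = None

    def newick(self, precision: int = 8) -> str:
        return self.topology.to_newick(self.lengths, precision=precision)

    @property
    def drawable_as_additive(self) -> bool:
        """False when any segment is negative: negative drift cannot be drawn
        as an additive branch."""
        return self.fit is not None and self.fit.all_positive


def _diagnostics(tree: UnrootedTree, lengths: dict[Edge, float], ssq: float) -> FitDiagnostics:
    neg_int = neg_term = 0
    for e, x in lengths.items():
        if x < -_NEG_TOL:
            if any(tree.is_leaf(n) for n in e):
                neg_term += 1
            else:
                neg_int += 1
    return FitDiagnostics(ssq, float(sum(lengths.values())), neg_int, neg_term)


def evaluate_lengths(
    tree: UnrootedTree, lengths: dict[Edge, float], dist: DistanceMatrix
) -> FitDiagnostics:
    """Diagnostics (residual sum of squares, total length, negative-segment
    counts) for an arbitrary length assignment on a topology."""
    A, y, edges = _design(tree, dist)
    x = np.array([lengths[e] for e in edges])
    ssq = float(np.sum((A @ x - y) ** 2))
    return _diagnostics(tree, lengths, ssq)


def _design(tree: UnrootedTree, dist: DistanceMatrix):
    """Path-indicator system A x = d over all leaf pairs.

    ``A[pair, edge]`` is 1 iff the edge lies on the path between the pair's
    leaves, i.e. iff exactly one of the two leaves is inside the edge's split.
    """
    if set(tree.leaf_names) != set(dist.pop_ids):
        raise ValueError("topology leaf set does not match distance matrix populations")
    edges = tree.edges()
    splits = [tree.canonical_split(e) for e in edges]
    pairs = list(combinations(dist.pop_ids, 2))
    A = np.zeros((len(pairs), len(edges)))
    for r, (a, b) in enumerate(pairs):
        for c, s in enumerate(splits):
            if (a in s) != (b in s):
                A[r, c] = 1.0
    y = np.array([dist[a, b] for a, b in pairs])
    return A, y, edges


def ls_fit(
    topology: "PopTree | UnrootedTree", dist: DistanceMatrix, nonnegative: bool = False
) -> PopTree:
    """Exact least-squares segment lengths for a fixed topology.

    Solves the path-indicator linear system over all n(n-1)/2 leaf pairs by
    unconstrained ordinary least squares; negative solutions are reported in
    the diagnostics, never clipped.  ``nonnegative=True`` switches to NNLS for
    users who want a constrained fit.
    """
    tree = topology.topology if isinstance(topology, PopTree) else topology
    A, y, edges = _design(tree, dist)
    if nonnegative:
        from scipy.optimize import nnls

        x, _ = nnls(A, y)
    else:
        x, *_ = np.linalg.lstsq(A, y, rcond=None)
    lengths = dict(zip(edges, (float(v) for v in x)))
    ssq = float(np.sum((A @ x - y) ** 2))
    return PopTree(tree, lengths, _diagnostics(tree, lengths, ssq))


# ---------------------------------------------------------------------------
# Neighbor joining


def neighbor_joining(dist: DistanceMatrix) -> PopTree:
    """Saitou–Nei agglomeration producing an approximately additive unrooted
    tree; NJ's own branch-length estimates are retained (they may be
    negative).  Q-matrix ties are broken toward the lowest index pair."""
    n = len(dist.pop_ids)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 populations")
    tree = UnrootedTree()
    lengths: dict[Edge, float] = {}
    active = [tree.add_node(name) for name in dist.pop_ids]
    d: dict[Edge, float] = {
        frozenset((active[a], active[b])): dist.d[a, b]
        for a, b in combinations(range(n), 2)
    }

    while len(active) > 3:
        r = len(active)
        R = {u: sum(d[frozenset((u, v))] for v in active if v != u) for u in active}
        best, best_q = None, np.inf
        for a, b in combinations(range(r), 2):  # lowest (a, b) wins ties
            u, v = active[a], active[b]
            q = (r - 2) * d[frozenset((u, v))] - R[u] - R[v]
            if q < best_q - 1e-12:
                best_q, best = q, (u, v)
        u, v = best
        duv = d[frozenset((u, v))]
        w = tree.add_node()
        lu = 0.5 * duv + (R[u] - R[v]) / (2 * (r - 2))
        tree.add_edge(u, w)
        tree.add_edge(v, w)
        lengths[frozenset((u, w))] = lu
        lengths[frozenset((v, w))] = duv - lu
        for k in active:
            if k in (u, v):
                continue
            d[frozenset((w, k))] = 0.5 * (
                d[frozenset((u, k))] + d[frozenset((v, k))] - duv
            )
        active = [x for x in active if x not in (u, v)] + [w]

    a, b, c = active
    dab, dac, dbc = (
        d[frozenset((a, b))],
        d[frozenset((a, c))],
        d[frozenset((b, c))],
    )
    w = tree.add_node()
    for node, ln in (
        (a, (dab + dac - dbc) / 2),
        (b, (dab + dbc - dac) / 2),
        (c, (dac + dbc - dab) / 2),
    ):
        tree.add_edge(node, w)
        lengths[frozenset((node, w))] = ln
    fit = evaluate_lengths(tree, lengths, dist)
    return PopTree(tree, lengths, fit)


# ---------------------------------------------------------------------------
# Topology search


@dataclass
class TreeSearchResult:
    """Unique topologies evaluated by least squares, ranked by (fewest
    negative internal segments, fewest negative terminal segments, smallest
    total length, smallest residual sum of squares)."""

    evaluated: list[PopTree]
    n_structures_evaluated: int

    @property
    def best(self) -> PopTree:
        return self.evaluated[0]


def _rank_key(t: PopTree):
    f = t.fit
    return (f.n_negative_internal, f.n_negative_terminal, f.total_length, f.ssq)


def nni_neighbors(tree: UnrootedTree) -> Iterator[UnrootedTree]:
    """All nearest-neighbor-interchange rearrangements: for each internal
    edge, the two swaps of one subtree from each side.  Enumeration order is
    deterministic (edges and subtrees in canonical split order)."""
    for edge in tree.edges():
        u, v = sorted(edge)
        if tree.is_leaf(u) or tree.is_leaf(v):
            continue
        sig = lambda x, anchor: tuple(sorted(tree.side_leaves(frozenset((x, anchor)), x)))
        others_u = sorted(tree.neighbors(u) - {v}, key=lambda x: sig(x, u))
        others_v = sorted(tree.neighbors(v) - {u}, key=lambda x: sig(x, v))
        b = others_u[1]
        for c in others_v:
            t = tree.copy()
            t.remove_edge(u, b)
            t.remove_edge(v, c)
            t.add_edge(u, c)
            t.add_edge(v, b)
            yield t


def search_topologies(
    dist: DistanceMatrix,
    start: "PopTree | UnrootedTree | Iterable | None" = None,
    max_structures: int = 1000,
    nonnegative: bool = False,
) -> TreeSearchResult:
    """Hill-climb over NNI moves for an all-positive, minimum-total-length
    least-squares tree.

    Starts from the NJ tree by default (or any user-supplied start tree(s))
    and evaluates every candidate topology by :func:`ls_fit`.  The climb
    itself descends on the residual sum of squares — the quantity NNI moves
    improve smoothly — while the *returned* structures are ranked by the
    preference criteria (fewest negative internal segments, fewest negative
    terminal segments, smallest total length, smallest ssq).  The search stops
    at a local optimum or after ``max_structures`` unique topologies, and may
    legitimately end on trees that still contain negative segments: that
    outcome is the diagnostic of a non-additive population system.
    """
    if start is None:
        starts = [neighbor_joining(dist)]
    elif isinstance(start, (PopTree, UnrootedTree)):
        starts = [start]
    else:
        starts = list(start)

    evaluated: dict[frozenset, PopTree] = {}

    def fit(topo: UnrootedTree) -> PopTree | None:
        key = topo.topology_key()
        if key in evaluated:
            return evaluated[key]
        if len(evaluated) >= max_structures:
            return None
        t = ls_fit(topo, dist, nonnegative=nonnegative)
        evaluated[key] = t
        return t

    for s in starts:
        topo = s.topology if isinstance(s, PopTree) else s
        current = fit(topo)
        if current is None:
            break
        def improves(cand: PopTree, over: PopTree) -> bool:
            return cand.fit.ssq < over.fit.ssq * (1 - 1e-12) - 1e-15

        while True:
            best = None
            neighbors: list[PopTree] = []
            for nb in nni_neighbors(current.topology):
                cand = fit(nb)
                if cand is None:
                    break
                neighbors.append(cand)
                if best is None or cand.fit.ssq < best.fit.ssq:
                    best = cand
            if best is not None and improves(best, current):
                current = best
                continue
            # stalled: depth-2 lookahead through the one-move neighborhood
            # escapes shallow NNI local optima without changing the move set
            jump = None
            for nb in sorted(neighbors, key=lambda t: t.fit.ssq):
                for nb2 in nni_neighbors(nb.topology):
                    cand = fit(nb2)
                    if cand is None:
                        break
                    if improves(cand, current) and (
                        jump is None or cand.fit.ssq < jump.fit.ssq
                    ):
                        jump = cand
            if jump is not None:
                current = jump
            else:
                break

    ranked = sorted(evaluated.values(), key=lambda t: (_rank_key(t), t.newick()))
    return TreeSearchResult(ranked, len(evaluated))


def enumerate_topologies(leaf_names: list[str]) -> Iterator[UnrootedTree]:
    """Exhaustively generate all (2n-5)!! unrooted binary topologies by
    sequential leaf insertion.  Usable as a brute-force oracle for small n."""
    leaf_names = sorted(leaf_names)
    if len(leaf_names) < 3:
        raise ValueError("need at least 3 leaves")

    base = UnrootedTree()
    center = base.add_node()
    for name in leaf_names[:3]:
        base.add_edge(base.add_node(name), center)

    def grow(tree: UnrootedTree, remaining: list[str]) -> Iterator[UnrootedTree]:
        if not remaining:
            yield tree
            return
        name, rest = remaining[0], remaining[1:]
        for u, v in [tuple(sorted(e)) for e in tree.edges()]:
            t = tree.copy()
            mid = t.add_node()
            t.remove_edge(u, v)
            t.add_edge(u, mid)
            t.add_edge(v, mid)
            t.add_edge(t.add_node(name), mid)
            yield from grow(t, rest)

    yield from grow(base, leaf_names[3:])


def robinson_foulds(a, b) -> int:
    """Robinson–Foulds distance: size of the symmetric difference of the two
    trees' non-trivial split sets.  Accepts trees or split sets."""
    sa = a.nontrivial_splits() if hasattr(a, "nontrivial_splits") else frozenset(a)
    sb = b.nontrivial_splits() if hasattr(b, "nontrivial_splits") else frozenset(b)
    return len(sa ^ sb)


# ---------------------------------------------------------------------------
# Reporting


def tree_report(result: TreeSearchResult, top: int | None = None) -> str:
    """Human-readable diagnostics table plus newick for each ranked tree.

    Trees with negative segments are marked not drawable as an additive tree
    (a negative drift branch has no graphical representation).
    """
    if not result.evaluated:
        raise ValueError("empty search result")
    trees = result.evaluated if top is None else result.evaluated[:top]
    lines = [
        f"# {result.n_structures_evaluated} tree structures evaluated by least squares",
        "rank\tneg_internal\tneg_terminal\ttotal_length\tssq\tdrawable\tnewick",
    ]
    for rank, t in enumerate(trees, start=1):
        f = t.fit
        lines.append(
            f"{rank}\t{f.n_negative_internal}\t{f.n_negative_terminal}"
            f"\t{f.total_length:.6g}\t{f.ssq:.6g}"
            f"\t{'yes' if f.all_positive else 'no (negative segments)'}"
            f"\t{t.newick()}"
        )
    return "\n".join(lines) + "\n"
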