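"""Tau distances, neighbor joining, least-squares trees, and NNI search."""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pytest

import popkit as pk
from popkit.tree import _design


def _freq_table(freq_rows, names=None):
    n_pops, n_loci = freq_rows.shape
    panel = pk.default_panel(n_loci)
    names = names or [f"Pop{i}" for i in range(n_pops)]
    pops = [pk.Population(nm, f"{i:03d}", 100) for i, nm in enumerate(names)]
    return pk.PopFrequencyTable(panel, pops, np.asarray(freq_rows, dtype=float))


class TestTauDistance:
    def test_identical_rows_give_zero(self):
        table = _freq_table(np.array([[0.3, 0.6], [0.3, 0.6]]))
        assert pk.tau_distance(table, "Pop0", "Pop1") == 0.0

    def test_single_locus_hand_value(self):
        # (0.2 - 0.4)^2 / (0.3 * 0.7) = 0.04 / 0.21
        table = _freq_table(np.array([[0.2], [0.4]]))
        assert pk.tau_distance(table, "Pop0", "Pop1") == pytest.approx(0.04 / 0.21)

    def test_jointly_monomorphic_loci_skipped(self):
        table = _freq_table(np.array([[0.0, 0.2], [0.0, 0.4]]))
        assert pk.tau_distance(table, "Pop0", "Pop1") == pytest.approx(0.04 / 0.21)

    def test_all_loci_monomorphic_is_error(self):
        table = _freq_table(np.array([[0.0, 1.0], [0.0, 1.0]]))
        with pytest.raises(ValueError):
            pk.tau_distance(table, "Pop0", "Pop1")

    def test_matrix_symmetry_and_diagonal(self):
        rng = np.random.default_rng(8)
        table = _freq_table(rng.uniform(0.1, 0.9, (5, 40)))
        dist = pk.tau_matrix(table)
        assert np.allclose(dist.d, dist.d.T)
        assert np.allclose(np.diag(dist.d), 0.0)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = pk.DistanceMatrix(["A", "B", "C"], np.array(
            [[0.0, 3.0, 4.0], [3.0, 0.0, 5.0], [4.0, 5.0, 0.0]]
        ))
        nj = pk.neighbor_joining(d)
        # x_A = (d_AB + d_AC - d_BC)/2 = 1, x_B = 2, x_C = 3
        lengths = sorted(nj.lengths.values())
        assert lengths == pytest.approx([1.0, 2.0, 3.0])
        assert nj.fit.ssq == pytest.approx(0.0, abs=1e-24)

    def test_fewer_than_three_taxa_rejected(self):
        d = pk.DistanceMatrix(["A", "B"], np.array([[0.0, 1.0], [1.0, 0.0]]))
        with pytest.raises(ValueError):
            pk.neighbor_joining(d)

    def test_recovers_topology_and_lengths_on_additive_4taxon(self, additive_oracle):
        names, D, true_splits = additive_oracle(list("ABCD"), np.random.default_rng(1))
        nj = pk.neighbor_joining(pk.DistanceMatrix(names, D))
        assert nj.topology.nontrivial_splits() == true_splits
        # additive input: NJ lengths reproduce all pairwise distances exactly
        assert nj.fit.ssq == pytest.approx(0.0, abs=1e-18)

    @pytest.mark.parametrize("n", [4, 5, 6, 7, 8, 10])
    def test_consistency_on_random_additive_matrices(self, additive_oracle, n):
        """Classical NJ consistency: the generating topology is recovered for
        every additive matrix."""
        for seed in range(5):
            rng = np.random.default_rng(100 * n + seed)
            names, D, true_splits = additive_oracle([f"t{i}" for i in range(n)], rng)
            nj = pk.neighbor_joining(pk.DistanceMatrix(names, D))
            assert nj.topology.nontrivial_splits() == true_splits

    def test_against_scikit_bio_on_noisy_matrix(self, additive_oracle):
        """Independent cross-check: on a perturbed additive matrix the
        in-package NJ topology matches scikit-bio's implementation."""
        skbio = pytest.importorskip("skbio")
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(42)
        names, D, _ = additive_oracle([f"t{i}" for i in range(7)], rng)
        noise = rng.uniform(-0.05, 0.05, D.shape)
        D = D + noise + noise.T
        D = (D + D.T) / 2.0  # exact float symmetry
        np.fill_diagonal(D, 0.0)
        ours = pk.neighbor_joining(pk.DistanceMatrix(names, D))
        theirs = skbio_nj(skbio.DistanceMatrix(D, ids=names))
        ref = min(names)
        all_names = frozenset(names)
        their_splits = set()
        for node in theirs.non_tips():
            clade = frozenset(t.name for t in node.tips())
            canon = all_names - clade if ref in clade else clade
            if 1 < len(canon) < len(names) - 1:
                their_splits.add(canon)
        assert ours.topology.nontrivial_splits() == frozenset(their_splits)


class TestLeastSquaresFit:
    def test_exact_fit_on_generating_topology(self, additive_oracle):
        rng = np.random.default_rng(3)
        names, D, _ = additive_oracle([f"t{i}" for i in range(6)], rng)
        dist = pk.DistanceMatrix(names, D)
        nj = pk.neighbor_joining(dist)
        fit = pk.ls_fit(nj, dist)
        assert fit.fit.ssq == pytest.approx(0.0, abs=1e-18)
        assert fit.fit.n_negative == 0
        # path sums reproduce every pairwise distance
        A, y, edges = _design(fit.topology, dist)
        x = np.array([fit.lengths[e] for e in edges])
        np.testing.assert_allclose(A @ x, y, atol=1e-9)

    def test_wrong_topology_has_strictly_larger_ssq(self, additive_oracle):
        """Brute force all three 4-taxon topologies: only the generating one
        fits an additive matrix exactly."""
        rng = np.random.default_rng(13)
        names, D, true_splits = additive_oracle(list("WXYZ"), rng)
        dist = pk.DistanceMatrix(names, D)
        ssqs = {}
        for topo in pk.enumerate_topologies(names):
            ssqs[topo.nontrivial_splits()] = pk.ls_fit(topo, dist).fit.ssq
        assert len(ssqs) == 3
        assert ssqs[true_splits] == pytest.approx(0.0, abs=1e-18)
        for splits, ssq in ssqs.items():
            if splits != true_splits:
                assert ssq > 1e-4

    def test_ols_beats_nj_lengths_on_same_topology(self, additive_oracle):
        """OLS optimality: on a non-additive matrix, the least-squares lengths
        never fit worse than NJ's own estimates on the same topology."""
        rng = np.random.default_rng(19)
        names, D, _ = additive_oracle([f"t{i}" for i in range(8)], rng)
        noise = rng.uniform(-0.1, 0.1, D.shape)
        D = D + noise + noise.T
        np.fill_diagonal(D, 0.0)
        dist = pk.DistanceMatrix(names, D)
        nj = pk.neighbor_joining(dist)
        ols = pk.ls_fit(nj, dist)
        assert ols.fit.ssq <= nj.fit.ssq + 1e-12

    def test_nonnegative_mode_has_no_negative_lengths(self, additive_oracle):
        rng = np.random.default_rng(29)
        names, D, _ = additive_oracle([f"t{i}" for i in range(6)], rng)
        noise = rng.uniform(-0.3, 0.3, D.shape)
        D = np.abs(D + noise + noise.T)
        np.fill_diagonal(D, 0.0)
        dist = pk.DistanceMatrix(names, D)
        fit = pk.ls_fit(pk.neighbor_joining(dist), dist, nonnegative=True)
        assert all(v >= 0 for v in fit.lengths.values())
        assert fit.fit.n_negative == 0

    def test_leaf_set_mismatch_rejected(self, additive_oracle):
        rng = np.random.default_rng(31)
        names, D, _ = additive_oracle(list("ABCD"), rng)
        dist = pk.DistanceMatrix(names, D)
        other = next(pk.enumerate_topologies(["P", "Q", "R", "S"]))
        with pytest.raises(ValueError):
            pk.ls_fit(other, dist)


class TestTopologySearch:
    def test_reaches_true_topology_from_wrong_start(self, additive_oracle):
        """6-taxon additive matrix, deliberately wrong start: the NNI climb
        must find the ssq=0 topology, verified against brute-force enumeration
        of all 105 six-taxon structures."""
        rng = np.random.default_rng(7)
        names, D, true_splits = additive_oracle([f"t{i}" for i in range(6)], rng)
        dist = pk.DistanceMatrix(names, D)

        all_topos = list(pk.enumerate_topologies(names))
        assert len(all_topos) == 105
        by_ssq = [(pk.ls_fit(t, dist).fit.ssq, t.nontrivial_splits()) for t in all_topos]
        best_ssq, best_splits = min(by_ssq, key=lambda t: t[0])
        assert best_ssq == pytest.approx(0.0, abs=1e-16)
        assert best_splits == true_splits

        wrong = next(t for t in all_topos if t.nontrivial_splits() != true_splits)
        result = pk.search_topologies(dist, start=wrong)
        assert result.best.topology.nontrivial_splits() == true_splits
        assert result.best.fit.ssq == pytest.approx(0.0, abs=1e-16)
        assert result.n_structures_evaluated <= 105

    def test_true_start_is_fixed_point(self, additive_oracle):
        rng = np.random.default_rng(23)
        names, D, true_splits = additive_oracle([f"t{i}" for i in range(6)], rng)
        dist = pk.DistanceMatrix(names, D)
        start = next(
            t for t in pk.enumerate_topologies(names)
            if t.nontrivial_splits() == true_splits
        )
        result = pk.search_topologies(dist, start=start)
        assert result.best.topology.nontrivial_splits() == true_splits

    def test_deterministic_ranking(self, additive_oracle):
        rng = np.random.default_rng(37)
        names, D, _ = additive_oracle([f"t{i}" for i in range(6)], rng)
        noise = rng.uniform(-0.05, 0.05, D.shape)
        D = D + noise + noise.T
        np.fill_diagonal(D, 0.0)
        dist = pk.DistanceMatrix(names, D)
        r1 = pk.search_topologies(dist)
        r2 = pk.search_topologies(dist)
        assert [t.newick() for t in r1.evaluated] == [t.newick() for t in r2.evaluated]

    def test_structure_cap_respected(self, additive_oracle):
        rng = np.random.default_rng(41)
        names, D, _ = additive_oracle([f"t{i}" for i in range(8)], rng)
        result = pk.search_topologies(pk.DistanceMatrix(names, D), max_structures=5)
        assert result.n_structures_evaluated <= 5

    def test_nni_neighborhood_size(self):
        # an unrooted binary tree with n leaves has n-3 internal edges and
        # two NNI rearrangements per internal edge
        topo = next(pk.enumerate_topologies([f"t{i}" for i in range(6)]))
        neighbors = list(pk.nni_neighbors(topo))
        assert len(neighbors) == 2 * (6 - 3)
        keys = {t.topology_key() for t in neighbors}
        assert len(keys) == len(neighbors)
        assert topo.topology_key() not in keys


class TestNewickAndReport:
    def test_three_taxon_newick_round_trip(self):
        d = pk.DistanceMatrix(["A", "B", "C"], np.array(
            [[0.0, 3.0, 4.0], [3.0, 0.0, 5.0], [4.0, 5.0, 0.0]]
        ))
        nj = pk.neighbor_joining(d)
        text = nj.newick()
        tree, lengths = pk.tree_from_newick(text)
        assert sorted(tree.leaf_names) == ["A", "B", "C"]
        assert sorted(lengths.values()) == pytest.approx([1.0, 2.0, 3.0])

    def test_negative_length_survives_newick_and_flags(self):
        # within-pair distances exceed cross distances: the internal branch of
        # the ((A,B),(C,D)) topology must fit negative
        d = np.array(
            [
                [0.0, 2.0, 1.0, 1.0],
                [2.0, 0.0, 1.0, 1.0],
                [1.0, 1.0, 0.0, 2.0],
                [1.0, 1.0, 2.0, 0.0],
            ]
        )
        dist = pk.DistanceMatrix(list("ABCD"), d)
        topo = next(
            t
            for t in pk.enumerate_topologies(list("ABCD"))
            if frozenset({"C", "D"}) in t.nontrivial_splits()
        )
        fit = pk.ls_fit(topo, dist)
        assert fit.fit.n_negative_internal == 1
        assert not fit.drawable_as_additive
        text = fit.newick()
        _, lengths = pk.tree_from_newick(text)
        assert min(lengths.values()) < 0

    def test_report_sorted_and_marked(self, additive_oracle):
        rng = np.random.default_rng(43)
        names, D, _ = additive_oracle([f"t{i}" for i in range(5)], rng)
        result = pk.search_topologies(pk.DistanceMatrix(names, D))
        report = pk.tree_report(result)
        lines = [l for l in report.splitlines() if l and not l.startswith("#")]
        assert lines[0].startswith("rank")
        assert lines[1].startswith("1\t")

    def test_rooted_newick_unrooted_on_parse(self):
        tree, lengths = pk.tree_from_newick("((A:1,B:2):0.5,(C:1,D:1):0.5);")
        # basal bifurcation suppressed: 4 leaves, 5 edges, one of length 1.0
        assert len(tree.leaf_names) == 4
        assert len(tree.edges()) == 5


def test_star_matrix_fits_exactly_with_zero_center():
    """The all-equal distance matrix is a star: every topology fits it exactly
    with terminal branches 0.5 and a zero-length internal branch — the
    degenerate boundary between additive and anti-additive systems."""
    d = np.ones((4, 4)) - np.eye(4)
    dist = pk.DistanceMatrix(list("ABCD"), d)
    for topo in pk.enumerate_topologies(list("ABCD")):
        fit = pk.ls_fit(topo, dist)
        assert fit.fit.ssq == pytest.approx(0.0, abs=1e-18)
        assert fit.fit.n_negative == 0
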