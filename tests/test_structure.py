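import numpy as np
import pytest

from tropiscan import simdata, structure
from tropiscan.datamodel import MISSING

from conftest import make_genotypes
from oracles import additive_distance_from_tree


def simulated_pops(n_pops, n_ind, n_loci, fst, seed):
    cfg = simdata.SimulationConfig(
        n_pops=n_pops, n_individuals=n_ind, n_markers=n_loci, target_fst=fst,
        seed=seed,
    )
    rng = np.random.default_rng(seed)
    freqs = simdata.sample_balding_nichols_freqs(cfg, rng)
    return simdata.simulate_genotypes(freqs, cfg, rng)


class TestPca:
    def test_duplicated_samples_coincide(self):
        rng = np.random.default_rng(0)
        dosage = rng.integers(0, 3, size=(8, 100)).astype(np.int8)
        doubled = np.repeat(dosage, 2, axis=0)
        g = make_genotypes(doubled)
        res = structure.pca(g, n_components=4)
        for i in range(8):
            gap = np.linalg.norm(res.coordinates[2 * i] - res.coordinates[2 * i + 1])
            assert gap < 1e-8

    def test_first_component_separates_populations(self):
        g = simulated_pops(2, 30, 2000, 0.1, seed=1)
        res = structure.pca(g, n_components=2)
        pc1 = res.coordinates[:, 0]
        a, b = pc1[:30], pc1[30:]
        centroid_gap = abs(a.mean() - b.mean())
        spread = max(np.ptp(a), np.ptp(b))
        assert centroid_gap > spread

    def test_eigenvalues_sorted_nonnegative(self):
        g = simulated_pops(2, 15, 300, 0.05, seed=2)
        res = structure.pca(g, n_components=10)
        ev = res.eigenvalues
        assert np.all(np.diff(ev) <= 1e-9)
        assert np.all(ev >= -1e-9)

    def test_locus_reordering_changes_nothing(self):
        g = simulated_pops(2, 12, 200, 0.05, seed=3)
        rng = np.random.default_rng(4)
        perm = rng.permutation(g.n_markers)
        res1 = structure.pca(g, n_components=3)
        # permute dosage columns under a fresh (valid) marker map
        res2 = structure.pca(make_genotypes(g.dosage[:, perm]), n_components=3)
        for k in range(3):
            c1, c2 = res1.coordinates[:, k], res2.coordinates[:, k]
            assert np.allclose(c1, c2, atol=1e-8) or np.allclose(c1, -c2, atol=1e-8)

    def test_excess_components_truncated_with_warning(self):
        g = simulated_pops(2, 4, 50, 0.05, seed=5)
        with pytest.warns(UserWarning, match="rank"):
            res = structure.pca(g, n_components=40)
        assert res.coordinates.shape[1] <= 8


class TestAlleleSharingDistance:
    def test_identical_individuals(self):
        dosage = np.array([[0, 1, 2, 1], [0, 1, 2, 1]], dtype=np.int8)
        d = structure.allele_sharing_distance(make_genotypes(dosage))
        assert d.iloc[0, 1] == 0.0

    def test_opposite_homozygotes_maximal(self):
        dosage = np.array([[0, 0, 0], [2, 2, 2]], dtype=np.int8)
        d = structure.allele_sharing_distance(make_genotypes(dosage))
        assert d.iloc[0, 1] == 1.0

    def test_hand_tally_3x4(self):
        dosage = np.array(
            [[0, 1, 2, 1], [0, 2, 2, 0], [1, 1, 0, MISSING]], dtype=np.int8
        )
        d = structure.allele_sharing_distance(make_genotypes(dosage))
        # hand IBS tally: d = mean(|gi - gj|) / 2 over loci complete in both
        assert d.iloc[0, 1] == pytest.approx((0 + 1 + 0 + 1) / 8)
        assert d.iloc[0, 2] == pytest.approx((1 + 0 + 2) / 6)
        assert d.iloc[1, 2] == pytest.approx((1 + 1 + 2) / 6)

    def test_population_level_is_cross_pair_mean(self):
        dosage = np.array(
            [[0, 0], [0, 2], [2, 2], [2, 0]], dtype=np.int8
        )
        g = make_genotypes(dosage, populations=["x", "x", "y", "y"])
        d_ind = structure.allele_sharing_distance(g)
        d_pop = structure.allele_sharing_distance(g, level="populations")
        want = np.mean(
            [d_ind.iloc[i, j] for i in (0, 1) for j in (2, 3)]
        )
        assert d_pop.loc["x", "y"] == pytest.approx(want)

    def test_disjoint_missingness_is_an_error(self):
        dosage = np.array([[0, MISSING], [MISSING, 2]], dtype=np.int8)
        with pytest.raises(ValueError, match="no complete loci"):
            structure.allele_sharing_distance(make_genotypes(dosage))


def newick_distances(tree):
    """Leaf-to-leaf path lengths parsed back via scikit-bio (oracle parser)."""
    import io

    from skbio import TreeNode

    t = TreeNode.read(io.StringIO(tree.to_newick(with_support=False)))
    return t.tip_tip_distances()


class TestNeighborJoining:
    def test_four_taxon_additive_recovery(self):
        # tree ((A:1,B:2):1,(C:3,D:1)) as an additive distance matrix
        edges = {
            ("A", "u"): 1.0,
            ("B", "u"): 2.0,
            ("u", "v"): 1.0,
            ("C", "v"): 3.0,
            ("D", "v"): 1.0,
        }
        leaves = ["A", "B", "C", "D"]
        dm = additive_distance_from_tree(edges, leaves)
        tree = structure.neighbor_joining(dm, taxa=leaves)
        assert tree.bipartitions() == {frozenset({"A", "B"})}
        got = newick_distances(tree)
        for i, a in enumerate(leaves):
            for j, b in enumerate(leaves):
                if i < j:
                    assert got[got.ids.index(a), got.ids.index(b)] == pytest.approx(
                        dm[i, j], abs=1e-9
                    )

    def test_three_taxa_closed_form(self):
        dm = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = structure.neighbor_joining(dm, taxa=["a", "b", "c"])
        got = newick_distances(tree)
        # three-point formulas: la=(dab+dac-dbc)/2 etc.; pairwise sums exact
        assert got[got.ids.index("a"), got.ids.index("b")] == pytest.approx(3.0)
        assert got[got.ids.index("a"), got.ids.index("c")] == pytest.approx(4.0)
        assert got[got.ids.index("b"), got.ids.index("c")] == pytest.approx(5.0)

    def test_random_additive_trees_recovered(self):
        """NJ must reconstruct any additive matrix exactly (up to 8 taxa)."""
        rng = np.random.default_rng(10)
        for case in range(40):
            n = int(rng.integers(4, 9))
            leaves = [f"L{k}" for k in range(n)]
            # random binary-ish topology: sequential attachment
            edges = {}
            internal = 0
            attached = [leaves[0], leaves[1]]
            edges[(leaves[0], "x0")] = float(rng.uniform(0.1, 2))
            edges[(leaves[1], "x0")] = float(rng.uniform(0.1, 2))
            spine = ["x0"]
            for leaf in leaves[2:]:
                host = spine[int(rng.integers(len(spine)))]
                internal += 1
                new = f"x{internal}"
                # split an existing edge at `host` by hanging a new internal node
                edges[(host, new)] = float(rng.uniform(0.1, 2))
                edges[(leaf, new)] = float(rng.uniform(0.1, 2))
                spine.append(new)
            dm = additive_distance_from_tree(edges, leaves)
            tree = structure.neighbor_joining(dm, taxa=leaves)
            got = newick_distances(tree)
            idx = [got.ids.index(l) for l in leaves]
            recovered = np.asarray(got.data)[np.ix_(idx, idx)]
            assert np.allclose(recovered, dm, atol=1e-8), f"case {case}"

    def test_agrees_with_skbio_on_random_matrix(self):
        """Cross-check against the independent scikit-bio NJ implementation."""
        from skbio import DistanceMatrix
        from skbio.tree import nj

        rng = np.random.default_rng(11)
        pts = rng.normal(size=(6, 3))
        dm = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        taxa = [f"t{k}" for k in range(6)]
        ours = structure.neighbor_joining(dm, taxa=taxa)
        theirs = nj(DistanceMatrix(dm, ids=taxa))
        ours_bps = ours.bipartitions()
        theirs_bps = set()
        all_leaves = frozenset(taxa)
        for node in theirs.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            other = all_leaves - side
            if len(side) >= 2 and len(other) >= 2:
                if len(side) < len(other) or (
                    len(side) == len(other) and sorted(side) < sorted(other)
                ):
                    theirs_bps.add(side)
                else:
                    theirs_bps.add(other)
        assert ours_bps == theirs_bps

    def test_asymmetric_matrix_rejected(self):
        dm = np.array([[0, 1, 2], [1, 0, 3], [9, 3, 0]], dtype=float)
        with pytest.raises(ValueError):
            structure.neighbor_joining(dm)


class TestBootstrapSupport:
    def test_strong_structure_high_support(self):
        g = simulated_pops(3, 8, 2000, 0.2, seed=12)
        tree = structure.bootstrap_support(g, n_boot=50, seed=13)
        pops = {"A": set(), "B": set(), "C": set()}
        for sid, pop in zip(g.samples.ids, g.samples.populations):
            pops[str(pop)].add(str(sid))
        bps = tree.bipartitions()
        for pop, members in pops.items():
            key = frozenset(members)
            assert key in bps, f"population {pop} not monophyletic"
            assert tree.support[key] >= 0.95

    def test_no_bootstrap_leaves_support_empty(self):
        g = simulated_pops(2, 4, 100, 0.1, seed=14)
        tree = structure.bootstrap_support(g, n_boot=0, seed=15)
        assert tree.support == {}

    def test_fixed_seed_reproducible(self):
        g = simulated_pops(2, 5, 150, 0.1, seed=16)
        t1 = structure.bootstrap_support(g, n_boot=20, seed=17)
        t2 = structure.bootstrap_support(g, n_boot=20, seed=17)
        assert t1.support == t2.support
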