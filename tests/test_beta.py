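"""PhyloSor beta diversity, geography and Mantel tests."""

import itertools
import math

import numpy as np
import pytest

import islephylo as ip
from conftest import EdgeOracle, random_tree


class TestPhylosor:
    def test_identical_sets_are_homogenized(self, example_tree):
        assert ip.phylosor(example_tree, {"A", "B"}, {"A", "B"}) == pytest.approx(1.0)
        assert ip.phylo_beta(example_tree, {"A", "B"}, {"A", "B"}) == pytest.approx(0.0)

    def test_worked_example(self, example_tree):
        assert ip.phylosor(example_tree, {"A", "B"}, {"A", "C"}) == pytest.approx(4 / 7)

    def test_disjoint_clades_reach_full_turnover(self, example_tree):
        # zero-length root edge -> no shared length between the two cherries
        assert ip.phylosor(example_tree, {"A", "B"}, {"C", "D"}) == pytest.approx(0.0)
        assert ip.phylo_beta(example_tree, {"A", "B"}, {"C", "D"}) == pytest.approx(1.0)

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(14)
        tree = random_tree(rng, 20, jitter=True)
        tm = ip.TreeMetrics(tree)
        labels = sorted(tree.tip_labels)
        for _ in range(20):
            a = set(rng.choice(labels, size=int(rng.integers(1, 10)), replace=False))
            b = set(rng.choice(labels, size=int(rng.integers(1, 10)), replace=False))
            s_ab, s_ba = ip.phylosor(tm, a, b), ip.phylosor(tm, b, a)
            assert s_ab == pytest.approx(s_ba)
            assert 0.0 <= s_ab <= 1.0 + 1e-12

    def test_shared_length_bounded_by_pd(self):
        rng = np.random.default_rng(15)
        tree = random_tree(rng, 12, jitter=True)
        oracle = EdgeOracle(ip.write_newick(tree, precision=10))
        labels = sorted(tree.tip_labels)
        for _ in range(15):
            a = set(rng.choice(labels, size=4, replace=False))
            b = set(rng.choice(labels, size=5, replace=False))
            shared = oracle.shared_length(a, b)
            assert shared <= min(oracle.pd(a), oracle.pd(b)) + 1e-12
        # equality iff one spanning subtree nests in the other
        nested = set(list(a)[:2])
        assert oracle.shared_length(nested, a) == pytest.approx(oracle.pd(nested))

    def test_oracle_agreement_small_trees(self):
        rng = np.random.default_rng(16)
        tree = random_tree(rng, 7, jitter=True)
        oracle = EdgeOracle(ip.write_newick(tree, precision=10))
        tm = ip.TreeMetrics(tree)
        labels = sorted(tree.tip_labels)
        subsets = [
            set(c)
            for r in (1, 2, 3)
            for c in itertools.combinations(labels, r)
        ]
        for a, b in itertools.combinations(subsets, 2):
            assert ip.phylosor(tm, a, b) == pytest.approx(
                oracle.phylosor(a, b), rel=1e-9
            )


class TestSESPhylosor:
    def test_identical_assemblages_degenerate(self, balanced64):
        taxa = {f"t{i:03d}" for i in range(10)}
        res = ip.ses_phylosor(balanced64, taxa, taxa, n_rand=49, rng_seed=1)
        assert res.degenerate and res.ses is None

    def test_disjoint_clades_exceed_chance(self, balanced64):
        left = {f"t{i:03d}" for i in range(16)}
        right = {f"t{i:03d}" for i in range(32, 48)}
        hits = 0
        for seed in range(20):
            res = ip.ses_phylosor(balanced64, left, right, n_rand=199,
                                  rng_seed=seed)
            hits += res.ses is not None and res.ses > 1.96
        assert hits >= 19  # construction maximizes unshared branch length


class TestTemporalBeta:
    def test_no_change_system_is_degenerate_zero(self):
        config = ip.SimConfig(
            native_pool_size=60, exotic_pool_size=10,
            occupancy_probability=0.4,
            extinction_fraction=0.0, introduction_count=0,
            rng_seed=2,
        )
        tree, matrix = ip.simulate_system(config)
        res = ip.temporal_beta(tree, matrix)
        assert all(v == pytest.approx(0.0) for v in res.values)
        assert res.ttest.degenerate

    def test_introductions_add_unshared_branches(self):
        config = ip.SimConfig(rng_seed=7)  # heavy default introductions
        tree, matrix = ip.simulate_system(config)
        tm = ip.TreeMetrics(tree)
        complete = ip.temporal_beta(tm, matrix, "complete")
        natives = ip.temporal_beta(tm, matrix, "native_only")
        assert complete.mean > natives.mean
        assert len(complete.values) == 6
        assert all(0.0 <= v <= 1.0 for v in complete.values)


class TestGeography:
    def test_zero_and_antipodal(self):
        a = ip.IslandMeta("a", 10.0, 20.0)
        assert ip.great_circle_km(a, a) == 0.0
        b = ip.IslandMeta("b", -10.0, -160.0)
        assert ip.great_circle_km(a, b) == pytest.approx(math.pi * 6371, rel=1e-6)

    def test_desventuradas_pair(self):
        felix = ip.IslandMeta("San Felix", -26.283, -80.083)
        ambrosio = ip.IslandMeta("San Ambrosio", -26.333, -79.883)
        assert ip.great_circle_km(felix, ambrosio) == pytest.approx(21, abs=1.0)


class TestMantel:
    def _random_distance(self, rng, n=6):
        m = np.zeros((n, n))
        iu = np.triu_indices(n, k=1)
        vals = rng.random(len(iu[0]))
        m[iu] = vals
        return m + m.T

    def test_self_correlation(self):
        rng = np.random.default_rng(30)
        x = self._random_distance(rng)
        res = ip.mantel(x, x, n_perm=199, rng_seed=1)
        assert res.r == pytest.approx(1.0)
        assert res.p <= 0.05

    def test_anti_ordered(self):
        rng = np.random.default_rng(31)
        x = self._random_distance(rng)
        # y = c - x off-diagonally is a perfectly decreasing transform
        y = x.max() + 1 - x
        np.fill_diagonal(y, 0)
        res = ip.mantel(x, y, n_perm=99, rng_seed=1)
        assert res.r == pytest.approx(-1.0)

    def test_zero_variance_flagged(self):
        x = np.ones((4, 4)) - np.eye(4)
        y = np.arange(16.0).reshape(4, 4)
        y = (y + y.T) / 2
        np.fill_diagonal(y, 0)
        assert ip.mantel(x, y, n_perm=9, rng_seed=0).degenerate

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(33)
        x, y = self._random_distance(rng), self._random_distance(rng)
        a = ip.mantel(x, y, n_perm=199, rng_seed=5)
        b = ip.mantel(x, y, n_perm=199, rng_seed=5)
        assert (a.r, a.p) == (b.r, b.p)

    def test_r_agrees_with_skbio(self):
        from skbio import DistanceMatrix as skbio_distance
        from skbio.stats.distance import mantel as skbio_mantel

        rng = np.random.default_rng(34)
        for _ in range(5):
            x, y = self._random_distance(rng), self._random_distance(rng)
            ours = ip.mantel(x, y, n_perm=99, rng_seed=0)
            r_ref, _, _ = skbio_mantel(
                skbio_distance(x), skbio_distance(y), permutations=0
            )
            assert ours.r == pytest.approx(float(r_ref), rel=1e-9)
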