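"""Newick round-trips, grafting and pruning."""

import itertools

import numpy as np
import pytest

import islephylo as ip
from conftest import EXAMPLE_NEWICK, EdgeOracle, canonical, random_tree


class TestParse:
    def test_counts_and_total_length(self, example_tree):
        assert example_tree.n_tips == 4
        assert example_tree.n_internal == 3
        assert example_tree.total_length() == pytest.approx(6.0)
        assert example_tree.tip_labels == {"A", "B", "C", "D"}

    def test_single_tip_without_length(self):
        tree = ip.parse_newick("(A);")
        assert tree.tip_labels == {"A"}
        assert tree.tip("A").length is None

    def test_internal_labels_preserved(self):
        tree = ip.parse_newick("((A:1,B:1)Poaceae:1,C:2)root;")
        assert [n.name for n in tree.find_nodes("Poaceae")] == ["Poaceae"]
        assert tree.root.name == "root"

    def test_underscores_literal_and_quoting(self):
        tree = ip.parse_newick("('Genus species':1,Genus_epithet:1):0;")
        assert tree.tip_labels == {"Genus species", "Genus_epithet"}
        again = ip.parse_newick(ip.write_newick(tree))
        assert again.tip_labels == tree.tip_labels

    @pytest.mark.parametrize("bad", ["((A,B);", "(A,B))", "", "(A:1,:2);"])
    def test_malformed_raises_parse_error(self, bad):
        with pytest.raises((ip.NewickParseError, ip.TreeValidationError)):
            ip.parse_newick(bad)

    def test_duplicate_tip_labels_rejected(self):
        with pytest.raises(ip.TreeValidationError):
            ip.parse_newick("((A:1,A:1):1,B:2);")


class TestWrite:
    def test_unset_lengths_omitted_not_zero(self):
        tree = ip.parse_newick("((A,B),C);")
        text = ip.write_newick(tree)
        assert ":" not in text  # absence of a length is not length 0

    def test_round_trip_identity(self):
        rng = np.random.default_rng(21)
        for n in (2, 5, 9, 33):
            tree = random_tree(rng, n, jitter=True)
            again = ip.parse_newick(ip.write_newick(tree))
            assert canonical(again, 6) == canonical(tree, 6)

    def test_round_trip_preserves_internal_names(self):
        tree = ip.parse_newick("((A:1,B:1)fam:1,(C:1,D:1):1)ord:0;")
        again = ip.parse_newick(ip.write_newick(tree))
        assert canonical(again) == canonical(tree)


class TestGraft:
    def test_single_tip_under_named_node(self):
        tree = ip.parse_newick("((A:1,B:1)Poaceae:1,C:2)r;")
        before_children = len(tree.find_nodes("Poaceae")[0].children)
        out = ip.graft(tree, "Poaceae", ip.parse_newick("(X);"))
        assert out.n_tips == tree.n_tips + 1
        assert len(out.find_nodes("Poaceae")[0].children) == before_children + 1

    def test_clade_under_root(self, example_tree):
        tree = ip.parse_newick("((A:1,B:1):1,(C:1,D:1):1)r:0;")
        sub = ip.parse_newick("((X:1,Y:1):1,Z:2);")
        assert ip.graft(tree, "r", sub).n_tips == 7

    def test_graft_then_prune_is_identity(self, example_tree):
        tree = ip.parse_newick("((A:1,B:1):1,(C:1,D:1)cd:1)r:0;")
        sub = ip.parse_newick("(X:1,Y:1):2;")
        grafted = ip.graft(tree, "cd", sub)
        back = ip.prune_to(grafted, tree.tip_labels)
        assert canonical(back) == canonical(tree)

    def test_missing_and_colliding_names(self, example_tree):
        with pytest.raises(ip.MissingTaxonError):
            ip.graft(example_tree, "nope", ip.parse_newick("(X);"))
        with pytest.raises(ip.TreeValidationError):
            ip.graft(
                ip.parse_newick("((A:1,B:1)n:1,C:2);"), "n", ip.parse_newick("(A);")
            )


class TestPrune:
    def test_identity_case(self, example_tree):
        out = ip.prune_to(example_tree, {"A", "B", "C", "D"})
        assert canonical(out) == canonical(example_tree)

    def test_collapsed_path_lengths(self, example_tree):
        out = ip.prune_to(example_tree, {"A", "C"})
        assert out.tip_labels == {"A", "C"}
        assert out.pairwise_distance("A", "C") == pytest.approx(4.0)

    def test_total_length_monotone(self):
        rng = np.random.default_rng(5)
        tree = random_tree(rng, 12, jitter=True)
        labels = sorted(tree.tip_labels)
        for k in (1, 3, 8):
            kept = set(rng.choice(labels, size=k, replace=False))
            assert ip.prune_to(tree, kept).total_length() <= tree.total_length() + 1e-9

    def test_preserves_pairwise_distances(self):
        rng = np.random.default_rng(7)
        for n in (4, 9, 16):
            tree = random_tree(rng, n, jitter=True)
            oracle = EdgeOracle(ip.write_newick(tree, precision=10))
            labels = sorted(tree.tip_labels)
            kept = sorted(rng.choice(labels, size=max(2, n // 2), replace=False))
            pruned = ip.prune_to(tree, kept)
            for a, b in itertools.combinations(kept, 2):
                assert pruned.pairwise_distance(a, b) == pytest.approx(
                    oracle.dist[(a, b)], rel=1e-6
                )

    def test_root_retained_for_root_inclusive_pd(self, example_tree):
        pruned = ip.prune_to(example_tree, {"A"})
        # tip edge (1) + collapsed stem to root (1) + root edge (0)
        assert pruned.total_length() == pytest.approx(2.0)
        assert ip.faith_pd(example_tree, {"A"}) == pytest.approx(
            ip.faith_pd(pruned, {"A"})
        )

    def test_unknown_taxa_listed(self, example_tree):
        with pytest.raises(ip.MissingTaxonError) as err:
            ip.prune_to(example_tree, {"A", "Q", "Z"})
        assert "Q" in str(err.value) and "Z" in str(err.value)

    def test_empty_set_rejected(self, example_tree):
        with pytest.raises(ip.TreeValidationError):
            ip.prune_to(example_tree, set())
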