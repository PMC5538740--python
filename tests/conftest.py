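"""Shared fixtures and independent oracles for the test suite.

Oracles deliberately bypass the package's own tree machinery: Newick
strings are re-parsed with dendropy and the indices are recomputed by
explicit edge-set / path enumeration, so agreement is a genuine
two-route check.
"""

from __future__ import annotations

import itertools

import dendropy
import numpy as np
import pytest

import islephylo as ip

EXAMPLE_NEWICK = "((A:1,B:1):1,(C:1,D:1):1):0;"


@pytest.fixture
def example_tree() -> ip.Phylogeny:
    """The worked 4-tip tree: two cherries of depth 2, root edge length 0."""
    return ip.parse_newick(EXAMPLE_NEWICK)


@pytest.fixture
def balanced64() -> ip.Phylogeny:
    """Balanced ultrametric 64-tip tree, unit edges (depth 6)."""
    return ip.parse_newick(balanced_newick(64))


def balanced_newick(n_tips: int, length: float = 1.0) -> str:
    labels = [f"t{i:03d}" for i in range(n_tips)]

    def build(lo: int, hi: int) -> str:
        if hi - lo == 1:
            return f"{labels[lo]}:{length:g}"
        mid = (lo + hi) // 2
        return f"({build(lo, mid)},{build(mid, hi)}):{length:g}"

    return build(0, n_tips)[: -len(f":{length:g}")] + ";"


def random_tree(rng: np.random.Generator, n_tips: int, jitter: bool = False) -> ip.Phylogeny:
    """Random seeded tree; optionally non-ultrametric (jittered lengths)."""
    tree = ip.yule_tree(rng, n_tips=n_tips, root_age=10.0)
    if jitter:
        for node in tree.iter_postorder():
            if node.length is not None:
                node.length = float(node.length * rng.uniform(0.2, 2.0))
    return tree


def canonical(tree: ip.Phylogeny, precision: int = 9):
    """Order-independent structural fingerprint (topology, labels, lengths)."""

    def rec(node):
        length = None if node.length is None else round(node.length, precision)
        if node.is_leaf:
            return (node.name, length)
        children = tuple(sorted((rec(c) for c in node.children), key=repr))
        return (children, node.name, length)

    return rec(tree.root)


# -- dendropy-based oracles ------------------------------------------------


class EdgeOracle:
    """Brute-force index computation from explicit edge enumeration."""

    def __init__(self, newick: str):
        self._dtree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
        self.edges: list[tuple[frozenset, float]] = []
        for node in self._dtree.postorder_node_iter():
            below = frozenset(
                leaf.taxon.label for leaf in node.leaf_iter() if leaf.taxon
            )
            if node.edge.length is not None:
                self.edges.append((below, float(node.edge.length)))
        self.tip_labels = sorted(
            t.label for t in self._dtree.taxon_namespace
            if any(l.taxon is t for l in self._dtree.leaf_node_iter())
        )
        pdm = self._dtree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in self._dtree.taxon_namespace}
        self.dist = {
            (a, b): float(pdm.patristic_distance(taxa[a], taxa[b]))
            for a, b in itertools.product(self.tip_labels, repeat=2)
        }

    def pd(self, taxa) -> float:
        taxa = set(taxa)
        return sum(l for below, l in self.edges if below & taxa)

    def mpd(self, taxa) -> float:
        pairs = list(itertools.combinations(sorted(taxa), 2))
        return sum(self.dist[p] for p in pairs) / len(pairs)

    def mntd(self, taxa) -> float:
        taxa = sorted(taxa)
        return float(
            np.mean(
                [min(self.dist[(a, b)] for b in taxa if b != a) for a in taxa]
            )
        )

    def shared_length(self, a, b) -> float:
        a, b = set(a), set(b)
        return sum(l for below, l in self.edges if below & a and below & b)

    def phylosor(self, a, b) -> float:
        return 2.0 * self.shared_length(a, b) / (self.pd(a) + self.pd(b))
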