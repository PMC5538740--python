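"""Phylogenetic alpha diversity: Faith's PD, MPD and MNTD.

All three indices are presence-based (no abundance weighting) and are
computed on the full regional chronogram; pruning the tree to an
assemblage first would give identical values because pruning preserves
patristic distances and the root-inclusive spanning subtree.

Conventions
-----------
* **PD is root-inclusive**: the minimal spanning subtree connecting an
  assemblage always includes the path to the root, so PD of a single
  species is its root path length and PD is monotone under adding taxa.
* MPD and MNTD require at least two species; they are means over unordered
  pairs and over per-species nearest neighbours, respectively, in units of
  millions of years for a chronogram.
* Species present in the occurrence data but absent from the tree are an
  error by default; ``skip_missing=True`` drops them (reported via
  ``n_matched``) for exploratory use.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .treeio import MissingTaxonError, Phylogeny

__all__ = [
    "AlphaResult",
    "TreeMetrics",
    "pairwise_distance",
    "faith_pd",
    "mpd",
    "mntd",
    "alpha_diversity",
]


@dataclass(frozen=True)
class AlphaResult:
    """PD/MPD/MNTD of one assemblage (MPD/MNTD are None below 2 species)."""

    pd: float
    mpd: float | None
    mntd: float | None
    n_species: int
    n_matched: int


class TreeMetrics:
    """Cached per-tree arrays for fast repeated index evaluation.

    Builds, once per tree: the tip order and patristic distance matrix, and
    per-node branch lengths with tip incidence (which tips descend from each
    node's edge).  PD of any tip subset is then a masked sum over edges, and
    MPD/MNTD are submatrix reductions — cheap enough for 999-fold null
    distributions.
    """

    def __init__(self, tree: Phylogeny):
        self.tree = tree
        self.tip_labels, self.dist = tree.tip_distance_matrix()
        self.index = {name: i for i, name in enumerate(self.tip_labels)}
        n = len(self.tip_labels)
        nodes = list(tree.iter_postorder())
        self.edge_lengths = np.array(
            [node.length if node.length is not None else 0.0 for node in nodes]
        )
        incidence = np.zeros((len(nodes), n), dtype=bool)
        pos = {node.uid: k for k, node in enumerate(nodes)}
        for k, node in enumerate(nodes):
            if node.is_leaf:
                incidence[k, self.index[node.name]] = True
            else:
                for child in node.children:
                    incidence[k] |= incidence[pos[child.uid]]
        self.incidence = incidence  # (n_nodes, n_tips): tips below each edge

    # -- index lookup ------------------------------------------------------

    def indices(self, taxa: Iterable[str]) -> np.ndarray:
        taxa = list(taxa)
        missing = [t for t in taxa if t not in self.index]
        if missing:
            raise MissingTaxonError(missing)
        return np.fromiter((self.index[t] for t in taxa), dtype=int, count=len(taxa))

    # -- metrics on integer tip subsets -----------------------------------

    def pd_idx(self, idx: np.ndarray) -> float:
        covered = self.incidence[:, idx].any(axis=1)  # edge on a member's root path
        return float(self.edge_lengths[covered].sum())

    def spanning_edges_idx(self, idx: np.ndarray) -> np.ndarray:
        """Boolean mask over postorder nodes whose edges the subset spans."""
        return self.incidence[:, idx].any(axis=1)

    def mpd_idx(self, idx: np.ndarray) -> float:
        sub = self.dist[np.ix_(idx, idx)]
        k = len(idx)
        return float(sub.sum() / (k * (k - 1)))

    def mntd_idx(self, idx: np.ndarray) -> float:
        sub = self.dist[np.ix_(idx, idx)].copy()
        np.fill_diagonal(sub, np.inf)
        return float(sub.min(axis=1).mean())

    def metric_idx(self, metric: str, idx: np.ndarray) -> float:
        if metric == "pd":
            return self.pd_idx(idx)
        if metric == "mpd":
            return self.mpd_idx(idx)
        if metric == "mntd":
            return self.mntd_idx(idx)
        raise ValueError(f"unknown metric {metric!r} (use pd, mpd or mntd)")


def _resolve(
    tree_or_metrics: Phylogeny | TreeMetrics,
) -> TreeMetrics:
    if isinstance(tree_or_metrics, TreeMetrics):
        return tree_or_metrics
    return TreeMetrics(tree_or_metrics)


def pairwise_distance(tree: Phylogeny, a: str, b: str) -> float:
    """Patristic distance (branch-length sum on the path) between two tips."""
    return tree.pairwise_distance(a, b)


def faith_pd(tree: Phylogeny | TreeMetrics, taxa: Iterable[str]) -> float:
    """Root-inclusive Faith's PD: total branch length of the minimal subtree
    connecting ``taxa`` and the root."""
    tm = _resolve(tree)
    taxa = set(taxa)
    if not taxa:
        raise ValueError("faith_pd: empty assemblage")
    return tm.pd_idx(tm.indices(taxa))


def mpd(tree: Phylogeny | TreeMetrics, taxa: Iterable[str]) -> float:
    """Mean patristic distance over all unordered species pairs."""
    tm = _resolve(tree)
    taxa = set(taxa)
    if len(taxa) < 2:
        raise ValueError("mpd requires at least 2 species")
    return tm.mpd_idx(tm.indices(taxa))


def mntd(tree: Phylogeny | TreeMetrics, taxa: Iterable[str]) -> float:
    """Mean distance from each species to its nearest co-occurring relative."""
    tm = _resolve(tree)
    taxa = set(taxa)
    if len(taxa) < 2:
        raise ValueError("mntd requires at least 2 species")
    return tm.mntd_idx(tm.indices(taxa))


def alpha_diversity(
    tree: Phylogeny | TreeMetrics,
    taxa: Iterable[str],
    skip_missing: bool = False,
) -> AlphaResult:
    """PD, MPD and MNTD of one assemblage against the regional tree."""
    tm = _resolve(tree)
    taxa = set(taxa)
    if not taxa:
        raise ValueError("empty assemblage")
    matched = taxa & set(tm.index)
    if len(matched) < len(taxa):
        if not skip_missing:
            raise MissingTaxonError(taxa - matched)
        if not matched:
            raise MissingTaxonError(taxa)
    idx = tm.indices(matched)
    return AlphaResult(
        pd=tm.pd_idx(idx),
        mpd=tm.mpd_idx(idx) if len(idx) >= 2 else None,
        mntd=tm.mntd_idx(idx) if len(idx) >= 2 else None,
        n_species=len(taxa),
        n_matched=len(matched),
    )
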