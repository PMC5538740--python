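"""Rooted phylogenies: container, Newick I/O, grafting and pruning.

The container is deliberately small: a rooted tree of :class:`Node` objects
with optional names, optional nonnegative branch lengths (millions of years
throughout this package) and an optional node age used by the calibration
module.  Newick parsing is delegated to :mod:`dendropy`; writing is done
directly so that unset branch lengths are omitted rather than serialized
as zero.

Conventions follow the megatree dialect: underscores in labels are literal
(never converted to spaces) and single-quoted labels are honoured.  Internal
node names (family/order labels) are preserved verbatim because they are the
attachment points for grafting.
"""

from __future__ import annotations

import itertools
import re
from typing import Iterable, Iterator, Mapping

import dendropy
import numpy as np

__all__ = [
    "TreeError",
    "NewickParseError",
    "TreeValidationError",
    "MissingTaxonError",
    "Node",
    "Phylogeny",
    "parse_newick",
    "write_newick",
    "graft",
    "prune_to",
    "read_newick_file",
    "write_newick_file",
]


class TreeError(ValueError):
    """Base class for phylogeny errors."""


class NewickParseError(TreeError):
    """Malformed Newick input."""


class TreeValidationError(TreeError):
    """Structurally invalid phylogeny (duplicate/empty tips, bad lengths...)."""


class MissingTaxonError(TreeError, KeyError):
    """A requested taxon or node name is absent from the tree."""

    def __init__(self, missing: Iterable[str], context: str = "tree"):
        self.missing = sorted(missing)
        super().__init__(f"names not found in {context}: {', '.join(self.missing)}")

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message
        return self.args[0]


_uid_counter = itertools.count()


class Node:
    """A tree node: name, branch length to parent, children, optional age."""

    __slots__ = ("name", "length", "age", "parent", "children", "uid")

    def __init__(self, name: str | None = None, length: float | None = None):
        if length is not None and length < 0:
            raise TreeValidationError(f"negative branch length {length!r} on {name!r}")
        self.name = name
        self.length = length
        self.age: float | None = None
        self.parent: Node | None = None
        self.children: list[Node] = []
        self.uid = next(_uid_counter)  # stable id, never serialized

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def __repr__(self) -> str:
        kind = "tip" if self.is_leaf else f"internal({len(self.children)})"
        return f"<Node {self.name!r} {kind} length={self.length}>"


class Phylogeny:
    """A rooted phylogeny with unique, nonempty tip labels."""

    def __init__(self, root: Node):
        self.root = root
        self._reindex()

    # -- construction / validation -------------------------------------

    def _reindex(self) -> None:
        tips: dict[str, Node] = {}
        n_nodes = 0
        for node in self.iter_postorder():
            n_nodes += 1
            if node.is_leaf:
                if not node.name:
                    raise TreeValidationError("tip with empty label")
                if node.name in tips:
                    raise TreeValidationError(f"duplicate tip label {node.name!r}")
                tips[node.name] = node
            if node.length is not None and node.length < 0:
                raise TreeValidationError(
                    f"negative branch length on {node.name!r}"
                )
        if self.root.parent is not None:
            raise TreeValidationError("root must not have a parent")
        self._tips = tips
        self.n_nodes = n_nodes

    # -- traversal ------------------------------------------------------

    def iter_postorder(self) -> Iterator[Node]:
        stack: list[tuple[Node, bool]] = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                yield node
            else:
                stack.append((node, True))
                stack.extend((c, False) for c in reversed(node.children))

    def iter_preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def iter_tips(self) -> Iterator[Node]:
        return (n for n in self.iter_postorder() if n.is_leaf)

    # -- basic queries ---------------------------------------------------

    @property
    def tip_labels(self) -> set[str]:
        return set(self._tips)

    @property
    def n_tips(self) -> int:
        return len(self._tips)

    @property
    def n_internal(self) -> int:
        return self.n_nodes - self.n_tips

    def tip(self, name: str) -> Node:
        try:
            return self._tips[name]
        except KeyError:
            raise MissingTaxonError([name]) from None

    def find_nodes(self, name: str) -> list[Node]:
        return [n for n in self.iter_preorder() if n.name == name]

    def total_length(self) -> float:
        """Sum of all set branch lengths, the root edge included."""
        return float(
            sum(n.length for n in self.iter_postorder() if n.length is not None)
        )

    def has_full_lengths(self) -> bool:
        return all(
            n.length is not None for n in self.iter_postorder() if n is not self.root
        )

    def _require_lengths(self) -> None:
        missing = [
            n.name or f"node#{n.uid}"
            for n in self.iter_postorder()
            if n is not self.root and n.length is None
        ]
        if missing:
            raise TreeValidationError(
                f"branch lengths unset on: {', '.join(missing[:5])}"
                + ("..." if len(missing) > 5 else "")
            )

    def copy(self) -> "Phylogeny":
        return Phylogeny(_copy_subtree(self.root))

    # -- editing ---------------------------------------------------------

    def graft(self, attachment_node_name: str, subtree: "Phylogeny") -> "Phylogeny":
        """Attach a copy of ``subtree`` as a new child of the named node.

        Returns a new tree; neither input is modified.  The attachment name
        must occur exactly once; subtree tip labels must be disjoint from
        this tree's.
        """
        overlap = self.tip_labels & subtree.tip_labels
        if overlap:
            raise TreeValidationError(
                f"graft would duplicate tip labels: {sorted(overlap)[:5]}"
            )
        new = self.copy()
        hits = new.find_nodes(attachment_node_name)
        if not hits:
            raise MissingTaxonError([attachment_node_name], "attachment points")
        if len(hits) > 1:
            raise TreeValidationError(
                f"ambiguous attachment name {attachment_node_name!r} "
                f"({len(hits)} matches)"
            )
        hits[0].add_child(_copy_subtree(subtree.root))
        return Phylogeny(new.root)

    def prune_to(self, taxa: Iterable[str]) -> "Phylogeny":
        """Restrict the tree to ``taxa``.

        Degree-2 internal nodes created by pruning are collapsed with branch
        lengths summed, so all pairwise tip path lengths are preserved.  The
        root is always retained, even when it ends up with a single child:
        the edge above the basal retained node is kept, so root-inclusive PD
        on the pruned tree equals PD on the original.
        """
        keep = set(taxa)
        if not keep:
            raise TreeValidationError("cannot prune to an empty taxon set")
        missing = keep - self.tip_labels
        if missing:
            raise MissingTaxonError(missing)
        root = _copy_subtree(self.root)

        def prune(node: Node) -> Node | None:
            if node.is_leaf:
                return node if node.name in keep else None
            kept = []
            for child in node.children:
                sub = prune(child)
                if sub is not None:
                    kept.append(sub)
            if not kept:
                return None
            if len(kept) == 1 and node.parent is not None:
                # splice: child absorbs this node's edge
                (child,) = kept
                if node.length is not None or child.length is not None:
                    child.length = (node.length or 0.0) + (child.length or 0.0)
                child.parent = node.parent
                return child
            node.children = kept
            for c in kept:
                c.parent = node
            return node

        pruned = prune(root)
        assert pruned is not None  # keep is nonempty and validated
        pruned.parent = None
        return Phylogeny(pruned)

    # -- distances -------------------------------------------------------

    def tip_distance_matrix(self) -> tuple[list[str], np.ndarray]:
        """Patristic distance matrix over tips, in a stable postorder.

        Requires branch lengths on all non-root edges.  The root edge never
        lies on a tip-to-tip path and is ignored.
        """
        self._require_lengths()
        labels = [t.name for t in self.iter_tips()]
        index = {name: i for i, name in enumerate(labels)}
        n = len(labels)
        dist = np.zeros((n, n))
        # postorder merge: carry (tip index, distance to current node) lists
        carry: dict[int, list[tuple[int, float]]] = {}
        for node in self.iter_postorder():
            if node.is_leaf:
                carry[node.uid] = [(index[node.name], 0.0)]
            else:
                lists = []
                for child in node.children:
                    lst = carry.pop(child.uid)
                    edge = child.length or 0.0
                    lists.append([(i, d + edge) for i, d in lst])
                for la, lb in itertools.combinations(lists, 2):
                    for i, di in la:
                        for j, dj in lb:
                            dist[i, j] = dist[j, i] = di + dj
                carry[node.uid] = [pair for lst in lists for pair in lst]
        return labels, dist

    def pairwise_distance(self, a: str, b: str) -> float:
        """Branch-length sum on the path between tips ``a`` and ``b``."""
        if a == b:
            self.tip(a)
            return 0.0
        na, nb = self.tip(a), self.tip(b)
        self._require_lengths()
        depth: dict[int, float] = {}
        anc: dict[int, Node] = {}
        node: Node | None = na
        d = 0.0
        while node is not None:
            depth[node.uid] = d
            anc[node.uid] = node
            d += node.length or 0.0
            node = node.parent
        node, d = nb, 0.0
        while node is not None:
            if node.uid in depth:
                return d + depth[node.uid]
            d += node.length or 0.0
            node = node.parent
        raise TreeError("tips are not connected")  # pragma: no cover

    def is_ultrametric(self, tol: float = 1e-9) -> bool:
        depths = []
        stack = [(self.root, 0.0)]
        while stack:
            node, d = stack.pop()
            if node.is_leaf:
                depths.append(d)
            for c in node.children:
                stack.append((c, d + (c.length or 0.0)))
        return max(depths) - min(depths) <= tol

    # -- serialization ---------------------------------------------------

    def to_newick(self, precision: int = 6) -> str:
        return _write_node(self.root, precision) + ";"

    def __repr__(self) -> str:
        return f"<Phylogeny {self.n_tips} tips, {self.n_internal} internal nodes>"


def _copy_subtree(node: Node) -> Node:
    new = Node(node.name, node.length)
    new.age = node.age
    for child in node.children:
        new.add_child(_copy_subtree(child))
    return new


_SAFE_LABEL = re.compile(r"^[^\s()\[\]{}:;,'\"]+$")


def _fmt_label(name: str) -> str:
    if _SAFE_LABEL.match(name):
        return name
    return "'" + name.replace("'", "''") + "'"


def _fmt_length(length: float, precision: int) -> str:
    s = f"{length:.{precision}f}".rstrip("0").rstrip(".")
    return s or "0"


def _write_node(node: Node, precision: int) -> str:
    if node.is_leaf:
        s = _fmt_label(node.name or "")
    else:
        inner = ",".join(_write_node(c, precision) for c in node.children)
        s = f"({inner})" + (_fmt_label(node.name) if node.name else "")
    if node.length is not None:
        s += ":" + _fmt_length(node.length, precision)
    return s


# -- module-level operations (the public surface used by the pipeline) ----


def parse_newick(text: str) -> Phylogeny:
    """Parse a single rooted Newick tree.

    Unlabelled internal nodes receive stable autogenerated ids (``Node.uid``)
    that are never serialized.  Malformed input raises
    :class:`NewickParseError` with the parser's position information;
    duplicate tip labels raise :class:`TreeValidationError`.
    """
    if not text or not text.strip():
        raise NewickParseError("empty Newick string")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=False,
        )
    except Exception as exc:  # dendropy raises several error classes
        msg = str(exc)
        if "uplicate" in msg:
            raise TreeValidationError(msg) from exc
        raise NewickParseError(msg) from exc

    def convert(dnode: dendropy.Node) -> Node:
        name = None
        if dnode.taxon is not None:
            name = dnode.taxon.label
        elif dnode.label:
            name = dnode.label
        node = Node(name, dnode.edge.length)
        for dchild in dnode.child_nodes():
            node.add_child(convert(dchild))
        return node

    return Phylogeny(convert(dtree.seed_node))


def write_newick(tree: Phylogeny, precision: int = 6) -> str:
    """Serialize to Newick; unset branch lengths are omitted, not written as 0."""
    return tree.to_newick(precision=precision)


def graft(tree: Phylogeny, attachment_node_name: str, subtree: Phylogeny) -> Phylogeny:
    return tree.graft(attachment_node_name, subtree)


def prune_to(tree: Phylogeny, taxa: Iterable[str]) -> Phylogeny:
    return tree.prune_to(taxa)


def read_newick_file(path) -> Phylogeny:
    with open(path) as fh:
        return parse_newick(fh.read())


def write_newick_file(tree: Phylogeny, path, precision: int = 6) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick(precision=precision) + "\n")
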