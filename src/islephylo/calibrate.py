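"""BLADJ-style node-age calibration.

Given a rooted topology and a table of fixed node ages (millions of years),
the algorithm fixes the listed nodes, sets every tip to age 0, and spaces
undated internal nodes evenly along the paths between consecutive dated
nodes.  Branch lengths of the output chronogram are parent age minus child
age, so the result is ultrametric whenever the topology admits it (it always
does for extant tips, which is the assumption here).

Even spacing: for a maximal chain of ``u`` undated nodes between a dated
ancestor (age ``a``) and the nearest dated descendant or tip (age ``b``),
the j-th node from the ancestor gets age ``a - j * (a - b) / (u + 1)``.

When an undated node has several dated descendants, its age is taken from
the path with the fewest intervening nodes, with older calibration points
resolved before younger ones so that deep fixed ages are never overridden
by nearer-but-younger constraints (which would invert ages).
"""

from __future__ import annotations

import csv
import heapq
from typing import Mapping

from .treeio import (
    MissingTaxonError,
    Node,
    Phylogeny,
    TreeValidationError,
)

__all__ = ["CalibrationError", "bladj", "read_age_table", "write_age_table"]


class CalibrationError(TreeValidationError):
    """Inconsistent or insufficient age constraints."""


def read_age_table(path) -> dict[str, float]:
    """Read a two-column ``node_name,age`` CSV (header optional)."""
    ages: dict[str, float] = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            if not row or row[0].startswith("#"):
                continue
            name, raw = row[0].strip(), row[1].strip()
            try:
                age = float(raw)
            except ValueError:
                if name.lower() in ("node_name", "node", "name"):
                    continue  # header row
                raise CalibrationError(f"non-numeric age {raw!r} for {name!r}")
            if name in ages:
                raise CalibrationError(f"duplicate node name {name!r} in age table")
            ages[name] = age
    return ages


def write_age_table(ages: Mapping[str, float], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["node_name", "age"])
        for name, age in ages.items():
            writer.writerow([name, f"{age:g}"])


def bladj(tree: Phylogeny, ages: Mapping[str, float]) -> Phylogeny:
    """Calibrate ``tree`` against the age table; returns a new chronogram.

    The root must be dated (named in the table).  Tips are implicitly dated
    at 0 and may appear in the table only with age 0.  A dated descendant
    older than a dated ancestor is a validation error naming both nodes.
    """
    for name, age in ages.items():
        if age < 0:
            raise CalibrationError(f"negative age {age} for node {name!r}")
    out = tree.copy()

    by_name: dict[str, list[Node]] = {}
    for node in out.iter_preorder():
        if node.name:
            by_name.setdefault(node.name, []).append(node)
    missing = [n for n in ages if n not in by_name]
    if missing:
        raise MissingTaxonError(missing, "tree (age table)")
    ambiguous = [n for n in ages if len(by_name[n]) > 1]
    if ambiguous:
        raise CalibrationError(f"age table names are not unique in tree: {ambiguous}")

    dated: dict[int, float] = {}  # node uid -> age
    named: dict[int, str] = {}
    for node in out.iter_postorder():
        node.age = None
        if node.is_leaf:
            listed = ages.get(node.name or "")
            if listed not in (None, 0, 0.0):
                raise CalibrationError(
                    f"tip {node.name!r} given nonzero age {listed} "
                    "(tips are extant, age 0)"
                )
            dated[node.uid] = 0.0
        elif node.name and node.name in ages:
            dated[node.uid] = float(ages[node.name])
            named[node.uid] = node.name
    if out.root.uid not in dated:
        raise CalibrationError("root is not dated; list the root node in the age table")

    _check_inversions(out, dated, named)

    # Regions headed by dated internal nodes, processed oldest-first.
    order = {node.uid: i for i, node in enumerate(out.iter_preorder())}
    heap: list[tuple[float, int, Node]] = []
    for node in out.iter_preorder():
        if not node.is_leaf and node.uid in dated:
            heapq.heappush(heap, (-dated[node.uid], order[node.uid], node))

    while heap:
        _, _, top = heapq.heappop(heap)
        _interpolate_region(top, dated, order)

    for node in out.iter_preorder():
        node.age = dated[node.uid]
        if node.parent is not None:
            length = dated[node.parent.uid] - dated[node.uid]
            if length < -1e-9:
                raise CalibrationError(
                    f"age inversion after interpolation at {node.name or node.uid}"
                )
            node.length = max(length, 0.0)
    return Phylogeny(out.root)


def _check_inversions(out: Phylogeny, dated: dict[int, float], named: dict[int, str]):
    """A dated ancestor must be strictly older than any dated descendant."""
    # carry the nearest dated ancestor down the tree
    stack: list[tuple[Node, int | None]] = [(out.root, None)]
    while stack:
        node, anc_uid = stack.pop()
        if node.uid in dated and not node.is_leaf:
            if anc_uid is not None and dated[node.uid] >= dated[anc_uid]:
                raise CalibrationError(
                    f"age inversion: descendant {named.get(node.uid, node.uid)!r} "
                    f"(age {dated[node.uid]}) is not younger than ancestor "
                    f"{named.get(anc_uid, anc_uid)!r} (age {dated[anc_uid]})"
                )
            anc_uid = node.uid
        stack.extend((c, anc_uid) for c in node.children)


def _interpolate_region(top: Node, dated: dict[int, float], order: dict[int, int]):
    """Date every undated node between ``top`` and its nearest dated descendants."""
    # collect boundary nodes: dated nodes/tips with no dated node in between
    boundaries: list[tuple[float, int, int, list[Node]]] = []

    def descend(node: Node, path: list[Node]) -> None:
        for child in node.children:
            if child.uid in dated:
                boundaries.append(
                    (-dated[child.uid], len(path), order[child.uid], path + [child])
                )
            else:
                descend(child, path + [child])

    descend(top, [])
    # oldest boundary first, then fewest intervening nodes
    for _, _, _, path in sorted(boundaries, key=lambda b: (b[0], b[1], b[2])):
        _assign_chain(top, path, dated)


def _assign_chain(top: Node, path: list[Node], dated: dict[int, float]) -> None:
    """Evenly date undated runs along top -> ... -> path[-1] (dated)."""
    last_age = dated[top.uid]
    run: list[Node] = []
    for node in path:
        if node.uid in dated:
            b = dated[node.uid]
            for j, undated_node in enumerate(run, start=1):
                dated[undated_node.uid] = last_age - j * (last_age - b) / (len(run) + 1)
            last_age = b
            run = []
        else:
            run.append(node)
    assert not run  # path ends at a dated boundary
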