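"""Dated trees and the nested average of range overlaps at internal nodes.

The age-range-correlation (ARC) approach asks how range overlap between the
two clades descending from a node varies with node age: under purely
vicariant speciation young nodes separate allopatric ranges (overlap near
0), with overlap accumulating in older nodes only through post-speciation
range movement; under sympatric speciation young nodes already overlap.

At each internal node the overlap between the daughter clades is the
*nested average* of the pairwise species overlaps: tips are down-weighted
by 1/2 for every internal node between them and their clade root, so both
daughters of any node contribute equally at every level of the recursion.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import dendropy
import numpy as np

from .geo import OverlapMatrix

logger = logging.getLogger(__name__)

_ULTRAMETRIC_RTOL = 1e-6


@dataclass
class Node:
    """Tree node; binary internal nodes after polytomy resolution."""

    node_id: str
    age: float
    children: list["Node"]
    label: str | None = None  # species id at tips

    @property
    def is_tip(self) -> bool:
        return not self.children

    def tips(self) -> list["Node"]:
        if self.is_tip:
            return [self]
        out: list[Node] = []
        for c in self.children:
            out.extend(c.tips())
        return out


class DatedTree:
    """Rooted binary tree with ultrametric-style node ages in Ma.

    Node ages are depths below the present: every tip has age >= 0 and every
    parent is at least as old as its children.  Node ids are assigned
    deterministically by post-order index.
    """

    def __init__(self, root: Node):
        self.root = root
        labels = [t.label for t in root.tips()]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate tip labels")
        self._assign_ids()

    def _assign_ids(self) -> None:
        for i, node in enumerate(self.postorder()):
            node.node_id = f"n{i}"

    def postorder(self) -> Iterator[Node]:
        def walk(n: Node) -> Iterator[Node]:
            for c in n.children:
                yield from walk(c)
            yield n

        return walk(self.root)

    @property
    def tip_labels(self) -> list[str]:
        return [t.label for t in self.root.tips()]

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.postorder() if not n.is_tip]

    def newick(self) -> str:
        def fmt(n: Node, parent_age: float | None) -> str:
            bl = "" if parent_age is None else f":{parent_age - n.age:.12g}"
            if n.is_tip:
                return f"{n.label}{bl}"
            inner = ",".join(fmt(c, n.age) for c in n.children)
            return f"({inner}){bl}"

        return fmt(self.root, None) + ";"

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.newick() + "\n")


def _from_dendropy(dtree: dendropy.Tree) -> DatedTree:
    dtree.calc_node_ages(ultrametricity_precision=False)
    # dendropy's node age = max tip depth minus node depth, which matches
    # the ultrametric reading and the stated non-ultrametric fallback
    def conv(dnode: dendropy.Node) -> Node:
        children = [conv(c) for c in dnode.child_nodes()]
        label = dnode.taxon.label if dnode.taxon is not None else None
        return Node("", float(dnode.age), children, label=label)

    # detect non-ultrametric input: tip depths should agree
    depths = dtree.calc_node_root_distances(return_leaf_distances_only=True)
    if depths and (max(depths) - min(depths)) > _ULTRAMETRIC_RTOL * max(max(depths), 1.0):
        warnings.warn(
            "tree is not ultrametric; node ages taken as max tip depth minus "
            "node depth",
            stacklevel=3,
        )
    root = conv(dtree.seed_node)
    root = _resolve_polytomies(root)
    return DatedTree(root)


def _resolve_polytomies(node: Node) -> Node:
    """Resolve polytomies into a caterpillar of zero-length internal edges."""
    node.children = [_resolve_polytomies(c) for c in node.children]
    while len(node.children) > 2:
        logger.warning(
            "polytomy at age %.4g resolved arbitrarily into a caterpillar",
            node.age,
        )
        first_two = node.children[:2]
        rest = node.children[2:]
        sub = Node("", node.age, first_two)
        node.children = [sub] + rest
    return node


def read_tree(path: str | Path) -> DatedTree:
    """Read a newick tree with branch lengths into a :class:`DatedTree`."""
    try:
        dtree = dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"cannot parse newick file {path}: {exc}") from exc
    labels = [lf.taxon.label for lf in dtree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate tip labels in {path}")
    return _from_dendropy(dtree)


def tree_from_newick(newick: str) -> DatedTree:
    dtree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    labels = [lf.taxon.label for lf in dtree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate tip labels")
    return _from_dendropy(dtree)


def trim_to_species(tree: DatedTree, keep: Sequence[str]) -> DatedTree:
    """Induced subtree on ``keep``: unary nodes suppressed, ages preserved.

    Used to reduce a multi-accession phylogeny to one tip per species before
    computing overlaps.
    """
    keep_set = set(keep)
    unknown = keep_set - set(tree.tip_labels)
    if unknown:
        raise ValueError(f"species not in tree: {sorted(unknown)}")

    def prune(n: Node) -> Node | None:
        if n.is_tip:
            return Node("", n.age, [], label=n.label) if n.label in keep_set else None
        kept = [c for c in (prune(c) for c in n.children) if c is not None]
        if not kept:
            return None
        if len(kept) == 1:
            return kept[0]  # suppress unary node; child keeps its own age
        return Node("", n.age, kept, label=n.label)

    new_root = prune(tree.root)
    if new_root is None:
        raise ValueError("no tips retained")
    return DatedTree(new_root)


def pick_representatives(labels: Sequence[str], sep: str = "_") -> dict[str, str]:
    """Map species -> representative accession (first alphabetically).

    Accession labels are assumed to be ``species<sep>accession``; labels
    without the separator are their own species.
    """
    by_sp: dict[str, list[str]] = {}
    for lab in labels:
        sp = lab.rsplit(sep, 1)[0] if sep in lab else lab
        by_sp.setdefault(sp, []).append(lab)
    return {sp: sorted(accs)[0] for sp, accs in by_sp.items()}


# ---------------------------------------------------------------------------
# nested overlap


def _clade_overlap(x: Node, y: Node, M: OverlapMatrix, memo: dict) -> float:
    key = (id(x), id(y))
    if key in memo:
        return memo[key]
    if x.is_tip and y.is_tip:
        val = M.get(x.label, y.label)
    elif not x.is_tip:
        a, b = x.children
        val = 0.5 * (
            _clade_overlap(a, y, M, memo) + _clade_overlap(b, y, M, memo)
        )
    else:
        a, b = y.children
        val = 0.5 * (
            _clade_overlap(x, a, M, memo) + _clade_overlap(x, b, M, memo)
        )
    memo[key] = val
    return val


def nested_overlap(node: Node, M: OverlapMatrix) -> float:
    """Nested average of range overlaps between the two clades at ``node``.

    Recursively averages: for clades X=(X1,X2) and Y, O(X,Y) =
    (O(X1,Y)+O(X2,Y))/2, bottoming out at the pairwise matrix entries.
    Equivalently a weighted sum over cross-clade tip pairs with tip weights
    halving at every internal node passed.
    """
    if node.is_tip:
        raise ValueError("nested_overlap is defined for internal nodes only")
    missing = {t.label for t in node.tips()} - set(M.species_ids)
    if missing:
        raise ValueError(f"species missing from overlap matrix: {sorted(missing)}")
    left, right = node.children
    return float(_clade_overlap(left, right, M, {}))


@dataclass(frozen=True)
class NodeOverlapRecord:
    node_id: str
    age: float
    nested_overlap: float


@dataclass(frozen=True)
class ArcRegression:
    slope: float
    intercept: float
    r_squared: float


def arc_table(
    tree: DatedTree, M: OverlapMatrix, regression: bool = False
) -> list[NodeOverlapRecord] | tuple[list[NodeOverlapRecord], ArcRegression]:
    """Per-node nested overlaps ordered by decreasing age (the ARC table).

    With ``regression=True`` also returns a descriptive OLS fit of nested
    overlap on node age (slope, intercept, r^2).
    """
    tips = set(tree.tip_labels)
    msp = set(M.species_ids)
    if tips != msp:
        raise ValueError(
            f"tree/matrix species mismatch: only in tree {sorted(tips - msp)}, "
            f"only in matrix {sorted(msp - tips)}"
        )
    records = [
        NodeOverlapRecord(n.node_id, n.age, nested_overlap(n, M))
        for n in tree.internal_nodes()
    ]
    records.sort(key=lambda r: (-r.age, r.node_id))
    if not regression:
        return records
    ages = np.array([r.age for r in records])
    ovl = np.array([r.nested_overlap for r in records])
    if len(records) >= 2 and np.ptp(ages) > 0:
        slope, intercept = np.polyfit(ages, ovl, 1)
        pred = slope * ages + intercept
        ss_res = float(np.sum((ovl - pred) ** 2))
        ss_tot = float(np.sum((ovl - ovl.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    else:
        slope = intercept = r2 = float("nan")
    return records, ArcRegression(float(slope), float(intercept), float(r2))


def write_arc_table(records: Sequence[NodeOverlapRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["node_id", "age_ma", "nested_overlap"])
        for r in records:
            w.writerow([r.node_id, f"{r.age:.8g}", f"{r.nested_overlap:.10g}"])
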