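"""Rooted phylogenetic trees: Newick I/O, manipulation, and random generation.

Trees are rooted with edge lengths in expected substitutions per site.
Under the time-reversible models used throughout this package the induced
character distribution does not depend on the root position (pulley
principle), so unrooted inputs are handled by keeping whatever rooting the
Newick string implies.
"""

from __future__ import annotations

import io
import warnings
from typing import Iterable, Iterator, Sequence

import dendropy
import numpy as np

__all__ = [
    "TreeNode",
    "PhyloTree",
    "NewickError",
    "parse_newick",
    "parse_newick_list",
    "write_newick",
    "write_newick_list",
    "restrict_to_taxa",
    "scale_edges",
    "yule_topology",
    "sample_edge_lengths",
    "random_spr",
    "felsenstein_farris_pair",
]


class NewickError(ValueError):
    """Raised for malformed or invalid Newick input."""


class TreeNode:
    """A node of a rooted tree.

    Leaves carry a ``label``; every non-root node carries the length of the
    edge to its parent.
    """

    __slots__ = ("label", "children", "edge_length", "parent")

    def __init__(self, label: str | None = None, edge_length: float | None = None):
        self.label = label
        self.children: list[TreeNode] = []
        self.edge_length = edge_length
        self.parent: TreeNode | None = None

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = f"leaf {self.label!r}" if self.is_leaf else f"internal({len(self.children)})"
        return f"<TreeNode {kind} len={self.edge_length}>"


class PhyloTree:
    """A rooted tree with uniquely labeled leaves and non-negative edge lengths."""

    def __init__(self, root: TreeNode, validate: bool = True):
        self.root = root
        if validate:
            self.validate()

    # -- structure -----------------------------------------------------

    def postorder(self) -> Iterator[TreeNode]:
        stack: list[tuple[TreeNode, bool]] = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def preorder(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.postorder() if n.is_leaf]

    @property
    def taxa(self) -> frozenset[str]:
        return frozenset(n.label for n in self.leaves())

    @property
    def n_leaves(self) -> int:
        return sum(1 for _ in self.leaves())

    def edges(self) -> list[TreeNode]:
        """Non-root nodes; each represents the edge to its parent."""
        return [n for n in self.postorder() if n.parent is not None]

    def validate(self) -> None:
        labels = [n.label for n in self.leaves()]
        if any(not lab for lab in labels):
            raise NewickError("every leaf must carry a non-empty label")
        if len(set(labels)) != len(labels):
            dup = sorted({l for l in labels if labels.count(l) > 1})
            raise NewickError(f"duplicate leaf labels: {dup}")
        for node in self.postorder():
            if node.parent is not None:
                bl = node.edge_length
                if bl is None or not np.isfinite(bl) or bl < 0:
                    raise NewickError(
                        f"invalid edge length {bl!r} above node {node.label or '<internal>'}"
                    )

    def copy(self) -> "PhyloTree":
        def rec(node: TreeNode) -> TreeNode:
            clone = TreeNode(node.label, node.edge_length)
            for child in node.children:
                clone.add_child(rec(child))
            return clone

        return PhyloTree(rec(self.root), validate=False)

    # -- measurements ---------------------------------------------------

    def leaf_path_lengths(self) -> dict[tuple[str, str], float]:
        """All pairwise leaf-to-leaf path lengths (unordered label pairs)."""
        # depth of every leaf below each node, accumulated upward
        below: dict[TreeNode, dict[str, float]] = {}
        out: dict[tuple[str, str], float] = {}
        for node in self.postorder():
            if node.is_leaf:
                below[node] = {node.label: 0.0}
                continue
            acc: dict[str, float] = {}
            kids = []
            for child in node.children:
                d = {lab: dist + child.edge_length for lab, dist in below.pop(child).items()}
                kids.append(d)
            for i in range(len(kids)):
                for j in range(i + 1, len(kids)):
                    for la, da in kids[i].items():
                        for lb, db in kids[j].items():
                            key = (la, lb) if la < lb else (lb, la)
                            out[key] = da + db
                acc.update(kids[i])
            acc.update(kids[-1])
            below[node] = acc
        return out

    def __repr__(self) -> str:  # pragma: no cover
        return f"<PhyloTree n_leaves={self.n_leaves}>"


# ---------------------------------------------------------------------------
# Newick I/O (parsing delegated to dendropy; validation and writing ours)
# ---------------------------------------------------------------------------


def _from_dendropy(dnode, strict: bool) -> TreeNode:
    if dnode.is_leaf():
        label = dnode.taxon.label if dnode.taxon is not None else dnode.label
        node = TreeNode(label=label)
    else:
        node = TreeNode()
    bl = dnode.edge.length
    if dnode.parent_node is not None:
        if bl is None:
            if strict:
                raise NewickError(
                    "missing branch length (use strict=False to treat as 0)"
                )
            warnings.warn("missing branch length treated as 0", stacklevel=3)
            bl = 0.0
        node.edge_length = float(bl)
    for child in dnode.child_nodes():
        node.add_child(_from_dendropy(child, strict))
    return node


def parse_newick(text: str, strict: bool = True) -> PhyloTree:
    """Parse a single Newick statement into a :class:`PhyloTree`.

    Internal node labels and bootstrap values are accepted and ignored;
    quoted labels are supported.  In strict mode (default) a missing branch
    length on a non-root edge is an error; otherwise it is read as 0 with a
    warning.  Duplicate leaf labels and negative lengths raise
    :class:`NewickError`.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise NewickError(f"malformed Newick: {exc}") from exc
    root = _from_dendropy(dtree.seed_node, strict)
    return PhyloTree(root)


def parse_newick_list(source: str | io.TextIOBase, strict: bool = True) -> list[PhyloTree]:
    """Parse a file (path or handle) with one Newick tree per line."""
    if isinstance(source, str):
        with open(source) as fh:
            lines = fh.readlines()
    else:
        lines = source.readlines()
    trees = []
    for i, line in enumerate(lines, 1):
        line = line.strip()
        if not line:
            continue
        try:
            trees.append(parse_newick(line, strict=strict))
        except NewickError as exc:
            raise NewickError(f"line {i}: {exc}") from exc
    return trees


def write_newick_list(
    trees: Iterable[PhyloTree], path: str, provenance: dict | None = None
) -> None:
    """Write trees one Newick statement per line.

    If ``provenance`` is given (e.g. generator seed and parameters), it is
    stored as a JSON sidecar at ``<path>.meta.json`` so fixtures stay
    reproducible.
    """
    import json

    with open(path, "w") as fh:
        for tree in trees:
            fh.write(write_newick(tree) + "\n")
    if provenance is not None:
        with open(path + ".meta.json", "w") as fh:
            json.dump(provenance, fh, indent=2)


def _fmt_length(x: float) -> str:
    # repr gives the shortest string that round-trips the float exactly
    return repr(float(x))


def _min_leaf(node: TreeNode, memo: dict) -> str:
    if node not in memo:
        if node.is_leaf:
            memo[node] = node.label
        else:
            memo[node] = min(_min_leaf(c, memo) for c in node.children)
    return memo[node]


def write_newick(tree: PhyloTree) -> str:
    """Serialize with canonical child ordering (by smallest descendant label)."""
    memo: dict = {}

    def rec(node: TreeNode) -> str:
        if node.is_leaf:
            label = node.label
            if any(c in label for c in "(),:;' \t"):
                label = "'" + label.replace("'", "''") + "'"
            core = label
        else:
            kids = sorted(node.children, key=lambda c: _min_leaf(c, memo))
            core = "(" + ",".join(rec(c) for c in kids) + ")"
        if node.parent is not None:
            core += ":" + _fmt_length(node.edge_length)
        return core

    return rec(tree.root) + ";"


# ---------------------------------------------------------------------------
# Manipulation
# ---------------------------------------------------------------------------


def restrict_to_taxa(tree: PhyloTree, keep: Iterable[str]) -> PhyloTree:
    """Crop a tree down to ``keep``, preserving all pairwise path lengths.

    Degree-2 nodes created by leaf removal are suppressed with their
    incident edge lengths summed.
    """
    keep = set(keep)
    if not keep:
        raise ValueError("keep must be non-empty")
    unknown = keep - tree.taxa
    if unknown:
        raise ValueError(f"unknown taxa: {sorted(unknown)}")

    def rec(node: TreeNode) -> TreeNode | None:
        if node.is_leaf:
            if node.label in keep:
                return TreeNode(node.label, node.edge_length)
            return None
        kept = [rec(c) for c in node.children]
        kept = [c for c in kept if c is not None]
        if not kept:
            return None
        if len(kept) == 1:
            # suppress this node: child inherits the summed edge length
            child = kept[0]
            if node.parent is None:
                child.edge_length = None  # child becomes the new root
            else:
                child.edge_length = child.edge_length + node.edge_length
            return child
        clone = TreeNode(None, node.edge_length)
        for c in kept:
            clone.add_child(c)
        return clone

    new_root = rec(tree.root)
    assert new_root is not None
    new_root.edge_length = None
    new_root.parent = None
    return PhyloTree(new_root)


def scale_edges(tree: PhyloTree, s: float) -> PhyloTree:
    """Multiply every edge length by ``s > 0``; topology unchanged."""
    if not (s > 0):
        raise ValueError(f"scale factor must be positive, got {s}")
    out = tree.copy()
    for node in out.edges():
        node.edge_length = node.edge_length * s
    return out


# ---------------------------------------------------------------------------
# Random generation
# ---------------------------------------------------------------------------


def yule_topology(
    n: int, rng: np.random.Generator, labels: Sequence[str] | None = None
) -> PhyloTree:
    """Random binary rooted topology on ``n`` leaves, Yule distributed.

    Realized by starting from n isolated lineages and repeatedly joining two
    uniformly chosen lineages, which yields the pure-birth topology
    distribution.  All edge lengths are set to 0 as placeholders.
    """
    if n < 2:
        raise ValueError("need at least 2 leaves")
    if labels is None:
        width = len(str(n))
        labels = [f"t{str(i + 1).zfill(width)}" for i in range(n)]
    if len(labels) != n:
        raise ValueError("len(labels) must equal n")
    lineages = [TreeNode(lab, 0.0) for lab in labels]
    while len(lineages) > 1:
        i, j = rng.choice(len(lineages), size=2, replace=False)
        i, j = (int(i), int(j)) if i < j else (int(j), int(i))
        parent = TreeNode(None, 0.0)
        parent.add_child(lineages[i])
        parent.add_child(lineages[j])
        lineages[j] = lineages[-1]
        lineages.pop()
        lineages[i] = parent
    root = lineages[0]
    root.edge_length = None
    return PhyloTree(root)


def sample_edge_lengths(
    tree: PhyloTree, mean: float, variance: float, rng: np.random.Generator
) -> PhyloTree:
    """Draw each edge length iid from a Gamma with the given mean and variance.

    Moment matching: shape = mean^2/variance, scale = variance/mean.
    """
    if mean <= 0 or variance <= 0:
        raise ValueError("mean and variance must be positive")
    shape = mean * mean / variance
    scale = variance / mean
    out = tree.copy()
    for node in out.edges():
        node.edge_length = float(rng.gamma(shape, scale))
    return out


def _is_binary(tree: PhyloTree) -> bool:
    return all(len(n.children) in (0, 2) for n in tree.postorder())


def random_spr(tree: PhyloTree, rng: np.random.Generator) -> PhyloTree:
    """One random subtree-prune-and-regraft move on a binary rooted tree.

    A non-root subtree is pruned uniformly at random and regrafted onto a
    uniformly chosen edge of the remaining tree; the attachment point bisects
    the target edge, and the node suppressed by pruning has its two incident
    edge lengths summed.  Taxa are conserved.
    """
    if tree.n_leaves < 4:
        raise ValueError("SPR requires at least 4 leaves")
    if not _is_binary(tree):
        raise ValueError("SPR requires a binary tree")
    while True:
        work = tree.copy()
        candidates = work.edges()
        prune = candidates[int(rng.integers(len(candidates)))]
        parent = prune.parent
        sibling = [c for c in parent.children if c is not prune][0]
        # detach and suppress the now-unary parent
        if parent.parent is None:
            new_root = sibling
            new_root.parent = None
            new_root.edge_length = None
            work = PhyloTree(new_root, validate=False)
        else:
            grand = parent.parent
            sibling.edge_length = sibling.edge_length + parent.edge_length
            grand.children[grand.children.index(parent)] = sibling
            sibling.parent = grand
        targets = work.edges()
        if not targets:
            continue  # pruned all but one leaf; redraw
        target = targets[int(rng.integers(len(targets)))]
        mid = TreeNode(None, target.edge_length / 2.0)
        tparent = target.parent
        tparent.children[tparent.children.index(target)] = mid
        mid.parent = tparent
        target.edge_length = target.edge_length / 2.0
        mid.add_child(target)
        mid.add_child(prune)
        return PhyloTree(work.root)


def felsenstein_farris_pair(
    long_len: float, short_len: float = 0.1
) -> tuple[PhyloTree, PhyloTree]:
    """The classic 4-taxon long-branch pair.

    Returns two trees on taxa A-D with two pendant edges of length
    ``long_len`` and all other edges ``short_len``: in the first the long
    edges are non-sister (Felsenstein zone), in the second they are sister
    (Farris zone).  The internal edge of total length ``short_len`` is split
    evenly by the root.
    """
    if long_len <= 0 or short_len <= 0:
        raise ValueError("edge lengths must be positive")
    h = short_len / 2.0

    def build(pairs):
        root = TreeNode()
        for (l1, b1), (l2, b2) in pairs:
            mid = TreeNode(None, h)
            mid.add_child(TreeNode(l1, b1))
            mid.add_child(TreeNode(l2, b2))
            root.add_child(mid)
        return PhyloTree(root)

    L, S = long_len, short_len
    felsenstein = build([((("A"), L), (("B"), S)), ((("C"), L), (("D"), S))])
    farris = build([((("A"), L), (("C"), L)), ((("B"), S), (("D"), S))])
    return felsenstein, farris
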