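"""Leaf-labelled phylogenetic trees: Newick I/O, bipartitions, rooting, consensus.

Trees are stored as nested tuples of children whose leaves are taxon
names.  An unrooted tree keeps an anchor node with three (or, for a
consensus, more) children; a rooted tree has a two-child root.  Equality
is topological: unrooted trees compare by their nontrivial bipartitions,
rooted trees by their clade sets, so the same tree anchored at different
internal nodes compares equal.
"""

from __future__ import annotations

import warnings
from typing import Callable, Iterable, Optional, Sequence

import dendropy

__all__ = [
    "PhyloTree",
    "read_newick",
    "write_newick",
    "root_with_outgroup",
    "majority_rule_consensus",
    "robinson_foulds",
    "NewickError",
]

Nested = tuple  # recursive: tuple of (str | Nested)


class NewickError(ValueError):
    """Malformed Newick input."""


def _leaves(node) -> frozenset[str]:
    if isinstance(node, str):
        return frozenset((node,))
    return frozenset().union(*(_leaves(c) for c in node))


def _canon(node):
    """Sort children recursively by smallest descendant leaf (display order)."""
    if isinstance(node, str):
        return node
    kids = tuple(sorted((_canon(c) for c in node), key=lambda k: min(_leaves(k))))
    return kids


class PhyloTree:
    """An unrooted (default) or rooted leaf-labelled tree."""

    def __init__(self, nested: Nested, rooted: bool = False):
        if isinstance(nested, str):
            raise ValueError("a tree needs at least two leaves")
        taxa = _leaves(nested)
        flat = _count_leaf_slots(nested)
        if flat != len(taxa):
            raise ValueError("duplicate leaf labels")
        if len(taxa) < (2 if rooted else 3):
            raise ValueError("too few leaves")
        if not rooted and len(nested) == 2:
            nested = _merge_root(nested)
        self._nested = _canon(nested)
        self.rooted = rooted
        self.taxa = taxa

    # -- representation ----------------------------------------------------
    @property
    def nested(self) -> Nested:
        return self._nested

    def __repr__(self) -> str:
        kind = "rooted" if self.rooted else "unrooted"
        return f"<PhyloTree {kind} {self.newick()}>"

    # -- topology ----------------------------------------------------------
    def clades(self) -> frozenset[frozenset[str]]:
        """Leaf sets of all internal nodes below the root/anchor."""
        out: set[frozenset[str]] = set()

        def walk(node) -> frozenset[str]:
            if isinstance(node, str):
                return frozenset((node,))
            ls = frozenset().union(*(walk(c) for c in node))
            out.add(ls)
            return ls

        for child in self._nested:
            walk(child)
        return frozenset(out)

    def bipartitions(self, include_trivial: bool = False) -> frozenset[frozenset[str]]:
        """Splits of the unrooted topology, each canonicalised to the side
        not containing the alphabetically first taxon."""
        ref = min(self.taxa)
        n = len(self.taxa)
        out: set[frozenset[str]] = set()
        for clade in self.clades():
            side = clade if ref not in clade else self.taxa - clade
            if include_trivial or 2 <= len(side) <= n - 2:
                out.add(frozenset(side))
        if include_trivial:
            for t in self.taxa:
                if t != ref:
                    out.add(frozenset((t,)))
                else:
                    out.add(frozenset(self.taxa - {t}))
        return frozenset(out)

    def is_binary(self) -> bool:
        def ok(node, top: bool) -> bool:
            if isinstance(node, str):
                return True
            want = (3 if not self.rooted else 2) if top else 2
            return len(node) == want and all(ok(c, False) for c in node)

        if not self.rooted and len(self.taxa) == 3:
            return ok(self._nested, True)
        return ok(self._nested, True)

    def has_bipartition(self, side: Iterable[str]) -> bool:
        side = frozenset(side)
        ref = min(self.taxa)
        canon = side if ref not in side else self.taxa - side
        return frozenset(canon) in self.bipartitions(include_trivial=True)

    def __eq__(self, other) -> bool:
        if not isinstance(other, PhyloTree):
            return NotImplemented
        if self.taxa != other.taxa or self.rooted != other.rooted:
            return False
        if self.rooted:
            return self.clades() == other.clades()
        return self.bipartitions() == other.bipartitions()

    def __hash__(self) -> int:
        key = self.clades() if self.rooted else self.bipartitions()
        return hash((self.taxa, self.rooted, key))

    # -- conversions ---------------------------------------------------------
    def newick(self, label_fn: Optional[Callable[[frozenset[str]], str]] = None) -> str:
        """Serialise to Newick.  ``label_fn`` maps an internal node's leaf
        set to a node label (used for bootstrap-annotated output)."""

        def fmt(node) -> str:
            if isinstance(node, str):
                return _quote(node)
            inner = ",".join(fmt(c) for c in node)
            label = label_fn(_leaves(node)) if label_fn else ""
            return f"({inner}){label}"

        return fmt(self._nested) + ";"

    def unroot(self) -> "PhyloTree":
        if not self.rooted:
            return self
        return PhyloTree(_merge_root(self._nested), rooted=False)


def _count_leaf_slots(node) -> int:
    if isinstance(node, str):
        return 1
    return sum(_count_leaf_slots(c) for c in node)


def _merge_root(nested: Nested) -> Nested:
    """Collapse a two-child root into an unrooted anchor (degree >= 3)."""
    if len(nested) != 2:
        return nested
    a, b = nested
    if isinstance(a, tuple):
        return tuple(a) + (b,)
    if isinstance(b, tuple):
        return (a,) + tuple(b)
    raise ValueError("cannot unroot a two-leaf tree")


def _quote(label: str) -> str:
    if any(ch in label for ch in " (),:;'"):
        return "'" + label.replace("'", "''") + "'"
    return label


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def read_newick(text: str, rooted: Optional[bool] = None) -> PhyloTree:
    """Parse a Newick string (via dendropy, so errors carry positions).

    A tree whose root has two children is treated as rooted unless
    ``rooted=False`` is forced; three or more children mean unrooted.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickError(f"malformed Newick: {exc}") from exc

    def conv(node):
        if node.is_leaf():
            if node.taxon is None or not node.taxon.label:
                raise NewickError("unlabelled leaf in Newick input")
            return node.taxon.label
        return tuple(conv(c) for c in node.child_nodes())

    nested = conv(dtree.seed_node)
    if isinstance(nested, str) or len(nested) < 2:
        raise NewickError("tree must have at least two leaves")
    if rooted is None:
        rooted = len(nested) == 2
    return PhyloTree(nested, rooted=rooted)


def write_newick(tree: PhyloTree) -> str:
    return tree.newick()


# ---------------------------------------------------------------------------
# rooting
# ---------------------------------------------------------------------------

def root_with_outgroup(tree: PhyloTree, outgroup: Iterable[str]) -> PhyloTree:
    """Root an unrooted tree on the edge separating the outgroup.

    If the outgroup is not monophyletic on the tree, the root goes on the
    edge best separating outgroup from ingroup (maximum count of correctly
    placed taxa) and a warning is emitted.
    """
    og = frozenset(outgroup)
    if not og or not og < tree.taxa:
        raise ValueError("outgroup must be a proper non-empty subset of the leaves")
    base = tree.unroot()
    # candidate edges = all clades of the anchored representation plus the
    # anchor's child edges; every edge corresponds to one side-set
    sides = set()
    for clade in base.clades():
        sides.add(clade)
        sides.add(base.taxa - clade)
    for t in base.taxa:  # leaf edges
        sides.add(frozenset((t,)))
        sides.add(base.taxa - {t})
    best, best_score = None, -1
    exact = None
    for side in sides:
        if side == og:
            exact = side
            break
        score = len(og & side) + len((base.taxa - og) - side)
        if score > best_score or (score == best_score and min(side) < min(best)):
            best, best_score = side, score
    if exact is None:
        warnings.warn(
            "outgroup is not monophyletic on this tree; rooting on the "
            "edge of maximum outgroup/ingroup separation"
        )
        side = best
    else:
        side = exact
    out_sub = _extract(base.nested, side)
    in_sub = _extract(base.nested, base.taxa - side)
    return PhyloTree((out_sub, in_sub), rooted=True)


def _adjacency(nested: Nested):
    """Flatten a nested tree into (adjacency lists, leaf labels by node id)."""
    adj: dict[int, list[int]] = {}
    labels: dict[int, str] = {}
    counter = [0]

    def new_node() -> int:
        counter[0] += 1
        adj[counter[0]] = []
        return counter[0]

    def walk(node, parent: int) -> None:
        nid = new_node()
        adj[parent].append(nid)
        adj[nid].append(parent)
        if isinstance(node, str):
            labels[nid] = node
        else:
            for c in node:
                walk(c, nid)

    root = new_node()
    for c in nested:
        walk(c, root)
    return adj, labels, root


def _extract(nested: Nested, side: frozenset[str]) -> Nested | str:
    """Rebuild the subtree spanning ``side``, one side of an edge of the
    tree anchored at ``nested``, rooted at that edge's endpoint."""
    if len(side) == 1:
        return next(iter(side))
    adj, labels, _ = _adjacency(nested)

    def leafset(node: int, parent: int) -> frozenset[str]:
        if node in labels:
            return frozenset((labels[node],))
        out: frozenset[str] = frozenset()
        for nb in adj[node]:
            if nb != parent:
                out |= leafset(nb, node)
        return out

    def build(node: int, parent: int):
        if node in labels:
            return labels[node]
        kids = [build(nb, node) for nb in adj[node] if nb != parent]
        return kids[0] if len(kids) == 1 else tuple(kids)

    # find the directed edge (parent -> node) whose far side equals `side`
    for node, nbs in adj.items():
        for parent in nbs:
            if leafset(node, parent) == side:
                sub = build(node, parent)
                # suppress a possible degree-2 anchor left behind
                return sub
    raise ValueError(f"{sorted(side)} is not one side of an edge of this tree")


# ---------------------------------------------------------------------------
# consensus and distances
# ---------------------------------------------------------------------------

def majority_rule_consensus(
    trees: Sequence[PhyloTree], threshold: float = 0.5
) -> PhyloTree:
    """Majority-rule consensus: keep bipartitions with frequency > threshold.

    ``threshold`` must be in [0.5, 1]; above 0.5 the retained splits are
    mutually compatible by construction, so the consensus always exists
    (possibly multifurcating).
    """
    if not trees:
        raise ValueError("no trees given")
    if not 0.5 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0.5, 1]")
    taxa = trees[0].taxa
    if any(t.taxa != taxa for t in trees):
        raise ValueError("trees must share one leaf set")
    counts: dict[frozenset[str], int] = {}
    for t in trees:
        for bp in t.unroot().bipartitions():
            counts[bp] = counts.get(bp, 0) + 1
    keep = [bp for bp, c in counts.items() if c / len(trees) > threshold]
    return tree_from_bipartitions(taxa, keep)


def tree_from_bipartitions(
    taxa: frozenset[str], sides: Sequence[frozenset[str]]
) -> PhyloTree:
    """Build the (possibly multifurcating) unrooted tree displaying exactly
    the given pairwise-compatible splits.  Each split is given as its
    canonical side (not containing the alphabetically first taxon)."""
    ref = min(taxa)
    clades = sorted(set(sides), key=len)
    for i, a in enumerate(clades):  # compatibility within the rooted view
        for b in clades[i + 1:]:
            if a & b and not a <= b:
                raise ValueError("incompatible bipartitions")

    def build(members: frozenset[str], inner: list[frozenset[str]]):
        # children of this node: maximal clades properly inside `members`
        maximal = [
            c for c in inner
            if c < members and not any(c < d < members for d in inner)
        ]
        kids = []
        covered: set[str] = set()
        for c in sorted(maximal, key=min):
            sub_in = [d for d in inner if d < c]
            kids.append(build(c, sub_in))
            covered |= c
        for leaf in sorted(members - covered):
            kids.append(leaf)
        if len(kids) == 1:
            return kids[0]
        return tuple(kids)

    top = build(taxa, clades)
    if isinstance(top, str):
        raise ValueError("degenerate consensus")
    return PhyloTree(top, rooted=False)


def robinson_foulds(a: PhyloTree, b: PhyloTree) -> int:
    """Unweighted Robinson–Foulds distance (symmetric split difference)."""
    if a.taxa != b.taxa:
        raise ValueError("trees must share one leaf set")
    return len(a.unroot().bipartitions() ^ b.unroot().bipartitions())
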