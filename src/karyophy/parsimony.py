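"""Maximum parsimony for binary chromosomal characters.

The engine implements Fitch small parsimony (unordered characters,
missing ``?`` treated as the full state set, so missing data is free),
exhaustive enumeration of all (2n-5)!! unrooted binary topologies by
stepwise leaf addition, the standard fit statistics

    CI = m / s,   RI = (g - s) / (g - m),   HI = 1 - CI,

where ``s`` is the realised tree length, ``m`` the sum over characters of
(observed states - 1) — the best conceivable length — and ``g`` the sum
of min(n0, n1) — the star-tree worst case, and a nonparametric bootstrap
(characters resampled with replacement, each replicate searched
exhaustively, ties contributing 1/k per most-parsimonious tree).

The model-object surface: ``MaxParsimony(matrix).fit()`` returns a
:class:`ParsimonyResults` carrying the MP trees, the statistics and a
``summary()``; ``results.bootstrap(...)`` and ``results.rooted_tree(...)``
hang off it.  The module-level functions (:func:`fitch_steps`,
:func:`exhaustive_search`, ...) are the same machinery unwrapped.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

from .characters import CharacterMatrix
from .trees import (
    PhyloTree,
    _adjacency,
    majority_rule_consensus,
    root_with_outgroup,
)

__all__ = [
    "ParsimonyScore",
    "TreeStats",
    "SearchResult",
    "BootstrapSupport",
    "MaxParsimony",
    "ParsimonyResults",
    "fitch_steps",
    "enumerate_trees",
    "n_unrooted_topologies",
    "exhaustive_search",
    "tree_stats",
    "bootstrap",
    "majority_rule_consensus",
    "root_with_outgroup",
    "round_half_up",
]

DEFAULT_TAXA_CAP = 10

_MASK = {"0": 1, "1": 2, "?": 3}


def round_half_up(x: float, places: int = 3) -> float:
    """Decimal round-half-up (0.0225 -> 0.023), as printed statistics are."""
    q = Decimal(1).scaleb(-places)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParsimonyScore:
    """Fitch length of one tree: total and per-character steps."""

    total_steps: int
    per_character_steps: tuple[int, ...]


@dataclass(frozen=True)
class TreeStats:
    """Length s with its conceivable bounds m <= s <= g and the derived
    consistency (CI), retention (RI) and homoplasy (HI) indices."""

    m: int
    g: int
    s: int
    ci: float
    ri: float
    hi: float

    def rounded(self, places: int = 3) -> "TreeStats":
        return TreeStats(
            self.m, self.g, self.s,
            round_half_up(self.ci, places),
            round_half_up(self.ri, places) if not math.isnan(self.ri) else self.ri,
            round_half_up(self.hi, places),
        )


@dataclass(frozen=True)
class SearchResult:
    """Outcome of an exhaustive search: all minimum-length trees."""

    mp_trees: tuple[PhyloTree, ...]
    length: int
    stats: TreeStats
    n_trees_examined: int
    score: ParsimonyScore


@dataclass(frozen=True)
class BootstrapSupport:
    """Bipartition support percentages over character-resampled replicates.

    Keys are canonical split sides (the side not containing the
    alphabetically first taxon); trivial splits are always at 100.
    """

    taxa: frozenset[str]
    support: dict[frozenset[str], float]
    n_replicates: int
    seed: int

    def percentage(self, side: Iterable[str]) -> float:
        side = frozenset(side)
        ref = min(self.taxa)
        canon = side if ref not in side else self.taxa - side
        if len(canon) <= 1 or len(canon) >= len(self.taxa) - 1:
            return 100.0
        return self.support.get(frozenset(canon), 0.0)


# ---------------------------------------------------------------------------
# Fitch small parsimony
# ---------------------------------------------------------------------------

def _column_masks(matrix: CharacterMatrix) -> list[tuple[int, ...]]:
    """Per character: bitmask per taxon in matrix taxon order (1=state 0,
    2=state 1, 3=missing)."""
    cols = []
    for j in range(matrix.n_characters):
        cols.append(tuple(_MASK[row[j]] for row in matrix.states))
    return cols


def _fitch_column(nested, anchor_mask: int, masks: Sequence[int]) -> int:
    """Fitch union/intersection count for one character on a tree given as
    a nested tuple over taxon indices, anchored at an extra leaf."""

    def rec(node):
        if isinstance(node, int):
            return masks[node], 0
        m1, s1 = rec(node[0])
        m2, s2 = rec(node[1])
        inter = m1 & m2
        if inter:
            return inter, s1 + s2
        return m1 | m2, s1 + s2 + 1

    m, s = rec(nested)
    return s if (m & anchor_mask) else s + 1


def _leaf_anchored(tree: PhyloTree, taxa_order: Sequence[str]):
    """Convert a PhyloTree to (anchor taxon index nested) form: the tree is
    re-rooted at taxa_order[0]'s pendant edge; leaves become indices."""
    index = {t: i for i, t in enumerate(taxa_order)}
    adj, labels, _ = _adjacency(tree.unroot().nested)
    anchor_node = next(n for n, lbl in labels.items() if lbl == taxa_order[0])
    (start,) = adj[anchor_node]

    def build(node: int, parent: int):
        if node in labels:
            return index[labels[node]]
        kids = [build(nb, node) for nb in adj[node] if nb != parent]
        if len(kids) == 1:  # degree-2 anchor left over: splice through
            return kids[0]
        if len(kids) != 2:
            raise ValueError("Fitch scoring requires a binary tree")
        return tuple(kids)

    return build(start, anchor_node)


def fitch_steps(tree: PhyloTree, matrix: CharacterMatrix) -> ParsimonyScore:
    """Minimum number of state changes of each character on ``tree``.

    The score is rooting-invariant; ``tree`` may be rooted or unrooted but
    must be binary and carry exactly the matrix's taxa.
    """
    if tree.taxa != frozenset(matrix.taxa):
        raise ValueError("tree leaves and matrix taxa differ")
    nested = _leaf_anchored(tree, matrix.taxa)
    cols = _column_masks(matrix)
    per = tuple(_fitch_column(nested, col[0], col) for col in cols)
    return ParsimonyScore(sum(per), per)


# ---------------------------------------------------------------------------
# exhaustive enumeration
# ---------------------------------------------------------------------------

def n_unrooted_topologies(n_taxa: int) -> int:
    """(2n-5)!! distinct unrooted binary topologies on n labelled leaves."""
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    out = 1
    for k in range(3, 2 * n_taxa - 4, 2):
        out *= k
    return out


def _insertions(tree, leaf: int) -> Iterator:
    yield (tree, leaf)
    if isinstance(tree, tuple):
        a, b = tree
        for sub in _insertions(a, leaf):
            yield (sub, b)
        for sub in _insertions(b, leaf):
            yield (a, sub)


def _nested_topologies(n: int) -> Iterator:
    """All binary trees over leaf indices 1..n-1 (anchored at leaf 0),
    generated by stepwise addition — each unrooted topology exactly once."""

    def gen(k: int) -> Iterator:
        if k == 2:
            yield (1, 2)
            return
        for t in gen(k - 1):
            yield from _insertions(t, k)

    yield from gen(n - 1)


def _nested_to_tree(nested, taxa: Sequence[str]) -> PhyloTree:
    def conv(node):
        if isinstance(node, int):
            return taxa[node]
        return tuple(conv(c) for c in node)

    a, b = nested
    return PhyloTree((taxa[0], conv(a), conv(b)), rooted=False)


def enumerate_trees(
    taxa: Sequence[str], cap: int = DEFAULT_TAXA_CAP
) -> Iterator[PhyloTree]:
    """Yield every unrooted binary topology on ``taxa`` exactly once.

    Refuses more than ``cap`` taxa: the count grows as (2n-5)!! and this
    package only does exhaustive search (heuristic search is out of scope).
    """
    taxa = list(taxa)
    if len(set(taxa)) != len(taxa):
        raise ValueError("taxa must be unique")
    if len(taxa) < 3:
        raise ValueError("need at least 3 taxa")
    if len(taxa) > cap:
        raise ValueError(
            f"{len(taxa)} taxa would require {n_unrooted_topologies(len(taxa))} "
            f"topologies; exhaustive enumeration is capped at {cap} taxa "
            "(heuristic search is out of scope for this package)"
        )
    for nested in _nested_topologies(len(taxa)):
        yield _nested_to_tree(nested, taxa)


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def _bounds(matrix: CharacterMatrix) -> tuple[int, int, list[int], list[int]]:
    m_per, g_per = [], []
    for j in range(matrix.n_characters):
        col = [row[j] for row in matrix.states]
        n0 = col.count("0")
        n1 = col.count("1")
        observed = (n0 > 0) + (n1 > 0)
        m_per.append(max(observed - 1, 0))
        g_per.append(min(n0, n1))
    return sum(m_per), sum(g_per), m_per, g_per


def tree_stats(matrix: CharacterMatrix, s: int) -> TreeStats:
    """CI, RI and HI for a tree of length ``s`` on this matrix.

    Computed over all characters, parsimony-uninformative ones included
    (autapomorphies contribute one step to both m and s), matching the
    convention of standard parsimony software.  When g = m and s > m the
    retention index is undefined and reported as NaN with a warning.
    """
    m, g, _, _ = _bounds(matrix)
    if s < m:
        raise ValueError(f"tree length {s} below the minimum conceivable {m}")
    if m == 0 and s == 0:
        ci = 1.0
    else:
        ci = m / s
    if g == m:
        if s == m:
            ri = 1.0
        else:
            warnings.warn(
                "retention index undefined (g == m with homoplasy present)"
            )
            ri = math.nan
    else:
        ri = (g - s) / (g - m)
    return TreeStats(m=m, g=g, s=s, ci=ci, ri=ri, hi=1.0 - ci)


# ---------------------------------------------------------------------------
# exhaustive search
# ---------------------------------------------------------------------------

def exhaustive_search(
    matrix: CharacterMatrix, cap: int = DEFAULT_TAXA_CAP
) -> SearchResult:
    """Evaluate every unrooted binary topology; return all minimum-length
    trees with their statistics."""
    taxa = list(matrix.taxa)
    if len(taxa) < 3:
        raise ValueError("exhaustive search needs at least 3 taxa")
    if len(taxa) > cap:
        raise ValueError(
            f"{len(taxa)} taxa exceed the exhaustive-search cap of {cap}"
        )
    cols = _column_masks(matrix)
    # collapse identical columns; Fitch is evaluated once per pattern
    patterns: dict[tuple[int, ...], int] = {}
    for col in cols:
        patterns[col] = patterns.get(col, 0) + 1
    pat_list = list(patterns.items())

    best: list = []
    best_len: Optional[int] = None
    examined = 0
    for nested in _nested_topologies(len(taxa)):
        examined += 1
        total = 0
        for col, weight in pat_list:
            total += weight * _fitch_column(nested, col[0], col)
            if best_len is not None and total > best_len:
                break
        if best_len is None or total < best_len:
            best_len = total
            best = [nested]
        elif total == best_len:
            best.append(nested)
    mp_trees = tuple(_nested_to_tree(n, taxa) for n in best)
    score = fitch_steps(mp_trees[0], matrix)
    stats = tree_stats(matrix, best_len)
    return SearchResult(
        mp_trees=mp_trees,
        length=best_len,
        stats=stats,
        n_trees_examined=examined,
        score=score,
    )


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def bootstrap(
    matrix: CharacterMatrix,
    n_replicates: int = 1000,
    seed: int = 0,
    cap: int = DEFAULT_TAXA_CAP,
) -> BootstrapSupport:
    """Nonparametric bootstrap over characters.

    Each replicate draws ``n_characters`` columns with replacement
    (replicate r uses the deterministic substream (seed, r)), searches
    exhaustively, and its k most-parsimonious trees each add 1/k to the
    tally of every nontrivial bipartition they display.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    taxa = frozenset(matrix.taxa)
    tally: dict[frozenset[str], float] = {}
    ncol = matrix.n_characters
    for r in range(n_replicates):
        rng = np.random.default_rng([seed, r])
        idx = rng.integers(0, ncol, size=ncol)
        res = exhaustive_search(matrix.subset_characters(list(idx)), cap=cap)
        w = 1.0 / len(res.mp_trees)
        for t in res.mp_trees:
            for bp in t.bipartitions():
                tally[bp] = tally.get(bp, 0.0) + w
    # tie weights are accumulated in floating point; clamp the roundoff
    support = {
        bp: min(100.0, max(0.0, 100.0 * v / n_replicates))
        for bp, v in tally.items()
    }
    return BootstrapSupport(
        taxa=taxa, support=support, n_replicates=n_replicates, seed=seed
    )


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------

class MaxParsimony:
    """Maximum-parsimony model over a binary character matrix.

    >>> model = MaxParsimony(pitheciinae_fixture())
    >>> results = model.fit()
    >>> print(results.summary())
    """

    def __init__(self, matrix: CharacterMatrix, cap: int = DEFAULT_TAXA_CAP):
        self.matrix = matrix
        self.cap = cap

    @classmethod
    def from_dataframe(cls, df, **kwargs) -> "MaxParsimony":
        """Build from a taxa-by-characters DataFrame of '0'/'1'/'?'."""
        from .characters import CharacterDefinition

        taxa = [str(t) for t in df.index]
        chars = [
            CharacterDefinition(f"c{j+1}", str(c)) for j, c in enumerate(df.columns)
        ]
        states = [[str(v) for v in df.loc[t]] for t in df.index]
        return cls(CharacterMatrix(taxa, chars, states), **kwargs)

    def score(self, tree: PhyloTree) -> ParsimonyScore:
        return fitch_steps(tree, self.matrix)

    def fit(self) -> "ParsimonyResults":
        res = exhaustive_search(self.matrix, cap=self.cap)
        return ParsimonyResults(self, res)


class ParsimonyResults:
    """Fitted exhaustive-search result with statistics and summaries."""

    def __init__(self, model: MaxParsimony, result: SearchResult):
        self.model = model
        self._result = result

    # plain attributes mirroring the search result
    @property
    def mp_trees(self) -> tuple[PhyloTree, ...]:
        return self._result.mp_trees

    @property
    def length(self) -> int:
        return self._result.length

    @property
    def stats(self) -> TreeStats:
        return self._result.stats

    @property
    def n_trees_examined(self) -> int:
        return self._result.n_trees_examined

    @property
    def per_character_steps(self) -> tuple[int, ...]:
        return self._result.score.per_character_steps

    def bootstrap(self, n_replicates: int = 1000, seed: int = 0) -> BootstrapSupport:
        return bootstrap(
            self.model.matrix, n_replicates=n_replicates, seed=seed,
            cap=self.model.cap,
        )

    def rooted_tree(
        self, outgroup: Iterable[str], tree_index: int = 0
    ) -> PhyloTree:
        return root_with_outgroup(self.mp_trees[tree_index], outgroup)

    def annotated_newick(
        self,
        outgroup: Iterable[str],
        support: Optional[BootstrapSupport] = None,
        tree_index: int = 0,
    ) -> str:
        """Rooted Newick with bootstrap percentages as internal labels."""
        rooted = self.rooted_tree(outgroup, tree_index)
        if support is None:
            return rooted.newick()

        def label(leafset: frozenset[str]) -> str:
            if len(leafset) <= 1 or len(leafset) >= len(rooted.taxa) - 1:
                return ""
            return format(support.percentage(leafset), ".0f")

        return rooted.newick(label_fn=label)

    def summary(self) -> str:
        st = self.stats.rounded()
        mat = self.model.matrix
        lines = [
            "Maximum parsimony (exhaustive search)",
            "=" * 45,
            f"Taxa                     {mat.n_taxa}",
            f"Characters               {mat.n_characters}",
            f"Topologies examined      {self.n_trees_examined}",
            f"Most parsimonious trees  {len(self.mp_trees)}",
            f"Tree length (s)          {self.length}",
            f"Min steps (m)            {st.m}",
            f"Max steps (g)            {st.g}",
            f"Consistency index (CI)   {st.ci:.3f}",
            f"Retention index (RI)     "
            + (f"{st.ri:.3f}" if not math.isnan(st.ri) else "undefined"),
            f"Homoplasy index (HI)     {st.hi:.3f}",
        ]
        for i, t in enumerate(self.mp_trees):
            lines.append(f"MP tree {i + 1}: {t.newick()}")
        return "\n".join(lines)
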