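"""Synthetic data with the statistical structure the pipeline assumes.

Two generators:

* binary characters evolved on a known tree by a symmetric two-state flip
  process (per-branch change *probability*, not a rate) — a stand-in for
  a real chromosomal character matrix with known ground truth;
* karyotypes evolved from an ancestral-Platyrrhini-like karyotype by
  typed rearrangement events (centric fusion/fission, pericentric and
  paracentric inversions, tandem fusion, one sex-autosome translocation),
  exported as homology maps against the ancestral segment alphabet.

No event creates or destroys ancestral segments, so every leaf karyotype
carries each ancestral segment exactly once — asserted after every event.
A recovery experiment closes the loop: simulate, code characters, search
exhaustively, and compare against the generating topology.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

from .characters import CharacterDefinition, CharacterMatrix, build_matrix
from .karyotype import HomologyMap, ProbeSegment, TargetChromosome
from .parsimony import exhaustive_search
from .synteny import detect_associations
from .trees import PhyloTree, _adjacency, robinson_foulds

__all__ = [
    "CharacterSimConfig",
    "KaryotypeSimConfig",
    "RearrangementEvent",
    "EVENT_TYPES",
    "ancestral_platyrrhini_karyotype",
    "simulate_characters",
    "simulate_karyotype_evolution",
    "recovery_experiment",
    "RecoveryReport",
]

EVENT_TYPES = (
    "centric_fusion",
    "centric_fission",
    "pericentric_inversion",
    "paracentric_inversion",
    "tandem_fusion",
    "sex_autosome_translocation",
)


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CharacterSimConfig:
    """Binary characters on a known tree.

    ``change_prob`` is the per-branch probability that a character flips
    state across that branch (symmetric 0<->1), in [0, 0.5).
    ``root_state_prob`` is the probability of state 1 at the root.
    """

    tree: PhyloTree
    n_characters: int
    change_prob: float = 0.05
    root_state_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.change_prob < 0.5:
            raise ValueError("change_prob must be in [0, 0.5)")
        if not 0 <= self.root_state_prob <= 1:
            raise ValueError("root_state_prob must be a probability")
        if self.n_characters < 1:
            raise ValueError("n_characters must be >= 1")


@dataclass(frozen=True)
class RearrangementEvent:
    """One applied karyotype mutation."""

    type: str
    branch: str
    operands: tuple
    index: int  # running number within the simulation

    def __post_init__(self) -> None:
        if self.type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.type!r}")

    @property
    def label(self) -> str:
        ops = ",".join(str(o) for o in self.operands)
        return f"{self.type}[{ops}]@{self.branch}#{self.index}"


@dataclass(frozen=True)
class KaryotypeSimConfig:
    """Karyotype evolution on a known tree.

    ``mean_events`` is the Poisson mean number of rearrangements per
    branch; ``event_weights`` the relative draw weights per event type.
    The default ancestral karyotype is a 22-autosome construction
    embedding the six ancestral Platyrrhini associations (a package
    convention for testing, not a scientific claim).
    """

    tree: PhyloTree
    mean_events: float = 1.0
    event_weights: dict[str, float] = field(
        default_factory=lambda: {
            "centric_fusion": 2.0,
            "centric_fission": 2.0,
            "pericentric_inversion": 1.0,
            "paracentric_inversion": 1.0,
            "tandem_fusion": 1.0,
            "sex_autosome_translocation": 0.25,
        }
    )
    seed: int = 0
    max_retries: int = 10

    def __post_init__(self) -> None:
        if self.mean_events < 0:
            raise ValueError("mean_events must be >= 0")
        bad = set(self.event_weights) - set(EVENT_TYPES)
        if bad:
            raise ValueError(f"unknown event types in weights: {sorted(bad)}")
        if any(w < 0 for w in self.event_weights.values()) or not any(
            w > 0 for w in self.event_weights.values()
        ):
            raise ValueError("event weights must be non-negative, not all zero")


# ---------------------------------------------------------------------------
# tree plumbing shared by both simulators
# ---------------------------------------------------------------------------

def _rooted_edges(tree: PhyloTree, anchor: str):
    """Represent the unrooted tree rooted at ``anchor``'s attachment node.

    Returns (children, leaf_label) maps over integer node ids plus the
    top node id and the anchor's node id; every node except the top has
    exactly one branch above it, and the anchor leaf's branch is the
    top's own edge.
    """
    adj, labels, _ = _adjacency(tree.unroot().nested)
    anchor_node = next(n for n, lbl in labels.items() if lbl == anchor)
    (top,) = adj[anchor_node]
    children: dict[int, list[int]] = {}

    def walk(node: int, parent: int) -> None:
        kids = [nb for nb in adj[node] if nb != parent]
        children[node] = kids
        for k in kids:
            walk(k, node)

    walk(top, anchor_node)
    return children, labels, top, anchor_node


def _branch_name(labels, children, node) -> str:
    """Stable branch id: sorted leaves below the branch."""
    below: list[str] = []

    def collect(n):
        if n in labels:
            below.append(labels[n])
        else:
            for k in children.get(n, ()):
                collect(k)

    collect(node)
    return "|".join(sorted(below))


# ---------------------------------------------------------------------------
# character simulation
# ---------------------------------------------------------------------------

def simulate_characters(
    config: CharacterSimConfig,
) -> tuple[CharacterMatrix, list[tuple[str, int]]]:
    """Evolve ``n_characters`` independent binary characters down the tree.

    Returns the leaf matrix (taxa sorted alphabetically) and the flip
    record, one ``(branch_id, character_index)`` entry per state change;
    branch ids name the sorted leaf set below the branch.
    """
    taxa = sorted(config.tree.taxa)
    anchor = taxa[0]
    children, labels, top, anchor_node = _rooted_edges(config.tree, anchor)
    rng = np.random.default_rng(config.seed)
    p = config.change_prob

    leaf_states: dict[str, list[str]] = {t: [] for t in taxa}
    flips: list[tuple[str, int]] = []

    for j in range(config.n_characters):
        root_state = int(rng.random() < config.root_state_prob)

        def descend(node: int, state: int) -> None:
            for kid in children.get(node, ()):
                s = state
                if p > 0 and rng.random() < p:
                    s ^= 1
                    flips.append((_branch_name(labels, children, kid), j))
                if kid in labels:
                    leaf_states[labels[kid]].append(str(s))
                else:
                    descend(kid, s)

        # the anchor leaf hangs off the top node by its own branch
        s_anchor = root_state
        if p > 0 and rng.random() < p:
            s_anchor ^= 1
            flips.append((anchor, j))
        leaf_states[anchor].append(str(s_anchor))
        descend(top, root_state)

    chars = [CharacterDefinition(f"c{j+1}", f"c{j+1}") for j in range(config.n_characters)]
    matrix = CharacterMatrix(taxa, chars, [leaf_states[t] for t in taxa])
    return matrix, flips


# ---------------------------------------------------------------------------
# karyotype simulation
# ---------------------------------------------------------------------------

class _SimKaryotype:
    """Haploid karyotype state: ordered autosomes of ancestral segments,
    an X, and (after a translocation) a Y-autosome composite + X2."""

    def __init__(self, autosomes: list[list[str]]):
        self.autosomes = [list(c) for c in autosomes]
        self.sex_system = "XY"
        self.y_segments: list[str] = []

    def copy(self) -> "_SimKaryotype":
        k = _SimKaryotype(self.autosomes)
        k.sex_system = self.sex_system
        k.y_segments = list(self.y_segments)
        return k

    def all_segments(self) -> list[str]:
        out = [s for c in self.autosomes for s in c]
        out.extend(self.y_segments)
        return out


def ancestral_platyrrhini_karyotype() -> _SimKaryotype:
    """A 22-autosome ancestral karyotype embedding the six catalogue
    associations (3a/21, 5/7a, 2b/16b, 8a/18, 14/15a, 10a/16a); the
    remaining segments sit on single-form chromosomes."""
    assoc = [["3a", "21"], ["5", "7a"], ["2b", "16b"], ["8a", "18"],
             ["14", "15a"], ["10a", "16a"]]
    singles = [["1"], ["2a"], ["4"], ["6"], ["7b"], ["8b"], ["9"], ["10b"],
               ["11"], ["12"], ["13"], ["15b"], ["17"], ["19"], ["20"], ["22"]]
    return _SimKaryotype(assoc + singles)


def _applicable(karyo: _SimKaryotype, etype: str) -> bool:
    if etype in ("centric_fusion", "tandem_fusion"):
        return len(karyo.autosomes) >= 2
    if etype == "centric_fission":
        return any(len(c) >= 2 for c in karyo.autosomes)
    if etype in ("pericentric_inversion", "paracentric_inversion"):
        return any(len(c) >= 2 for c in karyo.autosomes)
    if etype == "sex_autosome_translocation":
        return karyo.sex_system == "XY" and len(karyo.autosomes) >= 1
    return False


def _apply_event(
    karyo: _SimKaryotype, etype: str, rng: np.random.Generator
) -> Optional[tuple]:
    """Mutate ``karyo`` in place; return the operand tuple, or None if the
    drawn operands were inapplicable."""
    auts = karyo.autosomes
    if etype in ("centric_fusion", "tandem_fusion"):
        if len(auts) < 2:
            return None
        i, j = rng.choice(len(auts), size=2, replace=False)
        i, j = int(i), int(j)
        merged = auts[i] + auts[j]
        ops = (tuple(auts[i]), tuple(auts[j]))
        karyo.autosomes = [c for k, c in enumerate(auts) if k not in (i, j)]
        karyo.autosomes.append(merged)
        return ops
    if etype == "centric_fission":
        cands = [k for k, c in enumerate(auts) if len(c) >= 2]
        if not cands:
            return None
        k = int(rng.choice(cands))
        cut = int(rng.integers(1, len(auts[k])))
        left, right = auts[k][:cut], auts[k][cut:]
        karyo.autosomes = (
            auts[:k] + auts[k + 1:] + [left, right]
        )
        return (tuple(left), tuple(right))
    if etype in ("pericentric_inversion", "paracentric_inversion"):
        cands = [k for k, c in enumerate(auts) if len(c) >= 2]
        if not cands:
            return None
        k = int(rng.choice(cands))
        chrom = auts[k]
        a = int(rng.integers(0, len(chrom) - 1))
        b = int(rng.integers(a + 2, len(chrom) + 1))
        chrom[a:b] = chrom[a:b][::-1]
        return (tuple(chrom), a, b)
    if etype == "sex_autosome_translocation":
        if karyo.sex_system != "XY" or not auts:
            return None
        k = int(rng.integers(0, len(auts)))
        moved = auts[k]
        karyo.autosomes = auts[:k] + auts[k + 1:]
        karyo.y_segments = list(moved)
        karyo.sex_system = "X1X2Y"
        return (tuple(moved),)
    raise ValueError(etype)


_SEG_RE = re.compile(r"^(\d+|[XY])([a-z]\d?)?$")


def _karyotype_to_map(
    karyo: _SimKaryotype, probe_species: str, target_species: str,
    probe_chroms: list[str],
) -> HomologyMap:
    chroms = []
    for i, segs in enumerate(karyo.autosomes, start=1):
        chroms.append(
            TargetChromosome(
                str(i),
                [_segment(s) for s in segs],
            )
        )
    chroms.append(TargetChromosome("X", [ProbeSegment("X")]))
    n_aut = len(karyo.autosomes)
    if karyo.sex_system == "X1X2Y":
        chroms.append(TargetChromosome("Y", [_segment(s) for s in karyo.y_segments]))
        chroms.append(TargetChromosome("X2"))
        female = 2 * n_aut + 4
        male = female - 1
    else:
        female = male = 2 * (n_aut + 1)
    return HomologyMap(
        probe_species=probe_species,
        target_species=target_species,
        diploid_number_female=female,
        diploid_number_male=male,
        sex_system=karyo.sex_system,
        chromosomes=chroms,
        probe_chroms=probe_chroms,
    )


def _segment(seg_id: str) -> ProbeSegment:
    m = _SEG_RE.fullmatch(seg_id)
    if not m:
        raise ValueError(f"bad segment id {seg_id!r}")
    return ProbeSegment(m.group(1), m.group(2))


def simulate_karyotype_evolution(
    config: KaryotypeSimConfig,
    ancestral: Optional[_SimKaryotype] = None,
) -> tuple[dict[str, HomologyMap], CharacterMatrix, list[RearrangementEvent]]:
    """Evolve the ancestral karyotype along the tree.

    Per branch the event count is Poisson(``mean_events``); each event's
    type is drawn by weight and its operands uniformly over applicable
    choices, resampling an inapplicable draw up to ``max_retries`` times
    before skipping it.  Returns the leaf homology maps (against the
    ancestral segment alphabet), the true event presence/absence matrix
    (one column per applied event, 1 for every leaf below its branch) and
    the applied-event log.  Segment conservation is asserted after every
    event.
    """
    if ancestral is None:
        ancestral = ancestral_platyrrhini_karyotype()
    base_segments = sorted(ancestral.all_segments())
    probe_bases = sorted(
        {_SEG_RE.fullmatch(s).group(1) for s in base_segments},
        key=lambda b: (len(b), b),
    ) + ["X", "Y"]

    taxa = sorted(config.tree.taxa)
    anchor = taxa[0]
    children, labels, top, _ = _rooted_edges(config.tree, anchor)
    rng = np.random.default_rng(config.seed)
    weights = np.array([config.event_weights.get(t, 0.0) for t in EVENT_TYPES])
    weights = weights / weights.sum()

    events: list[RearrangementEvent] = []
    presence: dict[int, set[str]] = {}  # event index -> leaves carrying it
    leaf_maps: dict[str, HomologyMap] = {}

    def leaves_below(node: int) -> list[str]:
        if node in labels:
            return [labels[node]]
        out: list[str] = []
        for k in children.get(node, ()):
            out.extend(leaves_below(k))
        return out

    def mutate(karyo: _SimKaryotype, branch_id: str, below: list[str]) -> None:
        n_events = int(rng.poisson(config.mean_events))
        for _ in range(n_events):
            ops = None
            for _attempt in range(config.max_retries):
                etype = str(rng.choice(EVENT_TYPES, p=weights))
                if not _applicable(karyo, etype):
                    continue
                ops = _apply_event(karyo, etype, rng)
                if ops is not None:
                    break
            if ops is None:
                continue  # bounded retries exhausted: skip, keep count honest
            assert sorted(karyo.all_segments()) == base_segments, (
                "segment conservation violated"
            )
            ev = RearrangementEvent(etype, branch_id, ops, len(events))
            events.append(ev)
            presence[ev.index] = set(below)

    def descend(node: int, karyo: _SimKaryotype) -> None:
        for kid in children.get(node, ()):
            below = leaves_below(kid)
            child_karyo = karyo.copy()
            mutate(child_karyo, "|".join(sorted(below)), below)
            if kid in labels:
                leaf_maps[labels[kid]] = _karyotype_to_map(
                    child_karyo, "ANC", labels[kid], probe_bases
                )
            else:
                descend(kid, child_karyo)

    # anchor leaf branch first (its own edge off the top node)
    anchor_karyo = ancestral.copy()
    mutate(anchor_karyo, anchor, [anchor])
    leaf_maps[anchor] = _karyotype_to_map(anchor_karyo, "ANC", anchor, probe_bases)
    descend(top, ancestral.copy())

    chars = [
        CharacterDefinition(f"e{ev.index + 1}", ev.label, f"simulated {ev.type}")
        for ev in events
    ]
    states = [
        ["1" if t in presence[ev.index] else "0" for ev in events] for t in taxa
    ]
    truth = CharacterMatrix(taxa, chars, states)
    return leaf_maps, truth, events


# ---------------------------------------------------------------------------
# recovery experiment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RecoveryReport:
    """End-to-end pipeline validation against the generating topology.

    ``recovery_fraction`` counts runs where the generating topology is
    among the most-parsimonious trees; ``unique_recovery_fraction`` the
    stricter condition that it is the single MP tree.  Runs without any
    variable character cannot be evaluated and are reported separately.
    """

    n_runs: int
    n_evaluated: int
    recovery_fraction: float
    unique_recovery_fraction: float
    mean_rf: float
    n_undefined: int

    @property
    def defined(self) -> bool:
        return self.n_evaluated > 0


def _canonical_form_label(form) -> str:
    return "/".join(sorted(str(t) for t in form.tokens))


def recovery_experiment(
    config: CharacterSimConfig | KaryotypeSimConfig,
    n_runs: int,
    seed: int = 0,
) -> RecoveryReport:
    """Simulate -> code -> search -> compare, ``n_runs`` times.

    Character configs feed the simulated matrix straight to the search;
    karyotype configs first code each leaf map's detected syntenic
    associations as binary presence/absence characters.  Run r uses the
    deterministic seed substream (seed, r).
    """
    true_tree = config.tree.unroot()
    hits = unique_hits = 0
    rf_sum = 0.0
    undefined = 0
    for r in range(n_runs):
        run_seed = int(np.random.default_rng([seed, r]).integers(0, 2**31 - 1))
        if isinstance(config, CharacterSimConfig):
            matrix, _ = simulate_characters(replace(config, seed=run_seed))
        else:
            leaf_maps, _, _ = simulate_karyotype_evolution(
                replace(config, seed=run_seed)
            )
            obs = []
            forms: set[str] = set()
            per_taxon: dict[str, set[str]] = {}
            for taxon, hmap in leaf_maps.items():
                labels = {
                    _canonical_form_label(a.form)
                    for a in detect_associations(hmap)
                }
                per_taxon[taxon] = labels
                forms |= labels
            for taxon in sorted(leaf_maps):
                for f in sorted(forms):
                    obs.append((taxon, f, f in per_taxon[taxon]))
            if not forms:
                undefined += 1
                continue
            matrix = build_matrix(obs)
        variable = any(
            len({row[j] for row in matrix.states} - {"?"}) > 1
            for j in range(matrix.n_characters)
        )
        if not variable:
            undefined += 1
            continue
        res = exhaustive_search(matrix)
        in_set = any(t == true_tree for t in res.mp_trees)
        hits += in_set
        unique_hits += in_set and len(res.mp_trees) == 1
        rf_sum += float(
            np.mean([robinson_foulds(t, true_tree) for t in res.mp_trees])
        )
    n_eval = n_runs - undefined
    return RecoveryReport(
        n_runs=n_runs,
        n_evaluated=n_eval,
        recovery_fraction=hits / n_eval if n_eval else float("nan"),
        unique_recovery_fraction=unique_hits / n_eval if n_eval else float("nan"),
        mean_rf=rf_sum / n_eval if n_eval else float("nan"),
        n_undefined=undefined,
    )
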