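"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import pytest

from karyophy import fixtures as fx
from karyophy.characters import pitheciinae_fixture
from karyophy.trees import PhyloTree, read_newick


@pytest.fixture(scope="session")
def pir_map():
    return fx.load_hsa_pir()


@pytest.fixture(scope="session")
def ccr_map():
    return fx.load_hsa_ccr()


@pytest.fixture(scope="session")
def soe_map():
    return fx.load_soe_ccr()


@pytest.fixture(scope="session")
def cut_map():
    return fx.load_hsa_cut()


@pytest.fixture(scope="session")
def catalogue():
    return fx.ancestral_catalogue()


@pytest.fixture(scope="session")
def fixture_matrix():
    return pitheciinae_fixture()


@pytest.fixture(scope="session")
def balanced5() -> PhyloTree:
    return read_newick("((A,B),(C,D),E);")


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def brute_force_char_steps(tree: PhyloTree, column: dict[str, str]) -> int:
    """Minimum changes of one binary character on ``tree`` by exhaustive
    enumeration of all internal-node state assignments (and all completions
    of '?' leaves).  Independent of the Fitch implementation."""
    nested = tree.unroot().nested
    internals: list = []

    def collect(node):
        if isinstance(node, str):
            return
        internals.append(node)
        for c in node:
            collect(c)

    collect(nested)
    ids = {id(n): i for i, n in enumerate(internals)}
    qs = [t for t, s in column.items() if s == "?"]
    best = None
    for fill in itertools.product("01", repeat=len(qs)):
        leaf_state = dict(column)
        leaf_state.update(zip(qs, fill))
        for assign in itertools.product("01", repeat=len(internals)):

            def node_state(n):
                return leaf_state[n] if isinstance(n, str) else assign[ids[id(n)]]

            cost = 0
            stack = [nested]
            while stack:
                n = stack.pop()
                s = node_state(n)
                for c in n:
                    if node_state(c) != s:
                        cost += 1
                    if not isinstance(c, str):
                        stack.append(c)
            if best is None or cost < best:
                best = cost
    return best


def maps_equal(a, b) -> bool:
    """Field-wise homology-map equality, robust to row/segment ordering."""
    def canon(m):
        return (
            m.probe_species,
            m.target_species,
            m.diploid_number_female,
            m.diploid_number_male,
            m.sex_system,
            tuple(sorted(m.probe_chroms)),
            {
                c.chrom_id: sorted(
                    (s.probe_chrom, s.sub_segment or "", s.region_note or "")
                    for s in c.segments
                )
                for c in m.chromosomes
            },
        )

    return canon(a) == canon(b)
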