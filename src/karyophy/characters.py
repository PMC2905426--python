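"""Binary chromosomal character matrices for cladistic analysis.

Each character is the presence (1) / absence (0) of a discrete
chromosomal trait — a syntenic association retained from an ancestral
karyotype, or a derived rearrangement product (a fusion, fission or
inversion outcome, a morphology change, a sex-autosome translocation).
Unknown states are ``?``.  Matrices serialise to NEXUS (DATA block,
``symbols="01" missing=?``) and TSV.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import dendropy
import pandas as pd

__all__ = [
    "CharacterDefinition",
    "CharacterMatrix",
    "build_matrix",
    "pitheciinae_fixture",
    "to_nexus",
    "from_nexus",
    "write_nexus",
    "read_nexus",
    "to_tsv",
    "from_tsv",
    "ObservationError",
]

STATES = ("0", "1", "?")

_PRESENT = {"present", "1", 1, True}
_ABSENT = {"absent", "0", 0, False}
_UNKNOWN = {"unknown", "?", None}


class ObservationError(ValueError):
    """Contradictory or malformed character observations."""


@dataclass(frozen=True)
class CharacterDefinition:
    """One binary character: an identifier, the chromosome-form or
    rearrangement it encodes, and a free-text source note."""

    id: str
    label: str
    source: str = ""


@dataclass
class CharacterMatrix:
    """Taxa x binary characters, states in {0, 1, ?}."""

    taxa: list[str]
    characters: list[CharacterDefinition]
    states: list[list[str]]  # row per taxon, entry per character

    def __post_init__(self) -> None:
        if len(self.states) != len(self.taxa):
            raise ValueError("one state row per taxon required")
        ncol = len(self.characters)
        ids = [c.id for c in self.characters]
        if len(set(ids)) != len(ids):
            raise ValueError("character ids must be unique")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("taxon names must be unique")
        for t, row in zip(self.taxa, self.states):
            if len(row) != ncol:
                raise ValueError(f"row for {t!r} has wrong length")
            bad = set(row) - set(STATES)
            if bad:
                raise ValueError(f"states outside {{0,1,?}} for {t!r}: {bad}")
        for j in range(ncol):
            if all(row[j] == "?" for row in self.states):
                raise ValueError(
                    f"character {self.characters[j].id!r} is entirely missing"
                )

    # -- access -------------------------------------------------------------
    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_characters(self) -> int:
        return len(self.characters)

    def column(self, j: int) -> dict[str, str]:
        return {t: row[j] for t, row in zip(self.taxa, self.states)}

    def state(self, taxon: str, j: int) -> str:
        return self.states[self.taxa.index(taxon)][j]

    def subset_characters(self, indices: Sequence[int]) -> "CharacterMatrix":
        """Matrix restricted to (possibly repeated) character columns —
        the bootstrap resampling primitive."""
        chars = []
        for k, j in enumerate(indices):
            c = self.characters[j]
            # resampled ids must stay unique
            chars.append(CharacterDefinition(f"{c.id}.{k}", c.label, c.source))
        states = [[row[j] for j in indices] for row in self.states]
        return CharacterMatrix(list(self.taxa), chars, states)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.states,
            index=pd.Index(self.taxa, name="taxon"),
            columns=[c.id for c in self.characters],
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, CharacterMatrix):
            return NotImplemented
        return (
            self.taxa == other.taxa
            and [c.id for c in self.characters] == [c.id for c in other.characters]
            and self.states == other.states
        )


# ---------------------------------------------------------------------------
# building from observations
# ---------------------------------------------------------------------------

def _norm_state(value) -> str:
    if isinstance(value, str):
        value = value.strip().lower()
    if value in _PRESENT:
        return "1"
    if value in _ABSENT:
        return "0"
    if value in _UNKNOWN:
        return "?"
    raise ObservationError(f"unrecognised state {value!r}")


def build_matrix(
    observations: Iterable[tuple[str, str, object]],
    default_state: Optional[str] = None,
) -> CharacterMatrix:
    """Assemble a matrix from (taxon, form label, state) observations.

    One column per distinct form label, columns sorted by label; taxa keep
    first-appearance order.  Unobserved (taxon, form) pairs become ``?``
    unless ``default_state`` ("0" or "1") is given.  Duplicate observations
    must agree, otherwise :class:`ObservationError` names the conflict.
    """
    taxa: list[str] = []
    seen: dict[tuple[str, str], str] = {}
    labels: set[str] = set()
    for taxon, label, state in observations:
        s = _norm_state(state)
        key = (taxon, label)
        if key in seen and seen[key] != s:
            raise ObservationError(
                f"contradictory observations for taxon {taxon!r}, "
                f"character {label!r}: {seen[key]} vs {s}"
            )
        seen[key] = s
        labels.add(label)
        if taxon not in taxa:
            taxa.append(taxon)
    if len(taxa) < 2:
        raise ObservationError("at least two taxa are required")
    fill = "?" if default_state is None else _norm_state(default_state)
    cols = sorted(labels)
    chars = [CharacterDefinition(f"c{j+1}", lbl) for j, lbl in enumerate(cols)]
    states = [[seen.get((t, lbl), fill) for lbl in cols] for t in taxa]
    return CharacterMatrix(taxa, chars, states)


# ---------------------------------------------------------------------------
# the reconstructed Pitheciinae matrix
# ---------------------------------------------------------------------------

#: taxa of the study: three pitheciine ingroup taxa and two outgroups
#: (Brachyteles arachnoides, Cebus apella).
PITHECIINAE_TAXA = ("PIR", "CCR", "CUT", "BAR", "CAP")

# (label, source note, kind, states for PIR/CCR/CUT). kind "derived":
# outgroups 0; kind "retention": outgroups 1 under the ancestral policy.
_FIXTURE_CHARACTERS: list[tuple[str, str, str, tuple[str, str, str]]] = [
    # --- synapomorphies of the whole subfamily ---------------------------
    ("fusion 2a/10b", "pitheciine synapomorphy: fused 2a/10b form",
     "derived", ("1", "1", "1")),
    ("acrocentric 15/14", "pitheciine synapomorphy: 14/15a homologue acrocentric",
     "derived", ("1", "1", "1")),
    ("acrocentric 19", "pitheciine synapomorphy: human-19 homologue acrocentric",
     "derived", ("1", "1", "1")),
    ("inversion 16a/10a/16a/10a",
     "pericentric inversion of the 10a/16a form, interleaving the blocks; "
     "shared with Callicebus but derived relative to the outgroups",
     "derived", ("1", "1", "1")),
    # --- CCR + CUT exclusive synapomorphies ------------------------------
    ("fission 5a1+5a2", "Cacajao+Chiropotes: human-5 material fissioned into "
     "separate 5a1 and 5a2 segments", "derived", ("0", "1", "1")),
    ("fusion 20/15/14", "Cacajao+Chiropotes: 14/15a further fused with 20",
     "derived", ("0", "1", "1")),
    ("acrocentric 5/7a", "Cacajao+Chiropotes: 5/7a association on a derived "
     "acrocentric chromosome", "derived", ("0", "1", "1")),
    # --- PIR + CCR shared derived forms ----------------------------------
    ("acrocentric 7b", "Pithecia+Cacajao: pericentric inversion made the "
     "7b homologue acrocentric", "derived", ("1", "1", "0")),
    ("acrocentric 12", "Pithecia+Cacajao: human-12 homologue acrocentric",
     "derived", ("1", "1", "0")),
    # --- ancestral Platyrrhini associations retained by all three --------
    ("association 3a/21", "ancestral Platyrrhini association retained",
     "retention", ("1", "1", "1")),
    ("association 5/7a", "ancestral Platyrrhini association retained",
     "retention", ("1", "1", "1")),
    ("association 2b/16b", "ancestral Platyrrhini association retained",
     "retention", ("1", "1", "1")),
    ("association 8a/18", "ancestral Platyrrhini association retained",
     "retention", ("1", "1", "1")),
    ("association 14/15a", "ancestral Platyrrhini association retained",
     "retention", ("1", "1", "1")),
    ("association 10a/16a", "ancestral Platyrrhini association retained "
     "(in the inverted 16a/10a/16a/10a arrangement)",
     "retention", ("1", "1", "1")),
    # --- autapomorphies ---------------------------------------------------
    ("paracentric inversion 3a/21", "Pithecia only: ancestral 3a/21 form "
     "modified by a paracentric inversion", "derived", ("1", "0", "0")),
    ("fusion 13/22", "Pithecia only: 13 and 22 homologues fused (PIR 8)",
     "derived", ("1", "0", "0")),
    ("fusion 1b/15b", "Pithecia only: 1b and 15b segments fused (PIR 9)",
     "derived", ("1", "0", "0")),
    ("Y-autosome translocation 11", "Cacajao only: human-11 homologue "
     "translocated to the Y (X1X2Y system)", "derived", ("0", "1", "0")),
    ("fusion 3c/20/15/14", "Cacajao only: 20/15/14 further fused with 3c "
     "(CCR 1, form 3/20/15/14)", "derived", ("0", "1", "0")),
    ("fusion 1c/12", "Cacajao only: 1c and 12 segments fused (CCR 6)",
     "derived", ("0", "1", "0")),
    ("fusion 3b/5a1", "Cacajao only: 3b fused with 5a1 (CCR 2, form 3/5)",
     "derived", ("0", "1", "0")),
    ("pericentric inversion 2b/16b", "Chiropotes only: morphology of the "
     "2b/16b homologue changed by a pericentric inversion",
     "derived", ("0", "0", "1")),
]


def pitheciinae_fixture(outgroup_policy: str = "ancestral") -> CharacterMatrix:
    """The reconstructed 5-taxon binary chromosome character matrix.

    Taxa: PIR (*Pithecia irrorata*), CCR (*Cacajao calvus rubicundus*),
    CUT (*Chiropotes utahicki*) and the outgroups BAR (*Brachyteles
    arachnoides*), CAP (*Cebus apella*).  Columns encode the documented
    subfamily synapomorphies, the CCR+CUT and PIR+CCR shared derived
    forms, the six retained ancestral Platyrrhini associations and the
    per-taxon autapomorphies; each column's ``source`` states what it
    encodes.  This is a reconstruction: the study's own supplementary
    matrix, when available, should be read with :func:`from_nexus`.

    ``outgroup_policy`` — "ancestral" codes outgroups 0 for derived forms
    and 1 for ancestral retentions (standard polarity convention);
    "unknown" codes all outgroup cells ``?``.
    """
    if outgroup_policy not in ("ancestral", "unknown"):
        raise ValueError("outgroup_policy must be 'ancestral' or 'unknown'")
    chars = []
    columns = []
    for j, (label, source, kind, ingroup) in enumerate(_FIXTURE_CHARACTERS):
        chars.append(CharacterDefinition(f"c{j+1}", label, source))
        if outgroup_policy == "unknown":
            out_state = "?"
        else:
            out_state = "1" if kind == "retention" else "0"
        columns.append(tuple(ingroup) + (out_state, out_state))
    states = [[col[i] for col in columns] for i in range(len(PITHECIINAE_TAXA))]
    return CharacterMatrix(list(PITHECIINAE_TAXA), chars, states)


# ---------------------------------------------------------------------------
# NEXUS serialization
# ---------------------------------------------------------------------------

def _nexus_quote(label: str) -> str:
    if re.search(r"[\s(){}\[\]/\\,;:=*'\"`+<>-]", label):
        return "'" + label.replace("'", "''") + "'"
    return label


def to_nexus(matrix: CharacterMatrix) -> str:
    """Serialise to a NEXUS DATA block (``symbols="01" missing=?``) with
    CHARLABELS carrying the character labels."""
    if matrix.n_characters == 0 or matrix.n_taxa == 0:
        raise ValueError("cannot serialise an empty matrix")
    lines = [
        "#NEXUS",
        "BEGIN DATA;",
        f"    DIMENSIONS NTAX={matrix.n_taxa} NCHAR={matrix.n_characters};",
        '    FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=?;',
        "    CHARLABELS",
        "        "
        + " ".join(_nexus_quote(c.label) for c in matrix.characters),
        "    ;",
        "    MATRIX",
    ]
    width = max(len(_nexus_quote(t)) for t in matrix.taxa) + 2
    for taxon, row in zip(matrix.taxa, matrix.states):
        lines.append(f"        {_nexus_quote(taxon):<{width}}{''.join(row)}")
    lines += ["    ;", "END;", ""]
    return "\n".join(lines)


_CHARLABELS_RE = re.compile(r"CHARLABELS\s+(.*?);", re.IGNORECASE | re.DOTALL)
_LABEL_TOKEN_RE = re.compile(r"'((?:[^']|'')*)'|(\S+)")


def from_nexus(text: str) -> CharacterMatrix:
    """Parse a NEXUS standard (binary) matrix.

    Taxa and states come from dendropy's NEXUS parser; character labels
    are recovered from the CHARLABELS block (dendropy does not expose it)
    and default to ``c1..cN`` when absent.
    """
    try:
        dmat = dendropy.StandardCharacterMatrix.get(data=text, schema="nexus")
    except Exception as exc:
        raise ValueError(f"malformed NEXUS matrix: {exc}") from exc
    taxa = [t.label for t in dmat.taxon_namespace]
    states = []
    for t in dmat.taxon_namespace:
        row = [str(s) for s in dmat[t].symbols_as_list()]
        bad = set(row) - set(STATES)
        if bad:
            raise ValueError(f"states outside the 01? alphabet: {sorted(bad)}")
        states.append(row)
    ncol = len(states[0]) if states else 0
    labels = [f"c{j+1}" for j in range(ncol)]
    m = _CHARLABELS_RE.search(text)
    if m:
        found = [
            (g1.replace("''", "'") if g1 else g2)
            for g1, g2 in _LABEL_TOKEN_RE.findall(m.group(1))
        ]
        if len(found) == ncol:
            labels = found
    chars = [CharacterDefinition(f"c{j+1}", lbl) for j, lbl in enumerate(labels)]
    return CharacterMatrix(taxa, chars, states)


def write_nexus(matrix: CharacterMatrix, path: str | Path) -> None:
    Path(path).write_text(to_nexus(matrix), encoding="utf-8")


def read_nexus(path: str | Path) -> CharacterMatrix:
    return from_nexus(Path(path).read_text(encoding="utf-8"))


# ---------------------------------------------------------------------------
# TSV serialization
# ---------------------------------------------------------------------------

def to_tsv(matrix: CharacterMatrix, path: str | Path) -> None:
    """Taxa as rows, characters as columns (header = character labels)."""
    df = matrix.to_dataframe()
    df.columns = [c.label for c in matrix.characters]
    df.to_csv(path, sep="\t")


def from_tsv(path: str | Path) -> CharacterMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    taxa = [str(t) for t in df.index]
    chars = [
        CharacterDefinition(f"c{j+1}", str(lbl)) for j, lbl in enumerate(df.columns)
    ]
    states = [[str(v) for v in df.loc[t]] for t in df.index]
    return CharacterMatrix(taxa, chars, states)
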