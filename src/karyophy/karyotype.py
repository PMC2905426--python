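"""Domain model and file I/O for karyotypes and cross-species homology maps.

A homology map records the result of one chromosome-painting (ZOO-FISH)
experiment: whole-chromosome probes of one species hybridised onto
metaphases of another.  Every contiguous painted block is one
*hybridisation signal*; a target chromosome carrying material from two or
more probe chromosomes is a *syntenic association*.

The on-disk format is a small TSV dialect::

    # probe_species: HSA
    # target_species: PIR
    # diploid_female: 48
    # diploid_male: 48
    # sex_system: XY
    # probe_chroms: 1,2,...,22,X,Y
    probe_chrom<TAB>targets
    HSA1<TAB>10;9:q;23

``targets`` is a semicolon-separated list of ``chrom[:qualifier]``
entries.  The qualifier is the free-text positional note from the source
table ("q", "distal p", "proximal q + p", "proximal p-distal q", ...).
One target entry is always exactly one signal, even when the qualifier
describes a discontiguous span (interleaved inversion products such as
16/10/16/10 carry a two-block qualifier but were scored as one signal
per probe).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional

__all__ = [
    "ProbeSegment",
    "TargetChromosome",
    "HomologyMap",
    "ChromosomeForm",
    "FormToken",
    "read_homology_table",
    "write_homology_table",
    "validate_map",
    "parse_form_label",
    "HomologyTableError",
]


class HomologyTableError(ValueError):
    """Raised for unparseable or internally inconsistent homology tables."""


_SUBSEG_RE = re.compile(r"^(\d+|[XY]\d?)([a-z]\d?)?$")

#: Order of named positions along a chromosome, p-arm telomere first.
#: Used only to order tokens inside an association label; bare "p"/"q"
#: sort between the distal/proximal anchors of their arm.
_ARM_POSITIONS = {
    "distal p": 0.0,
    "p": 0.5,
    "proximal p": 1.0,
    "proximal q": 2.0,
    "q": 2.5,
    "distal q": 3.0,
}

#: Position assigned to a segment with no positional note: sorts after
#: every annotated position so unqualified material keeps table order.
_UNPLACED = 9.0


def _position_blocks(region_note: Optional[str]) -> list[float]:
    """Ordered block positions described by a positional qualifier.

    A plain arm note is one block.  A ``+`` compound ("proximal q + p")
    is one contiguous block spanning the centromere.  A ``-`` compound
    ("proximal p-distal q") names two separate blocks of the same signal,
    the interleaved layout produced by an inversion inside an association.
    """
    if not region_note:
        return [_UNPLACED]
    note = region_note.strip()
    if "+" in note:
        parts = [p.strip() for p in note.split("+")]
        keys = [_ARM_POSITIONS.get(p, _UNPLACED) for p in parts]
        return [min(keys)]
    if "-" in note:
        parts = [p.strip() for p in note.split("-")]
        return sorted(_ARM_POSITIONS.get(p, _UNPLACED) for p in parts)
    return [_ARM_POSITIONS.get(note, _UNPLACED)]


@dataclass(frozen=True)
class ProbeSegment:
    """One hybridisation signal: a block homologous to one probe chromosome.

    ``probe_chrom`` is the bare probe chromosome label ("1".."22", "X",
    "Y"); the species prefix lives on the enclosing map.  ``sub_segment``
    is the optional ancestral sub-block letter ("a", "b", "a1") carried
    only where the source names it.  ``region_note`` is the verbatim
    positional qualifier.
    """

    probe_chrom: str
    sub_segment: Optional[str] = None
    region_note: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.probe_chrom:
            raise ValueError("probe_chrom must be non-empty")
        if self.sub_segment is not None and not re.fullmatch(
            r"[a-z]\d?", self.sub_segment
        ):
            raise ValueError(f"bad sub_segment {self.sub_segment!r}")

    @property
    def label(self) -> str:
        """Probe chromosome plus sub-segment letter, e.g. ``"10a"``."""
        return self.probe_chrom + (self.sub_segment or "")

    def position_blocks(self) -> list[float]:
        return _position_blocks(self.region_note)


@dataclass
class TargetChromosome:
    """A chromosome of the painted species with its probe-homologous segments."""

    chrom_id: str
    segments: list[ProbeSegment] = field(default_factory=list)
    morphology: Optional[str] = None  # metacentric|submetacentric|acrocentric
    annotations: list[str] = field(default_factory=list)

    MORPHOLOGIES = ("metacentric", "submetacentric", "acrocentric")

    @property
    def is_sex(self) -> bool:
        return self.chrom_id.rstrip("12") in ("X", "Y")

    @property
    def is_y_composite(self) -> bool:
        """True for a Y carrying translocated autosomal material."""
        return self.chrom_id.startswith("Y") and bool(self.segments)

    def ordered_segments(self) -> list[ProbeSegment]:
        """Segments sorted by their first positional block (stable)."""
        return sorted(self.segments, key=lambda s: s.position_blocks()[0])

    def form(self) -> "ChromosomeForm":
        """The association form of this chromosome as an ordered token string.

        Every positional block contributes one token, so a signal whose
        qualifier names two interleaved blocks appears twice (e.g. the
        inverted ancestral association rendered as 16/10/16/10).
        """
        placed: list[tuple[float, int, str]] = []
        for order, seg in enumerate(self.segments):
            for key in seg.position_blocks():
                placed.append((key, order, seg.label))
        placed.sort(key=lambda t: (t[0], t[1]))
        return ChromosomeForm("/".join(lbl for _, _, lbl in placed))


@dataclass(frozen=True)
class FormToken:
    """One token of a chromosome-form label: base chromosome + optional letter."""

    base: str
    sub: Optional[str] = None

    def matches(self, other: "FormToken") -> bool:
        """Tokens match on base; sub-letters compared only when both present."""
        if self.base != other.base:
            return False
        if self.sub is None or other.sub is None:
            return True
        return self.sub == other.sub

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        return self.base + (self.sub or "")


def _parse_token(tok: str) -> FormToken:
    m = _SUBSEG_RE.fullmatch(tok.strip())
    if not m:
        raise ValueError(f"bad chromosome-form token {tok!r}")
    return FormToken(m.group(1), m.group(2))


def parse_form_label(label: str) -> list[FormToken]:
    """Parse a slash-joined association label like ``"3a/21"``."""
    if not label or not label.strip("/"):
        raise ValueError("empty chromosome-form label")
    return [_parse_token(t) for t in label.split("/")]


@dataclass(frozen=True)
class ChromosomeForm:
    """A slash-joined association string over probe segments, e.g. ``"3/20/15/14"``."""

    label: str

    def __post_init__(self) -> None:
        parse_form_label(self.label)  # validates

    @property
    def tokens(self) -> list[FormToken]:
        return parse_form_label(self.label)

    def token_multiset_contains(self, other: "ChromosomeForm") -> bool:
        """True if ``other``'s tokens inject into this form's token multiset.

        Comparison is order-insensitive; sub-segment letters are compared
        only when present on both sides.
        """
        pool = list(self.tokens)
        for want in other.tokens:
            for i, have in enumerate(pool):
                if have.matches(want):
                    del pool[i]
                    break
            else:
                return False
        return True


def _chrom_sort_key(chrom_id: str) -> tuple[int, int, str]:
    m = re.match(r"^(\d+)", chrom_id)
    if m:
        return (0, int(m.group(1)), chrom_id)
    return (1, 0, chrom_id)


@dataclass
class HomologyMap:
    """One painting experiment: probe species onto target species."""

    probe_species: str
    target_species: str
    diploid_number_female: int
    diploid_number_male: int
    sex_system: str = "XY"  # or "X1X2Y"
    chromosomes: list[TargetChromosome] = field(default_factory=list)
    probe_chroms: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.probe_chroms:
            # human-style default probe set
            self.probe_chroms = [str(i) for i in range(1, 23)] + ["X", "Y"]

    # -- convenience views ------------------------------------------------
    def chromosome(self, chrom_id: str) -> TargetChromosome:
        for c in self.chromosomes:
            if c.chrom_id == chrom_id:
                return c
        raise KeyError(chrom_id)

    def autosomes(self) -> list[TargetChromosome]:
        return [c for c in self.chromosomes if not c.is_sex]

    def autosomal_probe_chroms(self) -> list[str]:
        return [p for p in self.probe_chroms if p.rstrip("12") not in ("X", "Y")]

    def iter_segments(self) -> Iterator[tuple[TargetChromosome, ProbeSegment]]:
        for chrom in self.chromosomes:
            for seg in chrom.segments:
                yield chrom, seg

    def copy(self) -> "HomologyMap":
        return HomologyMap(
            probe_species=self.probe_species,
            target_species=self.target_species,
            diploid_number_female=self.diploid_number_female,
            diploid_number_male=self.diploid_number_male,
            sex_system=self.sex_system,
            chromosomes=[
                TargetChromosome(
                    c.chrom_id, list(c.segments), c.morphology, list(c.annotations)
                )
                for c in self.chromosomes
            ],
            probe_chroms=list(self.probe_chroms),
        )


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_map(hmap: HomologyMap) -> list[str]:
    """Check every structural invariant; return human-readable violations.

    An empty list means the map is internally consistent.
    """
    problems: list[str] = []
    seen: set[str] = set()
    for chrom in hmap.chromosomes:
        if chrom.chrom_id in seen:
            problems.append(f"duplicate target chromosome {chrom.chrom_id!r}")
        seen.add(chrom.chrom_id)
        if not chrom.is_sex and not chrom.segments:
            problems.append(
                f"autosome {chrom.chrom_id!r} carries no probe segment"
            )
        if chrom.morphology is not None and chrom.morphology not in (
            TargetChromosome.MORPHOLOGIES
        ):
            problems.append(
                f"chromosome {chrom.chrom_id!r}: unknown morphology "
                f"{chrom.morphology!r}"
            )
        for seg in chrom.segments:
            if seg.probe_chrom not in hmap.probe_chroms:
                problems.append(
                    f"chromosome {chrom.chrom_id!r}: probe chromosome "
                    f"{hmap.probe_species}{seg.probe_chrom} is not in the "
                    f"declared probe set"
                )
    if hmap.sex_system == "X1X2Y":
        if hmap.diploid_number_male != hmap.diploid_number_female - 1:
            problems.append(
                "X1X2Y sex system requires male 2n = female 2n - 1 "
                f"(got {hmap.diploid_number_male}/{hmap.diploid_number_female})"
            )
    elif hmap.sex_system == "XY":
        if hmap.diploid_number_male != hmap.diploid_number_female:
            problems.append(
                "XY sex system requires equal male and female 2n "
                f"(got {hmap.diploid_number_male}/{hmap.diploid_number_female})"
            )
    else:
        problems.append(f"unknown sex system {hmap.sex_system!r}")
    return problems


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

_META_KEYS = {
    "probe_species",
    "target_species",
    "diploid_female",
    "diploid_male",
    "sex_system",
    "probe_chroms",
    "extra_chromosomes",
}


def _strip_probe_prefix(label: str, species: str) -> str:
    if species and label.upper().startswith(species.upper()):
        label = label[len(species):]
    return label


def read_homology_table(
    path: str | Path,
    probe_species: Optional[str] = None,
    target_species: Optional[str] = None,
) -> HomologyMap:
    """Read a homology map from the TSV dialect described in the module docstring.

    Species names given as arguments override the file's metadata lines.
    Raises :class:`HomologyTableError` on unknown probe labels, duplicate
    target chromosome declarations or missing metadata.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    rows: list[tuple[str, str]] = []
    header_seen = False
    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, val = body.partition(":")
                if key.strip() in _META_KEYS:
                    meta[key.strip()] = val.strip()
            continue
        if not header_seen:
            cols = line.split("\t")
            if cols[:2] != ["probe_chrom", "targets"]:
                raise HomologyTableError(
                    f"{path}:{lineno}: expected header 'probe_chrom\\ttargets'"
                )
            header_seen = True
            continue
        cols = line.split("\t")
        if len(cols) != 2:
            raise HomologyTableError(
                f"{path}:{lineno}: expected 2 tab-separated columns"
            )
        rows.append((cols[0].strip(), cols[1].strip()))

    probe_species = probe_species or meta.get("probe_species")
    target_species = target_species or meta.get("target_species")
    if not probe_species or not target_species:
        raise HomologyTableError(
            f"{path}: probe/target species missing (pass as arguments or "
            "declare '# probe_species:' / '# target_species:' lines)"
        )
    probe_chroms = (
        [c.strip() for c in meta["probe_chroms"].split(",")]
        if "probe_chroms" in meta
        else [str(i) for i in range(1, 23)] + ["X", "Y"]
    )

    chrom_index: dict[str, TargetChromosome] = {}
    order: list[str] = []

    def target(chrom_id: str) -> TargetChromosome:
        if chrom_id not in chrom_index:
            chrom_index[chrom_id] = TargetChromosome(chrom_id)
            order.append(chrom_id)
        return chrom_index[chrom_id]

    for probe_label, targets in rows:
        bare = _strip_probe_prefix(probe_label, probe_species)
        m = _SUBSEG_RE.fullmatch(bare)
        if not m or m.group(1) not in probe_chroms:
            raise HomologyTableError(
                f"{path}: row {probe_label!r}: unknown probe chromosome for "
                f"species {probe_species!r}"
            )
        base, sub = m.group(1), m.group(2)
        if not targets:
            continue
        for entry in targets.split(";"):
            entry = entry.strip()
            if not entry:
                continue
            chrom_id, _, qualifier = entry.partition(":")
            chrom_id = chrom_id.strip()
            seg = ProbeSegment(
                probe_chrom=base,
                sub_segment=sub,
                region_note=qualifier.strip() or None,
            )
            target(chrom_id).segments.append(seg)

    for extra in meta.get("extra_chromosomes", "").split(","):
        extra = extra.strip()
        if extra:
            target(extra)

    hmap = HomologyMap(
        probe_species=probe_species,
        target_species=target_species,
        diploid_number_female=int(meta.get("diploid_female", 0)),
        diploid_number_male=int(meta.get("diploid_male", 0)),
        sex_system=meta.get("sex_system", "XY"),
        chromosomes=[chrom_index[c] for c in order],
        probe_chroms=probe_chroms,
    )
    dup = [c for c in {c.chrom_id for c in hmap.chromosomes}
           if sum(x.chrom_id == c for x in hmap.chromosomes) > 1]
    if dup:
        raise HomologyTableError(f"{path}: duplicate target chromosome(s) {dup}")
    return hmap


def write_homology_table(hmap: HomologyMap, path: str | Path) -> None:
    """Write the TSV dialect; :func:`read_homology_table` inverts it exactly."""
    path = Path(path)
    lines = [
        f"# probe_species: {hmap.probe_species}",
        f"# target_species: {hmap.target_species}",
        f"# diploid_female: {hmap.diploid_number_female}",
        f"# diploid_male: {hmap.diploid_number_male}",
        f"# sex_system: {hmap.sex_system}",
        f"# probe_chroms: {','.join(hmap.probe_chroms)}",
    ]
    empties = [c.chrom_id for c in hmap.chromosomes if not c.segments]
    if empties:
        lines.append(f"# extra_chromosomes: {','.join(empties)}")
    lines.append("probe_chrom\ttargets")

    # rows grouped by probe chromosome + sub-segment, in declared probe order;
    # target entries keep per-chromosome insertion order
    by_probe: dict[str, list[str]] = {}
    probe_order: list[str] = []
    for chrom in hmap.chromosomes:
        for seg in chrom.segments:
            key = seg.label
            entry = chrom.chrom_id + (f":{seg.region_note}" if seg.region_note else "")
            if key not in by_probe:
                by_probe[key] = []
                probe_order.append(key)
            by_probe[key].append(entry)

    def row_key(label: str) -> tuple:
        m = _SUBSEG_RE.fullmatch(label)
        base, sub = (m.group(1), m.group(2) or "") if m else (label, "")
        try:
            idx = hmap.probe_chroms.index(base)
        except ValueError:
            idx = len(hmap.probe_chroms)
        return (idx, sub)

    for label in sorted(probe_order, key=row_key):
        lines.append(
            f"{hmap.probe_species}{label}\t{';'.join(by_probe[label])}"
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
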