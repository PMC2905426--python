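"""Descriptive comparative cytogenetics on homology maps.

Four quantities summarise one painting experiment:

* **signal counts** — hybridisation signals per probe chromosome per
  haploid set (a probe split over three chromosomes contributes three);
* **conserved-synteny classes** — each autosomal probe chromosome is
  WHOLE (its single signal covers an entire target chromosome),
  ASSOCIATED (single signal on a chromosome shared with other probes'
  material) or SPLIT (two or more signals);
* **syntenic associations** — target chromosomes carrying material of two
  or more probe chromosomes (or interleaved repeats of the same probe),
  written as slash-joined forms like ``3/20/15/14``;
* **ancestral matching** — which forms of a reference catalogue (the
  inferred ancestral Platyrrhini associations) are present among the
  detected associations, compared as token multisets so that an inverted
  16/10/16/10 still carries the ancestral 10a/16a.

The X is excluded from autosomal totals; a probe signal on the
Y-autosome composite counts as one autosomal-probe signal (the
translocated material is autosomal) but the composite is reported
separately from the autosomal association list.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .karyotype import (
    ChromosomeForm,
    HomologyMap,
    TargetChromosome,
)

__all__ = [
    "SignalCount",
    "SyntenyClass",
    "Association",
    "AncestralMatch",
    "count_signals",
    "classify_synteny",
    "detect_associations",
    "match_ancestral",
    "synteny_report",
    "association_report",
]


@dataclass(frozen=True)
class SignalCount:
    """Signals per probe chromosome per haploid target set."""

    per_probe_chrom: dict[str, int]
    total_autosomal: int
    total_with_sex: int


@dataclass(frozen=True)
class SyntenyClass:
    """Conserved-synteny class of one autosomal probe chromosome."""

    probe_chrom: str
    synteny_class: str  # WHOLE | ASSOCIATED | SPLIT
    n_signals: int


@dataclass(frozen=True)
class Association:
    """A target chromosome carrying a syntenic association."""

    target_chrom: str
    form: ChromosomeForm
    is_sex_composite: bool = False


@dataclass(frozen=True)
class AncestralMatch:
    """Presence of one catalogue form among detected associations."""

    catalogue_form: ChromosomeForm
    found: bool
    target_chrom: Optional[str] = None
    matched_form: Optional[ChromosomeForm] = None


def _is_sex_probe(probe_chrom: str) -> bool:
    return probe_chrom.rstrip("12") in ("X", "Y")


def count_signals(hmap: HomologyMap, include_sex: bool = False) -> SignalCount:
    """Count hybridisation signals per probe chromosome per haploid set.

    Every stored segment is one signal (compound positional qualifiers
    included).  ``total_autosomal`` sums over autosomal probes only,
    wherever their material lies — including the Y-autosome composite;
    ``total_with_sex`` adds the sex-chromosome probes' signals.
    """
    per: dict[str, int] = {p: 0 for p in hmap.probe_chroms}
    for _, seg in hmap.iter_segments():
        per[seg.probe_chrom] = per.get(seg.probe_chrom, 0) + 1
    total_auto = sum(n for p, n in per.items() if not _is_sex_probe(p))
    total_all = sum(per.values())
    if not include_sex:
        per = {p: n for p, n in per.items() if not _is_sex_probe(p)}
    return SignalCount(
        per_probe_chrom=per,
        total_autosomal=total_auto,
        total_with_sex=total_all,
    )


def classify_synteny(hmap: HomologyMap) -> list[SyntenyClass]:
    """Assign each autosomal probe chromosome its conserved-synteny class.

    SPLIT iff the probe shows >= 2 signals.  With a single signal, the
    probe is WHOLE when its signal is the only segment on its target
    chromosome, ASSOCIATED otherwise.  A probe whose single signal sits on
    the Y-autosome composite alone is WHOLE: the composite's sex portion
    is not probe material.
    """
    locations: dict[str, list[TargetChromosome]] = {}
    for chrom, seg in hmap.iter_segments():
        locations.setdefault(seg.probe_chrom, []).append(chrom)
    out: list[SyntenyClass] = []
    for probe in hmap.autosomal_probe_chroms():
        chroms = locations.get(probe, [])
        n = len(chroms)
        if n >= 2:
            cls = "SPLIT"
        elif n == 1:
            only = chroms[0]
            cls = "WHOLE" if len(only.segments) == 1 else "ASSOCIATED"
        else:
            continue  # probe absent from this map
        out.append(SyntenyClass(probe, cls, n))
    return out


def detect_associations(hmap: HomologyMap) -> list[Association]:
    """Find every target chromosome carrying a syntenic association.

    A chromosome qualifies when its form has two or more tokens drawn
    from at least two signals — material of two different probe
    chromosomes, or the same probe twice non-contiguously (interleaved
    inversion products).  The Y-autosome composite is excluded from the
    autosomal list and returned flagged instead.
    """
    out: list[Association] = []
    for chrom in hmap.chromosomes:
        segs = [s for s in chrom.segments if not _is_sex_probe(s.probe_chrom)]
        if not segs:
            continue
        n_tokens = sum(len(s.position_blocks()) for s in segs)
        if chrom.is_y_composite:
            out.append(Association(chrom.chrom_id, chrom.form(), True))
        elif not chrom.is_sex and n_tokens >= 2:
            out.append(Association(chrom.chrom_id, chrom.form(), False))
    return out


def match_ancestral(
    associations: Sequence[Association],
    ancestral_catalogue: Sequence[ChromosomeForm],
) -> list[AncestralMatch]:
    """Report which catalogue forms are present among the associations.

    A catalogue form is *found* when its token multiset is contained in
    one association's token multiset; sub-segment letters are compared
    only when both sides carry them.
    """
    if not ancestral_catalogue:
        raise ValueError("ancestral catalogue must be non-empty")
    report: list[AncestralMatch] = []
    for form in ancestral_catalogue:
        hit = next(
            (
                a
                for a in associations
                if not a.is_sex_composite
                and a.form.token_multiset_contains(form)
            ),
            None,
        )
        if hit is None:
            report.append(AncestralMatch(form, False))
        else:
            report.append(AncestralMatch(form, True, hit.target_chrom, hit.form))
    return report


# ---------------------------------------------------------------------------
# tabular reports
# ---------------------------------------------------------------------------

def synteny_report(hmap: HomologyMap) -> pd.DataFrame:
    """Per-probe table: class and signal count (columns probe_chrom, class, n_signals)."""
    classes = classify_synteny(hmap)
    return pd.DataFrame(
        {
            "probe_chrom": [c.probe_chrom for c in classes],
            "class": [c.synteny_class for c in classes],
            "n_signals": [c.n_signals for c in classes],
        }
    )


def association_report(
    hmap: HomologyMap,
    catalogue: Optional[Sequence[ChromosomeForm]] = None,
) -> pd.DataFrame:
    """Per-association table with the matching catalogue entry, if any."""
    assocs = detect_associations(hmap)
    matched: dict[str, str] = {}
    if catalogue:
        for m in match_ancestral(assocs, catalogue):
            if m.found and m.target_chrom not in matched:
                matched[m.target_chrom] = m.catalogue_form.label
    return pd.DataFrame(
        {
            "target_chrom": [a.target_chrom for a in assocs],
            "form": [a.form.label for a in assocs],
            "sex_composite": [a.is_sex_composite for a in assocs],
            "matched_catalogue_entry": [
                matched.get(a.target_chrom, "") for a in assocs
            ],
        }
    )
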