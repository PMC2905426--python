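"""Bundled data: painting homology maps and the ancestral-association catalogue.

Three maps are verbatim transcriptions of published painting results
(human probes on *Pithecia irrorata*, human and *Saguinus oedipus* probes
on *Cacajao calvus rubicundus*); the *Chiropotes utahicki* map is an
explicitly synthetic reconstruction (see the file header) used only at
association granularity.  A SHA-256 manifest pins the transcriptions.
"""

from __future__ import annotations

import hashlib
from importlib import resources
from pathlib import Path

from .karyotype import ChromosomeForm, HomologyMap, read_homology_table

__all__ = [
    "fixture_path",
    "load_hsa_pir",
    "load_hsa_ccr",
    "load_soe_ccr",
    "load_hsa_cut",
    "ancestral_catalogue",
    "verify_manifest",
]

_DATA = resources.files(__package__) / "data"


def fixture_path(name: str) -> Path:
    """Filesystem path of a bundled data file."""
    return Path(str(_DATA / name))


def load_hsa_pir() -> HomologyMap:
    """Human probes on *Pithecia irrorata* (2n = 48)."""
    return read_homology_table(fixture_path("hsa_pir.tsv"))


def load_hsa_ccr() -> HomologyMap:
    """Human probes on *Cacajao calvus rubicundus* (2n = 46F/45M, X1X2Y)."""
    return read_homology_table(fixture_path("hsa_ccr.tsv"))


def load_soe_ccr() -> HomologyMap:
    """*Saguinus oedipus* probes on *C. c. rubicundus*."""
    return read_homology_table(fixture_path("soe_ccr.tsv"))


def load_hsa_cut() -> HomologyMap:
    """Synthetic reconstruction of human probes on *Chiropotes utahicki*.

    Association-level content (which CUT chromosome carries which human
    homologous form) follows the published cross-taxon correspondences;
    arm positions of minor segments are conventional.
    """
    return read_homology_table(fixture_path("hsa_cut_synthetic.tsv"))


def ancestral_catalogue(path: str | Path | None = None) -> list[ChromosomeForm]:
    """The six human homologous associations of the inferred ancestral
    Platyrrhini karyotype: 3a/21, 5/7a, 2b/16b, 8a/18, 14/15a, 10a/16a.

    A custom one-form-per-line file may be supplied instead.
    """
    p = Path(path) if path is not None else fixture_path("ancestral_platyrrhini.txt")
    forms = []
    for line in p.read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            forms.append(ChromosomeForm(line))
    return forms


def verify_manifest() -> dict[str, bool]:
    """Check every bundled data file against the SHA-256 manifest."""
    manifest = fixture_path("MANIFEST.sha256").read_text(encoding="utf-8")
    results: dict[str, bool] = {}
    for line in manifest.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        digest, name = line.split()
        actual = hashlib.sha256(fixture_path(name).read_bytes()).hexdigest()
        results[name] = actual == digest
    return results
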