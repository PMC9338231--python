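"""Sequence records, IUPAC alphabet handling, FASTA I/O and the assay's fixed configuration.

The five-species tephritid multiplex assay is defined by a *panel*: one
species-specific primer pair per species, each producing an amplicon of a
distinct declared size so that a single gel lane identifies the species.
This module holds the value types for that definition (:class:`Primer`,
:class:`PanelEntry`, :class:`Panel`, :class:`AssayProtocol`) plus the small
amount of sequence plumbing the rest of the stack needs.

Coordinates everywhere in the package are 0-based, half-open, reported on
the plus strand of the template; strand is recorded separately.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

__all__ = [
    "IUPAC_SETS",
    "SPECIES",
    "SeqRecord",
    "Primer",
    "PanelEntry",
    "Panel",
    "AssayProtocol",
    "PanelValidationError",
    "FastaParseError",
    "read_fasta",
    "write_fasta",
    "reverse_complement",
    "iupac_match",
    "load_panel",
    "save_panel",
]

#: Base sets of the 15 IUPAC nucleotide codes (gap excluded).
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

#: Target species of the published assay, in panel (Table) order.
SPECIES = ("capitata", "cosyra", "quilicii", "rosa", "dorsalis")

_SPECIES_TAGS = set(SPECIES) | {"custom"}


class FastaParseError(ValueError):
    """Raised when a FASTA file is malformed."""


class PanelValidationError(ValueError):
    """Raised when a panel definition violates an invariant."""


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


def _check_alphabet(seq: str, *, what: str = "sequence") -> None:
    bad = set(seq) - IUPAC_SETS.keys()
    if bad:
        raise ValueError(
            f"illegal character(s) {sorted(bad)} in {what}; "
            "expected IUPAC nucleotide codes"
        )


@dataclass(frozen=True)
class SeqRecord:
    """An ungapped DNA sequence with an identifier.

    Sequences are stored uppercase over the 15 IUPAC codes; gaps are
    rejected because templates represent physical DNA.
    """

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SeqRecord id must be non-empty")
        object.__setattr__(self, "sequence", _normalize(self.sequence))
        if len(self.sequence) < 1:
            raise ValueError(f"SeqRecord {self.id!r}: empty sequence")
        _check_alphabet(self.sequence, what=f"record {self.id!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Primer:
    """A named oligonucleotide, written 5'->3', tagged with its target species."""

    name: str
    sequence: str
    species_tag: str = "custom"
    role: str = "forward"

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("Primer name must be non-empty")
        object.__setattr__(self, "sequence", _normalize(self.sequence))
        if not 15 <= len(self.sequence) <= 35:
            raise ValueError(
                f"primer {self.name!r}: length {len(self.sequence)} outside 15..35"
            )
        _check_alphabet(self.sequence, what=f"primer {self.name!r}")
        if self.species_tag not in _SPECIES_TAGS:
            raise ValueError(
                f"primer {self.name!r}: unknown species tag {self.species_tag!r}"
            )
        if self.role not in ("forward", "reverse"):
            raise ValueError(f"primer {self.name!r}: role must be forward or reverse")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PanelEntry:
    """One species' primer pair and its declared amplicon size.

    ``cross_amplification_risk`` marks an entry whose primers sit in a
    region (e.g. intergenic) known to cross-amplify in related species;
    the species caller uses it for the duplex tie-break rule.
    ``primer_conc`` (µM per primer) is carried as assay metadata only and
    plays no role in site finding.
    """

    species: str
    forward: Primer
    reverse: Primer
    expected_size: int
    primer_conc: float = 0.4
    cross_amplification_risk: bool = False

    def __post_init__(self) -> None:
        if self.expected_size < len(self.forward) + len(self.reverse):
            raise PanelValidationError(
                f"{self.species}: expected_size {self.expected_size} smaller than "
                f"combined primer length {len(self.forward) + len(self.reverse)}"
            )
        if self.primer_conc <= 0:
            raise PanelValidationError(f"{self.species}: primer_conc must be > 0")


@dataclass(frozen=True)
class Panel:
    """An ordered multiplex of species-specific primer pairs."""

    entries: tuple[PanelEntry, ...]
    name: str = "panel"

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", tuple(self.entries))
        species = [e.species for e in self.entries]
        if len(set(species)) != len(species):
            raise PanelValidationError("duplicate species in panel")
        sizes = [e.expected_size for e in self.entries]
        if len(set(sizes)) != len(sizes):
            raise PanelValidationError("expected amplicon sizes must be unique")
        names = [p.name for e in self.entries for p in (e.forward, e.reverse)]
        if len(set(names)) != len(names):
            raise PanelValidationError("primer names must be unique within a panel")

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def primers(self) -> tuple[Primer, ...]:
        return tuple(p for e in self.entries for p in (e.forward, e.reverse))

    def entry(self, species: str) -> PanelEntry:
        for e in self.entries:
            if e.species == species:
                return e
        raise KeyError(f"species {species!r} not in panel {self.name!r}")

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(e.species for e in self.entries)


@dataclass(frozen=True)
class AssayProtocol:
    """Thermocycling and gel parameters of the wet-lab assay (metadata).

    Defaults reproduce the published protocol: 94 °C/5 min initial
    denaturation; 35 cycles of 94 °C/30 s, 55 °C/30 s annealing,
    72 °C/35 s extension; 72 °C/7 min final extension; 2 % agarose-TAE gel.
    """

    initial_denat_c: float = 94.0
    initial_denat_min: float = 5.0
    cycles: int = 35
    denat_c: float = 94.0
    denat_s: float = 30.0
    anneal_c: float = 55.0
    anneal_s: float = 30.0
    extend_c: float = 72.0
    extend_s: float = 35.0
    final_extend_c: float = 72.0
    final_extend_min: float = 7.0
    gel_percent: float = 2.0

    def __post_init__(self) -> None:
        if self.cycles < 1:
            raise ValueError("cycles must be >= 1")
        for attr in ("initial_denat_c", "denat_c", "anneal_c", "extend_c",
                     "final_extend_c"):
            t = getattr(self, attr)
            if not 0.0 <= t <= 100.0:
                raise ValueError(f"{attr}={t} outside 0..100 °C")


def reverse_complement(seq: str) -> str:
    """Reverse complement over the full IUPAC alphabet (R<->Y, B<->V, ...)."""
    seq = _normalize(seq)
    try:
        return "".join(_COMPLEMENT[b] for b in reversed(seq))
    except KeyError as exc:
        raise ValueError(f"non-IUPAC character {exc.args[0]!r}") from None


def iupac_match(template_base: str, primer_base: str) -> bool:
    """True iff the two codes' base sets intersect (an ambiguity-aware match)."""
    try:
        return not IUPAC_SETS[template_base].isdisjoint(IUPAC_SETS[primer_base])
    except KeyError as exc:
        raise ValueError(f"non-IUPAC character {exc.args[0]!r}") from None


def _find_bad_line(path: Path) -> int | None:
    """Locate the first line with an illegal sequence character, for error messages."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(">"):
                continue
            if set(_normalize(line)) - IUPAC_SETS.keys():
                return lineno
    return None


def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read a FASTA file into :class:`SeqRecord` objects, order preserved.

    Sequences are uppercased and U is normalized to T. Duplicate ids,
    illegal characters (with line number) and empty files are errors.
    """
    path = Path(path)
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FastaParseError(f"{path}: record with empty id")
        if rec.id in seen:
            raise FastaParseError(f"{path}: duplicate id {rec.id!r}")
        seen.add(rec.id)
        seq = _normalize(str(rec.seq))
        if set(seq) - IUPAC_SETS.keys():
            lineno = _find_bad_line(path)
            raise FastaParseError(
                f"{path}: illegal character in record {rec.id!r}"
                + (f" (line {lineno})" if lineno is not None else "")
            )
        if not seq:
            raise FastaParseError(f"{path}: record {rec.id!r} has empty sequence")
        records.append(SeqRecord(id=rec.id, sequence=seq, description=rec.description))
    if not records:
        raise FastaParseError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 70) -> None:
    """Write records as FASTA (fixed line width)."""
    bio = [
        _BioSeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# Panel serialization

def _entry_from_mapping(d: dict) -> PanelEntry:
    species = d["species"]
    fwd = Primer(
        name=d["forward"]["name"], sequence=d["forward"]["seq"],
        species_tag=species if species in SPECIES else "custom", role="forward",
    )
    rev = Primer(
        name=d["reverse"]["name"], sequence=d["reverse"]["seq"],
        species_tag=species if species in SPECIES else "custom", role="reverse",
    )
    return PanelEntry(
        species=species,
        forward=fwd,
        reverse=rev,
        expected_size=int(d["expected_size"]),
        primer_conc=float(d.get("conc_uM", 0.4)),
        cross_amplification_risk=bool(d.get("cross_amplification_risk", False)),
    )


def panel_from_mapping(doc: dict) -> Panel:
    """Build a :class:`Panel` from a parsed YAML/JSON panel document."""
    if "entries" not in doc or not doc["entries"]:
        raise PanelValidationError("panel document has no entries")
    entries = tuple(_entry_from_mapping(e) for e in doc["entries"])
    return Panel(entries=entries, name=doc.get("name", "panel"))


def panel_to_mapping(panel: Panel) -> dict:
    return {
        "name": panel.name,
        "entries": [
            {
                "species": e.species,
                "forward": {"name": e.forward.name, "seq": e.forward.sequence},
                "reverse": {"name": e.reverse.name, "seq": e.reverse.sequence},
                "expected_size": e.expected_size,
                "conc_uM": e.primer_conc,
                "cross_amplification_risk": e.cross_amplification_risk,
            }
            for e in panel.entries
        ],
    }


def load_panel(source: str | Path = "builtin:table1") -> Panel:
    """Load a panel from a YAML/JSON file, or the builtin published panel.

    ``"builtin:table1"`` returns the five-pair panel of the published assay
    (expected sizes 327/183/128/249/676 bp) exactly as printed.
    """
    if isinstance(source, str) and source.startswith("builtin:"):
        key = source.split(":", 1)[1]
        if key != "table1":
            raise KeyError(f"unknown builtin panel {key!r}")
        ref = importlib.resources.files("flymplex.data").joinpath("panel_table1.yaml")
        doc = yaml.safe_load(ref.read_text())
        return panel_from_mapping(doc)
    path = Path(source)
    text = path.read_text()
    doc = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return panel_from_mapping(doc)


def save_panel(panel: Panel, path: str | Path) -> None:
    """Write a panel as a YAML document loadable by :func:`load_panel`."""
    with open(path, "w") as fh:
        yaml.safe_dump(panel_to_mapping(panel), fh, sort_keys=False)
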