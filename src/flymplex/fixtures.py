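"""Deterministic synthetic templates and alignments for exercising the assay.

Real inputs to the assay are genomic DNA extracts (in software terms: the
deposited opsin-region contigs, or any FASTA a user supplies). This module
generates stand-ins with the properties the assay depends on:

* per-species templates that embed one panel entry's primer pair verbatim at
  a spacing producing exactly the declared amplicon size, surrounded by
  random filler rejection-sampled to contain *no* unintended binding site
  for any panel primer;
* a duplex variant carrying a second, cross-amplifying pair far enough away
  that only the two intended products fall under the amplicon-length cap —
  emulating the intergenic cross-amplification seen on real specimens;
* mutation injection into a primer footprint, to demonstrate the
  false-negative mode of 3'-terminal intraspecific variation;
* species-labelled alignments with implanted species-private SNP clusters,
  the input the panel-design pipeline is meant to recover from.

Everything is seeded; identical (entry, spec) inputs give identical bytes.
What these fixtures do NOT emulate: real intergenic sequence composition,
indel variation, heterozygosity, or sequencing error.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .insilico_pcr import DEFAULT_POLICY, MismatchPolicy, find_binding_sites
from .panel_design import Alignment
from .seq_core import (
    IUPAC_SETS,
    SPECIES,
    Panel,
    PanelEntry,
    SeqRecord,
    load_panel,
    reverse_complement,
)

__all__ = [
    "FixtureSpec",
    "synth_template",
    "synth_duplex_template",
    "inject_mutations",
    "synth_alignment",
    "fixture_manifest",
]

#: Spacer between the base and cross cassettes of a duplex template. Set to
#: the amplicon-length cap so the outer fwd x rev cross-pairing of the two
#: cassettes is always longer than any reportable product.
DUPLEX_SPACER = 3000

_BASES = np.array(list("ACGT"))
_MUT = {"A": "C", "C": "A", "G": "T", "T": "G"}  # deterministic transversion


@dataclass(frozen=True)
class FixtureSpec:
    """Knobs for template generation (all deterministic given ``seed``)."""

    seed: int = 0
    flank_len: int = 150
    gc: float = 0.5
    duplex: bool = False
    mutations: tuple[tuple[str, int, str | None], ...] = ()

    def __post_init__(self) -> None:
        if self.flank_len < 0:
            raise ValueError("flank_len must be >= 0")
        if not 0.0 < self.gc < 1.0:
            raise ValueError("gc must be in (0, 1)")


def _random_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    if n == 0:
        return ""
    at = (1.0 - gc) / 2.0
    p = [at, gc / 2.0, gc / 2.0, at]
    return "".join(rng.choice(_BASES, size=n, p=p))


def _random_dna_bounded(
    rng: np.random.Generator, n: int, gc: float, max_run: int = 4
) -> str:
    """Random DNA with homopolymer runs capped at ``max_run``.

    Used for the synthetic design locus: a region chosen for primer design
    is, by selection, primer-placeable, so the generator bounds the runs
    that would otherwise randomly forbid whole candidate windows.
    """
    at = (1.0 - gc) / 2.0
    p = [at, gc / 2.0, gc / 2.0, at]
    out: list[str] = []
    run = 0
    for _ in range(n):
        b = str(rng.choice(_BASES, p=p))
        while out and b == out[-1] and run >= max_run:
            b = str(rng.choice(_BASES, p=p))
        run = run + 1 if out and b == out[-1] else 1
        out.append(b)
    return "".join(out)


def _unwanted_sites(
    seq: str,
    panel: Panel,
    intended: Mapping[str, list[tuple[str, int]]],
    policy: MismatchPolicy,
) -> bool:
    """True if any panel primer binds anywhere other than its intended sites."""
    rec = SeqRecord(id="probe", sequence=seq)
    for primer in panel.primers:
        want = intended.get(primer.name, [])
        got = [(s.strand, s.start) for s in find_binding_sites(primer, rec, policy)]
        if got != sorted(want, key=lambda x: (x[1], x[0] != "plus")):
            return True
    return False


def _cassette(entry: PanelEntry, rng: np.random.Generator, gc: float) -> str:
    spacer = entry.expected_size - len(entry.forward) - len(entry.reverse)
    return (
        entry.forward.sequence
        + _random_dna(rng, spacer, gc)
        + reverse_complement(entry.reverse.sequence)
    )


def synth_template(
    entry: PanelEntry,
    spec: FixtureSpec,
    panel: Panel | None = None,
    max_attempts: int = 1000,
) -> SeqRecord:
    """A template whose only multiplex product is ``entry``'s declared amplicon.

    Layout: flank + forward primer + spacer + revcomp(reverse primer) + flank,
    with the primer-to-primer span exactly ``entry.expected_size``. Filler is
    rejection-resampled until no panel primer has an unintended binding site
    under the default mismatch policy.
    """
    panel = panel if panel is not None else load_panel("builtin:table1")
    if entry.expected_size < len(entry.forward) + len(entry.reverse):
        raise ValueError("expected_size smaller than combined primer length")
    rng = np.random.default_rng(spec.seed)
    f_start = spec.flank_len
    intended = {
        entry.forward.name: [("plus", f_start)],
        entry.reverse.name: [
            ("minus", f_start + entry.expected_size - len(entry.reverse))
        ],
    }
    for _ in range(max_attempts):
        seq = (
            _random_dna(rng, spec.flank_len, spec.gc)
            + _cassette(entry, rng, spec.gc)
            + _random_dna(rng, spec.flank_len, spec.gc)
        )
        if not _unwanted_sites(seq, panel, intended, DEFAULT_POLICY):
            return SeqRecord(
                id=f"{entry.species}_fixture_seed{spec.seed}",
                sequence=seq,
                description=f"synthetic template, {entry.species} "
                f"{entry.expected_size} bp cassette, seed {spec.seed}",
            )
    raise RuntimeError(
        f"could not place {entry.species} cassette without spurious primer "
        f"sites in {max_attempts} attempts; try a larger flank_len"
    )


def synth_duplex_template(
    base: PanelEntry,
    cross: PanelEntry,
    spec: FixtureSpec,
    panel: Panel | None = None,
    max_attempts: int = 1000,
) -> SeqRecord:
    """A template yielding both ``base``'s and ``cross``'s products.

    The cross cassette sits ``DUPLEX_SPACER`` bp downstream of the base
    cassette, so the outer pairing of base-forward with cross-reverse
    exceeds the default amplicon cap and exactly two products remain —
    the gel pattern of the observed duplex.
    """
    if base.species == cross.species:
        raise ValueError("base and cross must be different panel entries")
    panel = panel if panel is not None else load_panel("builtin:table1")
    rng = np.random.default_rng(spec.seed)
    b0 = spec.flank_len
    c0 = b0 + base.expected_size + DUPLEX_SPACER
    intended = {
        base.forward.name: [("plus", b0)],
        base.reverse.name: [("minus", b0 + base.expected_size - len(base.reverse))],
        cross.forward.name: [("plus", c0)],
        cross.reverse.name: [("minus", c0 + cross.expected_size - len(cross.reverse))],
    }
    for _ in range(max_attempts):
        seq = (
            _random_dna(rng, spec.flank_len, spec.gc)
            + _cassette(base, rng, spec.gc)
            + _random_dna(rng, DUPLEX_SPACER, spec.gc)
            + _cassette(cross, rng, spec.gc)
            + _random_dna(rng, spec.flank_len, spec.gc)
        )
        if not _unwanted_sites(seq, panel, intended, DEFAULT_POLICY):
            return SeqRecord(
                id=f"{base.species}_x_{cross.species}_duplex_seed{spec.seed}",
                sequence=seq,
                description=f"synthetic duplex template, {base.species} "
                f"{base.expected_size} bp + cross-amplifying {cross.species} "
                f"{cross.expected_size} bp cassette, seed {spec.seed}",
            )
    raise RuntimeError(
        "could not place duplex cassettes without spurious primer sites; "
        "try a larger flank_len"
    )


# permissive enough to re-find a footprint carrying prior injected mutations,
# tight enough that spurious matches in random filler stay vanishingly rare
_LOCATE_POLICY = MismatchPolicy(max_total=3, three_prime_window=1, max_3prime=3)


def inject_mutations(
    template: SeqRecord,
    panel: Panel,
    mutations: Sequence[tuple[str, int, str | None]],
) -> SeqRecord:
    """Substitute template bases inside a primer's binding footprint.

    Each mutation is (primer name, offset from the primer's 3' end as
    annealed, new plus-strand base or None). None picks, deterministically,
    a base that mismatches the primer at that position. The primer must
    have exactly one binding site on the template (located under a
    permissive policy so already-mutated sites are still found).
    """
    seq = list(template.sequence)
    primers = {p.name: p for p in panel.primers}
    for name, offset, new_base in mutations:
        if name not in primers:
            raise KeyError(f"primer {name!r} not in panel")
        primer = primers[name]
        if not 0 <= offset < len(primer):
            raise ValueError(f"offset {offset} outside primer {name!r}")
        sites = find_binding_sites(
            primer, SeqRecord(id="cur", sequence="".join(seq)), _LOCATE_POLICY
        )
        if len(sites) != 1:
            raise ValueError(
                f"primer {name!r} has {len(sites)} sites on {template.id!r}; "
                "need exactly one"
            )
        site = sites[0]
        # plus-strand position of the primer base `offset` in from its 3' end
        pos = site.end - 1 - offset if site.strand == "plus" else site.start + offset
        if new_base is None:
            # template base set the primer matches at this position
            if site.strand == "plus":
                pbase = primer.sequence[len(primer) - 1 - offset]
                allowed = IUPAC_SETS[pbase]
            else:
                pbase = primer.sequence[len(primer) - 1 - offset]
                allowed = {reverse_complement(b) for b in IUPAC_SETS[pbase]}
            new_base = next(
                b for b in "ACGT" if b not in allowed and b != seq[pos]
            )
        seq[pos] = new_base
    return SeqRecord(
        id=template.id,
        sequence="".join(seq),
        description=(template.description + "; " if template.description else "")
        + f"{len(mutations)} injected mutation(s)",
    )


# ---------------------------------------------------------------------------
# Synthetic species-labelled alignments for the design pipeline

#: Target amplicon size per species in the synthetic locus. All pairwise
#: log10 gaps exceed the default gel resolvability delta.
_SYNTH_SIZES = {"capitata": 380, "cosyra": 200, "quilicii": 140,
                "rosa": 280, "dorsalis": 560}
#: Forward-window anchor column per species (staggered; spans fit 800 cols).
_SYNTH_ANCHORS = {"capitata": 40, "cosyra": 80, "quilicii": 120,
                  "rosa": 160, "dorsalis": 200}
_WINDOW_W = 21  # primer-scale window the SNP clusters are placed against


def synth_alignment(
    n_per_species: int = 2,
    diag_per_species: int = 3,
    seed: int = 42,
    n_cols: int = 800,
    noise_rate: float = 0.002,
) -> tuple[Alignment, dict]:
    """A five-species alignment with implanted species-private SNP clusters.

    All rows derive from one random ancestral sequence. Each species gets
    ``diag_per_species`` private SNPs clustered in the 3'-proximal five
    columns of a forward primer window, and the same again at the 5' edge
    of a reverse window placed so the windows span that species' target
    amplicon size. Per-row noise at ``noise_rate`` emulates within-species
    polymorphism. Returns the alignment and a manifest recording every
    implanted coordinate (the ground truth design recovery is tested
    against).
    """
    if n_per_species < 1:
        raise ValueError("n_per_species must be >= 1")
    if diag_per_species < 0:
        raise ValueError("diag_per_species must be >= 0")
    rng = np.random.default_rng(seed)
    ancestral = list(_random_dna_bounded(rng, n_cols, 0.5))

    manifest: dict = {"seed": seed, "n_cols": n_cols, "species": {}}
    consensus: dict[str, list[str]] = {}
    for sp in SPECIES:
        a = _SYNTH_ANCHORS[sp]
        size = _SYNTH_SIZES[sp]
        fwd_window = (a, a + _WINDOW_W)
        rev_window = (a + size - _WINDOW_W, a + size)
        # 3'-proximal five columns of each window (forward 3' is the right
        # edge; the reverse primer's 3' end maps to the window's left edge)
        fwd_zone = list(range(fwd_window[1] - 5, fwd_window[1]))
        rev_zone = list(range(rev_window[0], rev_window[0] + 5))
        n_f = min(diag_per_species, 5)
        n_r = min(diag_per_species, 5)
        fwd_cols = sorted(rng.choice(fwd_zone, size=n_f, replace=False).tolist())
        rev_cols = sorted(rng.choice(rev_zone, size=n_r, replace=False).tolist())
        derived = list(ancestral)
        for col in fwd_cols + rev_cols:
            derived[col] = _MUT[ancestral[col]]
        consensus[sp] = derived
        manifest["species"][sp] = {
            "forward_diag_columns": fwd_cols,
            "reverse_diag_columns": rev_cols,
            "fwd_window": list(fwd_window),
            "rev_window": list(rev_window),
            "amplicon_span": [a, a + size],
            "target_size": size,
        }

    rows: list[tuple[str, str]] = []
    protected = {
        c
        for sp in SPECIES
        for c in manifest["species"][sp]["forward_diag_columns"]
        + manifest["species"][sp]["reverse_diag_columns"]
    }
    for sp in SPECIES:
        for i in range(n_per_species):
            row = list(consensus[sp])
            n_noise = rng.binomial(n_cols, noise_rate)
            for col in rng.integers(0, n_cols, size=n_noise):
                if int(col) in protected:
                    continue  # keep the diagnostic signal clean
                row[int(col)] = _MUT[row[int(col)]]
            rows.append((sp, "".join(row)))
    return Alignment(rows=tuple(rows)), manifest


def fixture_manifest(
    species: Sequence[str],
    spec: FixtureSpec,
    panel: Panel,
) -> dict:
    """JSON-serializable provenance record for a set of generated fixtures."""
    return {
        "panel": panel.name,
        "seed": spec.seed,
        "flank_len": spec.flank_len,
        "gc": spec.gc,
        "species": list(species),
        "mutations": [list(m) for m in spec.mutations],
        "expected_sizes": {
            sp: panel.entry(sp).expected_size for sp in species
        },
    }
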