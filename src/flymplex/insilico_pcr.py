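"""Mismatch-tolerant primer-binding search and multiplex amplicon prediction.

A primer anneals wherever its bases match the template under a
:class:`MismatchPolicy`: at most ``max_total`` mismatches over the whole
primer and at most ``max_3prime`` within the ``three_prime_window`` bases at
the primer's 3' terminus (3'-terminal mismatches block polymerase
extension, which is what makes species-specific priming work). Matching is
IUPAC-aware per base.

Amplicon prediction pairs *every* plus-strand site with *every*
downstream minus-strand site of any primer in the panel, capped at
``max_len``; cross-pairings between different species' primers are
deliberately included — that is exactly what produces the observed
cosyra/quilicii duplex band pattern on real specimens.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .seq_core import IUPAC_SETS, Panel, Primer, SeqRecord, iupac_match, reverse_complement

_CODES = sorted(IUPAC_SETS)
_CODE_IDX = {c: i for i, c in enumerate(_CODES)}
# pairwise set-intersection match matrix over the 15 IUPAC codes
_MATCH = np.array(
    [[not IUPAC_SETS[a].isdisjoint(IUPAC_SETS[b]) for b in _CODES] for a in _CODES],
    dtype=bool,
)
_CHAR_LUT = np.full(256, 255, dtype=np.uint8)
for _c, _i in _CODE_IDX.items():
    _CHAR_LUT[ord(_c)] = _i


def _encode(seq: str) -> np.ndarray:
    arr = _CHAR_LUT[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if (arr == 255).any():
        raise ValueError("non-IUPAC character in sequence")
    return arr

__all__ = [
    "MismatchPolicy",
    "BindingSite",
    "Amplicon",
    "find_binding_sites",
    "simulate_pcr",
    "simulate_multiplex",
    "amplicons_to_tsv",
    "amplicons_to_bed",
]


@dataclass(frozen=True)
class MismatchPolicy:
    """Annealing tolerance: total mismatches and a stricter 3'-window budget."""

    max_total: int = 2
    three_prime_window: int = 5
    max_3prime: int = 0

    def __post_init__(self) -> None:
        if self.three_prime_window < 1:
            raise ValueError("three_prime_window must be >= 1")
        if self.max_3prime > self.max_total:
            raise ValueError("max_3prime cannot exceed max_total")


DEFAULT_POLICY = MismatchPolicy()

#: Policy used when declaring a non-target "at risk" of cross-amplification.
SPECIFICITY_POLICY = MismatchPolicy(max_total=3, three_prime_window=5, max_3prime=1)


@dataclass(frozen=True)
class BindingSite:
    """A primer annealing position, in plus-strand half-open coordinates.

    ``strand`` is the strand the *primer's extension product* copies:
    a plus-strand site primes rightward synthesis, a minus-strand site
    leftward. The primer's 3' end sits at ``end - 1`` (plus) or ``start``
    (minus).
    """

    primer_name: str
    template_id: str
    strand: str  # "plus" | "minus"
    start: int
    end: int
    mismatches: int
    mismatches_3p: int


@dataclass(frozen=True)
class Amplicon:
    """A predicted PCR product, inclusive of both primer footprints."""

    template_id: str
    fwd_site: BindingSite
    rev_site: BindingSite
    length: int
    sequence: str
    fwd_primer: str
    rev_primer: str

    def __post_init__(self) -> None:
        assert self.length == len(self.sequence)
        assert self.length == self.rev_site.end - self.fwd_site.start


def _scan(
    primer_seq: str,
    template: str,
    policy: MismatchPolicy,
    three_prime_left: bool,
) -> list[tuple[int, int, int]]:
    """All (offset, mismatches, mismatches_3p) where primer_seq matches under policy.

    ``three_prime_left`` selects which footprint end counts as the primer's
    3' terminus (left for minus-strand sites, where the scanned sequence is
    the primer's reverse complement).
    """
    lp = len(primer_seq)
    w = min(policy.three_prime_window, lp)
    npos = len(template) - lp + 1
    if npos <= 0:
        return []
    t = _encode(template)
    p = _encode(primer_seq)
    window = range(0, w) if three_prime_left else range(lp - w, lp)
    window_set = set(window)
    mm = np.zeros(npos, dtype=np.int32)
    mm3 = np.zeros(npos, dtype=np.int32)
    for i in range(lp):
        miss = ~_MATCH[t[i : i + npos], p[i]]
        mm += miss
        if i in window_set:
            mm3 += miss
    ok = (mm <= policy.max_total) & (mm3 <= policy.max_3prime)
    return [(int(off), int(mm[off]), int(mm3[off])) for off in np.nonzero(ok)[0]]


def find_binding_sites(
    primer: Primer,
    template: SeqRecord,
    policy: MismatchPolicy = DEFAULT_POLICY,
) -> list[BindingSite]:
    """All annealing sites of ``primer`` on both strands of ``template``.

    A primer longer than the template yields an empty list. Sites are
    sorted by start coordinate, plus strand before minus at equal start.
    """
    seq = template.sequence
    if len(primer) > len(seq):
        return []
    sites = [
        BindingSite(primer.name, template.id, "plus", off, off + len(primer), mm, mm3)
        for off, mm, mm3 in _scan(primer.sequence, seq, policy, three_prime_left=False)
    ]
    rc = reverse_complement(primer.sequence)
    sites += [
        BindingSite(primer.name, template.id, "minus", off, off + len(primer), mm, mm3)
        for off, mm, mm3 in _scan(rc, seq, policy, three_prime_left=True)
    ]
    return sorted(sites, key=lambda s: (s.start, s.strand != "plus", s.primer_name))


def simulate_pcr(
    panel: Panel,
    template: SeqRecord,
    policy: MismatchPolicy = DEFAULT_POLICY,
    max_len: int = 3000,
) -> list[Amplicon]:
    """Predict all multiplex products of ``panel`` on one template.

    Every (plus site, downstream minus site) pair over *all* panel primers
    with product length in (0, max_len] yields an amplicon; overlapping
    primer footprints (rev.start < fwd.end) are physically impossible and
    excluded. Output is sorted by length descending.
    """
    if max_len <= 0:
        raise ValueError("max_len must be > 0")
    plus: list[BindingSite] = []
    minus: list[BindingSite] = []
    for primer in panel.primers:
        for site in find_binding_sites(primer, template, policy):
            (plus if site.strand == "plus" else minus).append(site)
    out: list[Amplicon] = []
    for f in plus:
        for r in minus:
            if r.start < f.end:
                continue
            length = r.end - f.start
            if length > max_len:
                continue
            out.append(
                Amplicon(
                    template_id=template.id,
                    fwd_site=f,
                    rev_site=r,
                    length=length,
                    sequence=template.sequence[f.start : r.end],
                    fwd_primer=f.primer_name,
                    rev_primer=r.primer_name,
                )
            )
    out.sort(key=lambda a: (-a.length, a.fwd_site.start, a.fwd_primer, a.rev_primer))
    return out


def simulate_multiplex(
    panel: Panel,
    templates: Sequence[SeqRecord],
    policy: MismatchPolicy = DEFAULT_POLICY,
    max_len: int = 3000,
) -> dict[str, list[Amplicon]]:
    """Run :func:`simulate_pcr` per template; templates never interact."""
    ids = [t.id for t in templates]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate template ids")
    return {t.id: simulate_pcr(panel, t, policy, max_len) for t in templates}


_TSV_HEADER = (
    "template_id\tfwd_primer\trev_primer\tstart\tend\tstrands\tlength\tmismatches"
)


def amplicons_to_tsv(results: Mapping[str, Iterable[Amplicon]]) -> str:
    lines = [_TSV_HEADER]
    for tid, amps in results.items():
        for a in amps:
            lines.append(
                f"{tid}\t{a.fwd_primer}\t{a.rev_primer}\t{a.fwd_site.start}\t"
                f"{a.rev_site.end}\t+/-\t{a.length}\t"
                f"{a.fwd_site.mismatches + a.rev_site.mismatches}"
            )
    return "\n".join(lines) + "\n"


def amplicons_to_bed(results: Mapping[str, Iterable[Amplicon]]) -> str:
    lines = []
    for tid, amps in results.items():
        for a in amps:
            lines.append(
                f"{tid}\t{a.fwd_site.start}\t{a.rev_site.end}\t"
                f"{a.fwd_primer}|{a.rev_primer}\t"
                f"{a.fwd_site.mismatches + a.rev_site.mismatches}\t+"
            )
    return "\n".join(lines) + ("\n" if lines else "")
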