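"""Primer quality metrics: nearest-neighbor melting temperature, GC content,
and 3'-anchored dimer/hairpin screening.

The Tm model is the unified DNA/DNA nearest-neighbor parameter set
(SantaLucia 1998) with the entropic monovalent-salt correction
dS' = dS + 0.368 (N-1) ln[Na+] and the two-state duplex formula

    Tm = 1000 dH / (dS' + R ln(C_T / x)) - 273.15

with x = 4 for non-self-complementary oligos (equimolar strands) and x = 1
plus the symmetry entropy term for self-complementary ones. Defaults
(50 mM monovalent, 250 nM total oligo) are pinned so that results are
reproducible; the parameter table ships as a plain-text file so an
alternate set can be swapped in by configuration.

Dimer and hairpin screening are alignment-run based: the score is the
longest contiguous Watson-Crick complementary run, with the dimer score
additionally required to touch a primer's 3'-terminal window (3' ends are
what the polymerase extends). No duplex free-energy model is attempted.
"""

from __future__ import annotations

import importlib.resources
import itertools
import math
from dataclasses import dataclass
from functools import lru_cache

from .seq_core import IUPAC_SETS, Primer, reverse_complement

__all__ = [
    "ThermoContext",
    "DimerReport",
    "load_nn_table",
    "melting_temperature",
    "gc_content",
    "dimer_score",
    "hairpin_score",
    "max_homopolymer_run",
]

R_GAS = 1.987  # cal / (mol K)

_WC = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class ThermoContext:
    """Solution conditions and parameter-set identity for Tm calculations."""

    monovalent_mM: float = 50.0
    primer_nM: float = 250.0
    parameter_set: str = "santalucia1998"

    def __post_init__(self) -> None:
        if self.monovalent_mM <= 0 or self.primer_nM <= 0:
            raise ValueError("concentrations must be > 0")


DEFAULT_CONTEXT = ThermoContext()


@dataclass(frozen=True)
class DimerReport:
    """Longest 3'-anchored complementary run between two primers."""

    score: int
    window: int
    pair: tuple[str, str]


@lru_cache(maxsize=4)
def load_nn_table(parameter_set: str = "santalucia1998") -> dict[str, tuple[float, float]]:
    """Load a nearest-neighbor parameter table {stack: (dH kcal/mol, dS cal/mol/K)}."""
    ref = importlib.resources.files("flymplex.data").joinpath(
        f"nn_{parameter_set}.tsv"
    )
    table: dict[str, tuple[float, float]] = {}
    for line in ref.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, dh, ds = line.split("\t")
        table[key] = (float(dh), float(ds))
    return table


def _expansions(seq: str, cap: int) -> list[str]:
    sets = [sorted(IUPAC_SETS[b]) for b in seq]
    total = math.prod(len(s) for s in sets)
    if total > cap:
        raise ValueError(
            f"degenerate primer expands to {total} sequences (> cap {cap})"
        )
    return ["".join(p) for p in itertools.product(*sets)]


def melting_temperature(
    seq: str,
    ctx: ThermoContext = DEFAULT_CONTEXT,
    *,
    ambiguity: str = "reject",
    expansion_cap: int = 64,
) -> float:
    """Nearest-neighbor melting temperature in °C.

    ``ambiguity="reject"`` (default) raises on degenerate bases;
    ``"expand"`` averages the Tm over all explicit expansions (capped).
    """
    seq = seq.upper().replace("U", "T")
    if len(seq) < 8:
        raise ValueError("sequence too short for a meaningful duplex Tm (< 8 nt)")
    if any(b not in IUPAC_SETS for b in seq):
        raise ValueError(f"non-IUPAC character in {seq!r}")
    if any(b not in "ACGT" for b in seq):
        if ambiguity == "reject":
            raise ValueError(
                "ambiguity codes present; pass ambiguity='expand' to average "
                "over explicit expansions"
            )
        return float(
            sum(melting_temperature(s, ctx) for s in _expansions(seq, expansion_cap))
            / len(_expansions(seq, expansion_cap))
        )

    table = load_nn_table(ctx.parameter_set)
    dh = table[f"init_{seq[0]}"][0] + table[f"init_{seq[-1]}"][0]
    ds = table[f"init_{seq[0]}"][1] + table[f"init_{seq[-1]}"][1]
    for i in range(len(seq) - 1):
        h, s = table[seq[i : i + 2]]
        dh += h
        ds += s
    selfcomp = seq == reverse_complement(seq)
    if selfcomp:
        dh += table["sym"][0]
        ds += table["sym"][1]
    # entropic salt correction, one term per phosphate linkage
    ds += 0.368 * (len(seq) - 1) * math.log(ctx.monovalent_mM / 1000.0)
    ct = ctx.primer_nM * 1e-9
    x = 1.0 if selfcomp else 4.0
    return 1000.0 * dh / (ds + R_GAS * math.log(ct / x)) - 273.15


def gc_content(seq: str) -> float:
    """Fraction of G+C bases in [0, 1]."""
    seq = seq.upper()
    if any(b not in "ACGT" for b in seq):
        raise ValueError("gc_content requires unambiguous DNA")
    if not seq:
        raise ValueError("empty sequence")
    return (seq.count("G") + seq.count("C")) / len(seq)


def max_homopolymer_run(seq: str) -> int:
    """Length of the longest single-base run."""
    best = run = 0
    prev = ""
    for b in seq:
        run = run + 1 if b == prev else 1
        prev = b
        best = max(best, run)
    return best


def _seq_of(p: Primer | str) -> tuple[str, str]:
    if isinstance(p, Primer):
        return p.name, p.sequence
    return p, str(p).upper()


def dimer_score(a: Primer | str, b: Primer | str, window: int = 5) -> DimerReport:
    """Longest contiguous WC-complementary run between two primers annealed
    antiparallel, counted only if the run touches either primer's 3'-terminal
    ``window`` bases. Symmetric in (a, b); a primer against itself screens
    self-dimers.
    """
    name_a, sa = _seq_of(a)
    name_b, sb = _seq_of(b)
    if window > min(len(sa), len(sb)):
        raise ValueError("window exceeds shorter primer length")
    na, nb = len(sa), len(sb)
    best = 0
    # antiparallel pairing: position i of a against position k of b with i+k = c
    for c in range(na + nb - 1):
        run = 0
        for i in range(max(0, c - nb + 1), min(na, c + 1)):
            k = c - i
            if _WC.get(sa[i]) == sb[k]:
                run += 1
                # run occupies a[i-run+1..i] and b[k..k+run-1]
                if i >= na - window or (k + run - 1) >= nb - window:
                    best = max(best, run)
            else:
                run = 0
    return DimerReport(score=best, window=window, pair=(name_a, name_b))


def hairpin_score(a: Primer | str, min_loop: int = 3) -> int:
    """Longest self-complementary stem closable with a loop of >= ``min_loop`` nt."""
    if min_loop < 3:
        raise ValueError("min_loop must be >= 3")
    _, s = _seq_of(a)
    n = len(s)
    best = 0
    for stem in range(1, n // 2 + 1):
        found = False
        for i in range(0, n - 2 * stem - min_loop + 1):
            for j in range(i + stem + min_loop, n - stem + 1):
                if all(_WC.get(s[i + t]) == s[j + stem - 1 - t] for t in range(stem)):
                    found = True
                    break
            if found:
                break
        if found:
            best = stem
        else:
            break
    return best
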