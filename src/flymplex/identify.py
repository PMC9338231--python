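"""Species calling from gel band sizes.

The assay reads out as band sizes in a lane; each species has one
declared diagnostic size (327/183/128/249/676 bp in the published panel).
A band matches a species when it lies within a relative size tolerance of
that species' expected size (gel size estimates are only accurate to a
few percent). One wrinkle, observed on real specimens: the quilicii
primer pair sits in an intergenic region and cross-amplifies in related
species, producing a non-specific band at the quilicii size alongside the
true diagnostic band (a duplex). The tie-break rule is therefore: when a
band at the cross-amplification-risk size co-occurs with a *larger* band
matching a different species, the risk-size band is discounted and the
larger band identifies the specimen; the risk species itself always
presents as a single band at its own size.

The rule is panel-driven (``cross_amplification_risk`` flag on the
entry), not hard-coded to any species name.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .gel_sim import Lane
from .seq_core import Panel, PanelEntry

__all__ = [
    "CallPolicy",
    "SpeciesCall",
    "RunReport",
    "match_band",
    "call_species",
    "classify_run",
    "validate_tolerance",
    "calls_to_tsv",
]


@dataclass(frozen=True)
class CallPolicy:
    """Band-to-size matching tolerance and the duplex tie-break switch.

    The default 8 % tolerance is wide enough for gel-estimated sizes
    (±~10 bp near 150 bp) yet narrow enough that adjacent diagnostic
    sizes of the published panel can never co-match one band.
    """

    size_tolerance: float = 0.08
    duplex_rule: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.size_tolerance < 0.5:
            raise ValueError("size_tolerance must be in (0, 0.5)")


DEFAULT_CALL_POLICY = CallPolicy()


@dataclass(frozen=True)
class SpeciesCall:
    """An auditable identification decision for one lane."""

    status: str  # identified | no_amplification | ambiguous | unrecognized_bands
    species: str | None = None
    diagnostic_size: int | None = None
    discounted_bands: tuple[int, ...] = ()
    candidates: tuple[str, ...] = ()
    notes: str = ""


@dataclass(frozen=True)
class RunReport:
    calls: tuple[tuple[str, SpeciesCall], ...]  # (lane label, call)
    contamination_suspected: bool
    ntc_labels: tuple[str, ...]

    def summary(self) -> pd.DataFrame:
        rows = [
            {
                "lane": label,
                "status": c.status,
                "species": c.species or "-",
                "diagnostic_size": c.diagnostic_size or "-",
                "discounted_bands": ",".join(map(str, c.discounted_bands)) or "-",
                "notes": c.notes,
            }
            for label, c in self.calls
        ]
        return pd.DataFrame(rows)


def validate_tolerance(panel: Panel, policy: CallPolicy) -> None:
    """Assert that no two expected sizes' match windows overlap.

    If they did, a single band could match two species and the assay's
    size-based readout would be ill-posed under this tolerance.
    """
    sizes = sorted(e.expected_size for e in panel.entries)
    t = policy.size_tolerance
    for a, b in zip(sizes, sizes[1:]):
        if a * (1 + t) >= b * (1 - t):
            raise ValueError(
                f"expected sizes {a} and {b} have overlapping match windows "
                f"under tolerance {t}; reduce size_tolerance"
            )


def match_band(
    size: float,
    panel: Panel,
    policy: CallPolicy = DEFAULT_CALL_POLICY,
) -> list[str]:
    """Species whose expected size matches ``size``, ordered by closeness."""
    if size < 1:
        raise ValueError("band size must be >= 1 bp")
    hits = [
        (abs(size - e.expected_size) / e.expected_size, e.species)
        for e in panel.entries
        if abs(size - e.expected_size) <= policy.size_tolerance * e.expected_size
    ]
    return [s for _, s in sorted(hits)]


def call_species(
    bands: Sequence[float],
    panel: Panel,
    policy: CallPolicy = DEFAULT_CALL_POLICY,
) -> SpeciesCall:
    """Decide the species for one lane's band sizes.

    Empty input is no_amplification; otherwise each band is matched to
    the panel, the duplex tie-break discounts a cross-amplification-risk
    size co-occurring with a larger diagnostic band, and the surviving
    diagnostic matches determine the call. Non-diagnostic extra bands
    never block an otherwise unique call.
    """
    if any(b <= 0 for b in bands):
        raise ValueError("band sizes must be positive")
    validate_tolerance(panel, policy)
    if not bands:
        return SpeciesCall(status="no_amplification", notes="no bands observed")

    bands = sorted(bands, reverse=True)
    # best (unique under a validated tolerance) species match per band
    matches: list[tuple[float, str | None]] = [
        (b, (match_band(b, panel, policy) or [None])[0]) for b in bands
    ]
    risk_species = {e.species for e in panel.entries if e.cross_amplification_risk}

    discounted: list[int] = []
    surviving: dict[str, float] = {}
    for b, sp in matches:
        if sp is None:
            continue
        if (
            policy.duplex_rule
            and sp in risk_species
            and any(b2 > b and sp2 not in (None, sp) for b2, sp2 in matches)
        ):
            # duplex: a larger diagnostic band from another species is present,
            # so this band is taken as cross-amplification, not identity
            discounted.append(round(b))
            continue
        surviving.setdefault(sp, b)

    unrecognized = [round(b) for b, sp in matches if sp is None]
    if len(surviving) == 1:
        species, size = next(iter(surviving.items()))
        notes = ""
        if discounted:
            notes = (
                "duplex: band(s) at cross-amplification-risk size discounted; "
                "larger diagnostic band used"
            )
        elif unrecognized:
            notes = f"non-diagnostic band(s) ignored: {unrecognized}"
        return SpeciesCall(
            status="identified",
            species=species,
            diagnostic_size=round(size),
            discounted_bands=tuple(discounted),
            candidates=(species,),
            notes=notes,
        )
    if len(surviving) >= 2:
        cands = tuple(sorted(surviving))
        return SpeciesCall(
            status="ambiguous",
            candidates=cands,
            discounted_bands=tuple(discounted),
            notes=f"multiple diagnostic bands: {cands}; possible mixed input",
        )
    return SpeciesCall(
        status="unrecognized_bands",
        discounted_bands=tuple(discounted),
        notes=f"bands {[round(b) for b in bands]} match no panel size",
    )


def _looks_like_ntc(label: str) -> bool:
    lab = label.lower()
    return "ntc" in lab or "no_template" in lab or "no template" in lab


def classify_run(
    lanes: Sequence[Lane],
    panel: Panel,
    policy: CallPolicy = DEFAULT_CALL_POLICY,
    ntc_labels: Sequence[str] | None = None,
) -> RunReport:
    """Call every lane and apply run-level control logic.

    Lanes whose label is in ``ntc_labels`` (or, if None, looks like a
    no-template control) must be band-free; any band there flags the whole
    run as contamination-suspected.
    """
    if not lanes:
        raise ValueError("classify_run requires at least one lane")
    ntc = (
        tuple(ntc_labels)
        if ntc_labels is not None
        else tuple(l.label for l in lanes if _looks_like_ntc(l.label))
    )
    calls = []
    contaminated = False
    for lane in lanes:
        call = call_species([b.size for b in lane.bands], panel, policy)
        if lane.label in ntc and lane.bands:
            contaminated = True
            call = SpeciesCall(
                status=call.status,
                species=call.species,
                diagnostic_size=call.diagnostic_size,
                discounted_bands=call.discounted_bands,
                candidates=call.candidates,
                notes=(call.notes + "; " if call.notes else "")
                + "band in no-template control",
            )
        calls.append((lane.label, call))
    return RunReport(
        calls=tuple(calls),
        contamination_suspected=contaminated,
        ntc_labels=ntc,
    )


def calls_to_tsv(report: RunReport) -> str:
    df = report.summary()
    return df.to_csv(sep="\t", index=False)
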