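"""Virtual agarose-gel electrophoresis.

Fragment migration on agarose is close to linear in log(size) over the
range a given gel percentage resolves, so the model maps log10(size)
affinely onto a relative migration distance normalized to the ladder:
the largest ladder rung migrates ~0, the smallest ~1. Two sizes are
called resolvable when they differ by at least ``resolvability_delta``
in log10 units; amplicons closer than that in the same lane merge into a
single band. The default delta (0.04, i.e. sizes within ~±4-5 % merge)
is calibrated so the assay's closest diagnostic pair (128 vs 183 bp,
Δlog10 ≈ 0.155) and the observed 183/128 duplex separate cleanly on the
2 % gel the assay prescribes, while gel-indistinguishable sizes collapse.

Band intensity is modeled only as integer support (number of merged
amplicons); no fluorescence or densitometry model is attempted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .insilico_pcr import Amplicon

__all__ = ["GelModel", "Band", "Lane", "migrate", "resolvable", "make_lanes",
           "lanes_to_tsv", "render_lanes"]


@dataclass(frozen=True)
class GelModel:
    """Gel percentage, resolvability threshold and ladder definition."""

    agarose_percent: float = 2.0
    resolvability_delta: float = 0.04
    ladder: tuple[int, ...] = (100, 200, 300, 400, 500, 600, 700, 800, 900, 1000)

    def __post_init__(self) -> None:
        if self.agarose_percent <= 0:
            raise ValueError("agarose_percent must be > 0")
        if self.resolvability_delta <= 0:
            raise ValueError("resolvability_delta must be > 0")
        if list(self.ladder) != sorted(set(self.ladder)) or len(self.ladder) < 2:
            raise ValueError("ladder must be strictly increasing with >= 2 rungs")


DEFAULT_GEL = GelModel()


@dataclass(frozen=True)
class Band:
    size: int
    support: int
    migration: float

    def __post_init__(self) -> None:
        if self.support < 1:
            raise ValueError("band support must be >= 1")


@dataclass(frozen=True)
class Lane:
    label: str
    bands: tuple[Band, ...]  # sorted by size descending

    @property
    def sizes(self) -> tuple[int, ...]:
        return tuple(b.size for b in self.bands)


def migrate(size: float, gel: GelModel = DEFAULT_GEL) -> float:
    """Relative migration distance: log-linear in size, ladder-normalized.

    Strictly decreasing in size; values slightly outside [0, 1] are
    possible for sizes beyond the ladder extremes.
    """
    if size < 1:
        raise ValueError("fragment size must be >= 1 bp")
    lo, hi = math.log10(gel.ladder[0]), math.log10(gel.ladder[-1])
    return (hi - math.log10(size)) / (hi - lo)


def resolvable(a: float, b: float, gel: GelModel = DEFAULT_GEL) -> bool:
    """True iff two sizes separate into distinct bands on this gel."""
    if a < 1 or b < 1:
        raise ValueError("fragment sizes must be >= 1 bp")
    return abs(math.log10(a) - math.log10(b)) >= gel.resolvability_delta


def _merge_sizes(sizes: Sequence[int], gel: GelModel) -> list[tuple[int, int]]:
    """Single-linkage merge of unresolvable sizes -> [(band size, support)]."""
    if not sizes:
        return []
    ordered = sorted(sizes, reverse=True)
    groups: list[list[int]] = [[ordered[0]]]
    for s in ordered[1:]:
        if not resolvable(groups[-1][-1], s, gel):
            groups[-1].append(s)
        else:
            groups.append([s])
    return [(round(sum(g) / len(g)), len(g)) for g in groups]


def make_lanes(
    results: Mapping[str, Iterable[Amplicon]],
    gel: GelModel = DEFAULT_GEL,
) -> list[Lane]:
    """Turn per-template amplicon predictions into gel lanes.

    Amplicons of gel-indistinguishable size in one lane merge into a
    single band whose support is the number of merged products; a
    template with no products yields a band-free lane (the NTC look).
    Lane order follows the input mapping order.
    """
    lanes = []
    for label, amps in results.items():
        sizes = [a.length for a in amps]
        bands = tuple(
            Band(size=s, support=n, migration=migrate(s, gel))
            for s, n in _merge_sizes(sizes, gel)
        )
        lanes.append(Lane(label=label, bands=bands))
    return lanes


def lanes_to_tsv(lanes: Sequence[Lane]) -> str:
    lines = ["lane_label\tband_size\tsupport\tmigration"]
    for lane in lanes:
        if not lane.bands:
            lines.append(f"{lane.label}\t-\t0\t-")
        for b in lane.bands:
            lines.append(f"{lane.label}\t{b.size}\t{b.support}\t{b.migration:.4f}")
    return "\n".join(lines) + "\n"


def render_lanes(
    lanes: Sequence[Lane],
    gel: GelModel = DEFAULT_GEL,
    height: int = 24,
) -> str:
    """ASCII rendering of the gel, ladder lane first (figure convention)."""
    ladder_lane = Lane(
        label="L",
        bands=tuple(
            Band(size=s, support=1, migration=migrate(s, gel))
            for s in sorted(gel.ladder, reverse=True)
        ),
    )
    all_lanes = [ladder_lane, *lanes]
    width = max(6, max(len(l.label) for l in all_lanes) + 2)
    rows = [["".ljust(width) for _ in all_lanes] for _ in range(height)]
    for col, lane in enumerate(all_lanes):
        for b in lane.bands:
            row = min(height - 1, max(0, int(round(b.migration * (height - 1)))))
            mark = f"={b.size}="
            rows[row][col] = mark.center(width)[:width]
    header = "".join(l.label.center(width)[:width] for l in all_lanes)
    body = "\n".join("".join(r) for r in rows)
    return header + "\n" + body + "\n"
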