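"""Craniometric alignment of PW and S atlas levels along the Bregma axis.

Two plates are *fully in register* when their Bregma coordinates are equal,
*narrowly in register* when they differ by at most a threshold (default
50 um, roughly the diameter of common injection/probe tracks), and *not in
register* otherwise.  The comparison is purely craniometric: only z is
used, never the plate ordering or tissue content.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

from .registry import AtlasGroup, AtlasLevel, GroupLike, Registry, _as_group


class RegisterClass(str, Enum):
    FULLY = "fully"
    NARROWLY = "narrowly"
    NOT = "not"

    def __str__(self) -> str:
        return self.value


@dataclass(frozen=True)
class AlignmentConfig:
    """``narrow_threshold_um``: largest |dz| still counted as narrowly in
    register (inclusive boundary: |dz| equal to the threshold is narrow)."""

    narrow_threshold_um: int = 50

    def __post_init__(self) -> None:
        if self.narrow_threshold_um <= 0:
            raise ValueError("narrow_threshold_um must be positive")


@dataclass(frozen=True)
class AlignmentPair:
    source: AtlasLevel
    dest: AtlasLevel
    delta_z_um: int
    register_class: RegisterClass


def classify(z_a: int, z_b: int, config: AlignmentConfig = AlignmentConfig()) -> RegisterClass:
    """Register class of two Bregma coordinates (um).  Symmetric."""
    dz = abs(z_a - z_b)
    if dz == 0:
        return RegisterClass.FULLY
    if dz <= config.narrow_threshold_um:
        return RegisterClass.NARROWLY
    return RegisterClass.NOT


@dataclass
class CrossAlignment:
    """Result of aligning every source-group level against a destination group.

    ``nearest`` holds, for each source level, the destination level(s) of
    minimal |dz| (ties are all reported, ordered by destination level
    index).  ``fully`` and ``narrowly`` are the exhaustive pair sets used to
    reproduce the published concordance tables: *every* (source, dest) pair
    at |dz| = 0, respectively 0 < |dz| <= threshold.
    """

    source_group: AtlasGroup
    dest_group: AtlasGroup
    config: AlignmentConfig
    nearest: list[AlignmentPair] = field(default_factory=list)
    fully: list[AlignmentPair] = field(default_factory=list)
    narrowly: list[AlignmentPair] = field(default_factory=list)


def cross_align(
    registry: Registry,
    source_group: GroupLike,
    dest_group: GroupLike,
    config: AlignmentConfig = AlignmentConfig(),
) -> CrossAlignment:
    source_group = _as_group(source_group)
    dest_group = _as_group(dest_group)
    sources = registry.group_levels(source_group)
    dests = registry.group_levels(dest_group)
    if not sources:
        raise ValueError(f"registry has no levels for group {source_group}")
    if not dests:
        raise ValueError(f"registry has no levels for group {dest_group}")

    result = CrossAlignment(source_group, dest_group, config)
    threshold = config.narrow_threshold_um
    for src in sources:
        best_dz = min(abs(src.z_um - d.z_um) for d in dests)
        for dst in dests:
            dz = abs(src.z_um - dst.z_um)
            cls = classify(src.z_um, dst.z_um, config)
            pair = AlignmentPair(src, dst, dz, cls)
            if dz == best_dz:
                result.nearest.append(pair)
            if cls is RegisterClass.FULLY:
                result.fully.append(pair)
            elif cls is RegisterClass.NARROWLY:
                result.narrowly.append(pair)
    return result


def narrowly_table(
    registry: Registry,
    source_group: GroupLike,
    dest_group: GroupLike,
    config: AlignmentConfig = AlignmentConfig(),
) -> list[tuple[int, int, int]]:
    """All (source level, dest level, |dz| um) pairs narrowly in register.

    This is the row set of the published narrow-registration tables; a
    source level may appear with several destination levels when more than
    one falls inside the threshold.
    """
    aligned = cross_align(registry, source_group, dest_group, config)
    rows = [
        (p.source.level, p.dest.level, p.delta_z_um) for p in aligned.narrowly
    ]
    rows.sort(key=lambda r: (-_z(registry, aligned.source_group, r[0]), r[1]))
    return rows


def fully_table(
    registry: Registry,
    source_group: GroupLike,
    dest_group: GroupLike,
    config: AlignmentConfig = AlignmentConfig(),
) -> list[tuple[int, int]]:
    """All (source level, dest level) pairs with identical Bregma z."""
    aligned = cross_align(registry, source_group, dest_group, config)
    rows = [(p.source.level, p.dest.level) for p in aligned.fully]
    rows.sort(key=lambda r: (-_z(registry, aligned.source_group, r[0]), r[1]))
    return rows


def _z(registry: Registry, group: AtlasGroup, level: int) -> int:
    return registry.z_of(group, level)


def write_alignment_pairs(aligned: CrossAlignment, path: str | Path) -> None:
    """`alignment_pairs.csv`: one row per nearest-match pair."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(
            ["source_group", "source_level", "dest_group", "dest_level",
             "delta_z_um", "class"]
        )
        for p in aligned.nearest:
            writer.writerow(
                [p.source.group.value, p.source.level, p.dest.group.value,
                 p.dest.level, p.delta_z_um, p.register_class.value]
            )


# ---------------------------------------------------------------------------
# Dot-plot export (one-dimensional Cleveland-style dot plot of all levels)
# ---------------------------------------------------------------------------

#: Vertical track order of the groups in the exported dot plot (a dummy
#: categorical axis; z is the only real coordinate).
TRACK_ORDER: tuple[AtlasGroup, ...] = (
    AtlasGroup.PW1, AtlasGroup.PW2, AtlasGroup.PW3, AtlasGroup.S,
)

_COLOR = {
    RegisterClass.FULLY: "black",
    RegisterClass.NARROWLY: "white",
    RegisterClass.NOT: "red",
}


@dataclass(frozen=True)
class DotPlotRow:
    group: AtlasGroup
    track: int
    level: int
    z_mm: float
    register_class: RegisterClass
    comparison_group: AtlasGroup


def dotplot_export(
    registry: Registry,
    config: AlignmentConfig = AlignmentConfig(),
    *,
    comparison: dict[AtlasGroup, AtlasGroup] | None = None,
) -> list[DotPlotRow]:
    """One dot per (group, level), colored by proximity to the comparison group.

    By default each PW group is compared against S, and S against the union
    of the PW groups (an S dot is "fully" if any PW level shares its z,
    else "narrowly" if any is within the threshold).
    """
    rows: list[DotPlotRow] = []
    pw_groups = [g for g in TRACK_ORDER if g is not AtlasGroup.S]
    for track, group in enumerate(TRACK_ORDER, start=1):
        levels = registry.group_levels(group)
        if not levels:
            continue
        if comparison is not None and group in comparison:
            other_z = [lv.z_um for lv in registry.group_levels(comparison[group])]
        elif group is AtlasGroup.S:
            other_z = [lv.z_um for g in pw_groups for lv in registry.group_levels(g)]
        else:
            other_z = [lv.z_um for lv in registry.group_levels(AtlasGroup.S)]
        cmp_group = (
            comparison[group] if comparison and group in comparison
            else (AtlasGroup.PW1 if group is AtlasGroup.S else AtlasGroup.S)
        )
        for lv in levels:
            best = min(abs(lv.z_um - z) for z in other_z) if other_z else None
            cls = (
                RegisterClass.NOT if best is None
                else classify(lv.z_um, lv.z_um + best, config)
            )
            rows.append(DotPlotRow(group, track, lv.level, lv.z_mm, cls, cmp_group))
    return rows


def write_dotplot_csv(rows: Sequence[DotPlotRow], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["group", "track", "level", "z_mm", "class", "color"])
        for r in rows:
            writer.writerow(
                [r.group.value, r.track, r.level, f"{r.z_mm:.2f}",
                 r.register_class.value, _COLOR[r.register_class]]
            )


def write_dotplot_svg(rows: Sequence[DotPlotRow], path: str | Path) -> None:
    """Minimal SVG rendering: one horizontal track per group, dots along z."""
    from ._svg import SvgDocument

    if not rows:
        raise ValueError("no dot-plot rows to render")
    z_values = [r.z_mm for r in rows]
    z_min, z_max = min(z_values), max(z_values)
    span = max(z_max - z_min, 1e-9)
    width, height, margin, track_gap = 1000.0, 40.0 * len(TRACK_ORDER) + 60, 40.0, 40.0

    doc = SvgDocument(width + 2 * margin, height)
    # anterior (larger z) on the left, matching stereotaxic convention
    def x_of(z: float) -> float:
        return margin + (z_max - z) / span * width

    for track, group in enumerate(TRACK_ORDER, start=1):
        y = 30.0 + track * track_gap
        doc.line(margin, y, margin + width, y, stroke="#ccc")
        doc.text(5, y + 4, group.value, size=12)
    for r in rows:
        y = 30.0 + r.track * track_gap
        fill = _COLOR[r.register_class]
        stroke = "black" if fill == "white" else "none"
        doc.circle(x_of(r.z_mm), y, 3.0, fill=fill, stroke=stroke)
    for z_tick in range(int(z_min) - 1, int(z_max) + 2, 2):
        doc.text(x_of(float(z_tick)) - 8, 25, f"{z_tick:+d}", size=10)
    doc.text(margin, 12, "anteroposterior distance from Bregma (mm)", size=11)
    doc.save(path)
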