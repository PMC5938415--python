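"""Point-source data migration between atlas coordinate frames.

A mapped experimental datum (here, the ventral tip of a microinjection
site) is a single (x, y) coordinate in millimeters within a 2 x 2 mm
Cartesian workspace centered on an origin O: x is mediolateral, y is
dorsoventral.  Migrating data from the PW frame into the S frame uses
anisotropic scaling of the S template (139% horizontally, 161% vertically,
after Swanson's published factors; alternatively both maps are normalized
with a single 139.5% factor).  Because craniometric transfer alone leaves
residual error, migrated points are then relocated by a subject-matter
expert; the relocation is an *input* here, never computed.

This module quantifies those expert corrections.  For an uncorrected
position A and corrected position B the correction vector has components

    ABx = |Bx - Ax|        (mediolateral)
    ABy = Ay - By          (dorsoventral)

magnitude sqrt(ABx^2 + ABy^2), and direction phi = atan2(ABy, ABx) in
degrees.  The component conventions are exactly those satisfied by the
published reference dataset bundled with the package (all 24 of its rows,
including those where Bx < Ax and the one where the correction crosses the
midline); phi therefore lands in the first quadrant for ventral
corrections, and phi is 0 by convention when A = B.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PointSource", "ScaleSpec", "MigrationRecord", "MigrationSummary",
    "scale_points", "error_vector", "summarize", "migrate_dataset",
    "read_points_csv", "write_migration_report", "write_migration_summary",
    "load_bundled_point_data", "SCALE_S_TO_PW", "NORMALIZE_BOTH",
    "write_vector_svg",
]

#: Horizontal/vertical factors aligning the S template grid to PW space.
DEFAULT_SX = 1.39
DEFAULT_SY = 1.61
#: Single normalization factor applied to both axes in the alternate mode.
DEFAULT_NORMALIZE = 1.395

SCALE_S_TO_PW = "scale_S_to_PW"
NORMALIZE_BOTH = "normalize_both"

WORKSPACE_HALF_MM = 1.0  # the quadrants span a 2 x 2 mm Cartesian plane


@dataclass(frozen=True)
class PointSource:
    """One point-source datum in a 2 x 2 mm workspace (mm from origin O)."""

    case_label: str
    tag: str
    x_mm: float
    y_mm: float
    pair: str = ""

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.pair, self.case_label, self.tag)


@dataclass(frozen=True)
class ScaleSpec:
    """Anisotropic scaling about the workspace origin.

    ``scale_S_to_PW`` stretches the S template onto the PW grid with
    separate horizontal/vertical factors; ``normalize_both`` applies one
    shared factor (the published alternative differs from the two-factor
    route by ~0.4% horizontally and ~0.1% vertically).
    """

    sx: float = DEFAULT_SX
    sy: float = DEFAULT_SY
    mode: str = SCALE_S_TO_PW

    def __post_init__(self) -> None:
        if self.mode not in (SCALE_S_TO_PW, NORMALIZE_BOTH):
            raise ValueError(f"unknown scaling mode {self.mode!r}")
        if self.sx <= 0 or self.sy <= 0:
            raise ValueError("scale factors must be positive")

    @classmethod
    def normalize(cls, factor: float = DEFAULT_NORMALIZE) -> "ScaleSpec":
        return cls(sx=factor, sy=factor, mode=NORMALIZE_BOTH)

    def inverse(self) -> "ScaleSpec":
        return ScaleSpec(1.0 / self.sx, 1.0 / self.sy, self.mode)


def scale_points(
    points: Sequence[PointSource], spec: ScaleSpec = ScaleSpec()
) -> list[PointSource]:
    """Scale every (x, y) about the origin: (sx * x, sy * y).  Invertible."""
    return [
        PointSource(p.case_label, p.tag, spec.sx * p.x_mm, spec.sy * p.y_mm, p.pair)
        for p in points
    ]


def error_vector(
    a: tuple[float, float], b: tuple[float, float]
) -> tuple[float, float, float, float]:
    """Correction vector (ABx, ABy, magnitude, phi_deg) from A to B.

    ABx = |Bx - Ax|, ABy = Ay - By (positive = ventral correction),
    phi = atan2(ABy, ABx) in degrees within (-180, 180]; A = B gives
    (0, 0, 0, 0) by convention.
    """
    ax, ay = float(a[0]), float(a[1])
    bx, by = float(b[0]), float(b[1])
    if not all(map(math.isfinite, (ax, ay, bx, by))):
        raise ValueError("coordinates must be finite")
    abx = abs(bx - ax)
    aby = ay - by
    magnitude = math.hypot(abx, aby)
    phi = 0.0 if magnitude == 0.0 else math.degrees(math.atan2(aby, abx))
    return abx, aby, magnitude, phi


@dataclass(frozen=True)
class MigrationRecord:
    point: PointSource          # identity (labels refer to the A-side datum)
    ax: float
    ay: float
    bx: float
    by: float
    abx: float
    aby: float
    magnitude_ab: float
    phi_deg: float

    @classmethod
    def from_positions(
        cls, point: PointSource, a: tuple[float, float], b: tuple[float, float]
    ) -> "MigrationRecord":
        abx, aby, mag, phi = error_vector(a, b)
        return cls(point, a[0], a[1], b[0], b[1], abx, aby, mag, phi)


_SUMMARY_COLUMNS = ("ax", "ay", "bx", "by", "abx", "aby", "magnitude_ab", "phi_deg")


@dataclass(frozen=True)
class MigrationSummary:
    """Column-wise mean and SEM over migration records.

    SEM uses the sample standard deviation (denominator n - 1) divided by
    sqrt(n).  Component means are in mm (multiply by 1000 for um).
    """

    n: int
    mean: dict[str, float]
    sem: dict[str, float]


def summarize(records: Sequence[MigrationRecord]) -> MigrationSummary:
    if len(records) < 2:
        raise ValueError("SEM is undefined for fewer than 2 records")
    data = {
        col: np.array([getattr(r, col) for r in records], dtype=np.float64)
        for col in _SUMMARY_COLUMNS
    }
    n = len(records)
    mean = {col: float(v.mean()) for col, v in data.items()}
    sem = {col: float(v.std(ddof=1) / math.sqrt(n)) for col, v in data.items()}
    return MigrationSummary(n, mean, sem)


# ---------------------------------------------------------------------------
# CSV interfaces
# ---------------------------------------------------------------------------

_BASE_COLUMNS = ["case_label", "tag", "x_mm", "y_mm"]


def read_points_csv(path: str | Path) -> list[PointSource]:
    """Read a point-source CSV: ``[pair,]case_label,tag,x_mm,y_mm``.

    The optional leading ``pair`` column names the migration pair (e.g.
    source and destination plates) and becomes part of the join key, which
    lets one file carry several migrated levels whose case labels repeat.
    Duplicate keys within one file are an error.  Positions outside the
    2 x 2 mm workspace are accepted with a warning.
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype={"case_label": str, "tag": str})
    columns = list(frame.columns)
    if columns not in (_BASE_COLUMNS, ["pair"] + _BASE_COLUMNS):
        raise ValueError(
            f"{path}: expected columns {_BASE_COLUMNS} (optionally preceded "
            f"by 'pair'), got {columns}"
        )
    if "pair" not in frame.columns:
        frame.insert(0, "pair", "")
    points = [
        PointSource(row.case_label, row.tag, float(row.x_mm), float(row.y_mm),
                    str(row.pair))
        for row in frame.itertuples(index=False)
    ]
    seen: set[tuple[str, str, str]] = set()
    for p in points:
        if p.key in seen:
            raise ValueError(
                f"{path}: duplicate point key pair={p.pair!r} "
                f"case_label={p.case_label!r} tag={p.tag!r}"
            )
        seen.add(p.key)
    outside = [
        p for p in points
        if abs(p.x_mm) > WORKSPACE_HALF_MM or abs(p.y_mm) > WORKSPACE_HALF_MM
    ]
    if outside:
        warnings.warn(
            f"{path}: {len(outside)} point(s) fall outside the 2 x 2 mm "
            "workspace (|x|, |y| <= 1 mm)",
            stacklevel=2,
        )
    return points


@dataclass
class MigrationReport:
    scaled_a: list[PointSource]
    records: list[MigrationRecord]
    summary: MigrationSummary | None
    unmatched_a: list[PointSource]
    unmatched_b: list[PointSource]


def migrate_dataset(
    points_a: Sequence[PointSource] | str | Path,
    points_b: Sequence[PointSource] | str | Path | None = None,
    spec: ScaleSpec | None = None,
) -> MigrationReport:
    """Scale the A positions and, when corrected B positions are given,
    quantify the expert corrections.

    A and B records join on (pair, case_label, tag); unmatched labels are
    reported (with a warning), not silently dropped.  Without B only the
    scaled transfer is produced.  ``spec=None`` skips scaling (positions
    already in the destination frame, as in the bundled reference data).
    """
    a_points = (
        read_points_csv(points_a)
        if isinstance(points_a, (str, Path)) else list(points_a)
    )
    scaled_a = scale_points(a_points, spec) if spec is not None else list(a_points)
    if points_b is None:
        return MigrationReport(scaled_a, [], None, [], [])

    b_points = (
        read_points_csv(points_b)
        if isinstance(points_b, (str, Path)) else list(points_b)
    )
    b_index = {p.key: p for p in b_points}
    if len(b_index) != len(b_points):
        raise ValueError("duplicate point keys in corrected (B) dataset")
    a_index = {p.key: p for p in scaled_a}
    if len(a_index) != len(scaled_a):
        raise ValueError("duplicate point keys in source (A) dataset")

    records: list[MigrationRecord] = []
    unmatched_a: list[PointSource] = []
    for p in scaled_a:
        match = b_index.get(p.key)
        if match is None:
            unmatched_a.append(p)
            continue
        records.append(
            MigrationRecord.from_positions(
                p, (p.x_mm, p.y_mm), (match.x_mm, match.y_mm)
            )
        )
    unmatched_b = [p for p in b_points if p.key not in a_index]
    for p in unmatched_a + unmatched_b:
        warnings.warn(
            f"unmatched point pair={p.pair!r} case_label={p.case_label!r} "
            f"tag={p.tag!r}",
            stacklevel=2,
        )
    summary = summarize(records) if len(records) >= 2 else None
    return MigrationReport(scaled_a, records, summary, unmatched_a, unmatched_b)


def write_migration_report(report: MigrationReport, path: str | Path) -> None:
    """``migration_report.csv``: positions to 5 dp (mm), phi to 3 dp (deg)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        if report.records:
            writer.writerow(
                ["pair", "case_label", "tag", "Ax", "Ay", "Bx", "By",
                 "ABx", "ABy", "AB", "phi_deg"]
            )
            for r in report.records:
                writer.writerow(
                    [r.point.pair, r.point.case_label, r.point.tag]
                    + [f"{v:.5f}" for v in (r.ax, r.ay, r.bx, r.by, r.abx, r.aby)]
                    + [f"{r.magnitude_ab:.6f}", f"{r.phi_deg:.3f}"]
                )
        else:
            writer.writerow(["pair", "case_label", "tag", "x_mm", "y_mm"])
            for p in report.scaled_a:
                writer.writerow(
                    [p.pair, p.case_label, p.tag, f"{p.x_mm:.5f}", f"{p.y_mm:.5f}"]
                )


def write_migration_summary(summary: MigrationSummary, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["statistic"] + list(_SUMMARY_COLUMNS))
        writer.writerow(
            ["mean"]
            + [f"{summary.mean[c]:.6f}" for c in _SUMMARY_COLUMNS[:-1]]
            + [f"{summary.mean['phi_deg']:.3f}"]
        )
        writer.writerow(
            ["sem"]
            + [f"{summary.sem[c]:.6f}" for c in _SUMMARY_COLUMNS[:-1]]
            + [f"{summary.sem['phi_deg']:.3f}"]
        )
        writer.writerow(["n"] + [summary.n] * len(_SUMMARY_COLUMNS))


def write_vector_svg(records: Iterable[MigrationRecord], path: str | Path) -> None:
    """Correction vectors drawn inside the unit (1 mm) circle."""
    from ._svg import SvgDocument

    size, half = 400.0, 200.0
    scale = half / WORKSPACE_HALF_MM * 0.9
    doc = SvgDocument(size, size)
    doc.circle(half, half, scale * WORKSPACE_HALF_MM, fill="none", stroke="#999")
    doc.line(0, half, size, half, stroke="#ccc")
    doc.line(half, 0, half, size, stroke="#ccc")
    for r in records:
        # origin-anchored vector; SVG y grows downward = ventral
        x1, y1 = half, half
        x2 = half + scale * r.abx
        y2 = half + scale * r.aby
        doc.line(x1, y1, x2, y2, stroke="red")
        doc.circle(x2, y2, 2.0, fill="red")
    doc.text(size - 14, half - 4, "l", size=11)
    doc.text(half + 4, 12, "d", size=11)
    doc.text(half + 4, size - 4, "v", size=11)
    doc.save(path)


def load_bundled_point_data() -> tuple[list[PointSource], list[PointSource]]:
    """The bundled reference dataset of 24 migrated injection sites:
    uncorrected (A) and expert-corrected (B) positions in S space."""
    data = resources.files("ratlas.data")
    a = read_points_csv(str(data.joinpath("table7_A.csv")))
    b = read_points_csv(str(data.joinpath("table7_B.csv")))
    return a, b
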