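"""Craniometric registry of rat-brain atlas levels.

The registry is the machine-readable form of the cross-atlas concordance
table: every plate ("atlas level") of the Paxinos-Watson (PW) and Swanson
(S) rat-brain atlases, keyed by its anteroposterior distance from the skull
landmark Bregma (the beta coordinate, z).  The eleven published atlas
editions collapse into four reference spaces:

* ``PW1`` -- Paxinos & Watson 1982/1986/1997 (one tissue set, shared level
  numbering),
* ``PW2`` -- Paxinos & Watson 1998 (same tissue set as PW1 plus two extra
  plates, which shifts the numbering),
* ``PW3`` -- Paxinos & Watson 2005/2007/2014 (a different animal, sampled
  at ~120 um instead of ~500 um),
* ``S``   -- Swanson 1992/1998/2004/2018 (one tissue set throughout).

z is stored as an integer number of micrometers (positive = anterior to
Bregma).  Integer storage makes the "fully in register" comparison
(z_PW == z_S) exact; the source table prints z to 0.01 mm so nothing is
lost.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Union


class AtlasGroup(str, Enum):
    """One of the four atlas reference spaces."""

    PW1 = "PW1"
    PW2 = "PW2"
    PW3 = "PW3"
    S = "S"

    def __str__(self) -> str:  # so CSV/error output prints "PW1", not the repr
        return self.value


GroupLike = Union[AtlasGroup, str]


def _as_group(group: GroupLike, *, line: int | None = None) -> AtlasGroup:
    try:
        return AtlasGroup(group)
    except ValueError:
        where = f" (line {line})" if line is not None else ""
        raise RegistryValidationError(
            f"unknown atlas group {group!r}{where}; expected one of "
            f"{[g.value for g in AtlasGroup]}"
        ) from None


class RegistryError(Exception):
    """Base class for registry loading/validation problems."""


class RegistryParseError(RegistryError):
    """A CSV row could not be parsed; the message names the line number."""


class RegistryValidationError(RegistryError):
    """Parsed data violate a registry invariant (e.g. duplicate level)."""


class LevelLookupError(RegistryError, KeyError):
    """A (group, level) pair is absent from the registry."""


@dataclass(frozen=True, order=True)
class AtlasLevel:
    """One atlas plate: its reference space, plate number, and Bregma z.

    ``z_um`` is the anteroposterior distance from Bregma in micrometers,
    positive anterior.  It is always a multiple of 10 (the source prints z
    to 0.01 mm).
    """

    group: AtlasGroup
    level: int
    z_um: int

    def __post_init__(self) -> None:
        if self.level <= 0:
            raise RegistryValidationError(f"level must be positive, got {self.level}")
        if self.z_um % 10 != 0:
            raise RegistryValidationError(
                f"z_um must be a multiple of 10 um, got {self.z_um}"
            )

    @property
    def z_mm(self) -> float:
        return self.z_um / 1000.0


@dataclass
class Registry:
    """A collection of atlas levels with unique (group, level) keys.

    ``allow_duplicates=True`` relaxes uniqueness for auditing verbatim
    transcriptions of the printed source table, which repeats a handful of
    level indices; such a registry supports iteration and
    :func:`validate_monotonicity` but refuses ambiguous :meth:`z_of` lookups.
    """

    levels: list[AtlasLevel] = field(default_factory=list)
    provenance: str = ""
    allow_duplicates: bool = False
    _index: dict[tuple[AtlasGroup, int], list[AtlasLevel]] = field(
        default_factory=dict, repr=False
    )

    def __post_init__(self) -> None:
        entries, self.levels = list(self.levels), []
        for entry in entries:
            self.add(entry)

    def __len__(self) -> int:
        return len(self.levels)

    def __iter__(self):
        return iter(self.levels)

    def add(self, entry: AtlasLevel) -> None:
        key = (entry.group, entry.level)
        bucket = self._index.setdefault(key, [])
        if bucket and not self.allow_duplicates:
            raise RegistryValidationError(
                f"duplicate atlas level ({entry.group}, {entry.level}): "
                f"z = {bucket[0].z_mm:+.2f} mm and {entry.z_mm:+.2f} mm"
            )
        bucket.append(entry)
        self.levels.append(entry)

    def groups(self) -> list[AtlasGroup]:
        return sorted({lv.group for lv in self.levels}, key=lambda g: g.value)

    def group_levels(self, group: GroupLike) -> list[AtlasLevel]:
        """All levels of one reference space, sorted by plate number."""
        group = _as_group(group)
        return sorted(
            (lv for lv in self.levels if lv.group == group),
            key=lambda lv: (lv.level, -lv.z_um),
        )

    def z_of(self, group: GroupLike, level: int) -> int:
        """Bregma z in micrometers for one plate; raises on absent keys."""
        group = _as_group(group)
        bucket = self._index.get((group, level))
        if not bucket:
            raise LevelLookupError(f"no atlas level ({group}, {level}) in registry")
        if len(bucket) > 1:
            raise LevelLookupError(
                f"({group}, {level}) is ambiguous: {len(bucket)} entries "
                f"(registry loaded with allow_duplicates)"
            )
        return bucket[0].z_um


def _parse_z_mm(text: str) -> int:
    """Parse a signed decimal mm value to integer um, half away from zero.

    Floating-point rounding of values like 2.675 is banker's-rounded by
    ``round``; the table's classification depends on exact um values, so the
    conversion goes through the decimal digits instead.
    """
    text = text.strip().replace("−", "-")  # tolerate U+2212 minus
    sign = -1 if text.startswith("-") else 1
    mantissa = text.lstrip("+-")
    if "." in mantissa:
        whole, frac = mantissa.split(".", 1)
    else:
        whole, frac = mantissa, ""
    if not (whole + frac).isdigit() or len(frac) > 3:
        raise ValueError(f"not a millimeter value: {text!r}")
    frac = (frac + "000")[:3]
    return sign * (int(whole or "0") * 1000 + int(frac))


def load_registry(
    path: str | Path,
    *,
    provenance: str | None = None,
    allow_duplicates: bool = False,
) -> Registry:
    """Load a registry from a ``group,level,z_mm`` CSV.

    z is parsed as decimal millimeters and stored as integer micrometers
    (rounded half away from zero).  Duplicate (group, level) rows raise
    :class:`RegistryValidationError` unless ``allow_duplicates`` is set.
    """
    path = Path(path)
    registry = Registry(
        provenance=provenance if provenance is not None else path.name,
        allow_duplicates=allow_duplicates,
    )
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != ["group", "level", "z_mm"]:
            raise RegistryParseError(
                f"{path}: expected header 'group,level,z_mm', got {header!r}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not cell.strip() for cell in row):
                continue
            if len(row) != 3:
                raise RegistryParseError(
                    f"{path}: line {lineno}: expected 3 fields, got {len(row)}"
                )
            group = _as_group(row[0].strip(), line=lineno)
            try:
                level = int(row[1])
                z_um = _parse_z_mm(row[2])
            except ValueError as exc:
                raise RegistryParseError(f"{path}: line {lineno}: {exc}") from exc
            registry.add(AtlasLevel(group, level, z_um))
    return registry


def write_registry(registry: Registry, path: str | Path) -> None:
    """Write a registry back to the ``group,level,z_mm`` CSV dialect."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["group", "level", "z_mm"])
        for lv in registry:
            writer.writerow([lv.group.value, lv.level, f"{lv.z_mm:.2f}"])


def z_of(registry: Registry, group: GroupLike, level: int) -> int:
    return registry.z_of(group, level)


@dataclass(frozen=True)
class MonotonicityViolation:
    group: AtlasGroup
    level_a: int
    level_b: int
    description: str


def validate_monotonicity(registry: Registry) -> list[MonotonicityViolation]:
    """Flag adjacent level pairs whose z does not strictly decrease.

    Atlas plates are numbered front to back, so within each reference space
    z should strictly decrease as the plate number increases.  The printed
    source table violates this in a few places (duplicated level indices
    near z = -11 mm); this check surfaces those anomalies.  It is advisory
    only -- nothing is corrected.
    """
    report: list[MonotonicityViolation] = []
    for group in registry.groups():
        entries = registry.group_levels(group)
        for prev, cur in zip(entries, entries[1:]):
            if prev.level == cur.level:
                report.append(
                    MonotonicityViolation(
                        group, prev.level, cur.level,
                        f"level {cur.level} occurs more than once "
                        f"(z = {prev.z_mm:+.2f} and {cur.z_mm:+.2f} mm)",
                    )
                )
            elif cur.z_um >= prev.z_um:
                report.append(
                    MonotonicityViolation(
                        group, prev.level, cur.level,
                        f"z does not decrease: level {prev.level} at "
                        f"{prev.z_mm:+.2f} mm, level {cur.level} at {cur.z_mm:+.2f} mm",
                    )
                )
    return report


def write_monotonicity_report(
    report: Iterable[MonotonicityViolation], path: str | Path
) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["group", "level_a", "level_b", "description"])
        for item in report:
            writer.writerow([item.group.value, item.level_a, item.level_b, item.description])


def bundled_registry_path(name: str = "table1_registry.csv") -> Path:
    """Path to a bundled data file (context-manager-free; files are real)."""
    return Path(str(resources.files("ratlas.data").joinpath(name)))


def load_bundled_registry(*, as_printed: bool = False) -> Registry:
    """The bundled cross-atlas concordance registry.

    With ``as_printed=True`` the verbatim transcription is returned instead
    (it repeats five level indices near z = -11 mm, as the printed source
    does, and therefore loads with ``allow_duplicates``).
    """
    if as_printed:
        return load_registry(
            bundled_registry_path("table1_as_printed.csv"), allow_duplicates=True
        )
    return load_registry(bundled_registry_path("table1_registry.csv"))
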