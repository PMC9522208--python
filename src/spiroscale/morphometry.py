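"""Spiracle morphometry: data model, derived geometric indices, table I/O.

A scarab beetle has eight spiracles per side: mesothoracic (S),
metathoracic (T) and six abdominal (A1..A6), anterior to posterior.
For each spiracle two orthogonal opening diameters (transverse and
sagittal planes, mm) and a depth (outer opening to the interior valve,
mm) are measured.  The opening is modelled as an ellipse; from its area
(cm^2) and depth (cm) two indices follow:

* ``area / depth``   (cm)  — proportional to Fick diffusive conductance
* ``area^2 / depth`` (cm^3) — proportional to Poiseuille advective
  conductance

Measurement tables are long-form CSV: one row per (specimen, spiracle).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from . import units

#: Anatomical order, anterior to posterior.
SPIRACLE_LABELS = ("S", "T", "A1", "A2", "A3", "A4", "A5", "A6")

SEXES = ("M", "F", "unknown")

#: Columns of the long-form measurement CSV, in order.
TABLE_COLUMNS = (
    "specimen_id",
    "species",
    "sex",
    "mass_g",
    "spiracle",
    "d_transverse_mm",
    "d_sagittal_mm",
    "depth_mm",
)


class InvalidMeasurementError(ValueError):
    """A spiracle dimension is nonpositive or a label is unknown."""


class IncompleteSpecimenError(ValueError):
    """Specimen totals requested with spiracles missing."""

    def __init__(self, specimen_id: str, missing: Sequence[str]):
        self.specimen_id = specimen_id
        self.missing = tuple(missing)
        super().__init__(
            f"specimen {specimen_id!r} is missing spiracles: {', '.join(missing)}"
        )


class TableParseError(ValueError):
    """Malformed measurement table; carries the offending row number."""

    def __init__(self, row: int, message: str):
        self.row = row
        super().__init__(f"row {row}: {message}")


def elliptical_area(
    d_transverse: float, d_sagittal: float, *, literal_semi_axes: bool = False
) -> float:
    """Elliptical opening area (cm^2) from two full diameters (mm).

    The standard ellipse area from two diameters is pi*d1*d2/4.  With
    ``literal_semi_axes=True`` the diameters are instead treated as the
    semi-axes themselves (pi*d1*d2), a 4x larger reading retained only
    for sensitivity analysis; it breaks the circle limit and is never
    the default.
    """
    if d_transverse <= 0:
        raise InvalidMeasurementError(f"d_transverse must be > 0, got {d_transverse}")
    if d_sagittal <= 0:
        raise InvalidMeasurementError(f"d_sagittal must be > 0, got {d_sagittal}")
    if literal_semi_axes:
        area_mm2 = math.pi * d_transverse * d_sagittal
    else:
        area_mm2 = math.pi * (d_transverse / 2.0) * (d_sagittal / 2.0)
    return units.mm2_to_cm2(area_mm2)


@dataclass(frozen=True)
class SpiracleMeasurement:
    """Raw dimensions of one spiracle (all lengths in mm)."""

    spiracle_label: str
    d_transverse: float
    d_sagittal: float
    depth: float

    def __post_init__(self):
        if self.spiracle_label not in SPIRACLE_LABELS:
            raise InvalidMeasurementError(
                f"unknown spiracle label {self.spiracle_label!r}; "
                f"expected one of {SPIRACLE_LABELS}"
            )
        for name in ("d_transverse", "d_sagittal", "depth"):
            v = getattr(self, name)
            if not (v > 0):
                raise InvalidMeasurementError(f"{name} must be > 0, got {v}")


@dataclass(frozen=True)
class MorphometricRecord:
    """Derived geometry of one spiracle (or a specimen total).

    area in cm^2, depth in cm, diff_index = area/depth in cm,
    adv_index = area^2/depth in cm^3.
    """

    area: float
    depth: float
    diff_index: float
    adv_index: float

    def __post_init__(self):
        for name in ("area", "depth", "diff_index", "adv_index"):
            v = getattr(self, name)
            if not (v > 0):
                raise InvalidMeasurementError(f"{name} must be > 0, got {v}")
        if not math.isclose(self.diff_index * self.depth, self.area, rel_tol=1e-12):
            raise InvalidMeasurementError("diff_index * depth != area")
        if not math.isclose(
            self.adv_index * self.depth, self.area**2, rel_tol=1e-12
        ):
            raise InvalidMeasurementError("adv_index * depth != area^2")


@dataclass(frozen=True)
class Specimen:
    """One beetle: identity, body mass (g) and its measured spiracles."""

    specimen_id: str
    species: str
    sex: str
    mass: float
    spiracles: tuple[SpiracleMeasurement, ...] = field(default_factory=tuple)

    def __post_init__(self):
        if not (self.mass > 0):
            raise InvalidMeasurementError(f"mass must be > 0, got {self.mass}")
        if self.sex not in SEXES:
            raise InvalidMeasurementError(
                f"sex must be one of {SEXES}, got {self.sex!r}"
            )
        labels = [m.spiracle_label for m in self.spiracles]
        if len(labels) != len(set(labels)):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise InvalidMeasurementError(
                f"duplicate spiracle labels in specimen "
                f"{self.specimen_id!r}: {dupes}"
            )

    def spiracle(self, label: str) -> SpiracleMeasurement:
        for m in self.spiracles:
            if m.spiracle_label == label:
                return m
        raise KeyError(label)

    @property
    def missing_labels(self) -> tuple[str, ...]:
        present = {m.spiracle_label for m in self.spiracles}
        return tuple(l for l in SPIRACLE_LABELS if l not in present)


def to_morphometrics(
    m: SpiracleMeasurement, *, literal_semi_axes: bool = False
) -> MorphometricRecord:
    """Derived area/depth/indices for one spiracle, mm inputs -> cm outputs."""
    area = elliptical_area(
        m.d_transverse, m.d_sagittal, literal_semi_axes=literal_semi_axes
    )
    depth = units.mm_to_cm(m.depth)
    return MorphometricRecord(
        area=area,
        depth=depth,
        diff_index=area / depth,
        adv_index=area**2 / depth,
    )


@dataclass(frozen=True)
class SpecimenTotals:
    """Whole-animal capacities: per-spiracle indices summed over the 8
    spiracles and doubled for the two body sides.  A summed record has
    no single depth, so the per-spiracle record invariants do not apply."""

    area: float        # cm^2, doubled summed opening area
    diff_index: float  # cm,   doubled summed area/depth
    adv_index: float   # cm^3, doubled summed area^2/depth

    def __post_init__(self):
        for name in ("area", "diff_index", "adv_index"):
            if not (getattr(self, name) > 0):
                raise InvalidMeasurementError(f"{name} must be > 0")


def specimen_totals(
    s: Specimen,
    *,
    literal_semi_axes: bool = False,
    impute_from: Sequence[Specimen] | None = None,
) -> SpecimenTotals:
    """Summed-and-doubled diffusive and advective indices for one beetle.

    All eight spiracles must be present; a specimen with missing labels
    raises :class:`IncompleteSpecimenError` unless ``impute_from`` is
    given, in which case each missing spiracle is imputed by the mean
    dimensions of that label over conspecifics in ``impute_from``.
    """
    if s.missing_labels:
        if impute_from is None:
            raise IncompleteSpecimenError(s.specimen_id, s.missing_labels)
        s = _completed(s, impute_from)
    records = [
        to_morphometrics(s.spiracle(l), literal_semi_axes=literal_semi_axes)
        for l in SPIRACLE_LABELS
    ]
    return SpecimenTotals(
        area=2.0 * sum(r.area for r in records),
        diff_index=2.0 * sum(r.diff_index for r in records),
        adv_index=2.0 * sum(r.adv_index for r in records),
    )


def _completed(s: Specimen, impute_from: Sequence[Specimen]) -> Specimen:
    spiracles = {m.spiracle_label: m for m in s.spiracles}
    for label in s.missing_labels:
        donors = [
            sp.spiracle(label)
            for sp in impute_from
            if sp.species == s.species
            and label not in sp.missing_labels
            and sp.specimen_id != s.specimen_id
        ]
        if not donors:
            raise IncompleteSpecimenError(s.specimen_id, (label,))
        spiracles[label] = SpiracleMeasurement(
            spiracle_label=label,
            d_transverse=sum(d.d_transverse for d in donors) / len(donors),
            d_sagittal=sum(d.d_sagittal for d in donors) / len(donors),
            depth=sum(d.depth for d in donors) / len(donors),
        )
    return replace(
        s, spiracles=tuple(spiracles[l] for l in SPIRACLE_LABELS if l in spiracles)
    )


# ---------------------------------------------------------------------------
# Table I/O (long-form CSV; '#' comment lines; '.' decimal separator)
# ---------------------------------------------------------------------------

def specimens_to_frame(specimens: Iterable[Specimen]) -> pd.DataFrame:
    rows = []
    for s in specimens:
        for m in s.spiracles:
            rows.append(
                {
                    "specimen_id": s.specimen_id,
                    "species": s.species,
                    "sex": s.sex,
                    "mass_g": s.mass,
                    "spiracle": m.spiracle_label,
                    "d_transverse_mm": m.d_transverse,
                    "d_sagittal_mm": m.d_sagittal,
                    "depth_mm": m.depth,
                }
            )
    return pd.DataFrame(rows, columns=list(TABLE_COLUMNS))


def frame_to_specimens(df: pd.DataFrame) -> list[Specimen]:
    missing_cols = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise TableParseError(0, f"missing columns: {missing_cols}")
    specimens: dict[str, dict] = {}
    seen: set[tuple[str, str]] = set()
    for i, row in enumerate(df.itertuples(index=False), start=1):
        sid = str(row.specimen_id)
        label = str(row.spiracle)
        if label not in SPIRACLE_LABELS:
            raise TableParseError(i, f"unknown spiracle label {label!r}")
        if (sid, label) in seen:
            raise TableParseError(i, f"duplicate (specimen, spiracle) ({sid}, {label})")
        seen.add((sid, label))
        for col in ("mass_g", "d_transverse_mm", "d_sagittal_mm", "depth_mm"):
            v = getattr(row, col)
            try:
                float(v)
            except (TypeError, ValueError):
                raise TableParseError(i, f"nonnumeric {col}: {v!r}") from None
            if pd.isna(v):
                raise TableParseError(i, f"nonnumeric {col}: {v!r}")
        entry = specimens.setdefault(
            sid,
            {
                "species": str(row.species),
                "sex": str(row.sex),
                "mass": float(row.mass_g),
                "spiracles": [],
            },
        )
        entry["spiracles"].append(
            SpiracleMeasurement(
                spiracle_label=label,
                d_transverse=float(row.d_transverse_mm),
                d_sagittal=float(row.d_sagittal_mm),
                depth=float(row.depth_mm),
            )
        )
    out = []
    for sid, entry in specimens.items():
        spir = sorted(
            entry["spiracles"], key=lambda m: SPIRACLE_LABELS.index(m.spiracle_label)
        )
        out.append(
            Specimen(
                specimen_id=sid,
                species=entry["species"],
                sex=entry["sex"],
                mass=entry["mass"],
                spiracles=tuple(spir),
            )
        )
    return out


def read_measurement_table(path: str | Path) -> list[Specimen]:
    """Read a long-form measurement CSV into Specimen objects."""
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    if df.empty:
        return []
    return frame_to_specimens(df)


def write_measurement_table(specimens: Iterable[Specimen], path: str | Path) -> None:
    # %.17g keeps read(write(x)) an exact identity on the float fields
    specimens_to_frame(specimens).to_csv(path, index=False, float_format="%.17g")
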