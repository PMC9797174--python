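"""Domain types and readers/writers for dose grids, structure sets, and
per-structure mean-dose summaries.

The comparison pipeline consumes two calculations of the same treatment
plan: a *reference* plan (e.g. produced by an automated planning service on
a standard beam model) and a *local* recalculation in the user's treatment
planning system.  This module holds the plumbing both sides share: a
regular axis-aligned dose grid in patient coordinates, planar-contour
structures, the machine parameters that distinguish local calculations
(dosimetric leaf gap, MLC transmission factor), and flat per-structure
mean-dose summaries that round-trip through CSV.

Two dialects are supported for volumetric inputs: DICOM RT Dose / RT
Structure Set (read via :mod:`pydicom`) and a plain JSON fixture format so
the whole pipeline can be exercised without clinical data.

Conventions
-----------
* Patient coordinates in millimetres; doses in gray.
* Grid axes are ordered ``(x, y, z)``; ``values[i, j, k]`` is the dose at
  the voxel whose *center* is ``origin + (i, j, k) * spacing``.
* ``NaN`` in a dose array is an "outside source support" sentinel written
  by resampling; readers reject non-finite input, and mean-dose
  computations skip the sentinel.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Polygon as _ShapelyPolygon

__all__ = [
    "DoseModelError",
    "DoseGrid",
    "Contour",
    "Structure",
    "StructureSet",
    "MachineParameters",
    "PlanDoseSummary",
    "read_dose_grid",
    "write_dose_grid_fixture",
    "read_structure_set",
    "write_structure_set_fixture",
    "read_summaries",
    "write_summaries",
]

log = logging.getLogger(__name__)

SUMMARY_COLUMNS = ["case_id", "source", "structure", "mean_dose_gy"]
SUMMARY_PARAM_COLUMNS = ["dlg_cm", "mlc_tf", "algorithm"]


class DoseModelError(ValueError):
    """Raised for malformed dose, structure or summary inputs."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DoseGrid:
    """Regular, axis-aligned 3-D dose field in patient space.

    Parameters
    ----------
    origin:
        Position (mm) of the center of voxel ``(0, 0, 0)``, axes (x, y, z).
    spacing:
        Voxel pitch per axis (mm); strictly positive.
    values:
        Dose (Gy) array of shape ``(nx, ny, nz)``.  NaN marks voxels with
        no support (only produced by resampling); negative or infinite
        doses are rejected.
    frame_id:
        Opaque frame-of-reference label used to guard against evaluating a
        structure set on the wrong grid.
    """

    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    values: np.ndarray
    frame_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))
        object.__setattr__(self, "spacing", tuple(float(v) for v in self.spacing))
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if len(self.origin) != 3 or len(self.spacing) != 3:
            raise DoseModelError("origin and spacing must have 3 components")
        if any(s <= 0 for s in self.spacing):
            raise DoseModelError(f"non-positive spacing: {self.spacing}")
        if vals.ndim != 3 or any(n < 1 for n in vals.shape):
            raise DoseModelError(f"dose array must be 3-D with shape >= 1 per axis, got {vals.shape}")
        finite = np.isfinite(vals)
        if np.any(np.isinf(vals)):
            raise DoseModelError("infinite dose values")
        if np.any(vals[finite] < 0):
            raise DoseModelError("negative dose values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(int(n) for n in self.values.shape)  # type: ignore[return-value]

    def axis_coords(self, axis: int) -> np.ndarray:
        """Voxel-center coordinates (mm) along one axis (0=x, 1=y, 2=z)."""
        n = self.shape[axis]
        return self.origin[axis] + self.spacing[axis] * np.arange(n)

    def with_values(self, values: np.ndarray) -> "DoseGrid":
        return replace(self, values=values)


@dataclass(frozen=True)
class Contour:
    """Closed planar polygon on a constant-z plane, vertices in mm."""

    z: float
    points: np.ndarray  # shape (n, 2) of (x, y)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "z", float(self.z))
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise DoseModelError("contour points must be an (n, 2) array")

    @property
    def n_vertices(self) -> int:
        return int(self.points.shape[0])

    def area(self) -> float:
        """Unsigned shoelace area (mm^2)."""
        x, y = self.points[:, 0], self.points[:, 1]
        return abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))) / 2.0

    def is_degenerate(self) -> bool:
        return self.n_vertices < 3 or self.area() == 0.0

    def is_simple(self) -> bool:
        """True if the polygon does not self-intersect."""
        if self.is_degenerate():
            return False
        return bool(_ShapelyPolygon(self.points).is_valid)


@dataclass(frozen=True)
class Structure:
    """Named structure made of one or more planar contours.

    Construction validates every polygon (>= 3 vertices, nonzero area,
    non-self-intersecting); readers drop degenerate polygons *before*
    constructing the structure, with a warning.
    """

    name: str
    contours: tuple[Contour, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "contours", tuple(self.contours))
        if not self.name:
            raise DoseModelError("structure name must be nonempty")
        if not self.contours:
            raise DoseModelError(f"structure {self.name!r} has no contours")
        for c in self.contours:
            if c.is_degenerate():
                raise DoseModelError(
                    f"structure {self.name!r} has a degenerate polygon "
                    f"({c.n_vertices} vertices, area {c.area():g})"
                )
            if not c.is_simple():
                raise DoseModelError(f"structure {self.name!r} has a self-intersecting polygon")


@dataclass(frozen=True)
class StructureSet:
    structures: tuple[Structure, ...]
    frame_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "structures", tuple(self.structures))
        names = [s.name for s in self.structures]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise DoseModelError(f"duplicate structure name: {sorted(dupes)}")

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.structures]

    def __getitem__(self, name: str) -> Structure:
        for s in self.structures:
            if s.name == name:
                return s
        raise KeyError(name)


@dataclass(frozen=True)
class MachineParameters:
    """Beam-model parameters of a local dose calculation.

    dlg_cm : dosimetric leaf gap (cm), in (0, 1).
    mlc_tf : MLC transmission factor (dimensionless), in (0, 0.1).
    algorithm : free-text dose-algorithm label (e.g. "AAA", "Acuros", "CCC").
    """

    dlg_cm: float
    mlc_tf: float
    algorithm: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "dlg_cm", float(self.dlg_cm))
        object.__setattr__(self, "mlc_tf", float(self.mlc_tf))
        if not (0.0 < self.dlg_cm < 1.0):
            raise DoseModelError(f"dlg_cm must lie in (0, 1) cm, got {self.dlg_cm}")
        if not (0.0 < self.mlc_tf < 0.1):
            raise DoseModelError(f"mlc_tf must lie in (0, 0.1), got {self.mlc_tf}")


@dataclass(frozen=True)
class PlanDoseSummary:
    """Per-structure mean doses for one calculation of one case."""

    case_id: str
    source: str  # "reference" | "local"
    mean_dose_by_structure: Mapping[str, float]
    params: MachineParameters | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean_dose_by_structure", dict(self.mean_dose_by_structure))
        if self.source not in ("reference", "local"):
            raise DoseModelError(f"source must be 'reference' or 'local', got {self.source!r}")
        for name, dose in self.mean_dose_by_structure.items():
            if not name:
                raise DoseModelError("empty structure name in summary")
            if not np.isfinite(dose) or dose < 0:
                raise DoseModelError(f"invalid mean dose {dose!r} for structure {name!r}")


# ---------------------------------------------------------------------------
# dose-grid IO
# ---------------------------------------------------------------------------


def read_dose_grid(path: str | Path, dialect: str = "fixture") -> DoseGrid:
    """Read a dose grid in Gy from a DICOM RT Dose file or a JSON fixture.

    The fixture dialect is a JSON object with keys ``origin``, ``spacing``,
    ``shape`` (each 3 numbers, axes x/y/z) and ``values`` (flat list in C
    order over that shape), plus optional ``frame_id``.
    """
    path = Path(path)
    if not path.exists():
        raise DoseModelError(f"no such file: {path}")
    if dialect == "fixture":
        return _read_fixture_grid(path)
    if dialect == "dicom-rtdose":
        return _read_dicom_dose(path)
    raise DoseModelError(f"unknown dose dialect: {dialect!r}")


def _read_fixture_grid(path: Path) -> DoseGrid:
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise DoseModelError(f"unreadable fixture grid {path}: {exc}") from exc
    for key in ("origin", "spacing", "shape", "values"):
        if key not in doc:
            raise DoseModelError(f"fixture grid missing field {key!r}")
    shape = tuple(int(n) for n in doc["shape"])
    values = np.asarray(doc["values"], dtype=float)
    if values.size != int(np.prod(shape)):
        raise DoseModelError(
            f"fixture grid value count {values.size} does not match shape {shape}"
        )
    if not np.all(np.isfinite(values)):
        raise DoseModelError("fixture grid contains non-finite dose values")
    return DoseGrid(
        origin=tuple(doc["origin"]),
        spacing=tuple(doc["spacing"]),
        values=values.reshape(shape),
        frame_id=str(doc.get("frame_id", "")),
    )


def write_dose_grid_fixture(grid: DoseGrid, path: str | Path) -> None:
    doc = {
        "origin": list(grid.origin),
        "spacing": list(grid.spacing),
        "shape": list(grid.shape),
        "frame_id": grid.frame_id,
        "values": [float(v) for v in grid.values.ravel()],
    }
    Path(path).write_text(json.dumps(doc))


_AXIAL_ORIENTATION = np.array([1.0, 0.0, 0.0, 0.0, 1.0, 0.0])


def _read_dicom_dose(path: Path) -> DoseGrid:
    import pydicom

    try:
        ds = pydicom.dcmread(path)
    except Exception as exc:  # pydicom raises several flavors
        raise DoseModelError(f"unreadable DICOM file {path}: {exc}") from exc
    for tag in ("ImagePositionPatient", "PixelSpacing"):
        if getattr(ds, tag, None) is None:
            raise DoseModelError(f"DICOM RT Dose missing geometry tag {tag}")
    orient = getattr(ds, "ImageOrientationPatient", None)
    if orient is not None and not np.allclose(np.asarray(orient, float), _AXIAL_ORIENTATION):
        raise DoseModelError(
            "oblique ImageOrientationPatient not supported; grid must be axis-aligned"
        )
    scaling = float(getattr(ds, "DoseGridScaling", 1.0))
    raw = ds.pixel_array  # (frames, rows, cols) == (z, y, x)
    if raw.ndim == 2:
        raw = raw[np.newaxis, ...]
    ipp = [float(v) for v in ds.ImagePositionPatient]
    dy, dx = (float(v) for v in ds.PixelSpacing)  # PixelSpacing is (row, col)
    offsets = getattr(ds, "GridFrameOffsetVector", None)
    if offsets is not None and len(offsets) > 1:
        offs = np.asarray([float(v) for v in offsets])
        diffs = np.diff(offs)
        if not np.allclose(diffs, diffs[0], rtol=1e-6, atol=1e-6):
            raise DoseModelError("non-uniform slice spacing in GridFrameOffsetVector")
        dz = float(diffs[0])
        z0 = ipp[2] + float(offs[0])
    else:
        dz = float(getattr(ds, "SliceThickness", 0) or 0) or 1.0
        z0 = ipp[2]
    if dz <= 0:
        raise DoseModelError("non-positive slice spacing in GridFrameOffsetVector")
    values = (raw.astype(float) * scaling).transpose(2, 1, 0)  # -> (x, y, z)
    frame = str(getattr(ds, "FrameOfReferenceUID", ""))
    return DoseGrid(origin=(ipp[0], ipp[1], z0), spacing=(dx, dy, dz), values=values, frame_id=frame)


# ---------------------------------------------------------------------------
# structure-set IO
# ---------------------------------------------------------------------------


def read_structure_set(path: str | Path, dialect: str = "fixture") -> StructureSet:
    """Read named planar-contour structures in patient coordinates (mm).

    Degenerate polygons (< 3 vertices or zero area) are dropped with a
    logged warning; a structure whose polygons are all degenerate is
    dropped entirely.  An input yielding no usable structures is an error,
    as are duplicate structure names.
    """
    path = Path(path)
    if not path.exists():
        raise DoseModelError(f"no such file: {path}")
    if dialect == "fixture":
        raw = _read_fixture_structures(path)
    elif dialect == "dicom-rtstruct":
        raw = _read_dicom_structures(path)
    else:
        raise DoseModelError(f"unknown structure dialect: {dialect!r}")
    frame_id, items = raw
    structures: list[Structure] = []
    for name, contours in items:
        kept = []
        for c in contours:
            if c.is_degenerate():
                log.warning("dropping degenerate polygon (%d vertices) in structure %r", c.n_vertices, name)
                continue
            kept.append(c)
        if not kept:
            log.warning("structure %r has no usable polygons; dropped", name)
            continue
        structures.append(Structure(name=name, contours=tuple(kept)))
    if not structures:
        raise DoseModelError(f"no usable structures in {path}")
    return StructureSet(structures=tuple(structures), frame_id=frame_id)


def _read_fixture_structures(path: Path) -> tuple[str, list[tuple[str, list[Contour]]]]:
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise DoseModelError(f"unreadable fixture structure set {path}: {exc}") from exc
    if "structures" not in doc:
        raise DoseModelError("fixture structure set missing field 'structures'")
    items: list[tuple[str, list[Contour]]] = []
    for s in doc["structures"]:
        contours = [Contour(z=c["z"], points=np.asarray(c["points"], float)) for c in s.get("contours", [])]
        items.append((str(s.get("name", "")), contours))
    return str(doc.get("frame_id", "")), items


def write_structure_set_fixture(ss: StructureSet, path: str | Path) -> None:
    doc = {
        "frame_id": ss.frame_id,
        "structures": [
            {
                "name": s.name,
                "contours": [{"z": c.z, "points": c.points.tolist()} for c in s.contours],
            }
            for s in ss.structures
        ],
    }
    Path(path).write_text(json.dumps(doc))


def _read_dicom_structures(path: Path) -> tuple[str, list[tuple[str, list[Contour]]]]:
    import pydicom

    try:
        ds = pydicom.dcmread(path)
    except Exception as exc:
        raise DoseModelError(f"unreadable DICOM file {path}: {exc}") from exc
    roi_names = {
        int(roi.ROINumber): str(roi.ROIName) for roi in getattr(ds, "StructureSetROISequence", [])
    }
    frame = ""
    for roi in getattr(ds, "StructureSetROISequence", []):
        frame = str(getattr(roi, "ReferencedFrameOfReferenceUID", "")) or frame
    items: list[tuple[str, list[Contour]]] = []
    for rc in getattr(ds, "ROIContourSequence", []):
        name = roi_names.get(int(rc.ReferencedROINumber), f"ROI{rc.ReferencedROINumber}")
        contours: list[Contour] = []
        for cs in getattr(rc, "ContourSequence", []):
            data = np.asarray([float(v) for v in cs.ContourData]).reshape(-1, 3)
            if data.size == 0:
                continue
            contours.append(Contour(z=float(np.mean(data[:, 2])), points=data[:, :2]))
        items.append((name, contours))
    if not items:
        raise DoseModelError(f"no structures in DICOM structure set {path}")
    return frame, items


# ---------------------------------------------------------------------------
# summary-table IO
# ---------------------------------------------------------------------------


def read_summaries(path: str | Path) -> list[PlanDoseSummary]:
    """Read per-structure mean-dose summaries from CSV.

    Required columns: case_id, source, structure, mean_dose_gy; optional
    dlg_cm, mlc_tf, algorithm (constant within a (case_id, source) group).
    One :class:`PlanDoseSummary` per (case_id, source), in file order.
    """
    df = pd.read_csv(path)
    missing = [c for c in SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise DoseModelError(f"summary CSV missing columns: {missing}")
    dup = df.duplicated(subset=["case_id", "source", "structure"])
    if dup.any():
        rows = df.loc[dup, ["case_id", "source", "structure"]].iloc[0].tolist()
        raise DoseModelError(f"duplicate (case_id, source, structure) row: {rows}")
    if (df["mean_dose_gy"] < 0).any():
        raise DoseModelError("negative mean_dose_gy in summary CSV")
    has_params = all(c in df.columns for c in ("dlg_cm", "mlc_tf"))
    summaries: list[PlanDoseSummary] = []
    for (case_id, source), grp in df.groupby(["case_id", "source"], sort=False):
        params = None
        if has_params and grp["dlg_cm"].notna().all() and grp["mlc_tf"].notna().all():
            dlg = grp["dlg_cm"].unique()
            tf = grp["mlc_tf"].unique()
            if len(dlg) > 1 or len(tf) > 1:
                raise DoseModelError(
                    f"inconsistent machine parameters within ({case_id}, {source})"
                )
            algo = ""
            if "algorithm" in grp.columns and grp["algorithm"].notna().any():
                algo = str(grp["algorithm"].dropna().iloc[0])
            params = MachineParameters(dlg_cm=float(dlg[0]), mlc_tf=float(tf[0]), algorithm=algo)
        summaries.append(
            PlanDoseSummary(
                case_id=str(case_id),
                source=str(source),
                mean_dose_by_structure=dict(
                    zip(grp["structure"].astype(str), grp["mean_dose_gy"].astype(float))
                ),
                params=params,
            )
        )
    return summaries


def write_summaries(summaries: Iterable[PlanDoseSummary], path: str | Path) -> None:
    """Write summaries to CSV; lossless round-trip with :func:`read_summaries`."""
    rows = []
    any_params = False
    for s in summaries:
        for name, dose in s.mean_dose_by_structure.items():
            row = {
                "case_id": s.case_id,
                "source": s.source,
                "structure": name,
                "mean_dose_gy": dose,
            }
            if s.params is not None:
                any_params = True
                row["dlg_cm"] = s.params.dlg_cm
                row["mlc_tf"] = s.params.mlc_tf
                row["algorithm"] = s.params.algorithm
            rows.append(row)
    cols = SUMMARY_COLUMNS + (SUMMARY_PARAM_COLUMNS if any_params else [])
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
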