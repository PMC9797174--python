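"""Per-structure mean doses and percent mean-dose differences.

The monitored statistic of the whole pipeline is, per structure *s* of one
case,

    d(s) = 100 * (meanDose_local(s) - meanDose_reference(s)) / meanDose_reference(s)  [%]

i.e. the percent mean-dose difference of the local recalculation relative
to the reference plan.  This module computes the per-plan mean doses from a
dose grid and a structure set (center-in-polygon voxel masks, even-odd
rule) and assembles the per-case differences.

Geometry policy: the reference plan's grid is authoritative.  When the two
calculations live on different grids, the local grid is resampled onto the
reference geometry (trilinear) before masking, so each structure uses a
single voxel mask per case and any difference is attributable to dose, not
to discretization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from matplotlib.path import Path as _MplPath
from scipy import ndimage

from .dose_model import (
    DoseGrid,
    MachineParameters,
    PlanDoseSummary,
    Structure,
    StructureSet,
)

__all__ = [
    "DoseMetricsError",
    "VoxelMask",
    "DoseComparison",
    "rasterize_structure",
    "resample_dose",
    "mean_dose",
    "summarize_plan",
    "percent_difference",
    "write_comparisons",
    "read_comparisons",
]

log = logging.getLogger(__name__)

#: Reference mean doses at or below this level (Gy) are excluded from
#: percent differences to avoid near-zero denominators.
DEFAULT_DOSE_FLOOR_GY = 0.01

COMPARISON_COLUMNS = ["case_id", "structure", "pct_diff"]
COMPARISON_PARAM_COLUMNS = ["dlg_cm", "mlc_tf", "algorithm"]

_PLANE_TOL = 1e-9


class DoseMetricsError(ValueError):
    pass


@dataclass(frozen=True)
class VoxelMask:
    """Boolean inclusion mask over the voxels of a companion grid."""

    shape: tuple[int, int, int]
    included: np.ndarray

    def __post_init__(self) -> None:
        inc = np.asarray(self.included, dtype=bool)
        object.__setattr__(self, "included", inc)
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        if inc.shape != self.shape:
            raise DoseMetricsError(f"mask array shape {inc.shape} != declared shape {self.shape}")

    @property
    def count(self) -> int:
        return int(self.included.sum())


@dataclass(frozen=True)
class DoseComparison:
    """Per-structure percent mean-dose differences for one case.

    Only structures present in both plans appear.  Values are percent,
    relative to the reference plan; ``params`` carries the local plan's
    machine parameters when known.
    """

    case_id: str
    pct_diff_by_structure: Mapping[str, float]
    params: MachineParameters | None = None

    def __post_init__(self) -> None:
        d = dict(self.pct_diff_by_structure)
        object.__setattr__(self, "pct_diff_by_structure", d)
        for name, v in d.items():
            if not np.isfinite(v):
                raise DoseMetricsError(f"non-finite percent difference for {name!r}")


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------


def rasterize_structure(structure: Structure, grid: DoseGrid) -> VoxelMask:
    """Voxel mask of a planar-contour structure on a grid.

    A voxel is included iff its center lies within half the grid's slice
    pitch of a contour plane (along z) and inside the plane's polygon(s)
    by the even-odd rule.  Multiple polygons on one plane combine by
    even-odd, which supports ring structures with holes.  No
    partial-volume weighting is applied.
    """
    nx, ny, nz = grid.shape
    xs, ys, zs = (grid.axis_coords(a) for a in range(3))
    dz = grid.spacing[2]

    # group contours by plane (exact z up to a small tolerance)
    planes: dict[float, list[np.ndarray]] = {}
    for c in structure.contours:
        key = next((z for z in planes if abs(z - c.z) <= _PLANE_TOL), c.z)
        planes.setdefault(key, []).append(c.points)

    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    centers = np.column_stack([gx.ravel(), gy.ravel()])

    included = np.zeros((nx, ny, nz), dtype=bool)
    for z_plane, polys in planes.items():
        ksel = np.abs(zs - z_plane) <= 0.5 * dz + _PLANE_TOL
        if not ksel.any():
            continue
        plane_mask = np.zeros(nx * ny, dtype=bool)
        for pts in polys:
            # Path(..., closed=True) needs the first vertex repeated
            ring = np.vstack([pts, pts[:1]])
            plane_mask ^= _MplPath(ring, closed=True).contains_points(centers)
        included[:, :, ksel] |= plane_mask.reshape(nx, ny)[:, :, np.newaxis]

    if not included.any():
        raise DoseMetricsError(f"empty mask for structure {structure.name!r}")
    return VoxelMask(shape=(nx, ny, nz), included=included)


# ---------------------------------------------------------------------------
# resampling and means
# ---------------------------------------------------------------------------


def resample_dose(
    grid: DoseGrid,
    origin: Sequence[float],
    spacing: Sequence[float],
    shape: Sequence[int],
) -> DoseGrid:
    """Trilinear resample of a dose grid onto a target geometry.

    Target voxel centers outside the source grid's support receive NaN,
    which downstream mean-dose computations exclude.  An identity target
    geometry returns the values bitwise unchanged.
    """
    origin = tuple(float(v) for v in origin)
    spacing = tuple(float(v) for v in spacing)
    shape = tuple(int(n) for n in shape)
    if any(s <= 0 for s in spacing) or any(n < 1 for n in shape):
        raise DoseMetricsError("invalid target geometry")
    if origin == grid.origin and spacing == grid.spacing and shape == grid.shape:
        return DoseGrid(origin=origin, spacing=spacing, values=grid.values.copy(), frame_id=grid.frame_id)

    # target voxel centers in source index coordinates
    idx = [
        (origin[a] + spacing[a] * np.arange(shape[a]) - grid.origin[a]) / grid.spacing[a]
        for a in range(3)
    ]
    ix, iy, iz = np.meshgrid(*idx, indexing="ij")
    values = ndimage.map_coordinates(
        grid.values, [ix, iy, iz], order=1, mode="constant", cval=np.nan
    )
    # any contribution from the NaN padding marks the point unsupported
    if not np.any(np.isfinite(values)):
        raise DoseMetricsError("target geometry entirely outside source grid support")
    return DoseGrid(origin=origin, spacing=spacing, values=values, frame_id=grid.frame_id)


def mean_dose(grid: DoseGrid, mask: VoxelMask) -> float:
    """Unweighted arithmetic mean dose (Gy) over included voxel centers.

    NaN voxels (the outside-support sentinel left by resampling) are
    excluded from the mean; a mask whose included voxels are all
    unsupported is an error.
    """
    if mask.shape != grid.shape:
        raise DoseMetricsError(f"mask shape {mask.shape} != grid shape {grid.shape}")
    if mask.count == 0:
        raise DoseMetricsError("empty mask")
    sub = grid.values[mask.included]
    finite = sub[np.isfinite(sub)]
    if finite.size == 0:
        raise DoseMetricsError("mask covers only unsupported (resampled-outside) voxels")
    return float(finite.mean())


def summarize_plan(
    grid: DoseGrid,
    ss: StructureSet,
    case_id: str,
    source: str,
    params: MachineParameters | None = None,
) -> PlanDoseSummary:
    """Mean dose of every structure of a set on one grid.

    Structures that produce an empty mask (e.g. entirely outside the grid)
    are omitted from the summary with a warning rather than failing the
    whole plan; a plan in which *no* structure yields a mean is an error.
    """
    if grid.frame_id and ss.frame_id and grid.frame_id != ss.frame_id:
        raise DoseMetricsError(
            f"frame-of-reference mismatch: grid {grid.frame_id!r} vs structures {ss.frame_id!r}"
        )
    means: dict[str, float] = {}
    for s in ss.structures:
        try:
            m = rasterize_structure(s, grid)
        except DoseMetricsError:
            log.warning("structure %r has no voxels on the grid; omitted from summary", s.name)
            continue
        means[s.name] = mean_dose(grid, m)
        log.debug("structure %r: %d voxels, mean %.4f Gy", s.name, m.count, means[s.name])
    if not means:
        raise DoseMetricsError("no structure yields a mean dose on this grid")
    return PlanDoseSummary(case_id=case_id, source=source, mean_dose_by_structure=means, params=params)


def percent_difference(
    local: PlanDoseSummary,
    reference: PlanDoseSummary,
    dose_floor: float = DEFAULT_DOSE_FLOOR_GY,
) -> DoseComparison:
    """Percent mean-dose difference of a local plan relative to the reference.

    For each structure present in both summaries,
    ``100 * (local - reference) / reference``; structures whose reference
    mean dose is at or below ``dose_floor`` (Gy) are skipped with a
    warning to keep the ratio numerically meaningful.
    """
    if local.case_id != reference.case_id:
        raise DoseMetricsError(
            f"case mismatch: local {local.case_id!r} vs reference {reference.case_id!r}"
        )
    shared = [s for s in local.mean_dose_by_structure if s in reference.mean_dose_by_structure]
    if not shared:
        raise DoseMetricsError(f"no shared structures for case {local.case_id!r}")
    diffs: dict[str, float] = {}
    for s in shared:
        ref = reference.mean_dose_by_structure[s]
        if ref <= dose_floor:
            log.warning(
                "case %s structure %r: reference mean dose %.4g Gy at/below floor %.4g Gy; skipped",
                local.case_id, s, ref, dose_floor,
            )
            continue
        diffs[s] = 100.0 * (local.mean_dose_by_structure[s] - ref) / ref
    if not diffs:
        raise DoseMetricsError(
            f"all shared structures below dose floor for case {local.case_id!r}"
        )
    return DoseComparison(case_id=local.case_id, pct_diff_by_structure=diffs, params=local.params)


# ---------------------------------------------------------------------------
# comparison-table IO
# ---------------------------------------------------------------------------


def write_comparisons(comparisons: Iterable[DoseComparison], path: str | Path) -> None:
    """Write comparisons as CSV (case_id, structure, pct_diff[, dlg_cm, mlc_tf, algorithm])."""
    rows = []
    any_params = False
    for c in comparisons:
        for name, v in c.pct_diff_by_structure.items():
            row = {"case_id": c.case_id, "structure": name, "pct_diff": v}
            if c.params is not None:
                any_params = True
                row["dlg_cm"] = c.params.dlg_cm
                row["mlc_tf"] = c.params.mlc_tf
                row["algorithm"] = c.params.algorithm
            rows.append(row)
    cols = COMPARISON_COLUMNS + (COMPARISON_PARAM_COLUMNS if any_params else [])
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_comparisons(path: str | Path) -> list[DoseComparison]:
    df = pd.read_csv(path)
    missing = [c for c in COMPARISON_COLUMNS if c not in df.columns]
    if missing:
        raise DoseMetricsError(f"comparison CSV missing columns: {missing}")
    has_params = all(c in df.columns for c in ("dlg_cm", "mlc_tf"))
    # in a crossed parameter sweep the same case recurs at several levels,
    # so the grouping key must include the parameter columns when present
    keys = ["case_id"] + (["dlg_cm", "mlc_tf"] if has_params else [])
    out: list[DoseComparison] = []
    for key, grp in df.groupby(keys, sort=False, dropna=False):
        case_id = key[0] if isinstance(key, tuple) else key
        params = None
        if has_params and grp["dlg_cm"].notna().all() and grp["mlc_tf"].notna().all():
            algo = ""
            if "algorithm" in grp.columns and grp["algorithm"].notna().any():
                algo = str(grp["algorithm"].dropna().iloc[0])
            params = MachineParameters(
                dlg_cm=float(grp["dlg_cm"].iloc[0]),
                mlc_tf=float(grp["mlc_tf"].iloc[0]),
                algorithm=algo,
            )
        out.append(
            DoseComparison(
                case_id=str(case_id),
                pct_diff_by_structure=dict(
                    zip(grp["structure"].astype(str), grp["pct_diff"].astype(float))
                ),
                params=params,
            )
        )
    return out
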