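"""Seeded synthetic cohorts with the statistical structure the method assumes.

The monitoring method models each structure's percent mean-dose difference
across a cohort as a structure-specific systematic offset plus independent
noise, with occasional gross outliers; a parameter sweep adds a linear
dependence of the offset on the swept machine parameter, anchored at the
parameter value where the local and reference calculations agree (the zero
crossing).  The generators here produce exactly that structure — nothing
more — so every downstream stage (comparison tables, control charts,
sensitivity fits) can be exercised and its parameter recovery verified
without clinical data.

Three generators:

* :func:`generate_cohort` — per-structure offsets + Gaussian (or
  Student-t) noise, with injected outliers, for chart construction.
* :func:`generate_sweep` — per-structure linear response
  ``slope * (level - crossing)`` + noise at each sweep level, annotated
  with machine parameters.
* :func:`generate_grid_fixture` — paired reference/local dose grids with
  an analytic dose law and rectangular structures, so mean doses and
  percent differences have closed-form expected values (a pure scale
  perturbation k gives exactly 100*(k-1) % for every structure).

Every generator is a pure function of its spec, including the seed.
Default specs mirror the study conditions the method was characterized
under: cohorts of 32 / 33 / 51 cases (head & neck, cervix, chest wall),
sweeps of 30 cases per level over DLG levels (0.1, 0.155, 0.17, 0.19,
0.23) cm or MLC-TF levels (0.0118, 0.0145, 0.0158, 0.0165), with the
reference machine at DLG 0.2 cm and MLC-TF 0.02.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .dose_model import Contour, DoseGrid, MachineParameters, Structure, StructureSet

__all__ = [
    "SyntheticError",
    "StructureEffect",
    "OutlierInjection",
    "CohortSpec",
    "SweepEffect",
    "SweepSpec",
    "generate_cohort",
    "generate_sweep",
    "generate_grid_fixture",
    "default_cohort_spec",
    "default_sweep_spec",
    "cohort_spec_from_dict",
    "sweep_spec_from_dict",
    "load_spec",
    "DEFAULT_DLG_LEVELS",
    "DEFAULT_MLC_TF_LEVELS",
    "REFERENCE_DLG_CM",
    "REFERENCE_MLC_TF",
]

from .dose_metrics import DoseComparison


class SyntheticError(ValueError):
    pass


#: Sweep levels used when characterizing parameter sensitivity.
DEFAULT_DLG_LEVELS = (0.1, 0.155, 0.17, 0.19, 0.23)
DEFAULT_MLC_TF_LEVELS = (0.0118, 0.0145, 0.0158, 0.0165)

#: Machine-parameter values of the reference calculation; the parameter
#: not being swept is held at these.
REFERENCE_DLG_CM = 0.2
REFERENCE_MLC_TF = 0.02


# ---------------------------------------------------------------------------
# cohort generator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StructureEffect:
    """One structure's systematic offset delta (%) and noise sigma (%)."""

    name: str
    offset_pct: float
    sigma_pct: float

    def __post_init__(self) -> None:
        if not self.name:
            raise SyntheticError("structure name must be nonempty")
        if self.sigma_pct < 0:
            raise SyntheticError(f"sigma_pct must be >= 0, got {self.sigma_pct}")


@dataclass(frozen=True)
class OutlierInjection:
    """Overwrite one (case, structure) cell with a fixed value (%)."""

    case_index: int
    structure: str
    value_pct: float


@dataclass(frozen=True)
class CohortSpec:
    structures: tuple[StructureEffect, ...]
    n_cases: int = 30
    seed: int = 0
    outliers: tuple[OutlierInjection, ...] = ()
    params: MachineParameters | None = None
    noise: str = "normal"  # "normal" | "t" (heavy-tail stress for the exclusion rule)
    t_df: float = 4.0
    case_prefix: str = "case"

    def __post_init__(self) -> None:
        object.__setattr__(self, "structures", tuple(self.structures))
        object.__setattr__(self, "outliers", tuple(self.outliers))
        if self.n_cases < 1:
            raise SyntheticError(f"n_cases must be >= 1, got {self.n_cases}")
        if not self.structures:
            raise SyntheticError("spec has no structures")
        if self.noise not in ("normal", "t"):
            raise SyntheticError(f"unknown noise model {self.noise!r}")
        names = [s.name for s in self.structures]
        if len(set(names)) != len(names):
            raise SyntheticError("duplicate structure names in spec")
        for o in self.outliers:
            if not (0 <= o.case_index < self.n_cases):
                raise SyntheticError(f"outlier case index {o.case_index} out of range")
            if o.structure not in names:
                raise SyntheticError(f"outlier names unknown structure {o.structure!r}")


def _noise_matrix(rng: np.random.Generator, n_cases: int, n_struct: int, noise: str, t_df: float) -> np.ndarray:
    if noise == "normal":
        return rng.standard_normal((n_cases, n_struct))
    return rng.standard_t(t_df, size=(n_cases, n_struct))


def generate_cohort(spec: CohortSpec) -> list[DoseComparison]:
    """Draw a seeded cohort: value(case, s) ~ Normal(delta_s, sigma_s^2).

    Outlier injections overwrite cells after sampling, so the rest of the
    cohort is unchanged by their presence.  Identical specs (including
    seed) produce identical output.
    """
    rng = np.random.default_rng(spec.seed)
    offsets = np.array([s.offset_pct for s in spec.structures])
    sigmas = np.array([s.sigma_pct for s in spec.structures])
    values = offsets + sigmas * _noise_matrix(rng, spec.n_cases, len(spec.structures), spec.noise, spec.t_df)
    name_idx = {s.name: j for j, s in enumerate(spec.structures)}
    for o in spec.outliers:
        values[o.case_index, name_idx[o.structure]] = o.value_pct
    return [
        DoseComparison(
            case_id=f"{spec.case_prefix}-{i + 1:04d}",
            pct_diff_by_structure={s.name: float(values[i, j]) for j, s in enumerate(spec.structures)},
            params=spec.params,
        )
        for i in range(spec.n_cases)
    ]


# ---------------------------------------------------------------------------
# sweep generator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SweepEffect:
    """One structure's linear response to the swept parameter.

    The response is anchored at its zero crossing:
    ``value = slope_pct_per_unit * (level - crossing) + noise``, so the
    structure reads 0 % exactly at ``crossing``.
    """

    name: str
    slope_pct_per_unit: float  # % per cm of DLG, or % per unit MLC-TF
    crossing: float
    sigma_pct: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.slope_pct_per_unit):
            raise SyntheticError("slope must be finite")
        if self.sigma_pct < 0:
            raise SyntheticError(f"sigma_pct must be >= 0, got {self.sigma_pct}")


@dataclass(frozen=True)
class SweepSpec:
    parameter: str  # "dlg_cm" | "mlc_tf"
    structures: tuple[SweepEffect, ...]
    levels: tuple[float, ...] = ()
    n_per_level: int = 30
    seed: int = 0
    held_constant: float | None = None
    algorithm: str = "AAA"
    layout: str = "crossed"  # "crossed": same plans at every level; "split": distinct plans
    outlier_structures: tuple[str, ...] = ()  # names given deliberately extreme crossings

    def __post_init__(self) -> None:
        object.__setattr__(self, "structures", tuple(self.structures))
        if self.parameter not in ("dlg_cm", "mlc_tf"):
            raise SyntheticError(f"unknown parameter {self.parameter!r}")
        levels = tuple(self.levels) or (
            DEFAULT_DLG_LEVELS if self.parameter == "dlg_cm" else DEFAULT_MLC_TF_LEVELS
        )
        object.__setattr__(self, "levels", tuple(float(v) for v in levels))
        if len(set(self.levels)) < 3:
            raise SyntheticError("need >= 3 distinct sweep levels")
        if self.held_constant is None:
            object.__setattr__(
                self,
                "held_constant",
                REFERENCE_MLC_TF if self.parameter == "dlg_cm" else REFERENCE_DLG_CM,
            )
        if self.n_per_level < 1:
            raise SyntheticError("n_per_level must be >= 1")
        if self.layout not in ("crossed", "split"):
            raise SyntheticError(f"unknown sweep layout {self.layout!r}")
        if not self.structures:
            raise SyntheticError("spec has no structures")
        object.__setattr__(self, "outlier_structures", tuple(self.outlier_structures))
        names = {s.name for s in self.structures}
        for n in self.outlier_structures:
            if n not in names:
                raise SyntheticError(f"outlier structure {n!r} not in spec structures")

    def machine_params(self, level: float) -> MachineParameters:
        if self.parameter == "dlg_cm":
            return MachineParameters(dlg_cm=level, mlc_tf=self.held_constant, algorithm=self.algorithm)
        return MachineParameters(dlg_cm=self.held_constant, mlc_tf=level, algorithm=self.algorithm)


def generate_sweep(spec: SweepSpec) -> list[DoseComparison]:
    """Draw a seeded parameter sweep, annotated with machine parameters.

    value(case, s, level) ~ Normal(slope_s * (level - crossing_s), sigma_s^2).
    Layout "crossed" reuses the same plan identifiers at every level (one
    cohort recalculated per level); "split" gives each level its own
    plans.  Levels are emitted in ascending order.
    """
    rng = np.random.default_rng(spec.seed)
    slopes = np.array([s.slope_pct_per_unit for s in spec.structures])
    crossings = np.array([s.crossing for s in spec.structures])
    sigmas = np.array([s.sigma_pct for s in spec.structures])
    out: list[DoseComparison] = []
    for li, level in enumerate(sorted(spec.levels)):
        params = spec.machine_params(level)
        mean = slopes * (level - crossings)
        noise = sigmas * rng.standard_normal((spec.n_per_level, len(spec.structures)))
        for i in range(spec.n_per_level):
            if spec.layout == "crossed":
                case_id = f"plan-{i + 1:04d}"
            else:
                case_id = f"plan-L{li + 1}-{i + 1:04d}"
            out.append(
                DoseComparison(
                    case_id=case_id,
                    pct_diff_by_structure={
                        s.name: float(mean[j] + noise[i, j]) for j, s in enumerate(spec.structures)
                    },
                    params=params,
                )
            )
    return out


# ---------------------------------------------------------------------------
# paired dose-grid fixtures
# ---------------------------------------------------------------------------


def generate_grid_fixture(
    origin: Sequence[float],
    spacing: Sequence[float],
    shape: Sequence[int],
    boxes: Mapping[str, tuple[tuple[float, float], tuple[float, float], tuple[float, float]]],
    dose_law: tuple = ("constant", 50.0),
    scale: float = 1.0,
    offset_gy: float = 0.0,
    frame_id: str = "fixture",
) -> tuple[DoseGrid, DoseGrid, StructureSet]:
    """Paired (reference, local) grids plus rectangular structures.

    ``dose_law`` is ``("constant", c)`` or ``("linear", g, c)`` meaning
    ``g * x + c`` Gy with x in mm; the local grid is
    ``scale * reference + offset_gy``.  Rectangular structures make mean
    doses analytic: under a pure scale perturbation the percent difference
    is exactly ``100 * (scale - 1)`` for every structure, and under the
    linear law a box's mean dose equals the dose at its voxel-center
    centroid.
    """
    origin = tuple(float(v) for v in origin)
    spacing = tuple(float(v) for v in spacing)
    shape = tuple(int(n) for n in shape)
    xs = origin[0] + spacing[0] * np.arange(shape[0])
    zs = origin[2] + spacing[2] * np.arange(shape[2])
    kind = dose_law[0]
    if kind == "constant":
        ref_vals = np.full(shape, float(dose_law[1]))
    elif kind == "linear":
        g, c = float(dose_law[1]), float(dose_law[2])
        ref_vals = np.broadcast_to((g * xs + c)[:, None, None], shape).copy()
    else:
        raise SyntheticError(f"unknown dose law {kind!r}")
    if np.any(ref_vals < 0):
        raise SyntheticError("dose law produces negative reference doses")
    local_vals = scale * ref_vals + offset_gy
    if np.any(local_vals < 0):
        raise SyntheticError("perturbation produces negative local doses")

    structures: list[Structure] = []
    lo = np.array(origin)
    hi = lo + (np.array(shape) - 1) * np.array(spacing)
    for name, ((x0, x1), (y0, y1), (z0, z1)) in boxes.items():
        if x0 < lo[0] - spacing[0] / 2 or x1 > hi[0] + spacing[0] / 2 \
                or y0 < lo[1] - spacing[1] / 2 or y1 > hi[1] + spacing[1] / 2:
            raise SyntheticError(f"structure {name!r} extends outside the grid")
        contours = tuple(
            Contour(z=float(z), points=np.array([[x0, y0], [x1, y0], [x1, y1], [x0, y1]]))
            for z in zs
            if z0 <= z <= z1
        )
        if not contours:
            raise SyntheticError(f"structure {name!r} spans no grid planes")
        structures.append(Structure(name=name, contours=contours))

    ref = DoseGrid(origin=origin, spacing=spacing, values=ref_vals, frame_id=frame_id)
    local = DoseGrid(origin=origin, spacing=spacing, values=local_vals, frame_id=frame_id)
    return ref, local, StructureSet(structures=tuple(structures), frame_id=frame_id)


# ---------------------------------------------------------------------------
# default study-condition specs
# ---------------------------------------------------------------------------

# Per-site offsets (%) and noise sigmas (%) typical of comparing a local
# recalculation against the reference autoplan; sigmas correspond to
# one-sixth of the expected control-limit range.
_SITE_EFFECTS: dict[str, tuple[int, tuple[tuple[str, float, float], ...]]] = {
    "head_neck": (
        32,
        (
            ("Brain", -0.21, 0.075),
            ("Larynx", 2.28, 0.397),
            ("Mandible", 1.11, 0.303),
            ("PTV1", 2.29, 0.432),
            ("PTV2", 2.18, 1.123),
            ("Left parotid", 0.49, 0.368),
        ),
    ),
    "cervix": (
        33,
        (
            ("Left femoral head", -1.78, 0.335),
            ("Right femoral head", -1.79, 0.340),
            ("L4", -2.21, 0.887),
            ("L5", -2.59, 0.282),
        ),
    ),
    "chest_wall": (
        51,
        (
            ("Clinical chest wall", 1.51, 1.053),
            ("Heart", -0.17, 0.172),
            ("Left lung", -0.40, 0.420),
            ("Right lung", -0.34, 0.452),
            ("Spinal canal", -0.17, 0.113),
            ("Sternum", 0.61, 0.390),
        ),
    ),
}

# Default sweep responses: slope per unit parameter and the crossing where
# the local calculation matches the reference.  Small optic structures get
# implausibly large DLG crossings to exercise the outlier rule.
_SWEEP_EFFECTS: dict[str, tuple[tuple[str, float, float, float], ...]] = {
    "dlg_cm": (
        ("Brain", 1.9, 0.2, 0.10),
        ("Larynx", 24.5, 0.2, 0.30),
        ("Mandible", 18.7, 0.2, 0.35),
        ("PTV1", 31.7, 0.2, 0.30),
        ("PTV2", 22.5, 0.2, 0.60),
        ("Left parotid", 17.4, 0.2, 0.30),
        ("Eye", 3.0, 0.80, 0.30),
        ("Lens", 2.5, 0.90, 0.30),
        ("Optic nerve", 3.5, 0.75, 0.30),
    ),
    "mlc_tf": (
        ("Brain", 42.0, 0.02, 0.10),
        ("Larynx", 246.0, 0.02, 0.30),
        ("Mandible", 228.0, 0.02, 0.35),
        ("PTV1", 189.0, 0.02, 0.30),
        ("PTV2", 185.0, 0.02, 0.60),
        ("Left parotid", 254.0, 0.02, 0.30),
        ("Eye", 30.0, 0.08, 0.30),
        ("Lens", 25.0, 0.09, 0.30),
        ("Optic nerve", 35.0, 0.075, 0.30),
    ),
}

_SWEEP_OUTLIER_NAMES = ("Eye", "Lens", "Optic nerve")


def default_cohort_spec(site: str = "head_neck", seed: int = 0) -> CohortSpec:
    """Study-condition cohort spec for a site: head_neck (32 cases),
    cervix (33) or chest_wall (51)."""
    if site not in _SITE_EFFECTS:
        raise SyntheticError(f"unknown site {site!r}; expected one of {sorted(_SITE_EFFECTS)}")
    n, effects = _SITE_EFFECTS[site]
    return CohortSpec(
        structures=tuple(StructureEffect(n_, d, s) for n_, d, s in effects),
        n_cases=n,
        seed=seed,
        params=MachineParameters(dlg_cm=REFERENCE_DLG_CM, mlc_tf=REFERENCE_MLC_TF, algorithm="AAA"),
        case_prefix=site,
    )


def default_sweep_spec(parameter: str = "dlg_cm", seed: int = 0, include_outliers: bool = True) -> SweepSpec:
    """Study-condition sweep spec: 30 cases per level over the default
    levels, responses crossing zero at the reference machine values, plus
    (optionally) small optic structures with implausible crossings."""
    if parameter not in _SWEEP_EFFECTS:
        raise SyntheticError(f"unknown parameter {parameter!r}")
    effects = _SWEEP_EFFECTS[parameter]
    if not include_outliers:
        effects = tuple(e for e in effects if e[0] not in _SWEEP_OUTLIER_NAMES)
    return SweepSpec(
        parameter=parameter,
        structures=tuple(SweepEffect(n, sl, cr, sg) for n, sl, cr, sg in effects),
        n_per_level=30,
        seed=seed,
        outlier_structures=_SWEEP_OUTLIER_NAMES if include_outliers else (),
    )


# ---------------------------------------------------------------------------
# spec files
# ---------------------------------------------------------------------------


def _require_keys(doc: Mapping, allowed: set[str], kind: str) -> None:
    unknown = set(doc) - allowed
    if unknown:
        raise SyntheticError(f"unknown {kind} spec fields: {sorted(unknown)}")


def cohort_spec_from_dict(doc: Mapping) -> CohortSpec:
    _require_keys(
        dict(doc),
        {"kind", "structures", "n_cases", "seed", "outliers", "params", "noise", "t_df", "case_prefix"},
        "cohort",
    )
    structures = tuple(
        StructureEffect(s["name"], float(s["offset_pct"]), float(s["sigma_pct"]))
        for s in doc["structures"]
    )
    outliers = tuple(
        OutlierInjection(int(o["case_index"]), str(o["structure"]), float(o["value_pct"]))
        for o in doc.get("outliers", [])
    )
    params = None
    if doc.get("params"):
        params = MachineParameters(**doc["params"])
    return CohortSpec(
        structures=structures,
        n_cases=int(doc.get("n_cases", 30)),
        seed=int(doc.get("seed", 0)),
        outliers=outliers,
        params=params,
        noise=str(doc.get("noise", "normal")),
        t_df=float(doc.get("t_df", 4.0)),
        case_prefix=str(doc.get("case_prefix", "case")),
    )


def sweep_spec_from_dict(doc: Mapping) -> SweepSpec:
    _require_keys(
        dict(doc),
        {"kind", "parameter", "structures", "levels", "n_per_level", "seed",
         "held_constant", "algorithm", "layout", "outlier_structures"},
        "sweep",
    )
    structures = tuple(
        SweepEffect(
            s["name"], float(s["slope_pct_per_unit"]), float(s["crossing"]), float(s["sigma_pct"])
        )
        for s in doc["structures"]
    )
    return SweepSpec(
        parameter=str(doc["parameter"]),
        structures=structures,
        levels=tuple(float(v) for v in doc.get("levels", ())),
        n_per_level=int(doc.get("n_per_level", 30)),
        seed=int(doc.get("seed", 0)),
        held_constant=(None if doc.get("held_constant") is None else float(doc["held_constant"])),
        algorithm=str(doc.get("algorithm", "AAA")),
        layout=str(doc.get("layout", "crossed")),
        outlier_structures=tuple(doc.get("outlier_structures", ())),
    )


def load_spec(path: str | Path) -> CohortSpec | SweepSpec:
    """Load a generator spec from YAML or JSON; ``kind`` selects the type."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        import yaml

        doc = yaml.safe_load(text)
    else:
        doc = json.loads(text)
    if not isinstance(doc, Mapping):
        raise SyntheticError("spec file must contain a mapping")
    kind = doc.get("kind")
    if kind == "cohort":
        return cohort_spec_from_dict(doc)
    if kind == "sweep":
        return sweep_spec_from_dict(doc)
    raise SyntheticError(f"spec field 'kind' must be 'cohort' or 'sweep', got {kind!r}")
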