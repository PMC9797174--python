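"""Linear response of chart statistics to machine-parameter changes.

A parameter sweep recalculates the same cohort of plans at several values
of one beam-model parameter — dosimetric leaf gap (DLG, cm) or MLC
transmission factor (MLC-TF, dimensionless) — holding the other fixed.
Per structure and per level, a control chart is established from that
level's cohort; ordinary least squares then fits each chart statistic
(UCL, mean, LCL) against the parameter value across levels.

Reported per structure:

* ``rate_per_step`` — the mean-line slope expressed per canonical step
  (0.1 cm of DLG, 0.01 of MLC-TF), the scale on which such rates are
  conventionally quoted;
* ``zero_crossing`` — the parameter value at which the fitted mean line
  equals 0 % dose difference, i.e. where the local beam model matches the
  reference calculation.

Zero crossings are summarized over structures with outlier exclusion:
small structures (eye, lens, optic nerve) are disproportionately
sensitive to leaf-end modelling and can produce physically implausible
crossings that skew the cohort mean.  Two explicit rules are provided —
a physical-plausibility range (default) and a median ± k·MAD robust rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .dose_metrics import DoseComparison
from .spc_charts import (
    DEFAULT_MAX_ITER,
    DEFAULT_MIN_POINTS,
    ChartError,
    ControlChart,
    estimate_limits,
)

__all__ = [
    "SensitivityError",
    "ParameterSweep",
    "LineFit",
    "SensitivityFit",
    "SensitivitySummary",
    "group_sweep",
    "fit_parameter_response",
    "summarize_zero_crossings",
    "export_sensitivity",
    "CANONICAL_STEP",
]

log = logging.getLogger(__name__)

PARAMETERS = ("dlg_cm", "mlc_tf")

#: Canonical reporting steps: rates are quoted per 0.1 cm of DLG and per
#: 0.01 of MLC-TF.
CANONICAL_STEP = {"dlg_cm": 0.1, "mlc_tf": 0.01}

#: Physically plausible zero-crossing ranges (exclusive lower, inclusive
#: upper); crossings outside are excluded under the physical-range rule.
PLAUSIBLE_RANGE = {"dlg_cm": (0.0, 0.5), "mlc_tf": (0.0, 0.05)}

STATISTICS = ("ucl", "mean", "lcl")

MIN_LEVELS = 3


class SensitivityError(ValueError):
    pass


@dataclass(frozen=True)
class ParameterSweep:
    """Comparisons grouped by exact level of one machine parameter."""

    parameter: str
    levels: tuple[float, ...]  # sorted ascending
    cohorts: Mapping[float, tuple[DoseComparison, ...]]
    held_constant: float  # the other parameter's fixed value

    def __post_init__(self) -> None:
        object.__setattr__(self, "levels", tuple(float(v) for v in self.levels))
        object.__setattr__(
            self, "cohorts", {float(k): tuple(v) for k, v in dict(self.cohorts).items()}
        )
        if self.parameter not in PARAMETERS:
            raise SensitivityError(f"unknown parameter {self.parameter!r}")
        if len(set(self.levels)) < MIN_LEVELS:
            raise SensitivityError(
                f"need >= {MIN_LEVELS} distinct levels for a fit, got {len(set(self.levels))}"
            )
        if any(not self.cohorts.get(lv) for lv in self.levels):
            raise SensitivityError("every sweep level must have a nonempty cohort")

    @property
    def other_parameter(self) -> str:
        return "mlc_tf" if self.parameter == "dlg_cm" else "dlg_cm"

    def structures(self) -> list[str]:
        names: list[str] = []
        for lv in self.levels:
            for comp in self.cohorts[lv]:
                for n in comp.pct_diff_by_structure:
                    if n not in names:
                        names.append(n)
        return names


@dataclass(frozen=True)
class LineFit:
    """OLS line y = slope * x + intercept with goodness of fit."""

    slope: float
    intercept: float
    r_squared: float
    stderr_slope: float  # standard error of the slope

    def predict(self, x: float) -> float:
        return self.slope * x + self.intercept


@dataclass(frozen=True)
class SensitivityFit:
    """Per-structure linear response of chart statistics to one parameter."""

    structure: str
    parameter: str
    lines: Mapping[str, LineFit]  # keys: "ucl", "mean", "lcl"
    rate_per_step: float  # mean-line slope x canonical step (%)
    zero_crossing: float | None  # parameter value where the mean line is 0 %
    levels: tuple[float, ...]
    statistics: Mapping[str, tuple[float, ...]]  # per-level chart values

    def rate_of(self, statistic: str) -> float:
        return self.lines[statistic].slope * CANONICAL_STEP[self.parameter]


@dataclass(frozen=True)
class SensitivitySummary:
    """Zero-crossing summary over structures, with and without outliers."""

    parameter: str
    crossings: Mapping[str, float | None]  # every fitted structure
    outlier_structures: Mapping[str, str]  # name -> exclusion reason
    mean_all: float
    sd_all: float
    mean_retained: float
    sd_retained: float

    @property
    def retained(self) -> list[str]:
        return [
            s for s, v in self.crossings.items()
            if v is not None and s not in self.outlier_structures
        ]


# ---------------------------------------------------------------------------
# sweep assembly
# ---------------------------------------------------------------------------


def group_sweep(comparisons: Sequence[DoseComparison], parameter: str) -> ParameterSweep:
    """Group annotated comparisons by exact level of one parameter.

    Every comparison must carry machine parameters; the *other* parameter
    must be held at a single value across the whole input (otherwise the
    sweep is confounded and rejected).  Levels are sorted ascending.
    """
    if parameter not in PARAMETERS:
        raise SensitivityError(f"unknown parameter {parameter!r}; expected one of {PARAMETERS}")
    if not comparisons:
        raise SensitivityError("no comparisons to group")
    other = "mlc_tf" if parameter == "dlg_cm" else "dlg_cm"
    cohorts: dict[float, list[DoseComparison]] = {}
    held: set[float] = set()
    for comp in comparisons:
        if comp.params is None:
            raise SensitivityError(
                f"comparison for case {comp.case_id!r} lacks machine-parameter annotations"
            )
        level = float(getattr(comp.params, parameter))
        held.add(float(getattr(comp.params, other)))
        cohorts.setdefault(level, []).append(comp)
    if len(held) > 1:
        raise SensitivityError(
            f"confounded sweep: {other} takes {len(held)} values {sorted(held)} "
            f"while sweeping {parameter}"
        )
    levels = tuple(sorted(cohorts))
    if len(levels) < MIN_LEVELS:
        raise SensitivityError(
            f"need >= {MIN_LEVELS} distinct {parameter} levels, got {len(levels)}"
        )
    return ParameterSweep(
        parameter=parameter,
        levels=levels,
        cohorts={lv: tuple(cohorts[lv]) for lv in levels},
        held_constant=held.pop(),
    )


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _ols(x: np.ndarray, y: np.ndarray) -> LineFit:
    """Least-squares line with hand-rolled r^2 so a constant response is
    reported as a perfect zero-slope fit rather than NaN."""
    xb, yb = x.mean(), y.mean()
    sxx = float(np.sum((x - xb) ** 2))
    sxy = float(np.sum((x - xb) * (y - yb)))
    slope = sxy / sxx
    intercept = yb - slope * xb
    resid = y - (slope * x + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - yb) ** 2))
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    dof = x.size - 2
    stderr = float(np.sqrt(ss_res / dof / sxx)) if dof > 0 else float("nan")
    return LineFit(slope=slope, intercept=intercept, r_squared=r2, stderr_slope=stderr)


def fit_parameter_response(
    sweep: ParameterSweep,
    structure: str,
    estimator: str = "sd",
    min_points: int = DEFAULT_MIN_POINTS,
    max_iter: int = DEFAULT_MAX_ITER,
) -> SensitivityFit:
    """OLS fit of a structure's per-level chart statistics vs the parameter.

    At every sweep level a control chart is established from that level's
    cohort (same estimator and exclusion rule as monitoring charts); the
    regression then has one (level, statistic) point per level.  A level at
    which the chart cannot be established is an error naming the level.
    """
    stats: dict[str, list[float]] = {k: [] for k in STATISTICS}
    for lv in sweep.levels:
        vals = [
            comp.pct_diff_by_structure[structure]
            for comp in sweep.cohorts[lv]
            if structure in comp.pct_diff_by_structure
        ]
        try:
            chart = estimate_limits(
                vals, estimator=estimator, min_points=min_points,
                max_iter=max_iter, structure=structure,
            )
        except ChartError as exc:
            raise SensitivityError(
                f"structure {structure!r} not chartable at {sweep.parameter}={lv:g}: {exc}"
            ) from exc
        stats["ucl"].append(chart.ucl)
        stats["mean"].append(chart.mu)
        stats["lcl"].append(chart.lcl)

    x = np.asarray(sweep.levels, dtype=float)
    lines = {k: _ols(x, np.asarray(v, dtype=float)) for k, v in stats.items()}
    mean_line = lines["mean"]
    if mean_line.slope == 0.0:
        zero_crossing = None
        log.warning(
            "structure %r: zero mean-line slope; zero crossing undefined", structure
        )
    else:
        zero_crossing = -mean_line.intercept / mean_line.slope
    return SensitivityFit(
        structure=structure,
        parameter=sweep.parameter,
        lines=lines,
        rate_per_step=mean_line.slope * CANONICAL_STEP[sweep.parameter],
        zero_crossing=zero_crossing,
        levels=sweep.levels,
        statistics={k: tuple(v) for k, v in stats.items()},
    )


# ---------------------------------------------------------------------------
# zero-crossing summary
# ---------------------------------------------------------------------------


def _mean_sd(values: Sequence[float]) -> tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    mean = float(arr.mean())
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
    return mean, sd


def summarize_zero_crossings(
    fits: Sequence[SensitivityFit],
    outlier_rule: str = "physical-range",
    plausible_range: tuple[float, float] | None = None,
    k_mad: float = 3.0,
) -> SensitivitySummary:
    """Mean ± SD of per-structure zero crossings, with outlier exclusion.

    Rules:

    * ``physical-range`` (default): exclude crossings outside a plausible
      interval — (0, 0.5] cm for DLG, (0, 0.05] for MLC-TF unless
      overridden via ``plausible_range``.
    * ``mad``: exclude crossings farther than ``k_mad`` x MAD from the
      median crossing.

    Structures whose crossing is undefined (zero slope) are excluded with
    that reason.  Both the all-structure and the retained summaries are
    reported (sample SD, n-1).
    """
    if not fits:
        raise SensitivityError("no fits to summarize")
    params = {f.parameter for f in fits}
    if len(params) > 1:
        raise SensitivityError(f"fits mix parameters: {sorted(params)}")
    parameter = params.pop()
    crossings: dict[str, float | None] = {f.structure: f.zero_crossing for f in fits}
    defined = {s: v for s, v in crossings.items() if v is not None}
    if len(defined) < 3:
        raise SensitivityError(f"need >= 3 defined zero crossings, got {len(defined)}")

    outliers: dict[str, str] = {
        s: "undefined (zero slope)" for s, v in crossings.items() if v is None
    }
    if outlier_rule == "physical-range":
        lo, hi = plausible_range if plausible_range is not None else PLAUSIBLE_RANGE[parameter]
        for s, v in defined.items():
            if not (lo < v <= hi):
                outliers[s] = f"crossing {v:.4g} outside plausible range ({lo:g}, {hi:g}]"
    elif outlier_rule == "mad":
        arr = np.asarray(list(defined.values()))
        med = float(np.median(arr))
        mad = float(np.median(np.abs(arr - med)))
        for s, v in defined.items():
            if abs(v - med) > k_mad * mad:
                outliers[s] = f"crossing {v:.4g} beyond {k_mad:g} MAD of median {med:.4g}"
    else:
        raise SensitivityError(f"unknown outlier rule {outlier_rule!r}")

    retained = [v for s, v in defined.items() if s not in outliers]
    if not retained:
        raise SensitivityError("all zero crossings excluded as outliers")
    mean_all, sd_all = _mean_sd(list(defined.values()))
    mean_ret, sd_ret = _mean_sd(retained)
    return SensitivitySummary(
        parameter=parameter,
        crossings=crossings,
        outlier_structures=outliers,
        mean_all=mean_all,
        sd_all=sd_all,
        mean_retained=mean_ret,
        sd_retained=sd_ret,
    )


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------


def export_sensitivity(
    fits: Sequence[SensitivityFit],
    summary: SensitivitySummary | None,
    out_dir: str | Path,
    plot: bool = True,
    image_format: str = "png",
) -> dict[str, Path]:
    """Write the rate table, crossing summary and per-structure fit plots.

    ``rate_table.csv`` has one row per (structure, parameter) with the
    UCL/mean/LCL rates per canonical step; ``zero_crossings.csv`` lists
    each structure's crossing with its exclusion status.  CSV output is
    deterministic.  Returns the paths written, keyed by artifact name.
    """
    if not fits:
        raise SensitivityError("no fits to export")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    rows = [
        {
            "structure": f.structure,
            "parameter": f.parameter,
            "step": CANONICAL_STEP[f.parameter],
            "ucl_rate_per_step_pct": f.rate_of("ucl"),
            "mean_rate_per_step_pct": f.rate_of("mean"),
            "lcl_rate_per_step_pct": f.rate_of("lcl"),
            "mean_r_squared": f.lines["mean"].r_squared,
            "zero_crossing": "" if f.zero_crossing is None else f.zero_crossing,
        }
        for f in sorted(fits, key=lambda f: (f.parameter, f.structure))
    ]
    rate_path = out_dir / "rate_table.csv"
    pd.DataFrame(rows).to_csv(rate_path, index=False, float_format="%.10g")
    written["rate_table"] = rate_path

    if summary is not None:
        srows = [
            {
                "parameter": summary.parameter,
                "structure": s,
                "zero_crossing": "" if v is None else v,
                "excluded": s in summary.outlier_structures,
                "reason": summary.outlier_structures.get(s, ""),
            }
            for s, v in sorted(summary.crossings.items())
        ]
        sum_path = out_dir / "zero_crossings.csv"
        pd.DataFrame(srows).to_csv(sum_path, index=False, float_format="%.10g")
        written["zero_crossings"] = sum_path

    if plot:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        for f in fits:
            fig, ax = plt.subplots(figsize=(5, 3.5))
            x = np.asarray(f.levels)
            xs = np.linspace(x.min(), x.max(), 50)
            colors = {"ucl": "black", "mean": "tab:orange", "lcl": "purple"}
            for stat in STATISTICS:
                ax.plot(x, f.statistics[stat], "+", color=colors[stat], label=stat.upper() if stat != "mean" else "mean")
                line = f.lines[stat]
                ax.plot(xs, line.slope * xs + line.intercept, ":", color=colors[stat])
            ax.axhline(0.0, color="gray", lw=0.5)
            ax.set_xlabel(f.parameter)
            ax.set_ylabel("dose difference (%)")
            ax.set_title(f.structure)
            ax.legend(fontsize=8)
            fig.tight_layout()
            safe = "".join(ch if (ch.isalnum() or ch in "-_") else "_" for ch in f.structure)
            p = out_dir / f"sensitivity_{f.parameter}_{safe}.{image_format}"
            fig.savefig(p)
            plt.close(fig)
            written[f"plot_{f.parameter}_{f.structure}"] = p
    return written
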