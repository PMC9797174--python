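"""Individual (I-) control charts for per-structure dose-difference series.

Each structure's ordered series of percent mean-dose differences is
monitored with an individuals chart:

    UCL = mu + 3 * sigma
    LCL = mu - 3 * sigma

where mu and sigma are estimated from the series itself after excluding
observations that fall outside the limits.  The exclusion rule is iterated
to a fixed point: pass 0 estimates mu/sigma over the full series; each
subsequent pass re-estimates them over the observations lying inside the
previous pass's limits, until the retained set stops changing (or a
configurable pass cap is hit).  Iterating makes the rule idempotent —
re-running estimation on the retained subset changes nothing — and allows
an observation excluded by an early, outlier-inflated sigma to re-enter
once the limits settle.

Two sigma estimators are offered: the sample standard deviation (n-1
denominator, the default) and the conventional individuals-chart
moving-range estimate, mean |successive difference| / 1.128.

Boundary convention: an observation exactly equal to a control limit is
in-control; flagging uses strict inequality.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .dose_metrics import DoseComparison

__all__ = [
    "ChartError",
    "ControlChart",
    "OutOfControlReport",
    "estimate_limits",
    "build_charts",
    "evaluate_case",
    "export_chart",
    "write_chart_summary",
]

log = logging.getLogger(__name__)

#: d2 constant for subgroup size 2, used by the moving-range sigma estimate.
MOVING_RANGE_D2 = 1.128

DEFAULT_MIN_POINTS = 20
DEFAULT_MAX_ITER = 10

ESTIMATORS = ("sd", "moving-range")


class ChartError(ValueError):
    pass


@dataclass(frozen=True)
class ControlChart:
    """Established individuals chart for one structure.

    ``observations`` is the full ordered input series (case_id, value %);
    ``excluded`` are the indices removed during mu/sigma estimation;
    ``iterations`` counts the re-estimation passes performed after pass 0.
    """

    structure: str
    case_ids: tuple[str, ...]
    values: np.ndarray  # percent, full series in input order
    mu: float
    sigma: float
    ucl: float
    lcl: float
    excluded: tuple[int, ...]
    n_used: int
    estimator: str
    iterations: int

    @property
    def observations(self) -> list[tuple[str, float]]:
        return list(zip(self.case_ids, self.values.tolist()))

    def status_of(self, index: int) -> str:
        return "excluded" if index in self.excluded else "retained"

    def to_frame(self) -> pd.DataFrame:
        """Observation table: structure, case_index, case_id, value_pct, status."""
        return pd.DataFrame(
            {
                "structure": self.structure,
                "case_index": np.arange(len(self.values)),
                "case_id": list(self.case_ids),
                "value_pct": self.values,
                "status": [self.status_of(i) for i in range(len(self.values))],
            }
        )


@dataclass(frozen=True)
class OutOfControlReport:
    """A single observation falling strictly outside a chart's limits."""

    structure: str
    case_id: str
    value: float
    violated: str  # "above_ucl" | "below_lcl"
    chart: ControlChart

    def __post_init__(self) -> None:
        if self.violated not in ("above_ucl", "below_lcl"):
            raise ChartError(f"invalid violation kind {self.violated!r}")


def _sigma_estimate(sub: np.ndarray, estimator: str) -> float:
    if estimator == "sd":
        return float(np.std(sub, ddof=1)) if sub.size > 1 else 0.0
    if estimator == "moving-range":
        if sub.size < 2:
            return 0.0
        return float(np.mean(np.abs(np.diff(sub))) / MOVING_RANGE_D2)
    raise ChartError(f"unknown sigma estimator {estimator!r}; expected one of {ESTIMATORS}")


def estimate_limits(
    values: Sequence[float],
    estimator: str = "sd",
    min_points: int = DEFAULT_MIN_POINTS,
    max_iter: int = DEFAULT_MAX_ITER,
    case_ids: Sequence[str] | None = None,
    structure: str = "",
) -> ControlChart:
    """Estimate mu, sigma and the 3-sigma limits with iterated outlier exclusion.

    Raises :class:`ChartError` if the series is shorter than ``min_points``,
    contains non-finite values, or exclusion would retain fewer than
    ``min_points`` observations.  A zero-variance retained set collapses
    both limits onto mu with a logged warning.
    """
    vals = np.asarray(values, dtype=float)
    if vals.ndim != 1:
        raise ChartError("values must be a 1-D series")
    if not np.all(np.isfinite(vals)):
        raise ChartError("non-finite values in series")
    n = vals.size
    if n < min_points:
        raise ChartError(f"chart not establishable: {n} observations < min_points {min_points}")
    if case_ids is None:
        ids = tuple(str(i) for i in range(n))
    else:
        ids = tuple(str(c) for c in case_ids)
        if len(ids) != n:
            raise ChartError("case_ids length does not match values")

    retained = np.ones(n, dtype=bool)
    iterations = 0
    while True:
        sub = vals[retained]
        mu = float(sub.mean())
        sigma = _sigma_estimate(sub, estimator)
        ucl = mu + 3.0 * sigma
        lcl = mu - 3.0 * sigma
        if sigma == 0.0:
            log.warning(
                "structure %r: zero-variance series; control limits collapse to the mean",
                structure or "<series>",
            )
        inside = (vals >= lcl) & (vals <= ucl)
        if np.array_equal(inside, retained) or iterations >= max_iter:
            if not np.array_equal(inside, retained):
                log.warning(
                    "structure %r: exclusion did not reach a fixed point in %d passes",
                    structure or "<series>", max_iter,
                )
            break
        if int(inside.sum()) < min_points:
            raise ChartError(
                f"chart not establishable: exclusion would retain {int(inside.sum())} "
                f"< min_points {min_points}"
            )
        retained = inside
        iterations += 1

    excluded = tuple(int(i) for i in np.flatnonzero(~retained))
    return ControlChart(
        structure=structure,
        case_ids=ids,
        values=vals,
        mu=mu,
        sigma=sigma,
        ucl=ucl,
        lcl=lcl,
        excluded=excluded,
        n_used=int(retained.sum()),
        estimator=estimator,
        iterations=iterations,
    )


def build_charts(
    comparisons: Sequence[DoseComparison],
    estimator: str = "sd",
    min_points: int = DEFAULT_MIN_POINTS,
    max_iter: int = DEFAULT_MAX_ITER,
) -> tuple[dict[str, ControlChart], list[str]]:
    """One chart per structure appearing in at least ``min_points`` comparisons.

    Returns ``(charts, unchartable)`` where ``unchartable`` lists structure
    names seen in the input but carried by too few cases (or whose
    exclusion left too few points).  Observation order follows the input
    comparison order.
    """
    series: dict[str, list[tuple[str, float]]] = {}
    for comp in comparisons:
        for name, v in comp.pct_diff_by_structure.items():
            series.setdefault(name, []).append((comp.case_id, v))
    charts: dict[str, ControlChart] = {}
    unchartable: list[str] = []
    for name, obs in series.items():
        ids, vals = zip(*obs)
        try:
            charts[name] = estimate_limits(
                vals, estimator=estimator, min_points=min_points,
                max_iter=max_iter, case_ids=ids, structure=name,
            )
        except ChartError as exc:
            log.warning("structure %r unchartable: %s", name, exc)
            unchartable.append(name)
    return charts, unchartable


def evaluate_case(
    charts: Mapping[str, ControlChart], case: DoseComparison
) -> list[OutOfControlReport]:
    """Flag the case's structures falling strictly outside their chart limits.

    Structures of the case with no established chart are skipped with a
    warning; in-limit structures produce no report.
    """
    reports: list[OutOfControlReport] = []
    for name, value in case.pct_diff_by_structure.items():
        chart = charts.get(name)
        if chart is None:
            log.warning("case %s: no chart for structure %r; skipped", case.case_id, name)
            continue
        if value > chart.ucl:
            reports.append(OutOfControlReport(name, case.case_id, value, "above_ucl", chart))
        elif value < chart.lcl:
            reports.append(OutOfControlReport(name, case.case_id, value, "below_lcl", chart))
    return reports


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------


def export_chart(
    chart: ControlChart,
    out_dir: str | Path,
    plot: bool = True,
    image_format: str = "png",
) -> tuple[Path, Path | None]:
    """Write a chart's observation CSV and (optionally) its plot.

    The CSV is deterministic byte-for-byte for a given chart.  The plot
    shows individual observations, a solid line at the chart mean and
    dotted lines at the control limits, with excluded points marked.
    Returns ``(csv_path, plot_path_or_None)``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    safe = "".join(ch if (ch.isalnum() or ch in "-_") else "_" for ch in chart.structure)
    csv_path = out_dir / f"chart_{safe}.csv"
    chart.to_frame().to_csv(csv_path, index=False, float_format="%.10g")

    plot_path: Path | None = None
    if plot:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(7, 3.5))
        idx = np.arange(len(chart.values))
        keep = np.ones(len(chart.values), dtype=bool)
        keep[list(chart.excluded)] = False
        ax.plot(idx[keep], chart.values[keep], "o", color="tab:blue", label="cases")
        if (~keep).any():
            ax.plot(idx[~keep], chart.values[~keep], "x", color="black", label="excluded")
        ax.axhline(chart.mu, color="green", label=f"mean {chart.mu:.2f}%")
        ax.axhline(chart.ucl, color="red", linestyle=":", label=f"UCL {chart.ucl:.2f}%")
        ax.axhline(chart.lcl, color="red", linestyle=":", label=f"LCL {chart.lcl:.2f}%")
        ax.set_xlabel("case index")
        ax.set_ylabel("mean dose difference (%)")
        ax.set_title(chart.structure)
        ax.legend(loc="best", fontsize=8)
        fig.tight_layout()
        plot_path = out_dir / f"chart_{safe}.{image_format}"
        fig.savefig(plot_path)
        plt.close(fig)
    return csv_path, plot_path


def write_chart_summary(charts: Mapping[str, ControlChart], path: str | Path) -> None:
    """Summary CSV: structure, mu, sigma, lcl, ucl, n_used, iterations.

    Rows are sorted by structure name so re-export is deterministic.
    """
    rows = [
        {
            "structure": name,
            "mu": c.mu,
            "sigma": c.sigma,
            "lcl": c.lcl,
            "ucl": c.ucl,
            "n_used": c.n_used,
            "iterations": c.iterations,
        }
        for name, c in sorted(charts.items())
    ]
    pd.DataFrame(
        rows, columns=["structure", "mu", "sigma", "lcl", "ucl", "n_used", "iterations"]
    ).to_csv(path, index=False, float_format="%.10g")
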