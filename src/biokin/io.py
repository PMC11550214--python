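"""CSV / JSON readers and writers for time-series data and fit reports.

CSV dialect is fixed: comma delimiter, ``.`` decimal, UTF-8, required header.
A time-series file has columns ``time`` and ``concentration`` plus an optional
``replicate`` column; replicate rows simply repeat a time value.  Reports are
JSON and echo everything needed to reproduce them (scenario, GA configuration
including the seed, package version).
"""

from __future__ import annotations

import datetime
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .fitting import FitConfig, FitResult
from .models import ConcentrationSeries, ExposureScenario
from .selection import ModelComparison

__all__ = [
    "ParseError",
    "read_timeseries_csv",
    "write_timeseries_csv",
    "write_series_csv",
    "write_plot_data_csv",
    "build_fit_report",
    "write_fit_report",
]


class ParseError(ValueError):
    """Malformed input file; message carries the offending line where known."""


def read_timeseries_csv(path: str | Path) -> ConcentrationSeries:
    """Read an observed concentration series, sorted by time.

    Raises :class:`ParseError` (with a 1-based line number where applicable)
    for missing columns, non-numeric cells, negative times or an empty table.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=",", decimal=".", encoding="utf-8")
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV structure
        raise ParseError(f"{path}: cannot parse CSV: {exc}") from exc

    missing = {"time", "concentration"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing required column(s): {', '.join(sorted(missing))}")
    if len(df) == 0:
        raise ParseError(f"{path}: file contains a header but no data rows")

    for col in ("time", "concentration"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise ParseError(f"{path}, line {line}: non-numeric value in column {col!r}")
        if numeric.isna().any():
            line = int(numeric.isna().idxmax()) + 2
            raise ParseError(f"{path}, line {line}: empty cell in column {col!r}")
        df[col] = numeric

    neg = df["time"] < 0
    if neg.any():
        line = int(neg.idxmax()) + 2
        raise ParseError(f"{path}, line {line}: negative time")

    df = df.sort_values("time", kind="stable").reset_index(drop=True)
    return ConcentrationSeries(
        times=df["time"].to_numpy(dtype=float),
        values=df["concentration"].to_numpy(dtype=float),
        label=path.stem,
    )


def write_timeseries_csv(series: ConcentrationSeries, path: str | Path) -> None:
    """Write a series in the same dialect :func:`read_timeseries_csv` consumes."""
    pd.DataFrame({"time": series.times, "concentration": series.values}).to_csv(
        Path(path), index=False
    )


def write_series_csv(series: ConcentrationSeries, path: str | Path) -> None:
    """Alias for predicted-curve output (column names shared with input)."""
    write_timeseries_csv(series, path)


def write_plot_data_csv(
    data: ConcentrationSeries,
    predictions: dict[str, np.ndarray],
    path: str | Path,
) -> None:
    """Observed values and per-model predictions at the observation times.

    Column count is 2 (time, observed) + one per fitted model.
    """
    frame = {"time": data.times, "observed": data.values}
    for label, pred in predictions.items():
        frame[f"predicted_{label}"] = np.asarray(pred)
    pd.DataFrame(frame).to_csv(Path(path), index=False)


def _scenario_dict(scenario: ExposureScenario) -> dict:
    return {
        "c_org0": scenario.c_org0,
        "c_exposure": scenario.c_exposure,
        "t_e": scenario.t_e,
        "t_total": scenario.t_total,
        "dt": scenario.dt,
        "time_unit": scenario.time_unit,
        "medium_unit": scenario.medium_unit,
    }


def build_fit_report(
    data: ConcentrationSeries,
    scenario: ExposureScenario,
    config: FitConfig,
    fits: Sequence[FitResult],
    comparison: ModelComparison | None,
) -> dict:
    """Self-contained JSON-ready fit report.

    Re-running the fit with the echoed data, scenario and configuration
    reproduces every number in the report (the timestamp aside).
    """
    report = {
        "tool": "biokin",
        "version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "data": {
            "label": data.label,
            "times": data.times.tolist(),
            "concentrations": data.values.tolist(),
        },
        "scenario": _scenario_dict(scenario),
        "config": json.loads(config.to_json()),
        "fits": [f.to_dict() for f in fits],
        "comparison": comparison.to_dict() if comparison is not None else None,
    }
    return report


def write_fit_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2) + "\n")
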