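"""Reading and writing traces and metrics tables.

Traces are exchanged as two-column CSV (``time_s,value``); per-condition
moment statistics use the seven-column layout of the published spike metrics
tables (condition, mean, SD, max, min, kurtosis, skewness). Time columns are
canonicalised to seconds from recording start with 0-based sample indexing;
decimal separator is ``.`` with comma delimiters, no locale handling.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    NonMonotoneTimeError,
    NonUniformSamplingError,
    TraceFormatError,
)

#: canonical unit strings; "μA" is accepted as an alias for "uA" on input
VALID_UNITS = ("mV", "uA")


def _canonical_unit(unit: str) -> str:
    if unit in ("μA", "uA", "µA"):
        return "uA"
    if unit == "mV":
        return "mV"
    raise ValueError(f"unit must be one of {VALID_UNITS}, got {unit!r}")


@dataclass
class Trace:
    """A uniformly sampled time series (voltage in mV or current in uA).

    Parameters
    ----------
    values : array-like
        Ordered samples. Must be non-empty.
    dt : float
        Sampling interval in seconds; strictly positive.
    t0 : float
        Time of the first sample, seconds from recording start.
    unit : {"mV", "uA"}
        Physical unit of ``values``.
    label : str
        Free-text label (typically the exposure condition).
    """

    values: np.ndarray
    dt: float = 1.0
    t0: float = 0.0
    unit: str = "mV"
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("values must be a non-empty 1-D array")
        if not self.dt > 0:
            raise ValueError("dt must be strictly positive")
        self.unit = _canonical_unit(self.unit)

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0 + self.dt * np.arange(self.values.size)

    @property
    def duration(self) -> float:
        """Span from first to last sample, seconds."""
        return self.dt * (self.values.size - 1)

    def with_values(self, values: np.ndarray, label: str | None = None) -> "Trace":
        """Copy of this trace with new sample values (same sampling/unit)."""
        return Trace(values, dt=self.dt, t0=self.t0, unit=self.unit,
                     label=self.label if label is None else label)


@dataclass
class MetricsRow:
    """One row of a per-condition moment-statistics table."""

    condition: str
    mean: float
    sd: float
    max: float
    min: float
    kurtosis: float
    skewness: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if not (self.min <= self.mean <= self.max):
            raise ValueError("min <= mean <= max violated")


METRICS_COLUMNS = ("Condition", "Mean", "Std Dev", "Max", "Min",
                   "Kurtosis", "Skewness")


def read_trace_csv(path: str | Path, unit: str, label: str = "") -> Trace:
    """Read a two-column ``time_s,value`` CSV into a :class:`Trace`.

    The time column must be strictly increasing and uniformly sampled
    (successive deltas within 1e-6 relative deviation of the median delta).
    """
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, UnicodeDecodeError) as exc:
        raise TraceFormatError(f"cannot parse {path}: {exc}") from exc
    if df.shape[1] != 2:
        raise TraceFormatError(
            f"expected 2 columns, found {df.shape[1]} in {path}")
    t = pd.to_numeric(df.iloc[:, 0], errors="coerce").to_numpy()
    v = pd.to_numeric(df.iloc[:, 1], errors="coerce").to_numpy()
    if np.isnan(t).any() or np.isnan(v).any():
        raise TraceFormatError(f"non-numeric cells in {path}")
    if len(t) < 2:
        raise TraceFormatError("trace needs at least two samples")
    deltas = np.diff(t)
    if np.any(deltas <= 0):
        raise NonMonotoneTimeError("time column is not strictly increasing")
    dt = float(np.median(deltas))
    if np.max(np.abs(deltas - dt)) >= 1e-6 * dt:
        raise NonUniformSamplingError(
            f"sampling is non-uniform beyond tolerance (dt={dt})")
    return Trace(v, dt=dt, t0=float(t[0]), unit=unit, label=label)


def write_trace_csv(trace: Trace, path: str | Path) -> None:
    """Write a trace as ``time_s,value`` CSV with full float precision."""
    df = pd.DataFrame({"time_s": trace.times, "value": trace.values})
    df.to_csv(path, index=False, float_format="%.12g")


def _fmt(x: float, decimals: int) -> str:
    s = f"{x:.{decimals}f}"
    if "." in s:
        s = s.rstrip("0").rstrip(".")
    return s if s not in ("-0", "") else "0"


def write_metrics_table(rows: list[MetricsRow], path: str | Path,
                        value_decimals: int = 3,
                        moment_decimals: int = 2) -> None:
    """Write metric rows as CSV in the seven-column published-table order.

    mean/SD/max/min are printed with ``value_decimals`` decimals,
    kurtosis/skewness with ``moment_decimals``; trailing zeros are trimmed.
    """
    if not rows:
        raise ValueError("rows must be non-empty")
    lines = [",".join(METRICS_COLUMNS)]
    for r in rows:
        lines.append(",".join([
            r.condition,
            _fmt(r.mean, value_decimals),
            _fmt(r.sd, value_decimals),
            _fmt(r.max, value_decimals),
            _fmt(r.min, value_decimals),
            _fmt(r.kurtosis, moment_decimals),
            _fmt(r.skewness, moment_decimals),
        ]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_metrics_table(path: str | Path) -> list[MetricsRow]:
    df = pd.read_csv(path)
    if tuple(df.columns) != METRICS_COLUMNS:
        raise TraceFormatError(
            f"unexpected metrics header {tuple(df.columns)}")
    return [
        MetricsRow(condition=str(row["Condition"]), mean=row["Mean"],
                   sd=row["Std Dev"], max=row["Max"], min=row["Min"],
                   kurtosis=row["Kurtosis"], skewness=row["Skewness"])
        for _, row in df.iterrows()
    ]


def metrics_to_json(rows: list[MetricsRow], path: str | Path | None = None) -> str:
    """JSON export of metric rows; returns the JSON string."""
    payload = json.dumps([dataclasses.asdict(r) for r in rows], indent=2)
    if path is not None:
        Path(path).write_text(payload)
    return payload
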