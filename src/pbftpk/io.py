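"""Reading and writing concentration-time series as plain CSV.

Expected layout: a header with `time` and `concentration` columns (hours and
a declared concentration unit).  Lines starting with `#` are metadata; a line
of the form `# unit: ng/mL` sets the unit label.  Trailing blank lines are
tolerated.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .models import ConcentrationTimeSeries

__all__ = ["read_series", "write_series"]


def _unit_from_comments(path: Path) -> str | None:
    with open(path) as fh:
        for line in fh:
            stripped = line.strip()
            if not stripped.startswith("#"):
                continue
            body = stripped.lstrip("#").strip()
            if body.lower().startswith("unit:"):
                return body.split(":", 1)[1].strip()
    return None


def read_series(path) -> ConcentrationTimeSeries:
    """Read a validated concentration-time series from a CSV file."""
    path = Path(path)
    df = pd.read_csv(path, comment="#", skip_blank_lines=True)
    df.columns = [str(c).strip().lower() for c in df.columns]
    missing = {"time", "concentration"} - set(df.columns)
    if missing:
        raise ValueError(
            f"{path}: missing required column(s) {sorted(missing)}; "
            f"found {list(df.columns)}"
        )
    for col in ("time", "concentration"):
        try:
            df[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: non-numeric value in column {col!r}: {exc}") from exc
    times = df["time"].to_numpy(dtype=float)
    dup = np.nonzero(np.diff(times) == 0)[0]
    if dup.size:
        rows = ", ".join(str(i + 2) for i in dup[:5])  # 1-based incl. header
        raise ValueError(f"{path}: duplicate time values at data row(s) {rows}")
    bad = np.nonzero(np.diff(times) < 0)[0]
    if bad.size:
        rows = ", ".join(str(i + 2) for i in bad[:5])
        raise ValueError(f"{path}: times not increasing at data row(s) {rows}")
    unit = _unit_from_comments(path) or "ng/mL"
    return ConcentrationTimeSeries(
        times=times,
        concentrations=df["concentration"].to_numpy(dtype=float),
        unit_label=unit,
        label=path.stem,
    )


def write_series(series: ConcentrationTimeSeries, path) -> None:
    """Write a series to CSV with the unit recorded as a comment line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# unit: {series.unit_label}\n")
        if series.label:
            fh.write(f"# label: {series.label}\n")
        fh.write("time,concentration\n")
        for t, c in zip(series.times, series.concentrations):
            fh.write(f"{t:.10g},{c:.10g}\n")
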