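"""CSV readers and writers for the logger and summary formats.

Two logger dialects are supported: the plain two-column export
(``timestamp,temp_c`` with ISO-8601 timestamps or ``minutes,temp_c``) and
the iButton-style export (free header lines, then ``Date/Time,Unit,Value``
rows).  All outputs are tidy CSVs with minutes-since-start alongside ISO
timestamps.
"""

from __future__ import annotations

import json
from dataclasses import asdict

import numpy as np
import pandas as pd

from .classify import LABEL_NAMES, TorporBout, WeeklyTorporSummary
from .trace import TemperatureTrace

DEFAULT_ORIGIN = "2013-07-01T00:00:00"


def _to_minutes(ts: pd.Series, origin: str | None) -> tuple[np.ndarray, str]:
    if pd.api.types.is_numeric_dtype(ts):
        return ts.to_numpy(dtype=float), origin or DEFAULT_ORIGIN
    parsed = pd.to_datetime(ts, format="ISO8601")
    org = pd.Timestamp(origin) if origin else parsed.iloc[0]
    minutes = (parsed - org).dt.total_seconds().to_numpy() / 60.0
    return minutes, str(org.isoformat())


def read_trace_csv(path, source: str, origin: str | None = None) -> TemperatureTrace:
    """Read a ``timestamp,temp_c`` logger CSV into a trace."""
    table = pd.read_csv(path)
    cols = {c.lower(): c for c in table.columns}
    if "temp_c" not in cols or "timestamp" not in cols:
        raise ValueError(f"{path}: expected columns timestamp,temp_c")
    minutes, _ = _to_minutes(table[cols["timestamp"]], origin)
    step = float(np.median(np.diff(minutes)))
    return TemperatureTrace(minutes, table[cols["temp_c"]].to_numpy(dtype=float),
                            source=source, sampling_interval=step)


def read_ibutton_csv(path, source: str = "body",
                     origin: str | None = None) -> TemperatureTrace:
    """Read an iButton-style export: header lines, then Date/Time,Unit,Value."""
    with open(path) as fh:
        lines = fh.readlines()
    start = None
    for i, line in enumerate(lines):
        if line.strip().lower().startswith("date/time"):
            start = i
            break
    if start is None:
        raise ValueError(f"{path}: no 'Date/Time,Unit,Value' header found")
    rows = [ln.strip().split(",") for ln in lines[start + 1:] if ln.strip()]
    stamps = pd.Series([r[0] for r in rows])
    values = np.array([float(r[2]) for r in rows])
    minutes, _ = _to_minutes(stamps, origin)
    step = float(np.median(np.diff(minutes)))
    return TemperatureTrace(minutes, values, source=source, sampling_interval=step)


def write_trace_csv(trace: TemperatureTrace, path,
                    origin: str = DEFAULT_ORIGIN) -> None:
    org = pd.Timestamp(origin)
    stamps = org + pd.to_timedelta(trace.timestamps, unit="m")
    pd.DataFrame({
        "timestamp": stamps.strftime("%Y-%m-%dT%H:%M:%S"),
        "temp_c": trace.values,
    }).to_csv(path, index=False, float_format="%.4f")


def write_episodes_csv(seg, path, origin: str = DEFAULT_ORIGIN) -> None:
    org = pd.Timestamp(origin)
    rows = [{
        "label": LABEL_NAMES[label],
        "start_min": start,
        "end_min": end,
        "start_iso": (org + pd.Timedelta(minutes=start)).isoformat(),
        "end_iso": (org + pd.Timedelta(minutes=end)).isoformat(),
    } for label, start, end in seg.episodes]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_bouts_csv(bouts: list[TorporBout], path,
                    origin: str = DEFAULT_ORIGIN) -> None:
    org = pd.Timestamp(origin)
    rows = [{
        "onset_min": b.onset, "offset_min": b.offset, "duration_min": b.duration,
        "min_temp_c": b.min_temp, "kind": b.kind,
        "onset_iso": (org + pd.Timedelta(minutes=b.onset)).isoformat(),
    } for b in bouts]
    pd.DataFrame(rows, columns=["onset_min", "offset_min", "duration_min",
                                "min_temp_c", "kind", "onset_iso"]
                 ).to_csv(path, index=False, float_format="%.2f")


def write_weekly_csv(weekly: list[WeeklyTorporSummary], path,
                     animal_id: str = "") -> None:
    rows = [dict(animal_id=animal_id, **asdict(w)) for w in weekly]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.2f")


def read_weekly_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_ground_truth(truth, path) -> None:
    """Serialize a generator ground-truth object as a JSON sidecar."""

    def default(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if hasattr(obj, "__dataclass_fields__"):
            return asdict(obj)
        raise TypeError(f"not serializable: {type(obj)}")

    with open(path, "w") as fh:
        json.dump(asdict(truth), fh, default=default, indent=1, sort_keys=True)
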