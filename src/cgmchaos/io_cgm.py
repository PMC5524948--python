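"""CGM trace data model: CSV I/O, landmark segmentation, episode detection.

A continuous glucose monitor reports a subcutaneous glucose value on a fixed
cadence (typically every 5 minutes).  :class:`GlucoseSeries` is the universal
input object of this package: a strictly-increasing timestamp vector paired
with positive glucose concentrations in mg/dL.  Sensor dropouts are *flagged*
as gaps, never imputed; downstream consumers that require contiguous data must
split at the gaps.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GlucoseSeries",
    "LandmarkWindow",
    "Episode",
    "LANDMARK_BOUNDS",
    "read_cgm_csv",
    "write_cgm_csv",
    "segment_landmarks",
    "detect_episodes",
    "landmark_of_time",
    "CGMError",
    "OrderingError",
    "ValueRangeError",
    "ParseError",
]

HYPO_THRESHOLD = 70.0   # mg/dL, strict: hypo samples are < 70
HYPER_THRESHOLD = 180.0  # mg/dL, strict: hyper samples are > 180


class CGMError(Exception):
    """Base class for CGM data errors."""


class OrderingError(CGMError):
    """Timestamps are not strictly increasing."""


class ValueRangeError(CGMError):
    """Glucose values outside the physically meaningful range."""


class ParseError(CGMError):
    """A CSV row could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message)
        self.line = line


@dataclass(frozen=True)
class GlucoseSeries:
    """Uniformly sampled glucose trace.

    Parameters
    ----------
    timestamps
        Calendar datetimes, strictly increasing.
    values
        Glucose concentration in mg/dL, all strictly positive.
    sampling_interval
        Nominal sampling cadence in minutes (default 5).
    gaps
        Indices ``i`` such that the step ``timestamps[i] -> timestamps[i+1]``
        exceeds 1.5x the nominal interval.  Recorded, never filled.
    """

    timestamps: np.ndarray
    values: np.ndarray
    sampling_interval: float = 5.0
    gaps: tuple[int, ...] = field(default=())

    def __post_init__(self):
        ts = pd.DatetimeIndex(self.timestamps)
        vals = np.asarray(self.values, dtype=float)
        if len(ts) != len(vals):
            raise CGMError("timestamps and values must have equal length")
        if len(ts) > 1 and not (np.diff(ts.asi8) > 0).all():
            raise OrderingError("timestamps must be strictly increasing")
        if len(vals) and (vals <= 0).any():
            raise ValueRangeError("glucose values must be positive")
        object.__setattr__(self, "timestamps", ts)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "gaps", tuple(self._find_gaps(ts)))

    def _find_gaps(self, ts: pd.DatetimeIndex) -> list[int]:
        if len(ts) < 2:
            return []
        steps = np.diff(ts.asi8) / 60e9  # minutes
        return list(np.nonzero(steps > 1.5 * self.sampling_interval)[0])

    def __len__(self) -> int:
        return len(self.values)

    @property
    def is_contiguous(self) -> bool:
        return not self.gaps

    def slice(self, start: int, stop: int) -> "GlucoseSeries":
        return GlucoseSeries(
            self.timestamps[start:stop], self.values[start:stop],
            self.sampling_interval,
        )

    def contiguous_segments(self) -> list["GlucoseSeries"]:
        """Split at flagged gaps; each returned piece is gap-free."""
        bounds = [0] + [g + 1 for g in self.gaps] + [len(self)]
        return [self.slice(a, b) for a, b in zip(bounds[:-1], bounds[1:]) if b > a]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"timestamp": self.timestamps, "glucose_mgdl": self.values}
        )


# The seven landmark intervals tiling the 24-h day, half-open [start, end).
# A sample at exactly 10:00 belongs to late_morning, etc.
LANDMARK_BOUNDS: dict[str, tuple[_dt.time, _dt.time]] = {
    "night": (_dt.time(0, 0), _dt.time(6, 0)),
    "morning": (_dt.time(6, 0), _dt.time(10, 0)),
    "late_morning": (_dt.time(10, 0), _dt.time(12, 30)),
    "noon": (_dt.time(12, 30), _dt.time(16, 0)),
    "afternoon": (_dt.time(16, 0), _dt.time(18, 30)),
    "early_evening": (_dt.time(18, 30), _dt.time(21, 30)),
    "evening": (_dt.time(21, 30), _dt.time(0, 0)),  # end 0:00 == midnight
}

# Synonyms seen in narrative descriptions of the seven intervals.
_LANDMARK_ALIASES = {"early_noon": "noon", "late_evening": "evening"}


@dataclass(frozen=True)
class LandmarkWindow:
    """One landmark interval of one calendar day with its samples."""

    label: str
    date: _dt.date
    start: _dt.time
    end: _dt.time
    sub_series: GlucoseSeries


@dataclass(frozen=True)
class Episode:
    """A maximal run of >= 2 consecutive out-of-range samples."""

    kind: Literal["hypo", "hyper"]
    start_index: int
    end_index: int  # inclusive
    extreme_value: float

    def __post_init__(self):
        if self.end_index - self.start_index + 1 < 2:
            raise CGMError("an episode spans at least two samples")


def landmark_of_time(t: _dt.time) -> str:
    """Map a clock time to its landmark label (half-open windows)."""
    minutes = t.hour * 60 + t.minute + t.second / 60
    for label, (a, b) in LANDMARK_BOUNDS.items():
        lo = a.hour * 60 + a.minute
        hi = b.hour * 60 + b.minute if b != _dt.time(0, 0) else 24 * 60
        if lo <= minutes < hi:
            return label
    raise AssertionError("landmark windows must tile the day")  # pragma: no cover


def read_cgm_csv(path: str | Path) -> GlucoseSeries:
    """Read a two-column CGM CSV (``timestamp,glucose_mgdl``).

    The header row is optional.  Timestamps must be ISO-8601 and strictly
    increasing; glucose must be positive.  Steps longer than 1.5x the nominal
    5-minute cadence are recorded in ``series.gaps``.
    """
    path = Path(path)
    rows: list[tuple[pd.Timestamp, float]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) < 2:
                raise ParseError(f"line {lineno}: expected two columns", lineno)
            if lineno == 1 and parts[0].lower() in ("timestamp", "time", "datetime"):
                continue
            try:
                ts = pd.Timestamp(parts[0].strip())
                if pd.isna(ts):
                    raise ValueError("not a timestamp")
                val = float(parts[1])
            except (ValueError, TypeError) as exc:
                raise ParseError(f"line {lineno}: {exc}", lineno) from exc
            rows.append((ts, val))
    if not rows:
        raise ParseError(f"{path}: no data rows")
    ts, vals = zip(*rows)
    return GlucoseSeries(pd.DatetimeIndex(ts), np.array(vals))


def write_cgm_csv(series: GlucoseSeries, path: str | Path) -> None:
    """Write the reader's dialect: header + ISO-8601 timestamps."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("timestamp,glucose_mgdl\n")
        for t, v in zip(series.timestamps, series.values):
            fh.write(f"{t.isoformat()},{float(v)!r}\n")


def write_gap_report(series: GlucoseSeries, path: str | Path) -> None:
    report = [
        {
            "after_index": int(i),
            "from": series.timestamps[i].isoformat(),
            "to": series.timestamps[i + 1].isoformat(),
        }
        for i in series.gaps
    ]
    Path(path).write_text(json.dumps(report, indent=2))


def segment_landmarks(series: GlucoseSeries) -> list[LandmarkWindow]:
    """Assign every sample to exactly one landmark window per calendar day.

    The seven windows tile each day; the ``evening`` window closes at
    midnight, so a sample at exactly 00:00 opens the *night* window of the
    next calendar day.  Empty windows are omitted.
    """
    if len(series) == 0:
        raise CGMError("cannot segment an empty series")
    ts = series.timestamps
    labels = np.array([landmark_of_time(t.time()) for t in ts])
    dates = np.array([t.date() for t in ts])
    windows: list[LandmarkWindow] = []
    for date in sorted(set(dates)):
        day_mask = dates == date
        for label, (a, b) in LANDMARK_BOUNDS.items():
            mask = day_mask & (labels == label)
            if not mask.any():
                continue
            idx = np.nonzero(mask)[0]
            windows.append(
                LandmarkWindow(
                    label=label, date=date, start=a, end=b,
                    sub_series=series.slice(idx[0], idx[-1] + 1),
                )
            )
    return windows


def detect_episodes(
    series: GlucoseSeries | Sequence[float], kind: Literal["hypo", "hyper"]
) -> list[Episode]:
    """Find maximal runs of >= 2 consecutive hypo (< 70) or hyper (> 180) samples."""
    values = series.values if isinstance(series, GlucoseSeries) else np.asarray(series, float)
    if kind == "hypo":
        qual = values < HYPO_THRESHOLD
    elif kind == "hyper":
        qual = values > HYPER_THRESHOLD
    else:
        raise ValueError(f"unknown episode kind: {kind!r}")
    episodes: list[Episode] = []
    n = len(values)
    i = 0
    while i < n:
        if not qual[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and qual[j + 1]:
            j += 1
        if j - i + 1 >= 2:
            segment = values[i : j + 1]
            extreme = segment.min() if kind == "hypo" else segment.max()
            episodes.append(Episode(kind, i, j, float(extreme)))
        i = j + 1
    return episodes
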