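"""Glycemic variability indices and hypo/hyper risk indices.

Risk scoring follows the Kovatchev blood-glucose risk framework: each reading
BG (mg/dL) is mapped through the symmetrizing transform

    f(BG) = 1.509 * ((ln BG)^1.084 - 5.381)

whose zero crossing (~112.5 mg/dL) separates the hypo- and hyper-glycemic
half-axes.  The per-reading risk is r = 10 * f(BG)^2, split into a low-side
component (f < 0) and a high-side component (f > 0); the low glucose index
(LGI) and high glucose index (HGI) are the means of the respective components
over all readings.  Categories:

    LGI:  minimal < 1.1 <= low <= 2.5 < moderate <= 5 < high
    HGI:  low < 4.5 <= moderate <= 9 < high

Boundary values fall in the lower-severity category except where the
defining wording is strict ("greater than"), so LGI = 2.5 is "low",
LGI = 5 is "moderate", HGI = 9 is "moderate".

Variability indices: intra-day SD, CV, J-index, MAGE and CONGA_n; inter-day
MODD, GVI and PGS.  Interpretation bands: J-index 10-20 ideal, 20-30 good,
30-40 upper borderline, > 40 inadequate; GVI 1.0-1.2 low (non-diabetic),
1.2-1.5 modest, > 1.5 high variability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_cgm import GlucoseSeries

__all__ = [
    "GVReport",
    "RiskReport",
    "risk_indices",
    "classify_risk",
    "intra_day_indices",
    "inter_day_indices",
    "gv_report",
    "risk_report",
    "mage",
    "conga",
    "TIR_LOW",
    "TIR_HIGH",
]

TIR_LOW = 70.0    # mg/dL, lower bound of the 70-180 target range
TIR_HIGH = 180.0

_SAMPLES_PER_HOUR = 12   # 5-minute cadence
_SAMPLES_PER_DAY = 288


@dataclass(frozen=True)
class GVReport:
    """Variability indices; inter-day members are None when not computable."""

    sd: float
    cv: float
    j_index: float
    mage: float
    conga_n: float
    conga_hours: float
    modd: float | None = None
    gvi: float | None = None
    pgs: float | None = None

    def to_dict(self) -> dict:
        return {
            "sd_mgdl": self.sd,
            "cv": self.cv,
            "j_index": self.j_index,
            "mage_mgdl": self.mage,
            f"conga_{self.conga_hours:g}h_mgdl": self.conga_n,
            "modd_mgdl": self.modd,
            "gvi": self.gvi,
            "pgs": self.pgs,
        }


@dataclass(frozen=True)
class RiskReport:
    lgi: float
    hgi: float
    hypo_category: str
    hyper_category: str

    def to_dict(self) -> dict:
        return {
            "lgi": self.lgi,
            "hgi": self.hgi,
            "hypo_risk": self.hypo_category,
            "hyper_risk": self.hyper_category,
        }


# ---------------------------------------------------------------------------
# risk indices
# ---------------------------------------------------------------------------

def _risk_transform(values: np.ndarray) -> np.ndarray:
    return 1.509 * (np.log(values) ** 1.084 - 5.381)


def risk_indices(values) -> tuple[float, float]:
    """(LGI, HGI): mean low-side and high-side transformed risks."""
    x = np.asarray(
        values.values if isinstance(values, GlucoseSeries) else values, float
    )
    if len(x) == 0:
        raise ValueError("empty glucose sequence")
    if (x <= 0).any():
        raise ValueError("glucose values must be positive")
    f = _risk_transform(x)
    r = 10.0 * f ** 2
    lgi = float(np.mean(np.where(f < 0, r, 0.0)))
    hgi = float(np.mean(np.where(f > 0, r, 0.0)))
    return lgi, hgi


def classify_risk(lgi: float, hgi: float) -> tuple[str, str]:
    """Map LGI/HGI to categorical risk levels (see module docstring)."""
    if lgi < 0 or hgi < 0:
        raise ValueError("risk indices are nonnegative")
    if lgi < 1.1:
        hypo = "minimal"
    elif lgi <= 2.5:
        hypo = "low"
    elif lgi <= 5:
        hypo = "moderate"
    else:
        hypo = "high"
    if hgi < 4.5:
        hyper = "low"
    elif hgi <= 9:
        hyper = "moderate"
    else:
        hyper = "high"
    return hypo, hyper


def risk_report(values) -> RiskReport:
    lgi, hgi = risk_indices(values)
    hypo, hyper = classify_risk(lgi, hgi)
    return RiskReport(lgi, hgi, hypo, hyper)


# ---------------------------------------------------------------------------
# intra-day variability
# ---------------------------------------------------------------------------

def mage(values: Sequence[float]) -> float:
    """Mean amplitude of glycemic excursions (Service criterion).

    Excursions are extracted with a threshold zig-zag on a 3-point
    moving-average smoothed trace: a new peak/nadir is confirmed only once
    the trace has reversed by more than one (raw) standard deviation, so
    sub-threshold wiggles never fragment a large excursion.  MAGE is the
    mean absolute amplitude between consecutive confirmed extremes
    (both directions); 0 when no excursion qualifies.
    """
    x = np.asarray(values, float)
    if len(x) < 3:
        return 0.0
    sd = x.std(ddof=1)
    if sd == 0:
        return 0.0
    smooth = np.convolve(x, np.ones(3) / 3, mode="valid")
    extremes: list[float] = []
    trend = 0  # +1 rising toward a peak, -1 falling toward a nadir
    cand = smooth[0]
    for v in smooth[1:]:
        if trend == 0:
            if v - cand > sd:
                extremes.append(cand)
                trend, cand = +1, v
            elif cand - v > sd:
                extremes.append(cand)
                trend, cand = -1, v
            else:
                cand = cand  # still undecided; keep the start anchor
        elif trend == +1:
            if v > cand:
                cand = v
            elif cand - v > sd:  # reversal confirms the peak
                extremes.append(cand)
                trend, cand = -1, v
        else:
            if v < cand:
                cand = v
            elif v - cand > sd:  # reversal confirms the nadir
                extremes.append(cand)
                trend, cand = +1, v
    extremes.append(cand)
    amps = np.abs(np.diff(extremes))
    amps = amps[amps > sd]
    return float(amps.mean()) if len(amps) else 0.0


def conga(values: Sequence[float], hours: float = 1.0) -> float:
    """CONGA_n: SD of differences between observations n hours apart."""
    x = np.asarray(values, float)
    lag = int(round(hours * _SAMPLES_PER_HOUR))
    if lag < 1 or lag >= len(x):
        raise ValueError("conga lag must be shorter than the series")
    d = x[lag:] - x[:-lag]
    return float(d.std(ddof=1)) if len(d) > 1 else 0.0


def intra_day_indices(values, conga_hours: float = 1.0) -> GVReport:
    """SD, CV, J-index, MAGE and CONGA_n for one day's trace.

    J-index = 0.001 * (mean + SD)^2 with glucose in mg/dL.
    """
    x = np.asarray(
        values.values if isinstance(values, GlucoseSeries) else values, float
    )
    if len(x) < 2:
        raise ValueError("need at least 2 samples")
    if conga_hours * _SAMPLES_PER_HOUR >= len(x):
        raise ValueError("series too short for requested CONGA window")
    sd = float(x.std(ddof=1))
    mean = float(x.mean())
    return GVReport(
        sd=sd,
        cv=sd / mean,
        j_index=0.001 * (mean + sd) ** 2,
        mage=mage(x),
        conga_n=conga(x, conga_hours),
        conga_hours=conga_hours,
    )


# ---------------------------------------------------------------------------
# inter-day variability
# ---------------------------------------------------------------------------

def _gvi(x: np.ndarray, dt_minutes: float) -> float:
    """Arc length of the trace over the straight chord spanning it."""
    dy = np.diff(x)
    arc = float(np.sum(np.sqrt(dt_minutes ** 2 + dy ** 2)))
    total_t = dt_minutes * (len(x) - 1)
    chord = math.hypot(total_t, float(x[-1] - x[0]))
    return arc / chord if chord > 0 else 1.0


def inter_day_indices(series) -> GVReport:
    """MODD, GVI and PGS for a multi-day trace.

    MODD averages |x_t - x_{t-288}| over all pairs aligned one day apart
    (None when the trace is shorter than 2 days).  GVI is the arc-length
    ratio of the trace (time in minutes, glucose in mg/dL).  PGS = GVI x
    mean glucose x fraction of time *outside* 70-180 mg/dL.
    """
    if isinstance(series, GlucoseSeries):
        x = series.values
        dt = series.sampling_interval
    else:
        x = np.asarray(series, float)
        dt = 5.0
    if len(x) < 2:
        raise ValueError("need at least 2 samples")
    modd = None
    if len(x) >= _SAMPLES_PER_DAY + 1:
        modd = float(np.mean(np.abs(x[_SAMPLES_PER_DAY:] - x[:-_SAMPLES_PER_DAY])))
    gvi = _gvi(x, dt)
    tir = float(np.mean((x >= TIR_LOW) & (x <= TIR_HIGH)))
    pgs = gvi * float(x.mean()) * (1.0 - tir)
    sd = float(x.std(ddof=1))
    mean = float(x.mean())
    return GVReport(
        sd=sd,
        cv=sd / mean,
        j_index=0.001 * (mean + sd) ** 2,
        mage=mage(x),
        conga_n=conga(x) if len(x) > _SAMPLES_PER_HOUR else 0.0,
        conga_hours=1.0,
        modd=modd,
        gvi=gvi,
        pgs=pgs,
    )


def gv_report(series) -> GVReport:
    """Convenience alias: the full variability report for a trace."""
    return inter_day_indices(series)
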