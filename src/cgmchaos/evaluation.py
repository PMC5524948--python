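"""Numerical error metrics and continuous glucose error-grid analysis.

CG-EGA grades each (reference, predicted) pair on two axes and combines
them:

* **Point accuracy (P-EGA)** — a Clarke-style error grid on the glucose
  values, with the zone boundaries expanded by 10 mg/dL in the direction of
  a rapid reference trend (falling faster than 2 mg/dL/min widens the upper
  A/B limits, rising faster than 2 mg/dL/min widens the lower limits), as in
  the continuous error-grid methodology.
* **Rate accuracy (R-EGA)** — an error grid on the rates of change
  (mg/dL/min, finite differences over the sampling interval; one-sided at
  the series ends), with zones A/B around the identity line and C/D/E cells
  for clinically misleading rate readings.

Each axis yields a zone A-E; the pair's combined grade is the more severe
of the two (severity A < B < C < D < E) and zone E collapses into D, giving
the four reported zones: A (no effect on clinical action), B (little or no
effect on clinical outcome), C (possible effect on clinical outcome) and
D (possible significant medical risk).  Results are stratified by the
reference range: hypoglycemia (< 70 mg/dL), euglycemia (70-180) and
hyperglycemia (> 180).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_cgm import GlucoseSeries, HYPO_THRESHOLD, HYPER_THRESHOLD

__all__ = [
    "ErrorReport",
    "CGEGAResult",
    "compute_errors",
    "cg_ega",
    "point_ega_zones",
    "rate_ega_zones",
]

ZONES = ("A", "B", "C", "D")
_SEVERITY = {"A": 0, "B": 1, "C": 2, "D": 3, "E": 4}


@dataclass(frozen=True)
class ErrorReport:
    rmse: float
    mae: float
    mape: float
    n: int
    n_mape_excluded: int = 0

    def to_dict(self) -> dict:
        return {
            "rmse_mgdl": self.rmse,
            "mae_mgdl": self.mae,
            "mape": self.mape,
            "n": self.n,
        }


@dataclass(frozen=True)
class CGEGAResult:
    zone_percent: dict
    per_range: dict
    n_pairs: int

    def to_dict(self) -> dict:
        return {
            "zone_percent": self.zone_percent,
            "per_range": self.per_range,
            "n_pairs": self.n_pairs,
        }


def compute_errors(predicted, actual) -> ErrorReport:
    """RMSE, MAE and MAPE of aligned prediction/reference pairs.

    Pairs whose reference value is zero are excluded from MAPE only; their
    count is reported.
    """
    p = np.asarray(
        predicted.values if isinstance(predicted, GlucoseSeries) else predicted, float
    )
    a = np.asarray(
        actual.values if isinstance(actual, GlucoseSeries) else actual, float
    )
    if p.shape != a.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {a.shape}")
    if len(p) == 0:
        raise ValueError("need at least one pair")
    err = p - a
    rmse = float(np.sqrt(np.mean(err ** 2)))
    mae = float(np.mean(np.abs(err)))
    nz = a != 0
    mape = float(np.mean(np.abs(err[nz] / a[nz]))) if nz.any() else float("nan")
    return ErrorReport(
        rmse=rmse, mae=mae, mape=mape, n=len(p), n_mape_excluded=int((~nz).sum())
    )


# ---------------------------------------------------------------------------
# P-EGA (point accuracy)
# ---------------------------------------------------------------------------

def point_ega_zones(
    reference: np.ndarray, predicted: np.ndarray, ref_rate: np.ndarray | None = None
) -> np.ndarray:
    """Clarke-style point zones A-E with rate-dependent boundary expansion.

    ``ref_rate`` (mg/dL/min) shifts the accepted band by 10 mg/dL upward
    when the reference is falling rapidly (rate < -2) and downward when it
    is rising rapidly (rate > 2), reflecting the sensor/prediction delay
    tolerated by the continuous error-grid methodology.
    """
    r = np.asarray(reference, float)
    p = np.asarray(predicted, float)
    if ref_rate is None:
        ref_rate = np.zeros_like(r)
    up = np.where(ref_rate < -2.0, 10.0, 0.0)    # falling fast: widen upward
    down = np.where(ref_rate > 2.0, 10.0, 0.0)   # rising fast: widen downward

    zones = np.empty(len(r), dtype="<U1")
    for i in range(len(r)):
        ri, pi, ui, di = r[i], p[i], up[i], down[i]
        hi_a = ri * 1.2 + ui
        lo_a = ri * 0.8 - di
        if (lo_a <= pi <= hi_a) or (ri < 70 and pi < 70 + ui):
            zones[i] = "A"
        elif (ri <= 70 and pi >= 180 - di) or (ri >= 180 and pi <= 70 + ui):
            zones[i] = "E"
        elif 70 <= ri <= 290 and pi >= ri + 110 + ui:
            zones[i] = "C"  # upper C: large overestimate
        elif 130 <= ri <= 180 and pi <= (7.0 / 5.0) * ri - 182 - di:
            zones[i] = "C"  # lower C: large underestimate in mid range
        elif ri < 70 <= pi <= 180 + ui:
            zones[i] = "D"  # hypoglycemia read as acceptable
        elif ri > 240 and 70 - di <= pi <= 180:
            zones[i] = "D"  # severe hyperglycemia read as acceptable
        else:
            zones[i] = "B"
    return zones


# ---------------------------------------------------------------------------
# R-EGA (rate accuracy)
# ---------------------------------------------------------------------------

def rate_ega_zones(ref_rate: np.ndarray, pred_rate: np.ndarray) -> np.ndarray:
    """Rate zones A-E on rates clipped to [-4, 4] mg/dL/min.

    A: within 1 mg/dL/min of the reference rate; B: within 2 (or matching an
    extreme rate in direction); C: spurious trend while the reference is
    stable; D: missed trend (prediction stable while the reference moves
    fast); E: opposite directions.
    """
    x = np.clip(np.asarray(ref_rate, float), -4.0, 4.0)
    y = np.clip(np.asarray(pred_rate, float), -4.0, 4.0)
    zones = np.empty(len(x), dtype="<U1")
    for i in range(len(x)):
        xi, yi = x[i], y[i]
        if xi <= -1.0 and yi >= 1.0:
            zones[i] = "E"  # reference falling, prediction rising
        elif xi >= 1.0 and yi <= -1.0:
            zones[i] = "E"  # reference rising, prediction falling
        elif -1.0 <= xi <= 1.0 and yi > xi + 2.0:
            zones[i] = "C"  # spurious rise
        elif -1.0 <= xi <= 1.0 and yi < xi - 2.0:
            zones[i] = "C"  # spurious fall
        elif -1.0 <= yi <= 1.0 and xi > yi + 2.0:
            zones[i] = "D"  # missed rise
        elif -1.0 <= yi <= 1.0 and xi < yi - 2.0:
            zones[i] = "D"  # missed fall
        elif abs(yi - xi) <= 1.0:
            zones[i] = "A"
        else:
            zones[i] = "B"
    return zones


# ---------------------------------------------------------------------------
# combined CG-EGA
# ---------------------------------------------------------------------------

def _rates(values: np.ndarray, dt_minutes: float) -> np.ndarray:
    """Finite-difference rates in mg/dL/min; one-sided at the endpoints."""
    v = np.asarray(values, float)
    out = np.empty(len(v))
    out[0] = (v[1] - v[0]) / dt_minutes
    out[-1] = (v[-1] - v[-2]) / dt_minutes
    if len(v) > 2:
        out[1:-1] = (v[2:] - v[:-2]) / (2.0 * dt_minutes)
    return out


def _percentages(zones: np.ndarray) -> dict:
    n = len(zones)
    return {z: 100.0 * float(np.sum(zones == z)) / n for z in ZONES}


def cg_ega(reference: GlucoseSeries, predicted: GlucoseSeries) -> CGEGAResult:
    """Continuous glucose error-grid analysis of a prediction run.

    Requires aligned series (identical timestamps) of length >= 2.  Returns
    overall zone A-D percentages and the per-range breakdown over the
    reference's hypo/eu/hyper strata.
    """
    if len(reference) != len(predicted) or len(reference) < 2:
        raise ValueError("need aligned series with at least 2 samples")
    if not (reference.timestamps == predicted.timestamps).all():
        raise ValueError("reference and predicted timestamps are misaligned")
    dt = reference.sampling_interval
    ref = reference.values
    pred = predicted.values
    ref_rate = _rates(ref, dt)
    pred_rate = _rates(pred, dt)

    p_zone = point_ega_zones(ref, pred, ref_rate)
    r_zone = rate_ega_zones(ref_rate, pred_rate)
    combined = np.where(
        [_SEVERITY[a] >= _SEVERITY[b] for a, b in zip(p_zone, r_zone)], p_zone, r_zone
    )
    combined = np.where(combined == "E", "D", combined)

    per_range = {}
    strata = {
        "hypo": ref < HYPO_THRESHOLD,
        "eu": (ref >= HYPO_THRESHOLD) & (ref <= HYPER_THRESHOLD),
        "hyper": ref > HYPER_THRESHOLD,
    }
    for name, mask in strata.items():
        if mask.any():
            per_range[name] = _percentages(combined[mask])
    return CGEGAResult(
        zone_percent=_percentages(combined),
        per_range=per_range,
        n_pairs=len(ref),
    )
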