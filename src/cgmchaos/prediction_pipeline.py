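"""End-to-end sliding-window glucose forecasting.

The forecasting loop mirrors the standard workflow for phase-space
prediction of CGM traces:

1. the trailing training window (default 8 h = 96 samples) is transformed
   (log + first differencing) to a variance-stabilized, stationary working
   series, then standardized;
2. the working series is optionally denoised by phase-space neighbourhood
   averaging (delay-1 embedding, radius from the dimension schedule);
3. the embedding dimension is estimated from the training window by Cao's
   method (the delay defaults to one sample; AMI/ACF selection is available
   via ``delay_policy="estimate"``), the window is embedded, and the
   configured model is fitted;
4. one-step predictions are iterated PH/5 times (6 steps for a 30-minute
   horizon, 12 for 60) feeding each prediction back into the delay vector;
5. the predicted increments are inverse-transformed back to mg/dL and
   recorded against the realized value at t + PH.

The model is refit every time the forecast origin advances by one
prediction horizon; between refits the fitted model is reused from the
latest data.  Fitting, parameter estimation and denoising only ever see
samples at or before the forecast origin, so mutating later samples cannot
change a forecast (no look-ahead).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chaos_analysis import (
    EmbeddingSpec,
    average_mutual_information,
    cao_embedding_dimension,
    denoise_phase,
    denoise_radius_for_dimension,
    embed,
    select_delay_acf,
)
from .io_cgm import GlucoseSeries, landmark_of_time
from .regime_models import FittedModel, fit_model, predict_one_step, select_model

__all__ = [
    "PipelineConfig",
    "PredictionResult",
    "TransformState",
    "test_stationarity",
    "transform",
    "inverse_transform",
    "sliding_predict",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Forecasting configuration.

    ``train_hours`` sets the trailing training-window length (8 h = 96
    samples at the 5-minute cadence); ``ph_minutes`` is the prediction
    horizon; ``model_kind`` one of lar/aar/nnar/setar/lstar/auto ("auto"
    fits all five and keeps the minimum-AIC candidate).
    """

    train_hours: float = 8.0
    ph_minutes: int = 30
    model_kind: str = "lstar"
    transform: str = "log"          # {"log", "none"}
    differencing: int = 1
    denoise: bool = True
    max_embedding_dim: int = 4
    max_lag: int = 20
    delay_policy: str = "fixed"     # {"fixed": tau=1, "estimate": AMI/ACF}
    max_rate_mgdl_min: float = 2.0  # physiological rate envelope for forecasts
    seed: int = 0

    def __post_init__(self):
        if self.model_kind.lower() not in ("lar", "aar", "nnar", "setar", "lstar", "auto"):
            raise ValueError(f"unknown model kind {self.model_kind!r}")
        if self.transform not in ("log", "none"):
            raise ValueError("transform must be 'log' or 'none'")
        if self.differencing not in (0, 1):
            raise ValueError("differencing order must be 0 or 1")
        if self.delay_policy not in ("fixed", "estimate"):
            raise ValueError("delay_policy must be 'fixed' or 'estimate'")

    def train_samples(self, sampling_interval: float = 5.0) -> int:
        return int(round(self.train_hours * 60.0 / sampling_interval))

    def ph_steps(self, sampling_interval: float = 5.0) -> int:
        steps, rem = divmod(self.ph_minutes, sampling_interval)
        if rem:
            raise ValueError("ph_minutes must be divisible by the sampling interval")
        return int(steps)


@dataclass(frozen=True)
class TransformState:
    """Everything needed to invert the variance/stationarity transform."""

    kind: str
    differencing: int
    heads: tuple[float, ...]  # initial values consumed by each differencing


@dataclass(frozen=True)
class PredictionResult:
    """Aligned predicted/actual traces plus per-landmark error slices."""

    predicted: GlucoseSeries
    actual: GlucoseSeries
    ph_minutes: int
    landmarks: tuple[str, ...]
    skipped_windows: int = 0

    def per_landmark(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        labels = np.asarray(self.landmarks)
        for label in sorted(set(self.landmarks)):
            mask = labels == label
            out[label] = (self.predicted.values[mask], self.actual.values[mask])
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "timestamp": self.predicted.timestamps,
                "actual_mgdl": self.actual.values,
                "predicted_mgdl": self.predicted.values,
                "ph_minutes": self.ph_minutes,
                "landmark": list(self.landmarks),
            }
        )


# ---------------------------------------------------------------------------
# stationarity and transforms
# ---------------------------------------------------------------------------

def test_stationarity(series, significance: float = 0.05) -> tuple[float, float, bool]:
    """Augmented Dickey-Fuller test (AIC lag selection).

    Returns ``(statistic, p_value, is_stationary)`` with stationarity
    declared when the unit-root null is rejected at ``significance``.
    """
    from statsmodels.tsa.stattools import adfuller

    x = np.asarray(
        series.values if isinstance(series, GlucoseSeries) else series, float
    )
    if len(x) < 20:
        raise ValueError("need at least 20 samples for the ADF test")
    if np.ptp(x) == 0:
        warnings.warn("constant series: ADF degenerate, reported non-stationary")
        return float("nan"), 1.0, False
    stat, pvalue, *_ = adfuller(x, autolag="AIC")
    return float(stat), float(pvalue), bool(pvalue < significance)


def transform(values, kind: str = "log", differencing: int = 1) -> tuple[np.ndarray, TransformState]:
    """Variance-stabilizing log transform followed by differencing.

    The returned state retains the leading values consumed by each
    differencing pass so :func:`inverse_transform` is exact.
    """
    x = np.asarray(
        values.values if isinstance(values, GlucoseSeries) else values, float
    )
    if kind == "log":
        if (x <= 0).any():
            raise ValueError("log transform requires positive values")
        x = np.log(x)
    elif kind != "none":
        raise ValueError("kind must be 'log' or 'none'")
    heads = []
    for _ in range(differencing):
        heads.append(float(x[0]))
        x = np.diff(x)
    return x, TransformState(kind=kind, differencing=differencing, heads=tuple(heads))


def inverse_transform(working: np.ndarray, state: TransformState) -> np.ndarray:
    """Exact inverse of :func:`transform`."""
    x = np.asarray(working, float)
    for head in reversed(state.heads):
        x = np.concatenate([[head], head + np.cumsum(x)])
    if state.kind == "log":
        x = np.exp(x)
    return x


def _continue_transformed(
    future_working: np.ndarray, last_level: float, state: TransformState
) -> np.ndarray:
    """Map predicted working-scale increments to mg/dL continuing a trace.

    ``last_level`` is the last observed glucose value (mg/dL); the predicted
    increments are accumulated on the transformed scale from that anchor.
    """
    if state.kind == "log":
        anchor = np.log(last_level)
    else:
        anchor = last_level
    if state.differencing == 0:
        levels = np.asarray(future_working, float)
    else:
        levels = anchor + np.cumsum(future_working)
    if state.kind == "log":
        levels = np.exp(levels)
    return levels


# ---------------------------------------------------------------------------
# sliding-window forecasting
# ---------------------------------------------------------------------------

def _estimate_spec(work: np.ndarray, config: PipelineConfig, linear: bool) -> EmbeddingSpec:
    """(m, tau) from the training window.

    The embedding dimension comes from Cao's method on the window.  The
    delay is fixed at 1 sample under the default policy: a 5-min-sampled
    glucose trace is heavily oversampled relative to its ~hours-scale
    oscillations, and iterated short-horizon forecasts degrade sharply when
    the delay vector spans more than the horizon itself.  The AMI/ACF
    estimate (``delay_policy="estimate"``) remains available for dynamical
    characterization-style embeddings.
    """
    n = len(work)
    max_lag = int(min(config.max_lag, n // 4))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if config.delay_policy == "fixed":
            tau = 1
        elif linear:
            tau = select_delay_acf(work, max_lag=max(max_lag, 2))
        else:
            _, tau = average_mutual_information(work, max_lag=max(max_lag, 2))
        tau = max(1, min(tau, max(1, (n - 4) // config.max_embedding_dim)))
        m_max = min(config.max_embedding_dim, max(2, (n - 2) // max(tau, 1) - 1))
        try:
            m, _ = cao_embedding_dimension(work, tau=tau, m_max=m_max)
        except ValueError:
            m = 2
    m = int(np.clip(m, 2, config.max_embedding_dim))
    return EmbeddingSpec(m=m, tau=tau)


def _fit_window(train_values: np.ndarray, config: PipelineConfig) -> tuple[FittedModel, TransformState, float, float]:
    """Fit the configured model on one training window.

    Returns (model, transform state, working mean, working sd); the model is
    fitted on the standardized working series.
    """
    work, state = transform(train_values, config.transform, config.differencing)
    mu = float(work.mean())
    sd = float(work.std()) or 1.0
    work = (work - mu) / sd

    kind = config.model_kind.lower()
    linear = kind == "lar"
    spec = _estimate_spec(work, config, linear=linear)

    fit_series = work
    if config.denoise:
        radius = denoise_radius_for_dimension(spec.m)
        fit_series = denoise_phase(work, m=spec.m, radius=radius)

    matrix = embed(fit_series, spec)
    kwargs_by_kind = {"nnar": {"seed": config.seed}}
    if kind == "auto":
        candidates = []
        for k in ("lar", "aar", "nnar", "setar", "lstar"):
            try:
                candidates.append(
                    fit_model(matrix, k, **kwargs_by_kind.get(k, {}))
                )
            except Exception:
                continue
        if not candidates:
            raise RuntimeError("no model could be fitted on this window")
        model = select_model(candidates)
    else:
        model = fit_model(matrix, kind, **kwargs_by_kind.get(kind, {}))
    return model, state, mu, sd


def _iterate_forecast(
    model: FittedModel,
    work: np.ndarray,
    steps: int,
    bounds: tuple[float, float] | None = None,
) -> np.ndarray:
    """Iterated one-step forecasts on the (standardized) working scale.

    Each prediction is clipped to ``bounds`` (the training window's observed
    range, slightly widened) before being fed back: iterating a fitted
    nonlinear map outside the region it was trained on can diverge, and no
    admissible forecast leaves the attractor's observed range anyway.
    """
    m, tau = model.spec.m, model.spec.tau
    buf = list(work)
    out = np.empty(steps)
    for s in range(steps):
        vec = np.array([buf[-1 - (m - 1 - j) * tau] for j in range(m)])
        nxt = predict_one_step(model, vec)
        if bounds is not None:
            nxt = float(np.clip(nxt, bounds[0], bounds[1]))
        out[s] = nxt
        buf.append(nxt)
    return out


def sliding_predict(series: GlucoseSeries, config: PipelineConfig) -> PredictionResult:
    """Continuously forecast ``config.ph_minutes`` ahead along the series.

    For every origin t from the end of the initial training window to
    ``len(series) - steps - 1``, the trailing ``train_samples`` window (data
    up to and including t only) is used to fit/refresh the model, one-step
    predictions are iterated ``steps`` times, and the PH-ahead prediction is
    recorded against the realized value at t + steps.  The model is refit
    whenever the origin has advanced by one horizon since the last fit.
    """
    if not series.is_contiguous:
        raise ValueError(
            "series has gaps; split into contiguous segments before forecasting"
        )
    dt = series.sampling_interval
    steps = config.ph_steps(dt)
    train_n = config.train_samples(dt)
    values = series.values
    n = len(values)
    if n < train_n + steps + 1:
        raise ValueError(
            f"series of length {n} too short: needs >= {train_n + steps + 1} samples"
        )

    preds: list[float] = []
    actuals: list[float] = []
    stamps: list = []
    landmarks: list[str] = []
    skipped = 0

    model = None
    state = None
    mu = sd = 0.0
    last_fit_origin = None

    for origin in range(train_n - 1, n - steps):
        window = values[origin - train_n + 1 : origin + 1]
        if model is None or origin - last_fit_origin >= steps:
            try:
                model, state, mu, sd = _fit_window(window, config)
                last_fit_origin = origin
            except Exception:
                skipped += 1
                if model is None:
                    continue
        # working series from the CURRENT trailing window (observed data only;
        # denoising here sees nothing beyond the forecast origin)
        work, state_now = transform(window, config.transform, config.differencing)
        work = (work - mu) / sd
        if config.denoise:
            radius = denoise_radius_for_dimension(model.spec.m)
            work = denoise_phase(work, m=model.spec.m, radius=radius)
        span = model.spec.span
        if len(work) < span:
            skipped += 1
            continue
        pad = 0.5 * (work.max() - work.min())
        bounds = (work.min() - pad, work.max() + pad)
        fut = _iterate_forecast(model, work, steps, bounds=bounds)
        fut = fut * sd + mu  # back to the raw working scale
        levels = _continue_transformed(fut, float(values[origin]), state_now)
        # physiological rate envelope: glucose rarely moves faster than
        # ~2 mg/dL/min, so a PH-ahead forecast cannot leave that cone
        cap = config.max_rate_mgdl_min * dt * steps
        lo = max(values[origin] - cap, 1.0)
        hi = min(values[origin] + cap, 1000.0)
        pred = float(np.clip(levels[-1], lo, hi))
        target_idx = origin + steps
        preds.append(pred)
        actuals.append(float(values[target_idx]))
        ts = series.timestamps[target_idx]
        stamps.append(ts)
        landmarks.append(landmark_of_time(ts.time()))

    predicted = GlucoseSeries(pd.DatetimeIndex(stamps), np.array(preds), dt)
    actual = GlucoseSeries(pd.DatetimeIndex(stamps), np.array(actuals), dt)
    return PredictionResult(
        predicted=predicted,
        actual=actual,
        ph_minutes=config.ph_minutes,
        landmarks=tuple(landmarks),
        skipped_windows=skipped,
    )
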