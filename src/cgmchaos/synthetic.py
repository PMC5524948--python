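"""Synthetic fixtures: canonical chaotic systems and realistic CGM traces.

Two kinds of generators live here.

``generate_chaotic_benchmark`` produces trajectories of textbook chaotic
systems (logistic map, Henon map, the x-component of the Lorenz flow) whose
invariants (largest Lyapunov exponent, correlation dimension) are known, so
the nonlinear-analysis code can be validated against closed-form or published
values.

``simulate_cgm`` emulates several days of 5-minute subcutaneous glucose
monitoring.  No public patient CGM data accompanies this package, so the
generator stands in for it: the deterministic core is a time-rescaled Lorenz
x-component (chaotic, smooth on the hour scale), circadian structure comes
from meal excursions at configurable clock times, hypo- and hyper-glycemic
exposure are controlled by two severity knobs, and sensor error is additive
truncated-Gaussian noise.  It is a *statistical* stand-in: it reproduces the
sampling cadence, circadian landmarks, chaotic determinism and risk strata of
real CGM traces, not insulin-glucose physiology.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .io_cgm import GlucoseSeries

__all__ = [
    "SimulationConfig",
    "SimulationError",
    "generate_chaotic_benchmark",
    "simulate_cgm",
    "RISK_PRESETS",
]

SAMPLES_PER_DAY = 288  # 5-minute cadence


class SimulationError(RuntimeError):
    """Trajectory diverged (non-finite values)."""


# ---------------------------------------------------------------------------
# canonical chaotic benchmarks
# ---------------------------------------------------------------------------

def _logistic(n: int, r: float, x0: float, burn_in: int) -> np.ndarray:
    x = x0
    out = np.empty(n)
    for i in range(-burn_in, n):
        if i >= 0:
            out[i] = x
        x = r * x * (1.0 - x)
    return out


def _henon(n: int, a: float, b: float, x0: float, y0: float, burn_in: int) -> np.ndarray:
    x, y = x0, y0
    out = np.empty(n)
    for i in range(-burn_in, n):
        x, y = 1.0 - a * x * x + y, b * x
        if i >= 0:
            out[i] = x
    return out


def _lorenz_x(
    n: int,
    sigma: float,
    rho: float,
    beta: float,
    x0: tuple[float, float, float],
    dt: float,
    burn_in: int,
) -> np.ndarray:
    def rhs(_, s):
        x, y, z = s
        return [sigma * (y - x), x * (rho - z) - y, x * y - beta * z]

    t_end = (burn_in + n - 1) * dt
    t_eval = np.arange(burn_in, burn_in + n) * dt
    sol = solve_ivp(
        rhs, (0.0, t_end), list(x0), t_eval=t_eval,
        rtol=1e-9, atol=1e-9, dense_output=False, method="RK45",
    )
    if not sol.success:
        raise SimulationError(f"Lorenz integration failed: {sol.message}")
    return sol.y[0]


def generate_chaotic_benchmark(
    system: str,
    n: int,
    params: dict | None = None,
    seed: int | None = None,
    x0=None,
    burn_in: int = 1000,
) -> np.ndarray:
    """Deterministic scalar trajectory of a canonical chaotic system.

    Parameters
    ----------
    system
        ``"logistic"`` (x' = r x (1-x), default r=4),
        ``"henon"`` (x' = 1 - a x^2 + y, y' = b x; a=1.4, b=0.3),
        ``"lorenz_x"`` (x-component of the Lorenz flow; sigma=10, rho=28,
        beta=8/3, sampled every ``dt`` time units, default 0.05).
    n
        Output length after discarding ``burn_in`` transient steps.
    seed
        Only used to draw a random initial state when ``x0`` is None; the
        trajectory itself is deterministic.
    burn_in
        Transient steps discarded so invariant statistics stabilize.
        Use 0 to start exactly at ``x0``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    params = dict(params or {})
    rng = np.random.default_rng(seed)
    if system == "logistic":
        r = params.get("r", 4.0)
        start = float(rng.uniform(0.1, 0.9)) if x0 is None else float(x0)
        out = _logistic(n, r, start, burn_in)
    elif system == "henon":
        a = params.get("a", 1.4)
        b = params.get("b", 0.3)
        if x0 is None:
            start = (float(rng.uniform(-0.1, 0.1)), float(rng.uniform(-0.1, 0.1)))
        else:
            start = (float(x0[0]), float(x0[1]))
        out = _henon(n, a, b, start[0], start[1], burn_in)
    elif system == "lorenz_x":
        sigma = params.get("sigma", 10.0)
        rho = params.get("rho", 28.0)
        beta = params.get("beta", 8.0 / 3.0)
        dt = params.get("dt", 0.05)
        if x0 is None:
            start = tuple(rng.uniform(-10, 10, 3))
        else:
            start = tuple(float(v) for v in x0)
        out = _lorenz_x(n, sigma, rho, beta, start, dt, burn_in)
    else:
        raise ValueError(f"unknown benchmark system: {system!r}")
    if not np.isfinite(out).all():
        raise SimulationError(f"{system} trajectory diverged")
    return out


# ---------------------------------------------------------------------------
# synthetic CGM traces
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationConfig:
    """Configuration of the synthetic CGM generator.

    ``hypo_intensity`` and ``hyper_intensity`` are dimensionless severity
    knobs in [0, 1]: 0 disables the respective excursions (no reading below
    70 mg/dL when ``hypo_intensity`` is 0) and increasing values deepen
    nocturnal/post-absorptive dips (raising LGI) or amplify and prolong meal
    excursions (raising HGI).
    """

    days: int = 5
    seed: int = 0
    noise_sd: float = 5.0          # mg/dL sensor noise, truncated at 3 SD
    meal_times: tuple[float, ...] = (7.5, 12.75, 19.0)  # clock hours
    basal_level: float = 130.0     # mg/dL fasting baseline
    hypo_intensity: float = 0.0
    hyper_intensity: float = 0.0
    chaos_amplitude: float = 22.0  # mg/dL scale of the chaotic core
    start: str = "2024-01-01 00:00:00"

    def __post_init__(self):
        if self.days < 1:
            raise ValueError("days must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for knob in (self.hypo_intensity, self.hyper_intensity):
            if not 0.0 <= knob <= 1.0:
                raise ValueError("intensity knobs must lie in [0, 1]")


def _meal_pulse(hours_since: np.ndarray, amplitude: float, t_peak: float = 1.3) -> np.ndarray:
    """Gamma-like post-prandial excursion peaking ``t_peak`` hours after a meal."""
    h = np.clip(hours_since, 0.0, None)
    return amplitude * (h / t_peak) * np.exp(1.0 - h / t_peak)


def _dip_pulse(hours_since: np.ndarray, depth: float, t_peak: float = 1.2) -> np.ndarray:
    h = np.clip(hours_since, 0.0, None)
    return -depth * (h / t_peak) * np.exp(1.0 - h / t_peak)


def simulate_cgm(config: SimulationConfig) -> GlucoseSeries:
    """Simulate ``days`` x 288 five-minute glucose samples.

    The trace is the sum of

    * the fasting baseline ``basal_level``,
    * a chaotic core: Lorenz x-component rescaled so one Lorenz time unit
      spans six hours of clock time, normalized and scaled to
      ``chaos_amplitude`` mg/dL,
    * post-prandial excursions at each meal time (amplitude grows with
      ``hyper_intensity``, which also adds a sustained upward shift),
    * post-absorptive/nocturnal dips scaled by ``hypo_intensity``,
    * additive Gaussian sensor noise truncated at +/-3 SD.

    With ``hypo_intensity`` = 0 a counter-regulatory floor keeps every value
    at or above 70 mg/dL; all values are clipped to the physical (20, 500)
    band.  Identical configs (same seed) produce bit-identical output.
    """
    n = config.days * SAMPLES_PER_DAY
    rng = np.random.default_rng(config.seed)
    # noise drawn FIRST so the draw stream is identical across intensity
    # settings with the same seed (keeps intensity comparisons paired)
    noise = rng.normal(0.0, 1.0, n)
    np.clip(noise, -3.0, 3.0, out=noise)
    noise *= config.noise_sd

    hours = np.arange(n) * (5.0 / 60.0)  # hours since start (midnight)
    clock = hours % 24.0

    # one Lorenz time unit spans 6 h of clock time, so the attractor's
    # ~0.75-unit pseudo-period maps to ~4.5 h and the core's rate of change
    # stays well inside the ~2 mg/dL/min envelope of real glycemic excursions
    core = generate_chaotic_benchmark(
        "lorenz_x", n=n, params={"dt": 1.0 / 72.0}, seed=config.seed, burn_in=500
    )
    core = (core - core.mean()) / core.std()
    core *= config.chaos_amplitude

    meals = np.zeros(n)
    meal_amp = 45.0 + 70.0 * config.hyper_intensity
    for day in range(config.days):
        for mt in config.meal_times:
            meals += _meal_pulse(hours - (day * 24.0 + mt), meal_amp, t_peak=1.3)
    sustained = 25.0 * config.hyper_intensity  # upward shift of the whole day

    dips = np.zeros(n)
    if config.hypo_intensity > 0:
        depth = 20.0 + 60.0 * config.hypo_intensity
        for day in range(config.days):
            # nocturnal dip (~03:00) and a late-afternoon post-absorptive dip
            dips += _dip_pulse(hours - (day * 24.0 + 2.0), depth, t_peak=1.5)
            dips += _dip_pulse(hours - (day * 24.0 + 16.5), 0.7 * depth, t_peak=1.0)

    values = config.basal_level + core + meals + sustained + dips + noise
    if config.hypo_intensity == 0.0:
        values = np.maximum(values, 70.0)  # counter-regulatory floor
    values = np.clip(values, 20.5, 499.5)
    if not np.isfinite(values).all():  # pragma: no cover
        raise SimulationError("CGM simulation produced non-finite values")

    timestamps = pd.date_range(config.start, periods=n, freq="5min")
    return GlucoseSeries(timestamps, values, sampling_interval=5.0)


# Preset configurations reaching the documented risk strata
# (hypo: minimal/low/moderate/high LGI; hyper: low/moderate/high HGI).
RISK_PRESETS: dict[str, SimulationConfig] = {
    "hypo_minimal": SimulationConfig(hypo_intensity=0.0, hyper_intensity=0.0),
    "hypo_low": SimulationConfig(hypo_intensity=0.75, hyper_intensity=0.0),
    "hypo_moderate": SimulationConfig(hypo_intensity=0.85, hyper_intensity=0.0,
                                      basal_level=120.0),
    "hypo_high": SimulationConfig(hypo_intensity=1.0, hyper_intensity=0.0,
                                  basal_level=110.0),
    "hyper_low": SimulationConfig(hypo_intensity=0.0, hyper_intensity=0.0),
    "hyper_moderate": SimulationConfig(hypo_intensity=0.0, hyper_intensity=0.5),
    "hyper_high": SimulationConfig(hypo_intensity=0.0, hyper_intensity=1.0,
                                   basal_level=160.0),
}
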