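"""Nonlinear characterization and phase-space machinery.

Implements the delay-coordinate toolchain for scalar time series:

* time-delay selection by average mutual information (first local minimum)
  or by the autocorrelation function (first drop below 1/e),
* embedding-dimension selection by Cao's method,
* Takens delay embedding and its exact inverse (series reconstruction),
* phase-space denoising by local neighbourhood averaging,
* Grassberger-Procaccia correlation dimension with Theiler exclusion,
* largest Lyapunov exponent by the Rosenstein divergence-curve method,
* recurrence matrices.

Conventions: natural logarithms throughout; the Lyapunov exponent is
reported per sample step; distances are Euclidean unless stated (Cao's
statistic uses the maximum norm, as in the original method).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "EmbeddingSpec",
    "PhaseMatrix",
    "ChaosReport",
    "average_mutual_information",
    "select_delay_acf",
    "cao_embedding_dimension",
    "embed",
    "reconstruct_series",
    "denoise_phase",
    "denoise_radius_for_dimension",
    "correlation_dimension",
    "lyapunov_exponent",
    "recurrence_matrix",
    "characterize",
]


@dataclass(frozen=True)
class EmbeddingSpec:
    """Delay-embedding parameters: dimension ``m`` and delay ``tau`` (samples)."""

    m: int
    tau: int = 1

    def __post_init__(self):
        if self.m < 1 or self.tau < 1:
            raise ValueError("embedding requires m >= 1 and tau >= 1")

    @property
    def span(self) -> int:
        """Number of samples covered by one delay vector: (m-1)*tau + 1."""
        return (self.m - 1) * self.tau + 1


@dataclass(frozen=True)
class PhaseMatrix:
    """Matrix of delay vectors; row t is [x_t, x_{t+tau}, ..., x_{t+(m-1)tau}]."""

    data: np.ndarray
    source_length: int
    spec: EmbeddingSpec

    @property
    def n_vectors(self) -> int:
        return self.data.shape[0]

    @property
    def m(self) -> int:
        return self.spec.m

    @property
    def tau(self) -> int:
        return self.spec.tau


@dataclass(frozen=True)
class ChaosReport:
    """Summary of a series' nonlinear characterization."""

    spec: EmbeddingSpec
    correlation_dimension: float
    d2_confident: bool
    lyapunov: float
    ami_profile: np.ndarray = field(repr=False)
    cao_e1_profile: np.ndarray = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "embedding_dimension": self.spec.m,
            "time_delay": self.spec.tau,
            "correlation_dimension": self.correlation_dimension,
            "d2_confident": self.d2_confident,
            "lyapunov_per_step": self.lyapunov,
            "ami_profile": [float(v) for v in self.ami_profile],
            "cao_e1_profile": [float(v) for v in self.cao_e1_profile],
        }


# ---------------------------------------------------------------------------
# delay selection
# ---------------------------------------------------------------------------

def _fd_bins(x: np.ndarray) -> int:
    """Freedman-Diaconis bin count, clamped to [4, 64]."""
    x = np.asarray(x, float)
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    if iqr <= 0:
        return 4
    width = 2 * iqr / len(x) ** (1 / 3)
    span = x.max() - x.min()
    if width <= 0 or span <= 0:
        return 4
    return int(np.clip(np.ceil(span / width), 4, 64))


def average_mutual_information(
    series, max_lag: int = 50, bins: int | None = None
) -> tuple[np.ndarray, int]:
    """AMI profile over lags 0..max_lag and the selected delay.

    AMI(tau) = sum_ij p_ij log(p_ij / (p_i p_j)) from the joint histogram of
    (x_t, x_{t+tau}), in nats.  The selected delay is the first local minimum
    of the profile; if none occurs within ``max_lag`` the lag with the
    smallest AMI is returned with a warning.  Bin count defaults to
    Freedman-Diaconis on the series.
    """
    x = np.asarray(series, float)
    n = len(x)
    if n <= max_lag + 1:
        raise ValueError("series too short for requested max_lag")
    if x.max() == x.min():
        warnings.warn("constant series: AMI identically 0, delay defaults to 1")
        return np.zeros(max_lag + 1), 1
    if bins is None:
        bins = _fd_bins(x)
    edges = np.linspace(x.min(), x.max(), bins + 1)
    edges[-1] += 1e-12
    profile = np.empty(max_lag + 1)
    for lag in range(max_lag + 1):
        a = x[: n - lag]
        b = x[lag:]
        joint, _, _ = np.histogram2d(a, b, bins=[edges, edges])
        pij = joint / joint.sum()
        pi = pij.sum(axis=1)
        pj = pij.sum(axis=0)
        mask = pij > 0
        denom = np.outer(pi, pj)[mask]
        profile[lag] = float(np.sum(pij[mask] * np.log(pij[mask] / denom)))
    # first local minimum over lags >= 1
    tau = None
    for lag in range(1, max_lag):
        if profile[lag] < profile[lag - 1] and profile[lag] <= profile[lag + 1]:
            tau = lag
            break
    if tau is None:
        tau = int(np.argmin(profile[1:]) + 1)
        warnings.warn("no local AMI minimum within max_lag; using global minimum")
    return profile, tau


def select_delay_acf(series, max_lag: int = 50) -> int:
    """Smallest lag where the autocorrelation first falls below 1/e.

    Used for linear models; nonlinear models use the AMI criterion.
    """
    from statsmodels.tsa.stattools import acf

    x = np.asarray(series, float)
    if len(x) <= max_lag + 1:
        raise ValueError("series too short for requested max_lag")
    rho = acf(x, nlags=max_lag, fft=True)
    below = np.nonzero(rho[1:] < 1.0 / np.e)[0]
    if len(below) == 0:
        warnings.warn("ACF never drops below 1/e within max_lag")
        return max_lag
    return int(below[0] + 1)


# ---------------------------------------------------------------------------
# embedding dimension (Cao's method)
# ---------------------------------------------------------------------------

def cao_embedding_dimension(
    series,
    tau: int = 1,
    m_max: int = 10,
    threshold: float = 0.90,
) -> tuple[int, np.ndarray]:
    """Minimal embedding dimension by Cao's method.

    For each trial dimension m, a(i, m) is the maximum-norm distance ratio
    between each point and its nearest neighbour after extending both vectors
    to dimension m+1; E(m) is the mean of a(i, m) and E1(m) = E(m+1)/E(m).
    The selected m is the smallest dimension at which E1 exceeds ``threshold``
    and stays above it for the next step (saturation).

    Noise is detected with Cao's companion statistic E2(m): for stochastic
    input E2 stays ~1 at every m, whereas deterministic signals show
    m-dependence.  When E2 never departs from 1 (and also when E1 never
    saturates) ``m_max`` is returned with a warning.

    Neighbours at (near-)machine-precision distance — exact recurrences of a
    noiseless periodic signal, repeated values — are skipped so the ratio
    statistics are not dominated by rounding noise.

    Returns ``(m, e1_profile)`` where ``e1_profile[k]`` is E1(k+1).
    """
    x = np.asarray(series, float)
    if len(x) < (m_max + 1) * tau + 2:
        raise ValueError("series too short for m_max and tau")
    span = np.ptp(x)
    floor = 1e-9 * (span if span > 0 else 1.0)
    E = np.empty(m_max + 1)       # E[k-1] holds E(k) for k = 1..m_max+1
    E_star = np.empty(m_max + 1)  # companion statistic for E2
    for m in range(1, m_max + 2):
        Y = _delay_matrix(x, m, tau)
        Y1 = _delay_matrix(x, m + 1, tau)
        n1 = Y1.shape[0]
        Y = Y[:n1]  # align so every point has an (m+1)-dim extension
        tree = cKDTree(Y)
        dist, idx = tree.query(Y, k=2, p=np.inf)
        d_m = dist[:, 1]
        nn = idx[:, 1]
        # duplicates / exact recurrences: fall back to a genuine neighbour
        dup = np.nonzero(d_m <= floor)[0]
        if len(dup):
            kmax = min(32, n1)
            dist_k, idx_k = tree.query(Y[dup], k=kmax, p=np.inf)
            for where, drow, irow in zip(dup, np.atleast_2d(dist_k), np.atleast_2d(idx_k)):
                pos = np.nonzero(drow > floor)[0]
                if len(pos):
                    d_m[where] = drow[pos[0]]
                    nn[where] = irow[pos[0]]
        valid = d_m > floor
        if valid.sum() < 10:
            raise ValueError("too few distinct delay vectors for Cao's method")
        d_m1 = np.abs(Y1[valid] - Y1[nn[valid]]).max(axis=1)
        E[m - 1] = np.mean(d_m1 / d_m[valid])
        E_star[m - 1] = np.mean(np.abs(Y1[valid][:, -1] - Y1[nn[valid]][:, -1]))
    e1 = E[1:] / E[:-1]  # e1[j] = E1(j+1) = E(j+2)/E(j+1)
    with np.errstate(divide="ignore", invalid="ignore"):
        e2 = E_star[1:] / E_star[:-1]
    noise_like = np.all(np.abs(e2[np.isfinite(e2)] - 1.0) < 0.1) if np.isfinite(e2).any() else False
    selected = None
    if not noise_like:
        for j in range(len(e1) - 1):
            if e1[j] >= threshold and e1[j + 1] >= threshold:
                selected = j + 1
                break
    if selected is None:
        warnings.warn(
            "Cao's statistics did not saturate: noise-like input, returning m_max"
        )
        selected = m_max
    return selected, e1


def _delay_matrix(x: np.ndarray, m: int, tau: int) -> np.ndarray:
    n = len(x) - (m - 1) * tau
    if n < 1:
        raise ValueError(
            f"series of length {len(x)} too short to embed with m={m}, tau={tau}"
            f" (needs >= {(m - 1) * tau + 1})"
        )
    idx = np.arange(n)[:, None] + tau * np.arange(m)[None, :]
    return x[idx]


# ---------------------------------------------------------------------------
# embedding and exact reconstruction
# ---------------------------------------------------------------------------

def embed(series, spec: EmbeddingSpec) -> PhaseMatrix:
    """Takens delay embedding: T = n - (m-1)*tau rows of lagged coordinates."""
    x = np.asarray(series, float)
    data = _delay_matrix(x, spec.m, spec.tau)
    return PhaseMatrix(data=data, source_length=len(x), spec=spec)


def reconstruct_series(matrix: PhaseMatrix) -> np.ndarray:
    """Invert :func:`embed` exactly.

    The first column of the phase matrix supplies x_0..x_{T-1}; the remaining
    (m-1)*tau trailing observations are read off the later columns of the
    final rows: x_{T-1+j} = row (T-1) column j//tau shifted — concretely,
    sample index i >= T equals ``data[T-1, :][i - (T-1)]`` when tau = 1, and
    in general comes from column ``c = ceil((i - T + 1)/tau)`` of row
    ``i - c*tau``.  Total length is T + (m-1)*tau, the original series length.
    """
    data = matrix.data
    T, m = data.shape
    tau = matrix.tau
    if m > 1 and T < tau:
        # with fewer rows than the delay, samples at indices T..tau-1 never
        # enter the matrix: the embedding is not invertible
        raise ValueError(
            f"cannot reconstruct: {T} vectors < tau={tau}; "
            "the delay matrix does not cover every sample"
        )
    n = T + (m - 1) * tau
    out = np.empty(n)
    out[:T] = data[:, 0]
    for i in range(T, n):
        c = -(-(i - T + 1) // tau)  # ceil division
        out[i] = data[i - c * tau, c]
    return out


# ---------------------------------------------------------------------------
# phase-space denoising
# ---------------------------------------------------------------------------

def denoise_radius_for_dimension(m: int, low: float = 0.2, high: float = 1e-4) -> float:
    """Neighbourhood radius schedule on standardized data.

    Low embedding dimensions (m <= 4) use the large radius 0.2; high
    dimensions (m >= 8) the small radius 1e-4; log-interpolated between.
    """
    if m <= 4:
        return low
    if m >= 8:
        return high
    frac = (m - 4) / 4.0
    return float(np.exp(np.log(low) + frac * (np.log(high) - np.log(low))))


def denoise_phase(series, m: int, radius: float) -> np.ndarray:
    """Average each delay-1 Takens vector with its neighbours within ``radius``.

    The series is embedded with delay 1 in an m-dimensional space; each vector
    is replaced by the mean of all vectors (itself included) within Euclidean
    distance ``radius``; the series is rebuilt by averaging the overlapping
    coordinates of the smoothed vectors.  ``radius`` is interpreted on the
    scale of the data passed in (standardize first to use the default
    schedule).  Radius 0 returns the input unchanged.
    """
    x = np.asarray(series, float)
    if radius < 0:
        raise ValueError("radius must be nonnegative")
    if radius == 0 or len(x) < m:
        return x.copy()
    Y = _delay_matrix(x, m, 1)
    tree = cKDTree(Y)
    neighbours = tree.query_ball_point(Y, r=radius)
    smoothed = np.vstack([Y[nb].mean(axis=0) for nb in neighbours])
    # overlap-average back to a series
    out = np.zeros(len(x))
    counts = np.zeros(len(x))
    T = Y.shape[0]
    for j in range(m):
        out[j : j + T] += smoothed[:, j]
        counts[j : j + T] += 1
    return out / counts


# ---------------------------------------------------------------------------
# correlation dimension (Grassberger-Procaccia)
# ---------------------------------------------------------------------------

def correlation_sum(
    vectors: np.ndarray, radii: np.ndarray, theiler: int = 0
) -> np.ndarray:
    """C(r): fraction of pairs (i, j), |i-j| > theiler, within distance r."""
    n = vectors.shape[0]
    d2 = []
    block = 512
    for start in range(0, n, block):
        stop = min(start + block, n)
        diff = vectors[start:stop, None, :] - vectors[None, :, :]
        dist = np.sqrt((diff ** 2).sum(axis=2))
        ii = np.arange(start, stop)[:, None]
        jj = np.arange(n)[None, :]
        mask = (jj - ii) > theiler  # upper triangle with temporal exclusion
        d2.append(dist[mask])
    dists = np.concatenate(d2)
    total = len(dists)
    if total == 0:
        raise ValueError("no admissible pairs: series too short for theiler window")
    return np.array([(dists <= r).sum() / total for r in radii])


def correlation_dimension(
    series,
    spec: EmbeddingSpec,
    theiler: int | None = None,
    n_radii: int = 32,
    max_vectors: int = 2500,
) -> tuple[float, bool]:
    """Grassberger-Procaccia D2 estimate.

    The correlation sum C(r) is computed over log-spaced radii between small
    and mid quantiles of the pairwise distances (with a Theiler window,
    default tau*m samples, excluding temporally close pairs).  D2 is the
    least-squares slope of log C vs log r over the most linear contiguous
    scaling window (minimum local-slope variance).  Returns ``(d2, confident)``
    where ``confident`` is False when no stable scaling region was found.
    """
    x = np.asarray(series, float)
    Y = _delay_matrix(x, spec.m, spec.tau)
    if Y.shape[0] > max_vectors:
        # deterministic thinning preserves attractor geometry
        stride = Y.shape[0] / max_vectors
        Y = Y[(np.arange(max_vectors) * stride).astype(int)]
    if theiler is None:
        theiler = spec.m * spec.tau
    n = Y.shape[0]
    if n < 50:
        raise ValueError("too few vectors for a correlation-dimension estimate")
    # distance scale from a sample of pairs
    rng = np.random.default_rng(0)
    ii = rng.integers(0, n, 4000)
    jj = rng.integers(0, n, 4000)
    keep = np.abs(ii - jj) > theiler
    sample = np.sqrt(((Y[ii[keep]] - Y[jj[keep]]) ** 2).sum(axis=1))
    sample = sample[sample > 0]
    r_lo, r_hi = np.quantile(sample, [0.005, 0.5])
    radii = np.exp(np.linspace(np.log(r_lo), np.log(r_hi), n_radii))
    C = correlation_sum(Y, radii, theiler=theiler)
    good = C > 0
    logr = np.log(radii[good])
    logC = np.log(C[good])
    return _scaling_region_slope(logr, logC)


def _scaling_region_slope(
    logr: np.ndarray, logC: np.ndarray, min_window: int = 8
) -> tuple[float, bool]:
    """Slope over the contiguous window with the most stable local slope."""
    k = len(logr)
    if k < min_window:
        slope = np.polyfit(logr, logC, 1)[0] if k >= 2 else np.nan
        return float(slope), False
    local = np.diff(logC) / np.diff(logr)
    best = None
    for w in range(min_window, k):
        for start in range(0, k - w):
            seg = local[start : start + w - 1]
            score = seg.std() / max(np.abs(seg.mean()), 1e-12)
            # prefer longer windows at comparable flatness
            score /= np.sqrt(w)
            if best is None or score < best[0]:
                best = (score, start, w)
    _, start, w = best
    slope = np.polyfit(logr[start : start + w], logC[start : start + w], 1)[0]
    confident = best[0] < 0.25
    return float(slope), bool(confident)


# ---------------------------------------------------------------------------
# largest Lyapunov exponent (Rosenstein)
# ---------------------------------------------------------------------------

def divergence_curve(
    series,
    spec: EmbeddingSpec,
    theiler: int | None = None,
    k_max: int = 30,
) -> np.ndarray:
    """Mean log divergence S(t) of initially close trajectory pairs.

    For each reference vector the nearest neighbour outside a temporal
    exclusion window is tracked forward; S(t) = <log(d(t)/d(0))> over all
    pairs still inside the data.  Natural log, t in sample steps.
    """
    x = np.asarray(series, float)
    Y = _delay_matrix(x, spec.m, spec.tau)
    n = Y.shape[0]
    if theiler is None:
        theiler = max(spec.m * spec.tau, 1)
    if n < 2 * theiler + 10:
        raise ValueError("series too short for divergence analysis")
    span = np.ptp(x)
    floor = 1e-9 * (span if span > 0 else 1.0)
    tree = cKDTree(Y)
    k = min(2 * theiler + 5, n)
    dist, idx = tree.query(Y, k=k)
    nn = np.full(n, -1)
    d0 = np.full(n, np.nan)
    for i in range(n):
        for dd, jj in zip(dist[i, 1:], idx[i, 1:]):
            # skip temporal neighbours and machine-precision recurrences
            if abs(jj - i) > theiler and dd > floor:
                nn[i] = jj
                d0[i] = dd
                break
    valid = nn >= 0
    refs = np.nonzero(valid)[0]
    if len(refs) < 10:
        raise ValueError("too few neighbour pairs for divergence analysis")
    S = np.zeros(k_max + 1)
    for t in range(k_max + 1):
        ok = refs[(refs + t < n) & (nn[refs] + t < n)]
        if len(ok) < 5:
            S = S[:t]
            break
        d_t = np.sqrt(((Y[ok + t] - Y[nn[ok] + t]) ** 2).sum(axis=1))
        good = d_t > 0
        S[t] = np.mean(np.log(d_t[good] / d0[ok][good]))
    return S


def lyapunov_exponent(
    series,
    spec: EmbeddingSpec,
    theiler: int | None = None,
    k_max: int = 30,
    fit_range: tuple[int, int] | None = None,
) -> float:
    """Largest Lyapunov exponent per sample step (Rosenstein method).

    lambda is the slope of the linear regression of S(t) on t over the early,
    pre-saturation part of the divergence curve.  The fit range defaults to
    the first third of the curve before saturation, detected as the point
    where S(t) first comes within 10% of its plateau; pass ``fit_range`` to
    override.
    """
    S = divergence_curve(series, spec, theiler=theiler, k_max=k_max)
    if fit_range is None:
        plateau = S.max()
        if plateau <= 1e-9:  # no divergence at all (periodic/constant)
            end = len(S)
        else:
            near = np.nonzero(S >= 0.9 * plateau)[0]
            sat = near[0] if len(near) else len(S)
            end = max(3, min(sat, max(3, len(S) // 3)))
        fit_range = (0, min(end, len(S) - 1))
    a, b = fit_range
    b = min(b, len(S) - 1)
    t = np.arange(a, b + 1)
    return float(np.polyfit(t, S[a : b + 1], 1)[0])


# ---------------------------------------------------------------------------
# recurrence plot
# ---------------------------------------------------------------------------

def recurrence_matrix(series, spec: EmbeddingSpec, cutoff: float) -> np.ndarray:
    """Binary matrix: entry (i, j) = 1 iff ||z_i - z_j|| <= cutoff.

    Symmetric about the diagonal with a unit diagonal.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    Y = _delay_matrix(np.asarray(series, float), spec.m, spec.tau)
    diff = Y[:, None, :] - Y[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=2))
    return (dist <= cutoff).astype(np.uint8)


# ---------------------------------------------------------------------------
# one-call characterization
# ---------------------------------------------------------------------------

def characterize(
    series,
    max_lag: int = 50,
    m_max: int = 10,
) -> ChaosReport:
    """Full nonlinear characterization: delay, dimension, D2 and lambda."""
    x = np.asarray(series, float)
    ami, tau = average_mutual_information(x, max_lag=min(max_lag, len(x) // 4))
    usable_m = max(2, min(m_max, (len(x) - 2) // max(tau, 1)))
    m, e1 = cao_embedding_dimension(x, tau=tau, m_max=usable_m)
    spec = EmbeddingSpec(m=m, tau=tau)
    d2, confident = correlation_dimension(x, spec)
    lam = lyapunov_exponent(x, spec)
    return ChaosReport(
        spec=spec,
        correlation_dimension=d2,
        d2_confident=confident,
        lyapunov=lam,
        ami_profile=ami,
        cao_e1_profile=e1,
    )
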