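"""Phase-space autoregressive predictors: LAR, AAR, NNAR, SETAR, LSTAR.

All five models operate on a :class:`~cgmchaos.chaos_analysis.PhaseMatrix`
whose row u is the delay vector [x_u, x_{u+tau}, ..., x_{u+(m-1)tau}].  The
one-step target for row u is the next scalar observation
x_{u+(m-1)tau + 1}, i.e. the new coordinate of the successor delay vector,
so multi-step forecasts append predictions autoregressively.

Model kinds
-----------
LAR    linear AR in embedding space, ordinary least squares.
AAR    additive AR: penalized cubic regression splines per lag
       (smoothing chosen by a small GCV grid).
NNAR   time-lagged feed-forward network, one tanh hidden layer and linear
       output, trained by gradient backpropagation (LBFGS), multiple
       restarts, best by training loss; q selected by AIC when "auto".
SETAR  two-regime piecewise-linear AR switching on the lagged value
       Y_t = z_{t - delta*tau}; threshold searched over candidates keeping
       >= 10% of observations per regime; pooled AIC across (th, delta).
LSTAR  logistic smooth-transition AR: regimes blended by
       G(Y; gamma, c) = 1 / (1 + exp(-gamma (Y - c))); low regime weighted
       by (1 - G), high regime by G.  (c, gamma) by a 200 x 40 grid search
       (c between the 0.1 and 0.9 quantiles of Y, gamma in [1, 40]) with the
       linear parameters solved by least squares at each grid point, then a
       local Nelder-Mead refinement around the best grid point.

AIC uses the Gaussian conditional likelihood with n = number of one-step
targets and k = free parameters (effective degrees of freedom for AAR,
weight count for NNAR), identically across kinds so comparisons are fair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .chaos_analysis import EmbeddingSpec, PhaseMatrix

__all__ = [
    "FittedModel",
    "LstarGrid",
    "MODEL_KINDS",
    "fit_lar",
    "fit_aar",
    "fit_nnar",
    "fit_setar",
    "fit_lstar",
    "fit_model",
    "select_model",
    "predict_one_step",
    "predict_matrix",
    "DegenerateRegimeError",
]

MODEL_KINDS = ("LAR", "AAR", "NNAR", "SETAR", "LSTAR")
_SIMPLICITY = {"LAR": 0, "AAR": 1, "SETAR": 2, "LSTAR": 3, "NNAR": 4}

MIN_REGIME_FRACTION = 0.10


class DegenerateRegimeError(RuntimeError):
    """Every candidate threshold left one regime (almost) empty."""


@dataclass(frozen=True)
class LstarGrid:
    """Grid-search specification for the LSTAR transition parameters."""

    n_thresholds: int = 200
    n_smoothing: int = 40
    gamma_range: tuple[float, float] = (1.0, 40.0)
    c_quantile_range: tuple[float, float] = (0.1, 0.9)
    min_regime_fraction: float = MIN_REGIME_FRACTION

    def __post_init__(self):
        if self.n_thresholds < 1 or self.n_smoothing < 1:
            raise ValueError("grid sizes must be positive")
        if not (0 < self.c_quantile_range[0] < self.c_quantile_range[1] < 1):
            raise ValueError("c quantile range must lie within (0, 1)")

    @property
    def n_points(self) -> int:
        return self.n_thresholds * self.n_smoothing


@dataclass
class FittedModel:
    """A fitted phase-space predictor with its fit-quality scores."""

    kind: str
    spec: EmbeddingSpec
    parameters: dict
    fit_aic: float
    fit_mape: float
    regime_orders: tuple[int, int] | None = None
    _predictor: object = field(default=None, repr=False, compare=False)

    def to_dict(self) -> dict:
        params = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in self.parameters.items()
            if not isinstance(v, (list, tuple)) or k != "_internal"
        }
        return {
            "kind": self.kind,
            "m": self.spec.m,
            "tau": self.spec.tau,
            "parameters": params,
            "aic": self.fit_aic,
            "mape": self.fit_mape,
            "regime_orders": self.regime_orders,
        }


# ---------------------------------------------------------------------------
# design-matrix helpers
# ---------------------------------------------------------------------------

def _design_and_targets(matrix: PhaseMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Predictor rows and their one-step scalar targets.

    Row u predicts x_{u + (m-1)tau + 1}; the last usable row is therefore
    T - 2 (its target is the final sample of the source series).
    """
    data = matrix.data
    T = data.shape[0]
    if T < 2:
        raise ValueError("phase matrix has too few rows for one-step targets")
    X = data[: T - 1]
    # target for row u is the last coordinate of row u+1
    y = data[1:, -1]
    return X, y


def _aic(rss: float, n: int, k: int) -> float:
    """Gaussian conditional-likelihood AIC (constants dropped)."""
    rss = max(rss, 1e-300)
    return n * np.log(rss / n) + 2 * k


def _mape(y: np.ndarray, yhat: np.ndarray) -> float:
    denom = np.abs(y)
    ok = denom > 1e-12
    if not ok.any():
        return float("nan")
    return float(np.mean(np.abs((y[ok] - yhat[ok]) / y[ok])))


# ---------------------------------------------------------------------------
# LAR
# ---------------------------------------------------------------------------

def fit_lar(matrix: PhaseMatrix) -> FittedModel:
    """Linear AR in embedding space by ordinary least squares."""
    X, y = _design_and_targets(matrix)
    n, m = X.shape
    if n < m + 2:
        raise ValueError(f"need at least {m + 2} rows, got {n}")
    if np.ptp(y) == 0 and np.all(np.ptp(X, axis=0) == 0):
        # constant series: intercept-only fit
        coef = np.zeros(m)
        intercept = float(y[0]) if n else 0.0
        yhat = np.full(n, intercept)
    else:
        A = np.column_stack([np.ones(n), X])
        rank = np.linalg.matrix_rank(A)
        if rank < A.shape[1]:
            # identify (near-)collinear lags for the error message
            _, R = np.linalg.qr(A)
            bad = [int(i) - 1 for i in np.nonzero(np.abs(np.diag(R)) < 1e-10)[0] if i > 0]
            raise np.linalg.LinAlgError(
                f"rank-deficient design: collinear lag columns {bad or 'unknown'}"
            )
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        intercept, coef = float(beta[0]), beta[1:]
        yhat = A @ beta
    rss = float(np.sum((y - yhat) ** 2))
    k = m + 1
    model = FittedModel(
        kind="LAR",
        spec=matrix.spec,
        parameters={"intercept": intercept, "coefficients": np.asarray(coef)},
        fit_aic=_aic(rss, n, k),
        fit_mape=_mape(y, yhat),
    )
    return model


def _lar_predict(params: dict, vec: np.ndarray) -> float:
    return float(params["intercept"] + params["coefficients"] @ vec)


# ---------------------------------------------------------------------------
# AAR
# ---------------------------------------------------------------------------

def fit_aar(matrix: PhaseMatrix, df: int = 8) -> FittedModel:
    """Additive AR with penalized cubic regression splines per lag.

    z_{t+1} = mu + sum_i s_i(z_{t-(i-1)tau}); the common smoothing penalty is
    chosen from a small log-spaced grid by generalized cross-validation.
    Degenerate (constant) lags fall back to a linear fit.
    """
    from statsmodels.gam.api import BSplines, GLMGam

    X, y = _design_and_targets(matrix)
    n, m = X.shape
    spreads = np.ptp(X, axis=0)
    if np.ptp(y) == 0 or (spreads == 0).all():
        lar = fit_lar(matrix)
        return FittedModel(
            kind="AAR", spec=matrix.spec,
            parameters=dict(lar.parameters, fallback="constant"),
            fit_aic=lar.fit_aic, fit_mape=lar.fit_mape,
            _predictor=("linear", lar.parameters),
        )
    df = int(min(df, max(4, (n - 1) // (2 * m))))
    if n < m * df + 2:
        raise ValueError(f"too few rows ({n}) for {m} spline terms of df {df}")
    smoother = BSplines(X, df=[df] * m, degree=[3] * m, include_intercept=False)
    best = None
    for alpha in (1e-2, 1e0, 1e2, 1e4):
        gam = GLMGam(y, exog=np.ones((n, 1)), smoother=smoother, alpha=[alpha] * m)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = gam.fit()
        yhat = np.asarray(res.fittedvalues)
        rss = float(np.sum((y - yhat) ** 2))
        edf = float(np.sum(res.edf)) if np.ndim(res.edf) else float(res.edf)
        gcv = n * rss / max(n - edf, 1.0) ** 2
        if best is None or gcv < best[0]:
            best = (gcv, alpha, res, yhat, rss, edf)
    _, alpha, res, yhat, rss, edf = best
    model = FittedModel(
        kind="AAR",
        spec=matrix.spec,
        parameters={
            "alpha": alpha,
            "edf": edf,
            "coefficients": np.asarray(res.params),
        },
        fit_aic=_aic(rss, n, int(round(edf))),
        fit_mape=_mape(y, yhat),
        _predictor=("gam", res, smoother),
    )
    return model


def _aar_predict(model: FittedModel, vec: np.ndarray) -> float:
    tag = model._predictor
    if tag is None:
        raise RuntimeError("AAR model was deserialized without its smoother state")
    if tag[0] == "linear":
        return _lar_predict(tag[1], vec)
    _, res, smoother = tag
    x = np.asarray(vec, float)[None, :]
    # clip to the training range: B-spline bases are undefined outside it
    lo = smoother.x.min(axis=0)
    hi = smoother.x.max(axis=0)
    x = np.clip(x, lo, hi)
    pred = res.predict(np.ones((1, 1)), exog_smooth=x)
    return float(np.asarray(pred)[0])


# ---------------------------------------------------------------------------
# NNAR
# ---------------------------------------------------------------------------

def fit_nnar(
    matrix: PhaseMatrix,
    q: int | str = "auto",
    seed: int = 0,
    restarts: int = 5,
    q_candidates: Sequence[int] = (1, 2, 3, 4),
) -> FittedModel:
    """Feed-forward AR network: tanh hidden layer, linear output.

    Trained by gradient backpropagation (LBFGS) with ``restarts`` seeded
    restarts, keeping the best training loss.  ``q="auto"`` selects the
    hidden-layer width over ``q_candidates`` by AIC (ties by MAPE).
    Inputs and targets are standardized internally; the fitted seed makes
    refits bit-reproducible.
    """
    from sklearn.neural_network import MLPRegressor

    X, y = _design_and_targets(matrix)
    n, m = X.shape
    if np.ptp(y) == 0:
        lar = fit_lar(matrix)
        return FittedModel(
            kind="NNAR", spec=matrix.spec,
            parameters=dict(lar.parameters, fallback="constant"),
            fit_aic=lar.fit_aic, fit_mape=lar.fit_mape,
            _predictor=("linear", lar.parameters),
        )
    mu_x, sd_x = X.mean(axis=0), X.std(axis=0)
    sd_x[sd_x == 0] = 1.0
    mu_y, sd_y = y.mean(), y.std() or 1.0
    Xs = (X - mu_x) / sd_x
    ys = (y - mu_y) / sd_y

    qs = [int(q)] if q != "auto" else list(q_candidates)
    candidates = []
    for qq in qs:
        best_net = None
        for r in range(restarts):
            net = MLPRegressor(
                hidden_layer_sizes=(qq,),
                activation="tanh",
                solver="lbfgs",
                alpha=1e-6,
                max_iter=500,
                random_state=seed * 1000 + r,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                net.fit(Xs, ys)
            loss = float(np.mean((net.predict(Xs) - ys) ** 2))
            if not np.isfinite(loss):
                continue
            if best_net is None or loss < best_net[0]:
                best_net = (loss, net)
        if best_net is None:
            raise RuntimeError(f"NNAR training diverged for q={qq}")
        _, net = best_net
        yhat = net.predict(Xs) * sd_y + mu_y
        rss = float(np.sum((y - yhat) ** 2))
        k = qq * (m + 2) + 1  # weights + biases of both layers
        candidates.append(
            (
                _aic(rss, n, k),
                _mape(y, yhat),
                qq,
                net,
            )
        )
    candidates.sort(key=lambda t: (t[0], t[1]))
    aic, mape, qq, net = candidates[0]
    model = FittedModel(
        kind="NNAR",
        spec=matrix.spec,
        parameters={
            "q": qq,
            "seed": seed,
            "hidden_weights": net.coefs_[0],
            "hidden_bias": net.intercepts_[0],
            "output_weights": net.coefs_[1],
            "output_bias": net.intercepts_[1],
            "x_mean": mu_x, "x_sd": sd_x, "y_mean": float(mu_y), "y_sd": float(sd_y),
        },
        fit_aic=aic,
        fit_mape=mape,
        _predictor=("net", net, (mu_x, sd_x, mu_y, sd_y)),
    )
    return model


def _nnar_predict(model: FittedModel, vec: np.ndarray) -> float:
    tag = model._predictor
    if tag is not None and tag[0] == "linear":
        return _lar_predict(tag[1], vec)
    p = model.parameters
    xs = (np.asarray(vec, float) - p["x_mean"]) / p["x_sd"]
    hidden = np.tanh(xs @ p["hidden_weights"] + p["hidden_bias"])
    out = hidden @ p["output_weights"] + p["output_bias"]
    return float(out[0] * p["y_sd"] + p["y_mean"])


# ---------------------------------------------------------------------------
# SETAR
# ---------------------------------------------------------------------------

def _regime_columns(m: int, order: int) -> np.ndarray:
    """Columns used by a regime of the given AR order (most recent lags).

    Column m-1 is z_t, column m-1-i is z_{t-i*tau}; order L uses lags
    0..L-1, i.e. columns m-L .. m-1.
    """
    return np.arange(m - order, m)


def _threshold_column(m: int, delta: int) -> int:
    """Column of Y_t = z_{t - delta*tau} in the ascending-time phase matrix."""
    if not 0 <= delta <= m - 1:
        raise ValueError("threshold delay must lie in {0, ..., m-1}")
    return m - 1 - delta


def _ols(A: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    return beta, float(resid @ resid)


def fit_setar(
    matrix: PhaseMatrix,
    orders: tuple[int, int] | None = None,
    delta: int | None = None,
    min_regime_fraction: float = MIN_REGIME_FRACTION,
    max_candidates: int = 200,
) -> FittedModel:
    """Two-regime self-exciting threshold AR.

    The threshold variable is Y_t = z_{t - delta*tau}; when ``delta`` is None
    it is chosen together with the threshold by pooled AIC over
    {0, ..., m-1}.  Candidate thresholds are the values of Y_t between its
    ``min_regime_fraction`` and 1 - ``min_regime_fraction`` empirical
    quantiles (at most ``max_candidates``, evenly thinned); each candidate
    must keep at least that fraction of observations in both regimes.
    Regime orders default to (m, m).
    """
    X, y = _design_and_targets(matrix)
    n, m = X.shape
    L, H = orders if orders is not None else (m, m)
    if not (1 <= L <= m and 1 <= H <= m):
        raise ValueError("regime orders must satisfy 1 <= L, H <= m")
    deltas = range(m) if delta is None else [delta]
    cols_L = _regime_columns(m, L)
    cols_H = _regime_columns(m, H)
    min_count = max(int(np.ceil(min_regime_fraction * n)), L + 2, H + 2)

    best = None
    for d in deltas:
        Yt = X[:, _threshold_column(m, d)]
        lo_q, hi_q = np.quantile(Yt, [min_regime_fraction, 1 - min_regime_fraction])
        cands = np.unique(Yt[(Yt >= lo_q) & (Yt <= hi_q)])
        if len(cands) > max_candidates:
            cands = cands[
                (np.arange(max_candidates) * (len(cands) / max_candidates)).astype(int)
            ]
        A_L = np.column_stack([np.ones(n), X[:, cols_L]])
        A_H = np.column_stack([np.ones(n), X[:, cols_H]])
        for th in cands:
            low = Yt <= th
            n_lo = int(low.sum())
            if n_lo < min_count or n - n_lo < min_count:
                continue
            beta_L, rss_L = _ols(A_L[low], y[low])
            beta_H, rss_H = _ols(A_H[~low], y[~low])
            k = (L + 1) + (H + 1) + 1  # + threshold
            aic = _aic(rss_L + rss_H, n, k)
            if best is None or aic < best[0]:
                best = (aic, d, float(th), beta_L, beta_H, rss_L + rss_H)
    if best is None:
        raise DegenerateRegimeError(
            "no candidate threshold keeps both regimes populated"
        )
    aic, d, th, beta_L, beta_H, rss = best
    params = {
        "threshold": th,
        "delta": d,
        "low_intercept": float(beta_L[0]),
        "low_coefficients": beta_L[1:],
        "high_intercept": float(beta_H[0]),
        "high_coefficients": beta_H[1:],
        "orders": (L, H),
    }
    yhat = _setar_predict_rows(params, matrix.spec, X)
    model = FittedModel(
        kind="SETAR",
        spec=matrix.spec,
        parameters=params,
        fit_aic=aic,
        fit_mape=_mape(y, yhat),
        regime_orders=(L, H),
    )
    return model


def _setar_predict_rows(params: dict, spec: EmbeddingSpec, X: np.ndarray) -> np.ndarray:
    m = spec.m
    L, H = params["orders"]
    Yt = X[:, _threshold_column(m, params["delta"])]
    low = Yt <= params["threshold"]
    out = np.empty(X.shape[0])
    out[low] = params["low_intercept"] + X[low][:, _regime_columns(m, L)] @ params["low_coefficients"]
    out[~low] = params["high_intercept"] + X[~low][:, _regime_columns(m, H)] @ params["high_coefficients"]
    return out


# ---------------------------------------------------------------------------
# LSTAR
# ---------------------------------------------------------------------------

def _logistic_G(Yt: np.ndarray, gamma: float, c: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(gamma * (Yt - c), -500, 500)))


def _lstar_rss(
    A_L: np.ndarray, A_H: np.ndarray, y: np.ndarray, G: np.ndarray
) -> tuple[np.ndarray, float]:
    Z = np.hstack([A_L * (1.0 - G)[:, None], A_H * G[:, None]])
    G_m = Z.T @ Z
    b = Z.T @ y
    try:
        beta = np.linalg.solve(G_m + 1e-10 * np.eye(G_m.shape[0]), b)
    except np.linalg.LinAlgError:  # pragma: no cover
        beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
    resid = y - Z @ beta
    return beta, float(resid @ resid)


def fit_lstar(
    matrix: PhaseMatrix,
    grid: LstarGrid | None = None,
    orders: tuple[int, int] | None = None,
    delta: int = 0,
    gamma_fixed: float | None = None,
    refine: bool = True,
) -> FittedModel:
    """Logistic smooth-transition AR fitted by grid search + least squares.

    At each (c, gamma) grid point the linear parameters of both regimes are
    solved by least squares on the G-weighted design; the best grid point
    (lowest residual sum of squares) is optionally refined by Nelder-Mead.
    ``gamma_fixed`` restricts the smoothing axis to a single value (useful
    for the large-gamma step-function limit).
    """
    grid = grid or LstarGrid()
    X, y = _design_and_targets(matrix)
    n, m = X.shape
    L, H = orders if orders is not None else (m, m)
    cols_L = _regime_columns(m, L)
    cols_H = _regime_columns(m, H)
    Yt = X[:, _threshold_column(m, delta)]
    lo_q, hi_q = np.quantile(Yt, list(grid.c_quantile_range))
    if hi_q <= lo_q:
        raise DegenerateRegimeError("threshold variable is (nearly) constant")
    c_grid = np.linspace(lo_q, hi_q, grid.n_thresholds)
    if gamma_fixed is not None:
        gamma_grid = np.array([float(gamma_fixed)])
    else:
        gamma_grid = np.linspace(grid.gamma_range[0], grid.gamma_range[1], grid.n_smoothing)
    A_L = np.column_stack([np.ones(n), X[:, cols_L]])
    A_H = np.column_stack([np.ones(n), X[:, cols_H]])
    best = None
    for gamma in gamma_grid:
        for c in c_grid:
            G = _logistic_G(Yt, gamma, c)
            beta, rss = _lstar_rss(A_L, A_H, y, G)
            if best is None or rss < best[0]:
                best = (rss, float(c), float(gamma), beta)
    rss, c_hat, gamma_hat, beta = best

    if refine and gamma_fixed is None:
        from scipy.optimize import minimize

        def objective(p):
            c, gamma = p
            if not (lo_q <= c <= hi_q and grid.gamma_range[0] <= gamma <= grid.gamma_range[1]):
                return np.inf
            _, r = _lstar_rss(A_L, A_H, y, _logistic_G(Yt, gamma, c))
            return r

        res = minimize(objective, [c_hat, gamma_hat], method="Nelder-Mead",
                       options={"maxiter": 120, "xatol": 1e-4, "fatol": 1e-10})
        if res.fun < rss:
            c_hat, gamma_hat = float(res.x[0]), float(res.x[1])
            G = _logistic_G(Yt, gamma_hat, c_hat)
            beta, rss = _lstar_rss(A_L, A_H, y, G)

    kL = L + 1
    params = {
        "c": c_hat,
        "gamma": gamma_hat,
        "delta": delta,
        "low_intercept": float(beta[0]),
        "low_coefficients": beta[1:kL],
        "high_intercept": float(beta[kL]),
        "high_coefficients": beta[kL + 1 :],
        "orders": (L, H),
        "c_grid_resolution": float((hi_q - lo_q) / max(grid.n_thresholds - 1, 1)),
    }
    k = kL + (H + 1) + 2  # + c + gamma
    yhat = _lstar_predict_rows(params, matrix.spec, X)
    model = FittedModel(
        kind="LSTAR",
        spec=matrix.spec,
        parameters=params,
        fit_aic=_aic(rss, n, k),
        fit_mape=_mape(y, yhat),
        regime_orders=(L, H),
    )
    return model


def _lstar_predict_rows(params: dict, spec: EmbeddingSpec, X: np.ndarray) -> np.ndarray:
    m = spec.m
    L, H = params["orders"]
    Yt = X[:, _threshold_column(m, params["delta"])]
    G = _logistic_G(Yt, params["gamma"], params["c"])
    low = params["low_intercept"] + X[:, _regime_columns(m, L)] @ params["low_coefficients"]
    high = params["high_intercept"] + X[:, _regime_columns(m, H)] @ params["high_coefficients"]
    return (1.0 - G) * low + G * high


# ---------------------------------------------------------------------------
# dispatch, selection, prediction
# ---------------------------------------------------------------------------

def fit_model(matrix: PhaseMatrix, kind: str, **kwargs) -> FittedModel:
    """Fit one model kind by name (case-insensitive)."""
    kind = kind.upper()
    if kind == "LAR":
        return fit_lar(matrix)
    if kind == "AAR":
        return fit_aar(matrix, **kwargs)
    if kind == "NNAR":
        return fit_nnar(matrix, **kwargs)
    if kind == "SETAR":
        return fit_setar(matrix, **kwargs)
    if kind == "LSTAR":
        return fit_lstar(matrix, **kwargs)
    raise ValueError(f"unknown model kind: {kind!r}")


def select_model(candidates: Sequence[FittedModel]) -> FittedModel:
    """Minimum-AIC candidate; ties broken by MAPE, then by simplicity."""
    if not candidates:
        raise ValueError("no candidate models")
    return min(
        candidates,
        key=lambda mdl: (mdl.fit_aic, mdl.fit_mape, _SIMPLICITY[mdl.kind]),
    )


def predict_one_step(model: FittedModel, vector) -> float:
    """Evaluate the fitted map F on one phase-space point (ascending lags)."""
    vec = np.asarray(vector, float)
    if vec.shape != (model.spec.m,):
        raise ValueError(f"expected a vector of dimension {model.spec.m}, got {vec.shape}")
    if model.kind == "LAR":
        return _lar_predict(model.parameters, vec)
    if model.kind == "AAR":
        return _aar_predict(model, vec)
    if model.kind == "NNAR":
        return _nnar_predict(model, vec)
    if model.kind == "SETAR":
        return float(_setar_predict_rows(model.parameters, model.spec, vec[None, :])[0])
    if model.kind == "LSTAR":
        return float(_lstar_predict_rows(model.parameters, model.spec, vec[None, :])[0])
    raise ValueError(f"unknown model kind: {model.kind!r}")


def predict_matrix(model: FittedModel, X: np.ndarray) -> np.ndarray:
    """Vectorized one-step predictions for many phase-space points."""
    X = np.asarray(X, float)
    if model.kind == "SETAR":
        return _setar_predict_rows(model.parameters, model.spec, X)
    if model.kind == "LSTAR":
        return _lstar_predict_rows(model.parameters, model.spec, X)
    return np.array([predict_one_step(model, row) for row in X])
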