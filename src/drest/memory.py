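"""Rate-adaptation (memory/hysteresis) model of QT and Tpe.

Ventricular repolarization intervals track not the instantaneous RR but a
weighted average of the recent RR history.  The model here is

    z(k) = sum_i w_i * rr(k - i),   w_i >= 0,  sum_i w_i = 1
    y(k) = g(z(k)) + noise,         g(z) = a*z + b  (monotone, linear)

with FIR weights over a configurable history window (default 300 s).  The
adaptation time t90 — the time for QT or Tpe to complete 90 % of its
transition after an abrupt heart-rate step — is read off the weight profile:
the step response of the filter equals the cumulative weight sum, so t90 is
the lag (in seconds, via the record's mean RR) at which cumsum(w) first
reaches 0.90.  The same filter output z, the "memory-compensated surrogate
RR", is what the restitution-dispersion index regresses Tpe against, removing
hysteresis between Tpe and RR.

Fitting is alternating least squares: with w fixed, (a, b) is an ordinary
least-squares fit of y on z; with (a, b) fixed, w is updated by least squares
constrained to the probability simplex (solved by accelerated projected
gradient, warm-started), optionally with a second-difference roughness
penalty on the weight profile.  Weights start uniform.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np

from .delineate import BeatSeries

__all__ = ["MemoryModel", "SurrogateRRSeries", "fit_memory_model",
           "surrogate_rr", "compute_t90"]


@dataclass
class MemoryModel:
    """Fitted rate-adaptation filter plus stationary curve.

    ``weights`` are beat-indexed (lag 0 = current beat); ``lag_s`` maps each
    lag to seconds via the mean RR of the fitting record.  ``g_slope`` /
    ``g_intercept`` define the stationary linear curve interval = a*z + b
    (ms per ms, ms).
    """

    weights: np.ndarray
    lag_s: np.ndarray
    window_s: float
    g_slope: float
    g_intercept: float
    target: str
    residual_rmse_ms: float
    mean_rr_ms: float
    degenerate: bool = False
    n_iterations: int = 0
    #: continuous-time single-exponential mode: when the fit finds the memory
    #: consistent with one exponential, its time constant is refined in
    #: continuous time (per-beat decay exp(-rr_k/tau)) and the surrogate is
    #: evaluated by the exact recursive filter instead of the FIR dot product
    tau_s: float | None = None

    @property
    def n_lags(self) -> int:
        return len(self.weights)

    def to_json(self) -> str:
        d = {
            "target": self.target,
            "window_s": self.window_s,
            "g_slope": self.g_slope,
            "g_intercept": self.g_intercept,
            "residual_rmse_ms": self.residual_rmse_ms,
            "mean_rr_ms": self.mean_rr_ms,
            "degenerate": self.degenerate,
            "n_iterations": self.n_iterations,
            "t90_s": compute_t90(self) if not self.degenerate else None,
            "tau_s": self.tau_s,
            "weights": self.weights.tolist(),
            "lag_s": self.lag_s.tolist(),
        }
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "MemoryModel":
        d = json.loads(text)
        return cls(
            weights=np.asarray(d["weights"], float),
            lag_s=np.asarray(d["lag_s"], float),
            window_s=d["window_s"], g_slope=d["g_slope"],
            g_intercept=d["g_intercept"], target=d["target"],
            residual_rmse_ms=d["residual_rmse_ms"], mean_rr_ms=d["mean_rr_ms"],
            degenerate=d["degenerate"], n_iterations=d["n_iterations"],
            tau_s=d.get("tau_s"),
        )


@dataclass
class SurrogateRRSeries:
    """Memory-filtered RR per beat; invalid where history is incomplete."""

    t: np.ndarray
    z_ms: np.ndarray
    valid: np.ndarray


def _lag_matrix(rr: np.ndarray, n_lags: int) -> tuple[np.ndarray, np.ndarray]:
    """Rows: beats with full history; columns: rr at lags 0..n_lags-1."""
    n = len(rr)
    if n < n_lags:
        return np.empty((0, n_lags)), np.array([], dtype=int)
    idx = np.arange(n_lags - 1, n)
    # R[k, i] = rr[idx[k] - i]
    R = rr[idx[:, None] - np.arange(n_lags)[None, :]]
    return R, idx


def fit_memory_model(series: BeatSeries, target: str = "Tpe",
                     window_s: float = 300.0, basis: str = "exp",
                     reg_lambda: float = 1e-3, max_iter: int = 50,
                     tol: float = 1e-4, n_atoms: int = 25,
                     tau_range_s: tuple = (2.0, 250.0)) -> MemoryModel:
    """Fit the FIR memory filter and linear stationary curve.

    Parameters
    ----------
    series : BeatSeries
        Needs >= 10 min of valid beats with heart-rate changes present
        (1-min-smoothed RR range >= 50 ms), otherwise a warning is issued.
    target : {"QT", "Tpe"}
    window_s : float
        History length in seconds (>= 60).
    basis : {"exp", "free"}
        ``exp`` (default) constrains the weight profile to a nonnegative
        mixture of exponential decays (log-spaced time constants spanning
        ``tau_range_s``) plus an instantaneous delta component.  Lagged RR
        values are heavily collinear, so the unrestricted FIR deconvolution
        is ill-conditioned; the mixture cone matches the monotone smooth
        decay rate-memory physiologically has and, because the stationary
        curve is linear, the whole fit collapses to one nonnegative
        least-squares problem with a global optimum.  ``free`` estimates an
        unrestricted simplex weight profile by alternating least squares
        (weight step: projected-gradient on the simplex) with an optional
        second-difference roughness penalty ``reg_lambda``.
    reg_lambda : float
        Roughness penalty for the ``free`` basis; ignored for ``exp``.
    """
    if target.lower() not in ("qt", "tpe"):
        raise ValueError("target must be 'QT' or 'Tpe'")
    if window_s < 60.0:
        raise ValueError("window_s must be >= 60 s")
    y_all = series.qt_ms if target.lower() == "qt" else series.tpe_ms

    v = series.valid & np.isfinite(series.rr_ms) & np.isfinite(y_all)
    t_v, rr, y = series.t[v], series.rr_ms[v], y_all[v]
    if len(rr) < 2:
        raise ValueError("too few valid beats")
    span_s = t_v[-1] - t_v[0]
    if span_s < 600.0:
        warnings.warn(f"only {span_s:.0f} s of valid beats; at least 10 min "
                      "recommended for rate-adaptation estimation")

    mean_rr = float(np.mean(rr))
    smoothed = _smooth_time(t_v, rr, 60.0)
    rr_range = float(np.ptp(smoothed))
    degenerate = rr_range < 50.0
    if degenerate:
        warnings.warn("insufficient heart-rate changes (1-min smoothed RR "
                      f"range {rr_range:.1f} ms < 50 ms); memory model is "
                      "unidentifiable")

    n_lags = max(2, int(np.ceil(window_s / (mean_rr / 1000.0))))
    n_lags = min(n_lags, max(2, len(rr) // 2))
    R, rows = _lag_matrix(rr, n_lags)
    lag_s = np.arange(n_lags) * (mean_rr / 1000.0)
    if R.shape[0] < n_lags or degenerate:
        w = np.full(n_lags, 1.0 / n_lags)
        a, b, rmse = _fit_g(R, y[rows], w) if R.shape[0] else (np.nan, np.nan, np.nan)
        return MemoryModel(w, lag_s, window_s, a, b, target, rmse, mean_rr,
                           degenerate=True)

    yr = y[rows]
    if basis == "exp":
        w, a, b, rmse = _fit_exp_mixture(R, yr, lag_s, n_atoms, tau_range_s)
        if w is None:  # target does not increase with RR: unidentifiable
            warnings.warn("memory fit degenerate: target does not increase "
                          "with the filtered RR")
            w = np.full(n_lags, 1.0 / n_lags)
            a, b, rmse = _fit_g(R, yr, w)
            return MemoryModel(w, lag_s, window_s, a, b, target, rmse,
                               mean_rr, degenerate=True)
        # continuous-time single-exponential refinement: exact for
        # exponential rate-memory, adopted only when it fits at least as
        # well as the mixture on the same beats
        ref = _refine_single_exp(rr, y, rows, tau_range_s)
        if ref is not None and ref[3] <= rmse * (1.0 + 1e-9):
            tau, a_e, b_e, rmse_e = ref
            w = np.exp(-lag_s / tau)
            w /= w.sum()
            return MemoryModel(w, lag_s, window_s, a_e, b_e, target, rmse_e,
                               mean_rr, degenerate=False, n_iterations=1,
                               tau_s=float(tau))
        return MemoryModel(w, lag_s, window_s, a, b, target, rmse, mean_rr,
                           degenerate=False, n_iterations=1)
    if basis != "free":
        raise ValueError("basis must be 'exp' or 'free'")
    w = np.full(n_lags, 1.0 / n_lags)

    # precompute Gram pieces for the projected-gradient weight step
    G = R.T @ R
    D2 = _second_diff(n_lags)
    P = D2.T @ D2
    reg_scale = reg_lambda * np.trace(G) / max(1, n_lags)  # relative penalty

    a, b, rmse = _fit_g(R, yr, w)
    n_it = 0
    for n_it in range(1, max_iter + 1):
        w = _simplex_ls(G, R.T @ ((yr - b) / a), P, reg_scale / a**2, w0=w)
        a, b, new_rmse = _fit_g(R, yr, w)
        if rmse > 0 and abs(rmse - new_rmse) / rmse < tol:
            rmse = new_rmse
            break
        rmse = new_rmse

    if a <= 0:
        warnings.warn("stationary curve is non-increasing; fit is suspect")
    return MemoryModel(w, lag_s, window_s, float(a), float(b), target,
                       float(rmse), mean_rr, degenerate=False, n_iterations=n_it)


def _fit_exp_mixture(R, y, lag_s, n_atoms, tau_range_s):
    """Joint weight/curve fit over the exponential-mixture cone.

    With g linear, y ~ a*(R w) + b and w a convex combination of unit-sum
    atoms reduces to nonnegative least squares in u = a * c (atom domain):
    the intercept is eliminated by centering and recovered afterwards.
    Returns (w, a, b, rmse), or (None, ...) when the fit is degenerate
    (all-zero coefficients, i.e. no increasing relation).
    """
    from scipy.optimize import nnls

    taus = np.geomspace(tau_range_s[0], tau_range_s[1], n_atoms)
    atoms = [np.exp(-lag_s / t) for t in taus]
    delta = np.zeros(len(lag_s))
    delta[0] = 1.0
    A0 = np.stack([delta] + [at / at.sum() for at in atoms], axis=1)
    RB = R @ A0
    Rc = RB - RB.mean(axis=0)
    yc = y - y.mean()
    c, _ = nnls(Rc, yc)
    if c.sum() <= 0:
        return None, np.nan, np.nan, np.nan
    u = A0 @ c
    a = float(u.sum())
    w = u / a
    fit = RB @ c
    b = float(np.mean(y - fit))
    rmse = float(np.sqrt(np.mean((y - fit - b) ** 2)))
    return w, a, b, rmse


def _recursive_exp_z(rr_ms: np.ndarray, tau_s: float) -> np.ndarray:
    """Continuous-time exponential memory: z(k) = lam_k z(k-1) +
    (1 - lam_k) rr(k) with lam_k = exp(-rr_k[s]/tau)."""
    z = np.empty_like(rr_ms)
    z[0] = rr_ms[0]
    lam = np.exp(-(rr_ms / 1000.0) / tau_s)
    for k in range(1, len(rr_ms)):
        z[k] = lam[k] * z[k - 1] + (1.0 - lam[k]) * rr_ms[k]
    return z


def _refine_single_exp(rr, y, rows, tau_range_s):
    """1-D least-squares refinement of a single continuous-time exponential
    time constant; residuals evaluated on the same beats as the FIR fit."""
    from scipy.optimize import minimize_scalar

    yr = y[rows]

    def sse(log_tau):
        z = _recursive_exp_z(rr, np.exp(log_tau))[rows]
        A = np.column_stack([z, np.ones_like(z)])
        coef, *_ = np.linalg.lstsq(A, yr, rcond=None)
        return float(np.sum((yr - A @ coef) ** 2))

    res = minimize_scalar(sse, bounds=(np.log(tau_range_s[0]),
                                       np.log(tau_range_s[1])),
                          method="bounded",
                          options={"xatol": 1e-10})
    if not res.success:
        return None
    tau = float(np.exp(res.x))
    z = _recursive_exp_z(rr, tau)[rows]
    A = np.column_stack([z, np.ones_like(z)])
    coef, *_ = np.linalg.lstsq(A, yr, rcond=None)
    if coef[0] <= 0:
        return None
    rmse = float(np.sqrt(np.mean((yr - A @ coef) ** 2)))
    return tau, float(coef[0]), float(coef[1]), rmse


def _fit_g(R, y, w):
    z = R @ w
    A = np.column_stack([z, np.ones_like(z)])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    return float(coef[0]), float(coef[1]), float(np.sqrt(np.mean(resid**2)))


def _second_diff(n):
    if n < 3:
        return np.zeros((1, n))
    D = np.zeros((n - 2, n))
    i = np.arange(n - 2)
    D[i, i], D[i, i + 1], D[i, i + 2] = 1.0, -2.0, 1.0
    return D


def _simplex_ls(G, c, P, lam, w0, n_iter=300, tol=1e-10):
    """min_w  1/2 w'(G + lam P)w - c'w  s.t.  w >= 0, sum w = 1  (FISTA)."""
    H = G + lam * P
    # Lipschitz constant via a few power iterations
    v = np.ones(H.shape[0]) / np.sqrt(H.shape[0])
    for _ in range(12):
        v = H @ v
        nv = np.linalg.norm(v)
        if nv == 0:
            return _project_simplex(w0)
        v /= nv
    L = float(v @ H @ v)
    step = 1.0 / max(L, 1e-12)

    w = _project_simplex(w0)
    yk = w.copy()
    tk = 1.0
    for _ in range(n_iter):
        grad = H @ yk - c
        w_new = _project_simplex(yk - step * grad)
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * tk**2))
        yk = w_new + (tk - 1.0) / t_new * (w_new - w)
        if np.max(np.abs(w_new - w)) < tol:
            w = w_new
            break
        w, tk = w_new, t_new
    return w


def _project_simplex(v):
    """Euclidean projection onto {w : w >= 0, sum w = 1}."""
    u = np.sort(v)[::-1]
    css = np.cumsum(u) - 1.0
    rho = np.nonzero(u - css / (np.arange(len(v)) + 1) > 0)[0][-1]
    theta = css[rho] / (rho + 1.0)
    return np.maximum(v - theta, 0.0)


def _smooth_time(t, x, win_s):
    """Centered moving average over a time window, on an irregular grid."""
    out = np.empty_like(x)
    j0 = j1 = 0
    n = len(t)
    for k in range(n):
        while t[k] - t[j0] > win_s / 2:
            j0 += 1
        while j1 < n and t[j1] - t[k] <= win_s / 2:
            j1 += 1
        out[k] = np.mean(x[j0:j1])
    return out


def surrogate_rr(model: MemoryModel, series: BeatSeries) -> SurrogateRRSeries:
    """Apply the fitted filter to a beat series: z(k) = sum_i w_i rr(k-i).

    Beats whose history window is incomplete, or that hinge on invalid RR
    measurements, are flagged invalid.
    """
    rr = series.rr_ms
    n = len(rr)
    n_lags = model.n_lags
    z = np.full(n, np.nan)
    ok = np.zeros(n, dtype=bool)
    finite = np.isfinite(rr) & series.valid
    # prefix sums of the finite mask to test full-history windows quickly
    cum = np.concatenate([[0], np.cumsum(finite)])
    if model.tau_s is not None:
        # single-exponential mode: exact recursive continuous-time filter
        idx = np.where(finite)[0]
        if len(idx):
            z_f = _recursive_exp_z(rr[idx], model.tau_s)
            z[idx] = z_f
        for k in range(n_lags - 1, n):
            ok[k] = (cum[k + 1] - cum[k + 1 - n_lags] == n_lags)
        z[~ok] = np.nan
        return SurrogateRRSeries(series.t.copy(), z, ok)
    for k in range(n_lags - 1, n):
        if cum[k + 1] - cum[k + 1 - n_lags] == n_lags:
            z[k] = model.weights @ rr[k - n_lags + 1:k + 1][::-1]
            ok[k] = True
    return SurrogateRRSeries(series.t.copy(), z, ok)


def compute_t90(model: MemoryModel) -> float:
    """Adaptation time t90 in seconds.

    After a heart-rate step the filter output completes the fraction
    cumsum(w) of its transition after each lag, so t90 is the first lag time
    at which the cumulative weight reaches 0.90.  Linear interpolation
    between lags gives sub-beat resolution; a delta filter at lag 0 yields 0.
    Undefined (nan) for a degenerate model.
    """
    if model.degenerate:
        return float("nan")
    cw = np.cumsum(model.weights)
    if cw[-1] <= 0:
        return float("nan")
    cw = cw / cw[-1]
    idx = int(np.searchsorted(cw, 0.90))
    if idx == 0:
        return 0.0
    if idx >= len(cw):
        return float(model.lag_s[-1])
    # interpolate within the beat interval ending at lag idx
    c0, c1 = cw[idx - 1], cw[idx]
    frac = (0.90 - c0) / (c1 - c0) if c1 > c0 else 1.0
    return float(model.lag_s[idx - 1] + frac * (model.lag_s[idx] - model.lag_s[idx - 1]))
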