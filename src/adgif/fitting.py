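"""Staged parameter estimation for the two-compartment model and the GLM.

The two-compartment fit exploits the model structure: given the four
nonlinear dendritic parameters (tau_m, D_m, E_m, tau_x), the calcium
activation m(t) and recovery x(t) can be reconstructed by driving their
dynamics with the *recorded* dendritic voltage, after which every remaining
dendritic parameter is linear in dV_d/dt and found by multilinear
regression.  The nonlinear parameters are then chosen by exhaustive grid
search on the regression mean-square error.  The somatic compartment is
fitted the same way (its only nonlinear input, m(t), comes from the fitted
dendrite); the three threshold parameters (D_T, tau_T, E_T), which do not
enter the voltage equation, are selected by simulating the model on the
training stimulus and maximizing the coincidence rate Gamma against the
recorded trains.

The passive GLM is fitted by maximum likelihood; with an exponential link
and kernels linear in their amplitudes the log-likelihood is concave, so a
quasi-Newton ascent with analytic gradient finds the global optimum.

All stages use only the training segment of the recordings, with all
repetitions concatenated.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.signal import fftconvolve

from ._simcore import activation_series
from .glm import GLMParams, log_likelihood
from .kernels import Kernel, RectBasis
from .metrics import SpikeTrain, averaged_gamma
from .model import (DendriticParams, SomaticParams, TwoCompartmentModel,
                    m_infinity, simulate)
from .protocol import RecordingSet, default_bases

__all__ = [
    "NonlinearGrid",
    "FitResult",
    "RankDeficientError",
    "estimate_derivative",
    "fit_dendritic_linear",
    "grid_search_dendritic",
    "fit_somatic",
    "fit_twocompartment",
    "fit_glm",
    "glm_log_likelihood",
    "default_dendritic_grid",
    "default_threshold_grid",
]


class RankDeficientError(ValueError):
    """Regression design matrix is (numerically) rank deficient."""


@dataclass(frozen=True)
class NonlinearGrid:
    """Named axes of candidate values for the exhaustive search."""

    axes: dict

    def __post_init__(self) -> None:
        for name, vals in self.axes.items():
            vals = np.asarray(vals, dtype=float)
            if vals.size == 0 or not np.all(np.isfinite(vals)):
                raise ValueError(f"axis {name!r} must be non-empty and finite")

    def points(self):
        """All grid points as dicts, in lexicographic axis order."""
        names = list(self.axes)
        for combo in itertools.product(*(self.axes[n] for n in names)):
            yield dict(zip(names, (float(v) for v in combo)))

    @property
    def size(self) -> int:
        return int(np.prod([len(v) for v in self.axes.values()]))


def default_dendritic_grid() -> NonlinearGrid:
    return NonlinearGrid({
        "tau_m": [2.0, 4.0, 6.7, 10.0, 15.0],
        "d_m": [2.0, 3.5, 5.5, 8.0, 12.0],
        "e_m": [-10.0, -5.0, -0.6, 5.0],
        "tau_x": [20.0, 35.0, 50.0, 70.0, 100.0],
    })


def default_threshold_grid() -> NonlinearGrid:
    return NonlinearGrid({
        "d_t": [1.0, 2.0, 4.0],
        "tau_t": [13.5, 27.0, 54.0],
        "e_t": [-56.0, -53.0, -50.0],
    })


@dataclass
class FitResult:
    """Fitted model plus the audit trail of the search that produced it."""

    model: object
    train_mse_dvd: float | None = None
    train_mse_dvs: float | None = None
    gamma_train: float | None = None
    grid_trace: pd.DataFrame | None = None
    diagnostics: dict = field(default_factory=dict)


def estimate_derivative(v: np.ndarray, dt: float) -> np.ndarray:
    """Forward first difference (V[k+1] - V[k]) / dt, length n-1.

    Paired with regressors evaluated at sample k this matches the forward
    Euler discretization of the model exactly, which is what makes noiseless
    parameter recovery exact.
    """
    v = np.asarray(v, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two samples")
    return np.diff(v) / dt


# ---------------------------------------------------------------------------
# shared regression machinery
# ---------------------------------------------------------------------------

def _conv_columns(signal: np.ndarray, basis: RectBasis, dt: float,
                  n_rows: int) -> np.ndarray:
    """Basis-convolved input columns (n_rows, n_bins), dt-scaled."""
    fs = basis.sample(dt)
    cols = np.empty((n_rows, fs.shape[0]))
    for j in range(fs.shape[0]):
        cols[:, j] = fftconvolve(signal, fs[j] * dt)[:n_rows]
    return cols


def _spike_columns(spike_idx: np.ndarray, basis: RectBasis, dt: float,
                   n_rows: int) -> np.ndarray:
    """Basis-summed spike-train columns (lag-0 bin included)."""
    fs = basis.sample(dt)
    cols = np.zeros((n_rows, fs.shape[0]))
    L = fs.shape[1]
    for s in spike_idx:
        if s >= n_rows:
            continue
        hi = min(n_rows, s + L)
        cols[s:hi] += fs[:, : hi - s].T
    return cols


def _solve_scaled(gram: np.ndarray, rhs: np.ndarray, names, cond_limit=1e10):
    """Solve the normal equations after unit-diagonal column scaling.

    Identically-zero columns (e.g. spike-kernel regressors when the segment
    has no spikes) carry no information and are dropped with coefficient 0.
    Raises RankDeficientError naming the columns that load on the near-null
    eigenvector when the scaled Gram is ill conditioned.
    """
    d = np.sqrt(np.diag(gram))
    keep = d > 0
    idx = np.nonzero(keep)[0]
    kept_names = [names[i] for i in idx]
    g = gram[np.ix_(idx, idx)]
    r = rhs[idx]
    s = 1.0 / d[idx]
    gs = g * np.outer(s, s)
    cond = np.linalg.cond(gs)
    if cond > cond_limit:
        evals, evecs = np.linalg.eigh(gs)
        loading = np.abs(evecs[:, 0])
        bad = [kept_names[i] for i in np.nonzero(loading > 0.3)[0]]
        raise RankDeficientError(
            f"design matrix numerically rank deficient (cond={cond:.2e}); "
            f"collinear column(s): {bad}")
    w = np.zeros(gram.shape[0])
    w[idx] = s * np.linalg.solve(gs, s * r)
    return w, cond


def _initial_activation(v_d0: float, d: dict) -> tuple[float, float]:
    m0 = m_infinity(v_d0, d["e_m"], d["d_m"])
    return m0, m0


class _DendriticRegression:
    """Precomputed design blocks for the dendritic grid search.

    The regressor table is {1, V_d, I_d, basis-convolved I_s, basis-summed
    spikes, m, x}; only the m and x columns depend on the nonlinear
    parameters, so the Gram matrix of the fixed block is computed once and
    each grid point only costs the activation filtering plus a handful of
    inner products.
    """

    def __init__(self, rec: RecordingSet, bases: dict):
        dt = rec.dt
        self.dt = dt
        split = rec.split_index
        self.n_rows = split - 1
        self.eps_basis = bases["eps"]
        self.bap_basis = bases["i_bap"]
        ne, nb = self.eps_basis.n_bins, self.bap_basis.n_bins
        self.names = (["const", "V_d", "I_d"]
                      + [f"eps_sd[{j}]" for j in range(ne)]
                      + [f"I_BAP[{j}]" for j in range(nb)]
                      + ["m", "x"])
        c_sd = _conv_columns(rec.i_s[:split], self.eps_basis, dt, self.n_rows)
        blocks = []
        ys = []
        self.v_d_train = []
        for r in range(rec.n_repetitions):
            v_d = rec.v_d[r][:split]
            self.v_d_train.append(v_d)
            spike_idx = np.round(rec.train_spikes(r) / dt).astype(np.int64)
            f = np.empty((self.n_rows, 3 + ne + nb))
            f[:, 0] = 1.0
            f[:, 1] = v_d[: self.n_rows]
            f[:, 2] = rec.i_d[: self.n_rows]
            f[:, 3: 3 + ne] = c_sd
            f[:, 3 + ne:] = _spike_columns(spike_idx, self.bap_basis, dt,
                                           self.n_rows)
            blocks.append(f)
            ys.append(estimate_derivative(v_d, dt))
        self.f = np.vstack(blocks)
        self.y = np.concatenate(ys)
        self.ftf = self.f.T @ self.f
        self.fty = self.f.T @ self.y
        self.yty = float(self.y @ self.y)
        self.n_total = self.y.size

    def activation(self, nl: dict) -> tuple[np.ndarray, np.ndarray]:
        ms, xs = [], []
        for v_d in self.v_d_train:
            m0, x0 = _initial_activation(v_d[0], nl)
            m, x = activation_series(v_d, self.dt, nl["tau_m"], nl["d_m"],
                                     nl["e_m"], nl["tau_x"], m0, x0)
            ms.append(m[: self.n_rows])
            xs.append(x[: self.n_rows])
        return np.concatenate(ms), np.concatenate(xs)

    def solve(self, nl: dict):
        m, x = self.activation(nl)
        p = self.ftf.shape[0]
        gram = np.empty((p + 2, p + 2))
        rhs = np.empty(p + 2)
        gram[:p, :p] = self.ftf
        fm = self.f.T @ m
        fx = self.f.T @ x
        gram[:p, p] = gram[p, :p] = fm
        gram[:p, p + 1] = gram[p + 1, :p] = fx
        gram[p, p] = m @ m
        gram[p + 1, p + 1] = x @ x
        gram[p, p + 1] = gram[p + 1, p] = m @ x
        rhs[:p] = self.fty
        rhs[p] = m @ self.y
        rhs[p + 1] = x @ self.y
        w, cond = _solve_scaled(gram, rhs, self.names)
        mse = (self.yty - 2.0 * w @ rhs + w @ gram @ w) / self.n_total
        return w, float(mse), cond

    def to_params(self, w: np.ndarray, nl: dict) -> DendriticParams:
        ne = self.eps_basis.n_bins
        c_d = 1.0 / w[2]
        g_d = -w[1] * c_d
        e_d = w[0] * c_d / g_d
        g1 = w[-2] * c_d
        g2 = w[-1] * c_d
        eps_sd = Kernel(self.eps_basis, w[3: 3 + ne] * c_d, units="1/ms")
        i_bap = Kernel(self.bap_basis, w[3 + ne: -2] * c_d, units="pA")
        return DendriticParams(c_d=c_d, g_d=g_d, e_d=e_d, g1=g1, g2=g2,
                               tau_m=nl["tau_m"], tau_x=nl["tau_x"],
                               e_m=nl["e_m"], d_m=nl["d_m"],
                               i_bap=i_bap, eps_sd=eps_sd)


def fit_dendritic_linear(recordings: RecordingSet, nl: dict, bases: dict | None = None
                         ) -> tuple[DendriticParams, float]:
    """Multilinear regression of dV_d/dt given fixed nonlinear parameters.

    ``nl`` maps {"tau_m", "d_m", "e_m", "tau_x"} to values.  Returns the
    recovered physical dendritic parameters and the training MSE of dV_d/dt
    in (mV/ms)^2.
    """
    bases = bases or default_bases()
    reg = _DendriticRegression(recordings, bases)
    w, mse, _ = reg.solve(nl)
    return reg.to_params(w, nl), mse


def grid_search_dendritic(recordings: RecordingSet, grid: NonlinearGrid | None = None,
                          bases: dict | None = None) -> FitResult:
    """Exhaustive search of the nonlinear dendritic parameters.

    Each grid point costs one multilinear regression; the argmin-MSE point
    wins, with deterministic first-in-lexicographic-order tie-breaking.
    Regression failures at individual points are recorded and skipped.
    """
    grid = grid or default_dendritic_grid()
    bases = bases or default_bases()
    reg = _DendriticRegression(recordings, bases)
    rows = []
    best = None
    for nl in grid.points():
        try:
            w, mse, cond = reg.solve(nl)
        except RankDeficientError as exc:
            rows.append({**nl, "mse": np.nan, "error": str(exc)})
            continue
        rows.append({**nl, "mse": mse, "error": ""})
        if best is None or mse < best[1]:
            best = (nl, mse, w, cond)
    trace = pd.DataFrame(rows)
    if best is None:
        raise RankDeficientError("regression failed at every grid point")
    nl, mse, w, cond = best
    params = reg.to_params(w, nl)
    return FitResult(model=params, train_mse_dvd=mse, grid_trace=trace,
                     diagnostics={"cond": cond, "grid_size": grid.size,
                                  "winner": nl})


# ---------------------------------------------------------------------------
# somatic stage
# ---------------------------------------------------------------------------

def _somatic_regression(rec: RecordingSet, dendrite: DendriticParams,
                        bases: dict, tau_r: float):
    """Regress dV_s/dt on {1, V_s, m, I_s, spike-summed I_A, conv eps_ds}.

    Samples whose forward difference spans a spike reset or the refractory
    clamp do not obey the somatic voltage equation and are excluded.
    """
    dt = rec.dt
    split = rec.split_index
    n_rows = split - 1
    ia_basis, eps_basis = bases["i_a"], bases["eps"]
    na, ne = ia_basis.n_bins, eps_basis.n_bins
    names = (["const", "V_s", "m", "I_s"]
             + [f"I_A[{j}]" for j in range(na)]
             + [f"eps_ds[{j}]" for j in range(ne)])
    c_ds = _conv_columns(rec.i_d[:split], eps_basis, dt, n_rows)
    n_ref = int(np.round(tau_r / dt))
    nl = {"tau_m": dendrite.tau_m, "d_m": dendrite.d_m,
          "e_m": dendrite.e_m, "tau_x": dendrite.tau_x}
    xs, ys = [], []
    for r in range(rec.n_repetitions):
        v_s = rec.v_s[r][:split]
        v_d = rec.v_d[r][:split]
        m0, x0 = _initial_activation(v_d[0], nl)
        m, _ = activation_series(v_d, dt, nl["tau_m"], nl["d_m"], nl["e_m"],
                                 nl["tau_x"], m0, x0)
        spike_idx = np.round(rec.train_spikes(r) / dt).astype(np.int64)
        f = np.empty((n_rows, 4 + na + ne))
        f[:, 0] = 1.0
        f[:, 1] = v_s[:n_rows]
        f[:, 2] = m[:n_rows]
        f[:, 3] = rec.i_s[:n_rows]
        f[:, 4: 4 + na] = _spike_columns(spike_idx, ia_basis, dt, n_rows)
        f[:, 4 + na:] = c_ds
        y = estimate_derivative(v_s, dt)
        keep = np.ones(n_rows, dtype=bool)
        for s in spike_idx:
            keep[max(0, s - 1): s + n_ref + 1] = False
        xs.append(f[keep])
        ys.append(y[keep])
    x = np.vstack(xs)
    y = np.concatenate(ys)
    gram = x.T @ x
    rhs = x.T @ y
    w, cond = _solve_scaled(gram, rhs, names)
    mse = float((y @ y - 2.0 * w @ rhs + w @ gram @ w) / y.size)
    return w, mse, cond, names


def fit_somatic(recordings: RecordingSet, dendrite: DendriticParams,
                grid: NonlinearGrid | None = None, bases: dict | None = None,
                tau_r: float = 4.0, e_r: float | None = None,
                delta: float = 4.0) -> FitResult:
    """Somatic stage: linear regression then Gamma-maximizing threshold search.

    The linear somatic parameters (C_s, g_s, E_s, alpha and the I_A and
    eps_ds kernel amplitudes) come from a single multilinear regression of
    dV_s/dt; the threshold parameters (D_T, tau_T, E_T), invisible to the
    voltage equation, are then selected by simulating the candidate model on
    the training stimulus and maximizing the averaged coincidence rate
    against the recorded training spike trains.
    """
    grid = grid or default_threshold_grid()
    bases = bases or default_bases()
    dt = recordings.dt
    w, mse, cond, _names = _somatic_regression(recordings, dendrite, bases, tau_r)
    na = bases["i_a"].n_bins
    c_s = 1.0 / w[3]
    g_s = -w[1] * c_s
    e_s = w[0] * c_s / g_s
    alpha = w[2] * c_s
    i_a = Kernel(bases["i_a"], w[4: 4 + na] * c_s, units="pA")
    eps_ds = Kernel(bases["eps"], w[4 + na:] * c_s, units="1/ms")

    split = recordings.split_index
    i_s_train = recordings.i_s[:split]
    i_d_train = recordings.i_d[:split]
    split_ms = recordings.split_ms
    data_trains = []
    for r in range(recordings.n_repetitions):
        st = recordings.train_spikes(r)
        data_trains.append(SpikeTrain(st, split_ms))
    if all(len(t) == 0 for t in data_trains):
        raise ValueError("no reference spikes in the training segment")

    rows = []
    best = None
    for point in grid.points():
        soma = SomaticParams(c_s=c_s, g_s=g_s, e_s=e_s, alpha=alpha,
                             e_t=point["e_t"], d_t=point["d_t"],
                             tau_t=point["tau_t"],
                             e_r=e_s if e_r is None else e_r, tau_r=tau_r,
                             i_a=i_a, eps_ds=eps_ds)
        candidate = TwoCompartmentModel(soma=soma, dendrite=dendrite)
        try:
            trace = simulate(candidate, i_s_train, i_d_train, dt)
            model_train = SpikeTrain(trace.spike_times, split_ms)
            gamma = averaged_gamma([model_train], data_trains, delta)
        except (ValueError, AssertionError) as exc:
            rows.append({**point, "gamma": np.nan, "error": str(exc)})
            continue
        rows.append({**point, "gamma": gamma, "error": ""})
        if best is None or gamma > best[1]:
            best = (candidate, gamma, point)
    trace_df = pd.DataFrame(rows)
    if best is None:
        raise ValueError("simulation failed at every threshold grid point")
    model, gamma, point = best
    return FitResult(model=model, train_mse_dvs=mse, gamma_train=gamma,
                     grid_trace=trace_df,
                     diagnostics={"cond": cond, "winner": point})


def fit_twocompartment(recordings: RecordingSet,
                       dend_grid: NonlinearGrid | None = None,
                       thresh_grid: NonlinearGrid | None = None,
                       bases: dict | None = None, tau_r: float = 4.0,
                       delta: float = 4.0) -> FitResult:
    """Full staged fit: dendritic grid search then somatic stage."""
    dend = grid_search_dendritic(recordings, dend_grid, bases)
    result = fit_somatic(recordings, dend.model, thresh_grid, bases,
                         tau_r=tau_r, delta=delta)
    result.train_mse_dvd = dend.train_mse_dvd
    result.diagnostics["dendritic"] = dend.diagnostics
    result.diagnostics["dendritic_trace"] = dend.grid_trace
    return result


# ---------------------------------------------------------------------------
# GLM maximum likelihood
# ---------------------------------------------------------------------------

def _glm_design(rec: RecordingSet, bases: dict):
    """Training-segment design matrix and spike indicator for the GLM.

    Columns: intercept, basis-convolved somatic current, basis-convolved
    dendritic current, spike-history sums (strictly-causal: a spike does not
    contribute to its own bin).
    """
    dt = rec.dt
    split = rec.split_index
    kb = bases["eps"]     # input filters share the coupling-filter support
    eb = bases["i_a"]     # spike history shares the adaptation support
    nk, ne = kb.n_bins, eb.n_bins
    c_s = _conv_columns(rec.i_s[:split], kb, dt, split)
    c_d = _conv_columns(rec.i_d[:split], kb, dt, split)
    eb_samp0 = eb.sample(dt)[:, 0]
    xs, ys = [], []
    for r in range(rec.n_repetitions):
        spike_idx = np.round(rec.train_spikes(r) / dt).astype(np.int64)
        hist = _spike_columns(spike_idx, eb, dt, split)
        hist[spike_idx] -= eb_samp0          # strictly-causal history
        f = np.empty((split, 1 + 2 * nk + ne))
        f[:, 0] = 1.0
        f[:, 1: 1 + nk] = c_s
        f[:, 1 + nk: 1 + 2 * nk] = c_d
        f[:, 1 + 2 * nk:] = hist
        y = np.zeros(split)
        y[spike_idx] = 1.0
        xs.append(f)
        ys.append(y)
    return np.vstack(xs), np.concatenate(ys), (kb, eb)


def _params_from_w(w: np.ndarray, kb: RectBasis, eb: RectBasis) -> GLMParams:
    nk = kb.n_bins
    return GLMParams(
        log_lambda0=float(w[0]),
        kappa_s=Kernel(kb, w[1: 1 + nk], units="1/(pA ms)"),
        kappa_ds=Kernel(kb, w[1 + nk: 1 + 2 * nk], units="1/(pA ms)"),
        eta_a=Kernel(eb, w[1 + 2 * nk:], units=""),
    )


def fit_glm(recordings: RecordingSet, init: GLMParams | None = None,
            max_iter: int = 500, tol: float = 1e-6,
            bases: dict | None = None) -> FitResult:
    """Maximum-likelihood fit of the passive GLM on the training segment.

    Quasi-Newton (L-BFGS) ascent of the concave discretized point-process
    log-likelihood with analytic gradient; terminates when the gradient
    norm falls below ``tol`` (per sample) or after ``max_iter`` iterations,
    in which case the result is flagged as not converged.
    """
    bases = bases or default_bases()
    x, y, (kb, eb) = _glm_design(recordings, bases)
    dt = recordings.dt
    n = y.size
    n_spikes = float(y.sum())
    if n_spikes < 1:
        raise ValueError("need at least one training spike to fit the GLM")

    if init is None:
        w0 = np.zeros(x.shape[1])
        w0[0] = np.log(n_spikes / (n * dt))
    else:
        w0 = np.concatenate([[init.log_lambda0], init.kappa_s.amplitudes,
                             init.kappa_ds.amplitudes, init.eta_a.amplitudes])

    # unit-RMS column scaling: keeps the quasi-Newton steps well conditioned
    scale = np.sqrt(np.mean(x * x, axis=0))
    scale[scale == 0] = 1.0
    xs = x / scale
    xty = xs.T @ y

    def nll_and_grad(v):
        eta = np.clip(xs @ v, None, 60.0)
        lam_dt = np.exp(eta) * dt
        nll = -(y @ eta + n_spikes * np.log(dt) - lam_dt.sum())
        grad = -(xty - xs.T @ lam_dt)
        return nll, grad

    trace = []
    res = minimize(nll_and_grad, w0 * scale, jac=True, method="L-BFGS-B",
                   callback=lambda v: trace.append(nll_and_grad(v)[0]),
                   options={"maxiter": max_iter, "gtol": tol * n,
                            "ftol": 1e-14})
    params = _params_from_w(res.x / scale, kb, eb)
    grad_norm = float(np.linalg.norm(res.jac))
    converged = bool(res.success or grad_norm < tol * n)
    return FitResult(
        model=params,
        diagnostics={"converged": converged, "n_iter": res.nit,
                     "grad_norm": grad_norm, "log_likelihood": -float(res.fun),
                     "nll_trace": trace, "message": str(res.message)},
    )


def glm_log_likelihood(params: GLMParams, recordings: RecordingSet,
                       segment: str = "train") -> float:
    """Point-process log-likelihood of a RecordingSet segment, summed over
    repetitions."""
    dt = recordings.dt
    split = recordings.split_index
    total = 0.0
    for r in range(recordings.n_repetitions):
        if segment == "train":
            i_s, i_d = recordings.i_s[:split], recordings.i_d[:split]
            st = recordings.train_spikes(r)
        elif segment == "test":
            i_s, i_d = recordings.i_s[split:], recordings.i_d[split:]
            st = recordings.test_spikes(r)
        else:
            i_s, i_d = recordings.i_s, recordings.i_d
            st = recordings.spike_times[r]
        total += log_likelihood(params, i_s, i_d, st, dt)
    return total
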