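"""Generalized passive control model: an exponential-link point process.

The control for the active-dendrite hypothesis treats dendritic integration
as purely passive: spikes are emitted stochastically with instantaneous rate

    lambda(t) = lambda_0 exp( (kappa_s * I_s)(t) + (kappa_ds * I_d)(t)
                              + sum_i eta_A(t - that_i) )

where kappa_s is the somatic input filter, kappa_ds the dendro-somatic input
filter, and eta_A a spike-history kernel expressing adaptation and
refractoriness.  With kernels on a rectangular basis the log-intensity is
linear in the parameters and the log-likelihood is concave, so maximum
likelihood is a convex problem (see :mod:`adgif.fitting`).

Time is discretized at the recording step dt; a spike affects the intensity
of strictly later bins.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from ._simcore import sample_glm_spikes
from .kernels import Kernel

__all__ = ["GLMParams", "intensity", "sample_spikes", "log_likelihood",
           "bernoulli_log_likelihood"]


@dataclass(frozen=True)
class GLMParams:
    """Baseline log-rate plus the three filters of the passive model."""

    log_lambda0: float                       # log of baseline rate, spikes/ms
    kappa_s: Kernel = field(default_factory=Kernel.zero)    # per pA per ms
    kappa_ds: Kernel = field(default_factory=Kernel.zero)   # per pA per ms
    eta_a: Kernel = field(default_factory=Kernel.zero)      # dimensionless

    def to_dict(self) -> dict:
        return {
            "log_lambda0": self.log_lambda0,
            "kappa_s": self.kappa_s.to_dict(),
            "kappa_ds": self.kappa_ds.to_dict(),
            "eta_A": self.eta_a.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GLMParams":
        return cls(
            log_lambda0=d["log_lambda0"],
            kappa_s=Kernel.from_dict(d["kappa_s"]),
            kappa_ds=Kernel.from_dict(d["kappa_ds"]),
            eta_a=Kernel.from_dict(d["eta_A"]),
        )

    def to_json(self, path=None) -> str:
        s = json.dumps(self.to_dict(), indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_json(cls, source) -> "GLMParams":
        try:
            obj = json.loads(source)
        except (json.JSONDecodeError, TypeError):
            with open(source) as fh:
                obj = json.load(fh)
        return cls.from_dict(obj)


def _validate(i_s, i_d, dt):
    i_s = np.ascontiguousarray(i_s, dtype=float)
    i_d = np.ascontiguousarray(i_d, dtype=float)
    if i_s.shape != i_d.shape or i_s.ndim != 1:
        raise ValueError("i_s and i_d must be 1-d arrays of equal length")
    if not (np.all(np.isfinite(i_s)) and np.all(np.isfinite(i_d))):
        raise ValueError("input currents must be finite")
    if dt <= 0:
        raise ValueError("dt must be positive")
    return i_s, i_d


def log_intensity_input(params: GLMParams, i_s, i_d, dt: float) -> np.ndarray:
    """Input-dependent part of log lambda (everything but spike history)."""
    i_s, i_d = _validate(i_s, i_d, dt)
    return (params.log_lambda0
            + params.kappa_s.convolve(i_s, dt)
            + params.kappa_ds.convolve(i_d, dt))


def _history_series(eta: Kernel, spike_times, t_grid) -> np.ndarray:
    """Summed spike-history kernel; a spike contributes only strictly after."""
    spike_times = np.asarray(spike_times, dtype=float)
    out = np.zeros_like(t_grid)
    for ts in spike_times:
        lags = t_grid - ts
        vals = np.asarray(eta.evaluate(lags))
        vals[lags <= 0] = 0.0
        out += vals
    return out


def intensity(params: GLMParams, i_s, i_d, spike_history=(), dt: float = 0.1
              ) -> np.ndarray:
    """Instantaneous firing rate lambda(t) (spikes/ms) on the input grid.

    Strictly positive and causal: the value at sample k depends only on
    inputs at samples <= k and spikes at strictly earlier times.
    """
    i_s, i_d = _validate(i_s, i_d, dt)
    t_grid = np.arange(i_s.size) * dt
    log_lam = log_intensity_input(params, i_s, i_d, dt)
    log_lam += _history_series(params.eta_a, spike_history, t_grid)
    return np.exp(log_lam)


def sample_spikes(params: GLMParams, i_s, i_d, dt: float, seed: int) -> np.ndarray:
    """Draw one spike train (times in ms) from the model.

    Bernoulli per bin with probability 1 - exp(-lambda dt), with the spike
    history updated online; reproducible given the seed.
    """
    i_s, i_d = _validate(i_s, i_d, dt)
    log_lam = log_intensity_input(params, i_s, i_d, dt)
    if np.exp(np.max(log_lam)) * dt >= 1.0:
        warnings.warn("lambda*dt reaches 1; discretization is coarse for this "
                      "rate -- consider a smaller dt", stacklevel=2)
    idx = sample_glm_spikes(log_lam, dt, params.eta_a.sample(dt),
                            int(seed) % (2 ** 32))
    return idx * dt


def log_likelihood(params: GLMParams, i_s, i_d, spike_times, dt: float) -> float:
    """Discretized point-process log-likelihood of one recorded train.

    sum over spike bins of log(lambda dt) minus sum over all bins of
    lambda dt.  Higher is better; concave in the kernel amplitudes and in
    log lambda_0.
    """
    i_s, i_d = _validate(i_s, i_d, dt)
    spike_times = np.asarray(spike_times, dtype=float)
    if spike_times.size and np.any(np.diff(spike_times) < 0):
        raise ValueError("spike times must be sorted")
    t_grid = np.arange(i_s.size) * dt
    log_lam = log_intensity_input(params, i_s, i_d, dt)
    log_lam += _history_series(params.eta_a, spike_times, t_grid)
    spike_idx = np.round(spike_times / dt).astype(int)
    if spike_idx.size and (spike_idx[0] < 0 or spike_idx[-1] >= i_s.size):
        raise ValueError("spike times outside the recording")
    return float(np.sum(log_lam[spike_idx]) + spike_idx.size * np.log(dt)
                 - np.sum(np.exp(log_lam)) * dt)


def bernoulli_log_likelihood(params: GLMParams, i_s, i_d, spike_times,
                             dt: float) -> float:
    """Exact Bernoulli-per-bin log-likelihood (matches ``sample_spikes``).

    Useful for cross-checking the Poisson-bin approximation used by
    :func:`log_likelihood`; the two agree to O(lambda dt) per bin.
    """
    i_s, i_d = _validate(i_s, i_d, dt)
    t_grid = np.arange(i_s.size) * dt
    log_lam = log_intensity_input(params, i_s, i_d, dt)
    log_lam += _history_series(params.eta_a, np.asarray(spike_times, float), t_grid)
    lam_dt = np.exp(log_lam) * dt
    p = 1.0 - np.exp(-lam_dt)
    y = np.zeros(i_s.size, dtype=bool)
    y[np.round(np.asarray(spike_times, float) / dt).astype(int)] = True
    return float(np.sum(np.log(p[y])) + np.sum(-lam_dt[~y]))
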