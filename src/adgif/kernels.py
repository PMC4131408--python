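"""Temporal filters on a rectangular (piecewise-constant) basis.

Every filter in the model -- the compartment coupling filters ``eps_sd`` and
``eps_ds``, the spike-triggered adaptation current ``I_A``, the
back-propagating action-potential current ``I_BAP``, and the three GLM
kernels ``kappa_s``, ``kappa_ds``, ``eta_A`` -- is a linear combination of
contiguous rectangular basis functions.  Writing a filter as
``k(t) = sum_i a_i f_i(t)`` with indicator functions ``f_i`` makes the
amplitudes ``a_i`` linear parameters of the voltage-derivative regression
and of the GLM log-likelihood, which is what the staged fitting procedure
exploits.

Bins are half-open ``[e_i, e_{i+1})``: the value at the exact left edge
belongs to that bin, and the kernel is zero before the first edge and from
the last edge on (causal, finite support).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import fftconvolve

__all__ = ["RectBasis", "Kernel", "log_spaced_edges"]


def log_spaced_edges(t_first: float, t_last: float, n_bins: int) -> np.ndarray:
    """Edges ``[0, t_first, ..., t_last]`` with geometric interior spacing.

    A short first bin plus geometrically growing bins covers fast transients
    and slow tails with few parameters; ``n_bins`` counts the total number of
    bins including the initial ``[0, t_first)`` one.
    """
    if not (0 < t_first < t_last):
        raise ValueError("need 0 < t_first < t_last")
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    return np.concatenate([[0.0], np.geomspace(t_first, t_last, n_bins)])


@dataclass(frozen=True)
class RectBasis:
    """Ordered bin edges (ms) defining contiguous half-open bins."""

    edges: np.ndarray

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges, dtype=float)
        if edges.ndim != 1 or edges.size < 2:
            raise ValueError("edges must be a 1-d sequence with at least 2 entries")
        if not np.all(np.isfinite(edges)):
            raise ValueError("edges must be finite")
        if np.any(np.diff(edges) <= 0):
            raise ValueError("edges must be strictly increasing")
        if edges[0] < 0:
            raise ValueError("first edge must be >= 0")
        object.__setattr__(self, "edges", edges)

    @property
    def n_bins(self) -> int:
        return self.edges.size - 1

    @property
    def support(self) -> tuple[float, float]:
        return float(self.edges[0]), float(self.edges[-1])

    def bin_index(self, t) -> np.ndarray:
        """Bin index for each time, -1 outside the support."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.edges, t, side="right") - 1
        idx = np.where((t < self.edges[0]) | (t >= self.edges[-1]), -1, idx)
        return idx

    def sample(self, dt: float) -> np.ndarray:
        """Indicator matrix ``(n_bins, n_samples)`` on the grid ``t = k*dt``."""
        n = int(np.ceil(self.edges[-1] / dt))
        t = np.arange(n) * dt
        idx = self.bin_index(t)
        out = np.zeros((self.n_bins, n))
        valid = idx >= 0
        out[idx[valid], np.nonzero(valid)[0]] = 1.0
        return out


@dataclass(frozen=True)
class Kernel:
    """Piecewise-constant causal filter: one amplitude per basis bin.

    Amplitude units depend on the filter's role (pA for spike-triggered
    currents, per-ms transfer gains for the coupling filters, per-pA-per-ms
    for the GLM input filters, dimensionless for spike history).
    """

    basis: RectBasis
    amplitudes: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        amp = np.asarray(self.amplitudes, dtype=float)
        if amp.ndim != 1 or amp.size != self.basis.n_bins:
            raise ValueError(
                f"expected {self.basis.n_bins} amplitudes, got {amp.size}"
            )
        if not np.all(np.isfinite(amp)):
            raise ValueError("amplitudes must be finite")
        object.__setattr__(self, "amplitudes", amp)

    # -- evaluation ---------------------------------------------------------

    def __call__(self, t):
        return self.evaluate(t)

    def evaluate(self, t):
        """Kernel value at time(s) ``t`` (ms); zero outside the support."""
        t = np.asarray(t, dtype=float)
        idx = self.basis.bin_index(t)
        padded = np.concatenate([self.amplitudes, [0.0]])
        out = padded[idx]
        return out if out.ndim else float(out)

    def sample(self, dt: float) -> np.ndarray:
        """Kernel values on the grid ``t = k*dt`` covering the support."""
        n = int(np.ceil(self.basis.edges[-1] / dt))
        return np.asarray(self.evaluate(np.arange(n) * dt))

    @property
    def integral(self) -> float:
        """Exact integral over the support (amplitude times bin width)."""
        return float(np.dot(self.amplitudes, np.diff(self.basis.edges)))

    # -- convolution --------------------------------------------------------

    def convolve(self, signal: np.ndarray, dt: float) -> np.ndarray:
        """Causal discrete convolution ``(k * s)[n] = sum_u k(u dt) s[n-u] dt``.

        The dt factor keeps the output in physical units regardless of the
        sampling rate.  Output has the input's length; sample ``n`` depends
        only on inputs at samples ``<= n``.
        """
        signal = np.asarray(signal, dtype=float)
        if dt <= 0:
            raise ValueError("dt must be positive")
        if signal.ndim != 1:
            raise ValueError("signal must be 1-d")
        k = self.sample(dt)
        if k.size == 0:
            return np.zeros_like(signal)
        return fftconvolve(signal, k * dt)[: signal.size]

    def convolve_spikes(self, spike_times: Sequence[float], t_grid: np.ndarray) -> np.ndarray:
        """Summed kernel responses ``sum_i k(t - that_i)`` on a time grid.

        Spikes must be sorted ascending; a spike contributes from its own
        grid time on (the bin at lag zero is included).
        """
        t_grid = np.asarray(t_grid, dtype=float)
        spike_times = np.asarray(spike_times, dtype=float)
        if spike_times.size and np.any(np.diff(spike_times) < 0):
            raise ValueError("spike times must be sorted ascending")
        out = np.zeros_like(t_grid)
        for ts in spike_times:
            out += self.evaluate(t_grid - ts)
        return out

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "edges": self.basis.edges.tolist(),
            "amplitudes": self.amplitudes.tolist(),
            "units": self.units,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Kernel":
        return cls(RectBasis(np.asarray(d["edges"])), np.asarray(d["amplitudes"]),
                   d.get("units", ""))

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "Kernel":
        return cls.from_dict(json.loads(s))

    def to_csv(self, path, dt: float = 0.1) -> None:
        """Two-column CSV (t_ms, value) sampled on a dt grid, for plotting."""
        t = np.arange(int(np.ceil(self.basis.edges[-1] / dt))) * dt
        np.savetxt(path, np.column_stack([t, self.sample(dt)]),
                   delimiter=",", header="t_ms,value", comments="")

    @classmethod
    def zero(cls, edges=(0.0, 1.0), units: str = "") -> "Kernel":
        basis = RectBasis(np.asarray(edges, dtype=float))
        return cls(basis, np.zeros(basis.n_bins), units)

    @classmethod
    def from_function(cls, f, edges, units: str = "") -> "Kernel":
        """Discretize a continuous function onto the basis by bin midpoints."""
        basis = RectBasis(np.asarray(edges, dtype=float))
        mid = 0.5 * (basis.edges[:-1] + basis.edges[1:])
        return cls(basis, np.asarray([float(f(t)) for t in mid]), units)
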