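"""Spike-timing evaluation: the coincidence rate Gamma and friends.

The pairwise coincidence rate between a reference ("neuron") train n and a
predicted ("model") train m counts the coincidences N_nm -- spikes of the
model within +/- Delta of a neuron spike, each spike participating in at
most one coincidence -- corrects for the chance count expected from a
Poisson process at the model's rate, N_Poisson = 2 Delta N_m N_n / T, and
normalizes so that a perfect match gives 1 and chance gives ~0:

    Gamma_nm = (N_nm - N_Poisson) / (0.5 (1 - N_Poisson/N_n) (N_n + N_m))

The formula is asymmetric: the reference train supplies N_n in the
normalization.  Averaging Gamma_nm over all model/data train pairings gives
the averaged coincidence rate; averaging over distinct pairs of data
repetitions to the same frozen stimulus gives the intrinsic reliability R,
the natural upper reference for model performance, and Gamma/R the scaled
coincidence rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SpikeTrain",
    "GammaReport",
    "count_coincidences",
    "pairwise_gamma",
    "averaged_gamma",
    "intrinsic_reliability",
    "gamma_report",
    "isi_histogram",
]


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted spike times (ms) on a recording segment of length ``duration``."""

    times: np.ndarray
    duration: float

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        if times.ndim != 1:
            raise ValueError("times must be 1-d")
        if times.size and (np.any(np.diff(times) <= 0)):
            raise ValueError("spike times must be strictly increasing")
        if times.size and (times[0] < 0 or times[-1] >= self.duration):
            raise ValueError("spike times must lie in [0, duration)")
        object.__setattr__(self, "times", times)

    def __len__(self) -> int:
        return self.times.size


def count_coincidences(a: np.ndarray, b: np.ndarray, delta: float) -> int:
    """Number of one-to-one coincidences within a closed window ``delta``.

    Greedy earliest-first matching over the two sorted trains; each spike
    participates in at most one coincidence, which prevents a single model
    spike near a burst from being counted several times.  For this interval
    structure the greedy count equals the maximum bipartite matching.
    """
    i = j = n = 0
    na, nb = len(a), len(b)
    while i < na and j < nb:
        d = a[i] - b[j]
        if abs(d) <= delta:
            n += 1
            i += 1
            j += 1
        elif d > delta:
            j += 1
        else:
            i += 1
    return n


def pairwise_gamma(neuron: SpikeTrain, model: SpikeTrain, delta: float = 4.0) -> float:
    """Chance-corrected coincidence rate between one data and one model train."""
    n_n, n_m = len(neuron), len(model)
    if n_n == 0:
        raise ValueError("no reference spikes")
    if neuron.duration != model.duration:
        raise ValueError("trains must share the same duration")
    t = neuron.duration
    n_nm = count_coincidences(neuron.times, model.times, delta)
    n_poisson = 2.0 * delta * n_m * n_n / t
    # algebraically 0.5 (1 - N_P/N_n)(N_n + N_m); this arrangement makes the
    # identical-train case collapse to exactly 1 in floating point
    denom = 0.5 * ((n_n + n_m) - n_poisson * (n_n + n_m) / n_n)
    return (n_nm - n_poisson) / denom


def averaged_gamma(model_trains, data_trains, delta: float = 4.0) -> float:
    """Mean pairwise Gamma over the full data x model cartesian product.

    Data trains act as the reference; empty data trains are skipped with a
    warning (Gamma is undefined without reference spikes).
    """
    model_trains = list(model_trains)
    data_trains = list(data_trains)
    if not model_trains or not data_trains:
        raise ValueError("need at least one model and one data train")
    values = []
    for data in data_trains:
        if len(data) == 0:
            warnings.warn("skipping empty reference train", stacklevel=2)
            continue
        for model in model_trains:
            values.append(pairwise_gamma(data, model, delta))
    if not values:
        raise ValueError("all reference trains empty")
    return float(np.mean(values))


def intrinsic_reliability(data_trains, delta: float = 4.0) -> float:
    """Mean pairwise Gamma over ordered distinct pairs of data repetitions."""
    data_trains = list(data_trains)
    if len(data_trains) < 2:
        raise ValueError("need at least two repetitions")
    values = []
    for i, a in enumerate(data_trains):
        for j, b in enumerate(data_trains):
            if i == j or len(a) == 0:
                continue
            values.append(pairwise_gamma(a, b, delta))
    if not values:
        raise ValueError("all reference trains empty")
    return float(np.mean(values))


@dataclass(frozen=True)
class GammaReport:
    """Pairwise Gamma matrix plus the summary rates for one evaluation."""

    pairwise: np.ndarray          # (n_data, n_model) Gamma_nm
    averaged_gamma: float
    intrinsic_r: float
    scaled: float                 # averaged_gamma / intrinsic_r
    delta: float

    def to_dict(self) -> dict:
        return {
            "pairwise": self.pairwise.tolist(),
            "averaged_gamma": self.averaged_gamma,
            "intrinsic_reliability": self.intrinsic_r,
            "scaled_coincidence": self.scaled,
            "delta_ms": self.delta,
        }


def gamma_report(model_trains, data_trains, delta: float = 4.0) -> GammaReport:
    """Full evaluation: pairwise matrix, averaged Gamma, R and Gamma/R."""
    model_trains = list(model_trains)
    data_trains = list(data_trains)
    pairwise = np.full((len(data_trains), len(model_trains)), np.nan)
    for i, data in enumerate(data_trains):
        if len(data) == 0:
            continue
        for j, model in enumerate(model_trains):
            pairwise[i, j] = pairwise_gamma(data, model, delta)
    avg = averaged_gamma(model_trains, data_trains, delta)
    r = intrinsic_reliability(data_trains, delta) if len(data_trains) > 1 else np.nan
    scaled = avg / r if r else np.nan
    return GammaReport(pairwise, avg, r, scaled, delta)


def isi_histogram(trains, bin_edges) -> np.ndarray:
    """Pooled inter-spike-interval histogram across trains."""
    bin_edges = np.asarray(bin_edges, dtype=float)
    isis = [np.diff(t.times) for t in trains if len(t) > 1]
    pooled = np.concatenate(isis) if isis else np.empty(0)
    counts, _ = np.histogram(pooled, bin_edges)
    return counts
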