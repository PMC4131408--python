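"""In-silico characterizations of dendritic excitability.

Three classic protocols probe whether a fitted model expresses the
back-propagation-activated calcium dynamics of layer-5 pyramidal cells:

* **critical frequency** -- force a train of 5 somatic spikes at increasing
  rates with no dendritic injection and measure the integral of the
  dendritic depolarization; supralinear summation of the BAP currents makes
  the curve rise above the frequency-independent linear prediction.
* **gain modulation** -- the slope of the firing-rate vs mean-somatic-current
  curve (measured between 5 and 50 Hz) as a function of the mean dendritic
  current; dendritic calcium activation increases the gain.
* **spike- and burst-triggered average input currents** -- bursts signal
  coincident dendritic drive, so the burst-triggered dendritic current
  exceeds the somatic one while isolated spikes show the opposite ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .metrics import SpikeTrain
from .model import TwoCompartmentModel, simulate, simulate_forced_spikes
from .protocol import ou_current

__all__ = [
    "CriticalFrequencyResult",
    "GainCurve",
    "critical_frequency",
    "gain_modulation",
    "triggered_average",
    "detect_bursts",
    "split_burst_events",
]


@dataclass(frozen=True)
class CriticalFrequencyResult:
    """Normalized dendritic-voltage integrals vs forced spiking frequency."""

    frequencies: np.ndarray        # Hz
    normalized_integrals: np.ndarray
    critical_frequency: float      # Hz, half-rise of the logistic fit
    supralinear: bool              # False when the curve is essentially flat
    logistic_params: tuple         # (bottom, top, midpoint, slope-scale)
    relative_rise: float           # (max - min) / max of the raw integrals


def _logistic(f, bottom, top, f0, scale):
    return bottom + (top - bottom) / (1.0 + np.exp(-(f - f0) / scale))


def critical_frequency(model: TwoCompartmentModel, frequencies,
                       n_spikes: int = 5, dt: float = 0.1,
                       settle_ms: float = 400.0,
                       supralinearity_threshold: float = 0.05
                       ) -> CriticalFrequencyResult:
    """Force ``n_spikes`` somatic spikes at each frequency and integrate V_d.

    For each frequency f the spikes are forced at intervals 1000/f ms with
    zero dendritic current; the response integral int (V_d - V_rest) dt is
    taken over the train plus ``settle_ms`` of relaxation, normalized to the
    maximum across frequencies.  The critical frequency is the midpoint
    (half-rise) of a 4-parameter logistic fit to the normalized integral vs
    frequency, clipped into the tested range.  When the integral varies by
    less than ``supralinearity_threshold`` (relative) across frequencies the
    curve is flagged non-supralinear -- a model without the calcium current
    sums BAPs linearly and its integral is frequency independent.
    """
    frequencies = np.asarray(frequencies, dtype=float)
    if frequencies.size < 3:
        raise ValueError("need at least three frequencies")
    if np.any(np.diff(frequencies) <= 0) or frequencies[0] <= 0:
        raise ValueError("frequencies must be positive and strictly increasing")
    rest = model.resting_state()["v_d"]
    integrals = np.empty(frequencies.size)
    for i, f in enumerate(frequencies):
        isi = 1000.0 / f
        spikes = np.arange(n_spikes) * isi
        duration = spikes[-1] + settle_ms
        trace = simulate_forced_spikes(model, spikes, None, dt, duration)
        integrals[i] = np.sum(trace.v_d - rest) * dt
    top = np.max(np.abs(integrals))
    if top == 0:
        raise ValueError("dendritic response identically zero")
    y = integrals / integrals.max()
    rise = float((integrals.max() - integrals.min()) / integrals.max())
    supralinear = rise >= supralinearity_threshold

    p0 = [float(y.min()), float(y.max()), float(np.median(frequencies)),
          float((frequencies[-1] - frequencies[0]) / 8.0)]
    try:
        popt, _ = curve_fit(_logistic, frequencies, y, p0=p0, maxfev=20000)
        f0 = float(popt[2])
    except RuntimeError:
        # fall back to the min-max half-rise crossing
        ymm = (y - y.min()) / (y.max() - y.min())
        f0 = float(frequencies[np.argmax(ymm >= 0.5)])
        popt = np.array([y.min(), y.max(), f0, np.nan])
    f0 = float(np.clip(f0, frequencies[0], frequencies[-1]))
    return CriticalFrequencyResult(frequencies, y, f0, supralinear,
                                   tuple(float(v) for v in popt), rise)


@dataclass(frozen=True)
class GainCurve:
    """f-I slope (5-50 Hz band) per mean dendritic current level."""

    mean_dendritic_currents: np.ndarray   # pA
    slopes: np.ndarray                    # Hz/pA; NaN where undefined
    rates: np.ndarray                     # (n_dendritic, n_somatic) Hz
    mean_somatic_currents: np.ndarray     # pA
    undefined: list = field(default_factory=list)


def gain_modulation(model: TwoCompartmentModel, mean_dendritic,
                    mean_somatic, sigma: float = 300.0, tau: float = 3.0,
                    duration: float = 20000.0, dt: float = 0.1,
                    seed: int = 0, rate_band: tuple = (5.0, 50.0)) -> GainCurve:
    """Measure the f-I slope at each mean dendritic current level.

    For each (mu_d, mu_s) pair the model is driven for ``duration`` ms by
    independent OU currents (std ``sigma``, correlation time ``tau``) and
    the mean firing rate recorded; per dendritic level, a least-squares line
    is fitted to rate vs mu_s over the somatic levels whose rates fall in
    ``rate_band`` (Hz).  Levels with fewer than two usable points get a NaN
    slope and are reported in ``undefined``.
    """
    mean_dendritic = np.asarray(mean_dendritic, dtype=float)
    mean_somatic = np.asarray(mean_somatic, dtype=float)
    rates = np.empty((mean_dendritic.size, mean_somatic.size))
    ss = np.random.SeedSequence([int(seed), 0x6A11])
    seeds = ss.generate_state(2 * rates.size).reshape(rates.shape + (2,))
    dur_s = duration / 1000.0
    for i, mu_d in enumerate(mean_dendritic):
        for j, mu_s in enumerate(mean_somatic):
            i_s = ou_current(mu_s, sigma, tau, duration, dt, seeds[i, j, 0])
            i_d = ou_current(mu_d, sigma, tau, duration, dt, seeds[i, j, 1])
            trace = simulate(model, i_s, i_d, dt)
            rates[i, j] = trace.n_spikes / dur_s
    slopes = np.full(mean_dendritic.size, np.nan)
    undefined = []
    lo, hi = rate_band
    for i in range(mean_dendritic.size):
        sel = (rates[i] >= lo) & (rates[i] <= hi)
        if sel.sum() < 2:
            undefined.append(float(mean_dendritic[i]))
            continue
        slopes[i] = np.polyfit(mean_somatic[sel], rates[i, sel], 1)[0]
    return GainCurve(mean_dendritic, slopes, rates, mean_somatic, undefined)


def triggered_average(current, trigger_times, window, dt: float = 0.1
                      ) -> tuple[np.ndarray, np.ndarray, int]:
    """Average of current segments aligned on trigger times.

    ``window`` is (pre_ms, post_ms); the returned lags run from -pre to
    +post.  Triggers whose window extends beyond the recording are dropped;
    the dropped count is returned alongside.
    """
    current = np.asarray(current, dtype=float)
    trigger_times = np.asarray(trigger_times, dtype=float)
    pre, post = window
    n_pre = int(round(pre / dt))
    n_post = int(round(post / dt))
    segments = []
    dropped = 0
    for ts in trigger_times:
        k = int(round(ts / dt))
        if k - n_pre < 0 or k + n_post + 1 > current.size:
            dropped += 1
            continue
        segments.append(current[k - n_pre: k + n_post + 1])
    if not segments:
        raise ValueError("no trigger with a complete window inside the recording")
    lags = np.arange(-n_pre, n_post + 1) * dt
    return lags, np.mean(segments, axis=0), dropped


def detect_bursts(train: SpikeTrain, max_isi: float = 15.0) -> np.ndarray:
    """Burst onset times: first spikes of maximal runs with ISIs <= max_isi."""
    onsets, _ = split_burst_events(train, max_isi)
    return onsets


def split_burst_events(train: SpikeTrain, max_isi: float = 15.0
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Partition a train into burst onsets and isolated spikes.

    A burst is a maximal run of >= 2 spikes whose consecutive ISIs are all
    <= ``max_isi`` (ms); every spike belongs to exactly one burst or is
    isolated.
    """
    if max_isi <= 0:
        raise ValueError("max_isi must be positive")
    t = train.times
    if t.size == 0:
        return np.empty(0), np.empty(0)
    short = np.diff(t) <= max_isi
    onsets, isolated = [], []
    i = 0
    while i < t.size:
        j = i
        while j < t.size - 1 and short[j]:
            j += 1
        if j > i:
            onsets.append(t[i])
        else:
            isolated.append(t[i])
        i = j + 1
    return np.asarray(onsets), np.asarray(isolated)
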