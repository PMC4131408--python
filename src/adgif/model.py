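"""Two-compartment model of a layer-5 pyramidal neuron with an active dendrite.

The soma is a leaky integrate-and-fire unit with a moving threshold and a
spike-triggered adaptation current; the apical dendrite is a leaky
compartment carrying a calcium-like current ``g1*m`` and a slower
calcium-activated-potassium-like current ``g2*x``, where m relaxes toward a
sigmoid of the dendritic voltage and x relaxes toward m.  The compartments
communicate through measurable impulse-response filters: injected currents
cross over through the passive coupling kernels (``eps_ds`` dendrite-to-soma,
``eps_sd`` soma-to-dendrite), each somatic spike injects a stereotyped
back-propagating action-potential current ``I_BAP`` into the dendrite, and
the calcium activation feeds back a current ``alpha*m`` into the soma.

State variables::

    C_s dV_s/dt = -g_s (V_s - E_s) + alpha m + I_s + sum I_A(t - that_i) + (eps_ds * I_d)(t)
    C_d dV_d/dt = -g_d (V_d - E_d) + g1 m + g2 x + I_d + sum I_BAP(t - that_i) + (eps_sd * I_s)(t)
    tau_m dm/dt = sigmoid((V_d - E_m)/D_m) - m
    tau_x dx/dt = m - x
    tau_T dV_T/dt = -(V_T - E_T)   with a jump of D_T at each spike

A spike is emitted when V_s exceeds the moving threshold V_T; V_s is then
reset to E_r and clamped for an absolute refractory period tau_R, during
which the dendrite and threshold keep evolving.

Units form a self-consistent (pA, pF, nS, mV, ms) system: pA/pF = mV/ms and
nS*mV = pA.  Integration is fixed-step forward Euler for the two voltage
equations with exact exponential updates for the linear relaxations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from ._simcore import run_twocomp
from .kernels import Kernel

__all__ = [
    "SomaticParams",
    "DendriticParams",
    "TwoCompartmentModel",
    "SimulationTrace",
    "m_infinity",
    "simulate",
    "simulate_forced_spikes",
]


def m_infinity(v_d, e_m: float, d_m: float):
    """Steady-state calcium activation: logistic sigmoid of dendritic voltage.

    Strictly increasing in ``v_d`` for positive sensitivity ``d_m`` (mV);
    equals 0.5 at the half-activation potential ``e_m``.
    """
    if d_m == 0:
        raise ValueError("activation sensitivity d_m must be nonzero")
    v_d = np.asarray(v_d, dtype=float)
    out = 1.0 / (1.0 + np.exp(-(v_d - e_m) / d_m))
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class SomaticParams:
    """Somatic compartment: leaky integrator, moving threshold, adaptation."""

    c_s: float = 379.0     # capacitance, pF
    g_s: float = 22.0      # leak conductance, nS
    e_s: float = -73.0     # leak reversal, mV
    alpha: float = 337.0   # somatic current per unit calcium activation, pA
    e_t: float = -53.0     # threshold baseline, mV
    d_t: float = 2.0       # spike-triggered threshold jump, mV
    tau_t: float = 27.0    # threshold relaxation time constant, ms
    e_r: float = -73.0     # post-spike reset potential, mV
    tau_r: float = 4.0     # absolute refractory period, ms
    i_a: Kernel = field(default_factory=Kernel.zero)       # adaptation current, pA
    eps_ds: Kernel = field(default_factory=Kernel.zero)    # dendrite->soma coupling

    def __post_init__(self) -> None:
        if self.c_s <= 0 or self.g_s <= 0:
            raise ValueError("c_s and g_s must be positive")
        if self.tau_t <= 0:
            raise ValueError("tau_t must be positive")
        if self.tau_r < 0:
            raise ValueError("tau_r must be nonnegative")


@dataclass(frozen=True)
class DendriticParams:
    """Dendritic compartment: leaky integrator with the calcium nonlinearity."""

    c_d: float = 86.0      # capacitance, pF
    g_d: float = 22.0      # leak conductance, nS
    e_d: float = -53.0     # leak reversal, mV
    g1: float = 567.0      # maximal calcium-like current, pA
    g2: float = -207.0     # maximal K(Ca)-like current, pA
    tau_m: float = 6.7     # activation time constant, ms
    tau_x: float = 49.9    # recovery time constant, ms
    e_m: float = -0.6      # half-activation potential, mV
    d_m: float = 5.5       # activation sensitivity, mV
    i_bap: Kernel = field(default_factory=Kernel.zero)     # BAP current, pA
    eps_sd: Kernel = field(default_factory=Kernel.zero)    # soma->dendrite coupling

    def __post_init__(self) -> None:
        if self.c_d <= 0 or self.g_d <= 0:
            raise ValueError("c_d and g_d must be positive")
        if self.tau_m <= 0 or self.tau_x <= 0:
            raise ValueError("tau_m and tau_x must be positive")
        if self.d_m == 0:
            raise ValueError("d_m must be nonzero")


@dataclass(frozen=True)
class TwoCompartmentModel:
    soma: SomaticParams = field(default_factory=SomaticParams)
    dendrite: DendriticParams = field(default_factory=DendriticParams)

    def resting_state(self) -> dict:
        """Fixed point of the subthreshold dynamics, found by iteration.

        With the default parameters the calcium activation at rest is tiny
        (m_inf(E_d) ~ 1e-4) so the rest potentials sit essentially at the
        leak reversals.
        """
        s, d = self.soma, self.dendrite
        v_d = d.e_d
        for _ in range(200):
            m = m_infinity(v_d, d.e_m, d.d_m)
            v_d_new = d.e_d + (d.g1 * m + d.g2 * m) / d.g_d
            if abs(v_d_new - v_d) < 1e-12:
                v_d = v_d_new
                break
            v_d = v_d_new
        m = m_infinity(v_d, d.e_m, d.d_m)
        v_s = s.e_s + s.alpha * m / s.g_s
        return {"v_s": v_s, "v_d": v_d, "m": m, "x": m, "v_t": s.e_t}

    def to_dict(self) -> dict:
        s, d = self.soma, self.dendrite
        return {
            "soma": {
                "C_s": s.c_s, "g_s": s.g_s, "E_s": s.e_s, "alpha": s.alpha,
                "E_T": s.e_t, "D_T": s.d_t, "tau_T": s.tau_t,
                "E_r": s.e_r, "tau_R": s.tau_r,
                "I_A": s.i_a.to_dict(), "eps_ds": s.eps_ds.to_dict(),
            },
            "dendrite": {
                "C_d": d.c_d, "g_d": d.g_d, "E_d": d.e_d,
                "g_1": d.g1, "g_2": d.g2,
                "tau_m": d.tau_m, "tau_x": d.tau_x, "E_m": d.e_m, "D_m": d.d_m,
                "I_BAP": d.i_bap.to_dict(), "eps_sd": d.eps_sd.to_dict(),
            },
        }

    @classmethod
    def from_dict(cls, obj: dict) -> "TwoCompartmentModel":
        s, d = obj["soma"], obj["dendrite"]
        return cls(
            soma=SomaticParams(
                c_s=s["C_s"], g_s=s["g_s"], e_s=s["E_s"], alpha=s["alpha"],
                e_t=s["E_T"], d_t=s["D_T"], tau_t=s["tau_T"],
                e_r=s["E_r"], tau_r=s["tau_R"],
                i_a=Kernel.from_dict(s["I_A"]), eps_ds=Kernel.from_dict(s["eps_ds"]),
            ),
            dendrite=DendriticParams(
                c_d=d["C_d"], g_d=d["g_d"], e_d=d["E_d"],
                g1=d["g_1"], g2=d["g_2"],
                tau_m=d["tau_m"], tau_x=d["tau_x"], e_m=d["E_m"], d_m=d["D_m"],
                i_bap=Kernel.from_dict(d["I_BAP"]), eps_sd=Kernel.from_dict(d["eps_sd"]),
            ),
        )

    def to_json(self, path=None) -> str:
        s = json.dumps(self.to_dict(), indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_json(cls, source) -> "TwoCompartmentModel":
        try:
            obj = json.loads(source)
        except (json.JSONDecodeError, TypeError):
            with open(source) as fh:
                obj = json.load(fh)
        return cls.from_dict(obj)


@dataclass(frozen=True)
class SimulationTrace:
    """Sampled state trajectories plus emitted (or forced) spike times."""

    dt: float
    v_s: np.ndarray
    v_d: np.ndarray
    v_t: np.ndarray
    m: np.ndarray
    x: np.ndarray
    spike_times: np.ndarray
    i_s: np.ndarray | None = None
    i_d: np.ndarray | None = None

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.v_s.size) * self.dt

    @property
    def duration(self) -> float:
        return self.v_s.size * self.dt

    @property
    def n_spikes(self) -> int:
        return self.spike_times.size


def _validate_inputs(i_s, i_d, dt):
    i_s = np.ascontiguousarray(i_s, dtype=float)
    i_d = np.ascontiguousarray(i_d, dtype=float)
    if i_s.shape != i_d.shape or i_s.ndim != 1:
        raise ValueError("i_s and i_d must be 1-d arrays of equal length")
    if not (np.all(np.isfinite(i_s)) and np.all(np.isfinite(i_d))):
        raise ValueError("input currents must be finite")
    if dt <= 0:
        raise ValueError("dt must be positive")
    return i_s, i_d


def _run(model, i_s, i_d, dt, forced_idx, forced_mode, initial_state=None):
    s, d = model.soma, model.dendrite
    drive_s = i_s + s.eps_ds.convolve(i_d, dt)
    drive_d = i_d + d.eps_sd.convolve(i_s, dt)
    init = model.resting_state() if initial_state is None else initial_state
    v_s, v_d, v_t, m, x, spike_idx = run_twocomp(
        dt, drive_s, drive_d,
        s.c_s, s.g_s, s.e_s, s.alpha, s.e_t, s.d_t, s.tau_t, s.e_r, s.tau_r,
        d.c_d, d.g_d, d.e_d, d.g1, d.g2, d.tau_m, d.tau_x, d.e_m, d.d_m,
        s.i_a.sample(dt), d.i_bap.sample(dt),
        init["v_s"], init["v_d"], init["v_t"], init["m"], init["x"],
        forced_idx, forced_mode,
    )
    spike_times = spike_idx * dt
    if not forced_mode and spike_times.size > 1:
        # refractoriness must hold on every run
        assert np.min(np.diff(spike_times)) >= s.tau_r, "refractory violation"
    return SimulationTrace(dt, v_s, v_d, v_t, m, x, spike_times, i_s, i_d)


def simulate(model: TwoCompartmentModel, i_s, i_d, dt: float,
             initial_state: dict | None = None) -> SimulationTrace:
    """Deterministically integrate the model under injected currents.

    ``i_s`` and ``i_d`` are the somatic and dendritic injected currents (pA)
    sampled at ``dt`` (ms).  Spikes are emitted on upward threshold
    crossings; the returned trace is bit-reproducible for identical inputs.
    """
    i_s, i_d = _validate_inputs(i_s, i_d, dt)
    return _run(model, i_s, i_d, dt, np.empty(0, dtype=np.int64), False,
                initial_state)


def simulate_forced_spikes(model: TwoCompartmentModel, forced_spike_times,
                           i_d, dt: float, duration: float | None = None) -> SimulationTrace:
    """Integrate with somatic spikes imposed at given times.

    Threshold crossing is bypassed; each forced spike triggers the usual
    spike bookkeeping (BAP current into the dendrite, adaptation current,
    threshold jump, somatic reset) while the dendritic equations run
    normally.  Used for the critical-frequency protocol where trains of
    spikes are imposed at a controlled rate.
    """
    forced = np.asarray(forced_spike_times, dtype=float)
    if forced.size and np.any(np.diff(forced) < 0):
        raise ValueError("forced spike times must be sorted ascending")
    if duration is None:
        n = np.asarray(i_d).size
        duration = n * dt
    else:
        n = int(round(duration / dt))
    i_d = np.zeros(n) if i_d is None else np.ascontiguousarray(i_d, dtype=float)
    if i_d.size != n:
        raise ValueError("i_d length inconsistent with duration")
    if forced.size and (forced[-1] >= duration or forced[0] < 0):
        raise ValueError("forced spikes must lie within the simulated window")
    i_s = np.zeros(n)
    forced_idx = np.round(forced / dt).astype(np.int64)
    return _run(model, i_s, i_d, dt, forced_idx, True)
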