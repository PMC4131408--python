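"""Synthetic frozen-noise stimulation protocol and ground-truth recordings.

The stimulation waveform emulates a dual somatic/dendritic current-injection
experiment: six 12-s blocks, each made of a 1-s low-variance somatic lead-in,
a 1-s low-variance dendritic lead-in, and a 10-s high-variance main segment
whose injection site depends on the block (block 1 dendrite only, block 2
soma only, blocks 3-6 both).  All currents are Ornstein-Uhlenbeck (OU)
processes with a 3-ms correlation time.  The 72-s waveform is frozen across
repetitions (so intrinsic reliability can be measured) but drawn
independently across blocks (so the first-half/second-half train/test split
uses independent noise).

Because no real recordings ship with the package, ``generate_recordings``
produces ground-truth data from a known model instance; an unfrozen
per-repetition OU noise current added to the somatic input makes repetitions
differ, emulating intrinsic neuronal noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .kernels import Kernel, RectBasis, log_spaced_edges
from .model import DendriticParams, SomaticParams, TwoCompartmentModel, simulate

__all__ = [
    "ProtocolConfig",
    "RecordingSet",
    "ou_current",
    "build_protocol",
    "generate_recordings",
    "default_ground_truth",
    "default_bases",
]


def ou_current(mu: float, sigma: float, tau: float, duration: float, dt: float,
               seed: int) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck current (pA).

    Mean ``mu``, stationary standard deviation ``sigma``, correlation time
    ``tau`` (ms).  Uses the exact discretization

        I[k+1] = mu + (I[k] - mu) e^(-dt/tau) + sigma sqrt(1 - e^(-2 dt/tau)) xi_k

    which has the correct stationary variance at any step size; the initial
    sample is drawn from the stationary distribution.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    n = int(round(duration / dt))
    rng = np.random.default_rng(seed)
    if sigma == 0:
        return np.full(n, float(mu))
    rho = np.exp(-dt / tau)
    e = np.empty(n)
    e[0] = sigma * rng.standard_normal()  # stationary initial condition
    e[1:] = sigma * np.sqrt(1.0 - rho * rho) * rng.standard_normal(n - 1)
    x = lfilter([1.0], [1.0, -rho], e)  # AR(1): x[k] = rho x[k-1] + e[k]
    return mu + x


@dataclass(frozen=True)
class ProtocolConfig:
    """Layout and noise parameters of the six-block frozen-noise stimulus."""

    n_blocks: int = 6
    block_s: float = 12.0        # total block length, s
    lead_in_s: float = 1.0       # each of the two low-variance lead-ins, s
    tau_ou: float = 3.0          # OU correlation time, ms
    sigma_high: float = 300.0    # main-segment OU std, pA
    sigma_low: float = 100.0     # lead-in OU std, pA
    mu_s: float = 400.0          # mean somatic current where stimulated, pA
    mu_d: float = 400.0          # mean dendritic current where stimulated, pA
    dt: float = 0.1              # sampling step, ms
    n_repetitions: int = 7
    train_fraction: float = 0.5  # first half trains, second half tests
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_blocks < 1 or self.n_repetitions < 1:
            raise ValueError("need at least one block and one repetition")
        if 2 * self.lead_in_s >= self.block_s:
            raise ValueError("lead-ins longer than the block")

    @property
    def duration_ms(self) -> float:
        return self.n_blocks * self.block_s * 1000.0

    @property
    def split_ms(self) -> float:
        """Boundary between training and test segments, ms."""
        return self.train_fraction * self.duration_ms

    def block_targets(self) -> list[str]:
        """Injection site of each block's main segment."""
        targets = []
        for b in range(self.n_blocks):
            if b == 0:
                targets.append("dendrite")
            elif b == 1:
                targets.append("soma")
            else:
                targets.append("both")
        return targets


def build_protocol(config: ProtocolConfig) -> tuple[np.ndarray, np.ndarray]:
    """Lay out the frozen (I_s, I_d) channels for one repetition.

    Noise is drawn independently per block and per segment from seeds derived
    from the master seed, so two calls with the same config are identical
    (frozen noise) while different blocks are uncorrelated.
    """
    dt = config.dt
    n_lead = int(round(config.lead_in_s * 1000.0 / dt))
    n_block = int(round(config.block_s * 1000.0 / dt))
    n_main = n_block - 2 * n_lead
    i_s = np.zeros(config.n_blocks * n_block)
    i_d = np.zeros(config.n_blocks * n_block)
    ss = np.random.SeedSequence(config.seed)
    seeds = ss.generate_state(3 * config.n_blocks)
    for b, target in enumerate(config.block_targets()):
        off = b * n_block
        lead_ms = n_lead * dt
        main_ms = n_main * dt
        s_lead, d_lead, main_seed = seeds[3 * b: 3 * b + 3]
        # part 1: low-variance, soma only
        i_s[off: off + n_lead] = ou_current(
            config.mu_s, config.sigma_low, config.tau_ou, lead_ms, dt, s_lead)
        # part 2: low-variance, dendrite only
        i_d[off + n_lead: off + 2 * n_lead] = ou_current(
            config.mu_d, config.sigma_low, config.tau_ou, lead_ms, dt, d_lead)
        # part 3: high-variance main segment
        lo = off + 2 * n_lead
        hi = off + n_block
        if target in ("soma", "both"):
            i_s[lo:hi] = ou_current(
                config.mu_s, config.sigma_high, config.tau_ou, main_ms, dt,
                main_seed)
        if target in ("dendrite", "both"):
            i_d[lo:hi] = ou_current(
                config.mu_d, config.sigma_high, config.tau_ou, main_ms, dt,
                int(main_seed) + 1)
    return i_s, i_d


@dataclass
class RecordingSet:
    """Frozen input currents plus per-repetition responses.

    All repetitions share the same ``i_s``/``i_d`` (the frozen stimulus);
    voltages and spike trains differ across repetitions when trial noise was
    added.  ``split_ms`` marks the train/test boundary: samples before it are
    the training segment, the rest the test segment.
    """

    dt: float
    i_s: np.ndarray
    i_d: np.ndarray
    v_s: list
    v_d: list
    spike_times: list
    split_ms: float
    ground_truth: TwoCompartmentModel | None = None
    config: ProtocolConfig | None = None

    def __post_init__(self) -> None:
        n = self.i_s.size
        if self.i_d.size != n:
            raise ValueError("i_s and i_d lengths differ")
        for v in list(self.v_s) + list(self.v_d):
            if v.size != n:
                raise ValueError("voltage trace length differs from stimulus")
        if not 0 < self.split_ms <= self.duration_ms:
            raise ValueError("split_ms outside the recording")

    @property
    def n_repetitions(self) -> int:
        return len(self.v_s)

    @property
    def duration_ms(self) -> float:
        return self.i_s.size * self.dt

    @property
    def split_index(self) -> int:
        return int(round(self.split_ms / self.dt))

    def spikes_in(self, rep: int, t0: float, t1: float) -> np.ndarray:
        st = self.spike_times[rep]
        return st[(st >= t0) & (st < t1)] - t0

    def train_spikes(self, rep: int) -> np.ndarray:
        return self.spikes_in(rep, 0.0, self.split_ms)

    def test_spikes(self, rep: int) -> np.ndarray:
        return self.spikes_in(rep, self.split_ms, self.duration_ms)


def generate_recordings(model: TwoCompartmentModel, config: ProtocolConfig,
                        trial_noise_sigma: float = 0.0) -> RecordingSet:
    """Simulate the frozen-noise protocol with a known model.

    Each repetition is driven by the frozen stimulus plus an independent
    (unfrozen) somatic OU noise current of standard deviation
    ``trial_noise_sigma`` (pA, same 3-ms correlation time), so repetitions
    differ and intrinsic reliability falls below 1.  With zero trial noise
    all repetitions are bit-identical.  The stored input currents are the
    frozen ones; the trial noise plays the role of unobserved intrinsic
    noise.
    """
    i_s, i_d = build_protocol(config)
    duration = i_s.size * config.dt
    noise_seeds = np.random.SeedSequence([config.seed, 0x7E57]).generate_state(
        config.n_repetitions)
    v_s, v_d, spikes = [], [], []
    for rep in range(config.n_repetitions):
        drive = i_s
        if trial_noise_sigma > 0:
            drive = i_s + ou_current(0.0, trial_noise_sigma, config.tau_ou,
                                     duration, config.dt, noise_seeds[rep])
        trace = simulate(model, drive, i_d, config.dt)
        v_s.append(trace.v_s)
        v_d.append(trace.v_d)
        spikes.append(trace.spike_times)
    return RecordingSet(config.dt, i_s, i_d, v_s, v_d, spikes,
                        split_ms=config.split_ms, ground_truth=model,
                        config=config)


# ---------------------------------------------------------------------------
# Default ground-truth model
# ---------------------------------------------------------------------------

def default_bases() -> dict:
    """Default rectangular-basis layouts for the seven model kernels.

    The coupling filters decay within a few tens of ms, the adaptation
    current extends to hundreds of ms, and the BAP current is a few ms long;
    log-spaced bins resolve the fast onset without many parameters.
    """
    return {
        "eps": RectBasis(log_spaced_edges(1.0, 50.0, 10)),
        "i_a": RectBasis(log_spaced_edges(5.0, 600.0, 10)),
        "i_bap": RectBasis(np.arange(0.0, 6.0)),
    }


def _alpha_shape(t, peak, t_peak):
    """Alpha-function bump peaking at ``t_peak`` with amplitude ``peak``."""
    return peak * (t / t_peak) * np.exp(1.0 - t / t_peak)


def default_ground_truth() -> TwoCompartmentModel:
    """Canonical parameter set with physiologically shaped default kernels.

    Membrane, threshold and calcium parameters follow the fitted values for
    layer-5 pyramidal cells (somatic capacitance 379 pF, maximal calcium
    current 567 pA, recovery time constant 49.9 ms, ...).  Kernels:

    * ``I_BAP``: a short (2 ms) strong (900 pA) depolarizing pulse;
    * ``I_A``: negative, monotonically rising toward zero over hundreds of
      ms (amplitude 80 pA, decay constant 150 ms);
    * ``eps_ds``/``eps_sd``: biphasic -- positive peak at 2-3 ms, weak
      negative tail beyond ~35 ms, with the soma-to-dendrite filter smaller
      and slightly slower than the dendrite-to-soma one.
    """
    bases = default_bases()

    def eps_ds_fn(t):
        return _alpha_shape(t, 0.06, 2.5) - _alpha_shape(t, 0.0008, 45.0)

    def eps_sd_fn(t):
        return _alpha_shape(t, 0.03, 3.5) - _alpha_shape(t, 0.0006, 50.0)

    def i_a_fn(t):
        return -80.0 * np.exp(-t / 150.0)

    eps_ds = Kernel.from_function(eps_ds_fn, bases["eps"].edges, units="1/ms")
    eps_sd = Kernel.from_function(eps_sd_fn, bases["eps"].edges, units="1/ms")
    i_a = Kernel.from_function(i_a_fn, bases["i_a"].edges, units="pA")
    i_bap = Kernel(bases["i_bap"], np.array([900.0, 900.0, 0.0, 0.0, 0.0]),
                   units="pA")

    return TwoCompartmentModel(
        soma=SomaticParams(i_a=i_a, eps_ds=eps_ds),
        dendrite=DendriticParams(i_bap=i_bap, eps_sd=eps_sd),
    )
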