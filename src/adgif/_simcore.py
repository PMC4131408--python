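"""Compiled inner loops for the two-compartment simulator and GLM sampler.

The state update is fixed-step forward Euler for the two membrane equations
with exact exponential-decay updates for the linear relaxations (calcium
activation m, recovery x, moving threshold V_T).  Spike-triggered currents
(adaptation into the soma, back-propagating action potential into the
dendrite) are accumulated into per-sample drive arrays as spikes occur, so
a step costs O(1) plus the kernel length per spike.

All functions are numba-compiled; keep signatures to plain float64/int64
arrays and scalars.
"""

import numpy as np
from numba import njit

__all__ = ["run_twocomp", "activation_series", "sample_glm_spikes"]


@njit(cache=True)
def activation_series(v_d, dt, tau_m, d_m, e_m, tau_x, m0, x0):
    """Integrate the calcium-activation pair (m, x) driven by a voltage trace.

    m relaxes toward the sigmoid of the dendritic voltage with time constant
    tau_m; x relaxes toward m with time constant tau_x.  Uses the same
    exponential stepping as the full simulator so that series computed from
    a recorded voltage reproduce the simulator's internal state exactly.
    """
    n = v_d.size
    m = np.empty(n)
    x = np.empty(n)
    m[0] = m0
    x[0] = x0
    em = np.exp(-dt / tau_m)
    ex = np.exp(-dt / tau_x)
    for k in range(n - 1):
        sig = 1.0 / (1.0 + np.exp(-(v_d[k] - e_m) / d_m))
        m[k + 1] = sig + (m[k] - sig) * em
        x[k + 1] = m[k] + (x[k] - m[k]) * ex
    return m, x


@njit(cache=True)
def run_twocomp(
    dt,
    drive_s,
    drive_d,
    c_s, g_s, e_s, alpha, e_t, d_t, tau_t, e_r, tau_r,
    c_d, g_d, e_d, g1, g2, tau_m, tau_x, e_m, d_m,
    ia_samp,
    ibap_samp,
    vs0, vd0, vt0, m0, x0,
    forced_idx,
    forced_mode,
):
    """Forward-integrate the coupled soma/dendrite system.

    drive_s / drive_d are the spike-independent input currents already
    including the cross-compartment convolution terms (I_s + eps_ds * I_d
    and I_d + eps_sd * I_s respectively).  Returns the five state traces and
    the spike sample indices.  In forced mode threshold crossing is disabled
    and spikes occur exactly at forced_idx.
    """
    n = drive_s.size
    v_s = np.empty(n)
    v_d = np.empty(n)
    v_t = np.empty(n)
    m = np.empty(n)
    x = np.empty(n)
    adapt = np.zeros(n)
    bap = np.zeros(n)
    v_s[0] = vs0
    v_d[0] = vd0
    v_t[0] = vt0
    m[0] = m0
    x[0] = x0

    em = np.exp(-dt / tau_m)
    ex = np.exp(-dt / tau_x)
    et = np.exp(-dt / tau_t)
    n_ref = int(np.round(tau_r / dt))
    n_ia = ia_samp.size
    n_bap = ibap_samp.size

    spikes = np.empty(n, dtype=np.int64)
    n_spikes = 0
    clamp_until = -1  # last clamped sample index
    next_forced = 0

    # a spike may be forced at sample 0
    if forced_mode and forced_idx.size > 0 and forced_idx[0] == 0:
        spikes[n_spikes] = 0
        n_spikes += 1
        next_forced = 1
        v_s[0] = e_r
        v_t[0] = vt0 + d_t
        for u in range(min(n_ia, n)):
            adapt[u] += ia_samp[u]
        for u in range(min(n_bap, n)):
            bap[u] += ibap_samp[u]
        clamp_until = n_ref

    for k in range(n - 1):
        sig = 1.0 / (1.0 + np.exp(-(v_d[k] - e_m) / d_m))
        m[k + 1] = sig + (m[k] - sig) * em
        x[k + 1] = m[k] + (x[k] - m[k]) * ex
        v_d[k + 1] = v_d[k] + (dt / c_d) * (
            -g_d * (v_d[k] - e_d) + g1 * m[k] + g2 * x[k] + drive_d[k] + bap[k]
        )
        v_t[k + 1] = e_t + (v_t[k] - e_t) * et
        if k + 1 <= clamp_until:
            v_s[k + 1] = e_r
        else:
            v_s[k + 1] = v_s[k] + (dt / c_s) * (
                -g_s * (v_s[k] - e_s) + alpha * m[k] + drive_s[k] + adapt[k]
            )

        fire = False
        if forced_mode:
            if next_forced < forced_idx.size and forced_idx[next_forced] == k + 1:
                fire = True
                next_forced += 1
        else:
            if v_s[k + 1] > v_t[k + 1] and k + 1 > clamp_until:
                fire = True

        if fire:
            s = k + 1
            spikes[n_spikes] = s
            n_spikes += 1
            v_s[s] = e_r
            v_t[s] += d_t
            hi = min(n, s + n_ia)
            for u in range(s, hi):
                adapt[u] += ia_samp[u - s]
            hi = min(n, s + n_bap)
            for u in range(s, hi):
                bap[u] += ibap_samp[u - s]
            clamp_until = s + n_ref

    return v_s, v_d, v_t, m, x, spikes[:n_spikes]


@njit(cache=True)
def sample_glm_spikes(log_lam_input, dt, eta_samp, seed):
    """Draw spikes bin-by-bin from the exponential-link point process.

    log_lam_input holds the input-dependent part of log lambda (baseline plus
    filtered currents); each emitted spike adds the sampled spike-history
    kernel to the log-intensity of strictly later bins, so the probability of
    the spike's own bin is well defined.  Per-bin spike probability is
    1 - exp(-lambda dt).
    """
    n = log_lam_input.size
    log_lam = log_lam_input.copy()
    n_eta = eta_samp.size
    spikes = np.empty(n, dtype=np.int64)
    n_spikes = 0
    np.random.seed(seed)
    for k in range(n):
        lam = np.exp(log_lam[k])
        p = 1.0 - np.exp(-lam * dt)
        if np.random.random() < p:
            spikes[n_spikes] = k
            n_spikes += 1
            hi = min(n, k + n_eta)
            for u in range(k + 1, hi):
                log_lam[u] += eta_samp[u - k]
    return spikes[:n_spikes]
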