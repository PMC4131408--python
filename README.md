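# adgif — active-dendrite generalized integrate-and-fire modeling

`adgif` is a toolkit for simulating and fitting a two-compartment model of
layer-5 cortical pyramidal neurons whose apical dendrite is excitable
(calcium spikes), and for asking whether that dendritic nonlinearity is
needed to predict somatic spike *times* under in-vivo-like dual current
injection.

The neuron is reduced to a somatic and a dendritic compartment coupled by
measurable impulse-response filters:

```
C_s dV_s/dt = -g_s (V_s - E_s) + α m + I_s + Σ_i I_A(t - t̂_i)   + (ε_ds ∗ I_d)(t)
C_d dV_d/dt = -g_d (V_d - E_d) + g₁ m + g₂ x + I_d + Σ_i I_BAP(t - t̂_i) + (ε_sd ∗ I_s)(t)
τ_m dm/dt  = σ((V_d - E_m)/D_m) - m
τ_x dx/dt  = m - x
τ_T dV_T/dt = -(V_T - E_T),   V_T → V_T + D_T at each spike
```

A spike is emitted when `V_s > V_T`; the soma is reset and held for an
absolute refractory period, each spike injects a stereotyped
back-propagating action-potential current `I_BAP` into the dendrite, and
`g₁ m` is a calcium-like current whose activation `m` follows a sigmoid of
the dendritic voltage.  All temporal filters (`ε_sd`, `ε_ds`, `I_A`,
`I_BAP` and the control model's kernels) live on a rectangular basis, which
makes their amplitudes *linear* parameters of the fitting problem.

The package provides:

* a fast forward simulator (`adgif.model`) in the self-consistent
  (pA, pF, nS, mV, ms) unit system;
* a synthetic frozen-noise protocol (`adgif.protocol`): six 12-s blocks of
  Ornstein–Uhlenbeck currents (τ = 3 ms) injected into soma, dendrite or
  both, frozen across repetitions, with optional unfrozen trial noise so
  repetitions disagree like real cells do;
* the staged fitting procedure (`adgif.fitting`): multilinear regression on
  `dV_d/dt` and `dV_s/dt` with exhaustive grid search over the nonlinear
  parameters, then a coincidence-rate-maximizing threshold search;
* a passive control model (`adgif.glm`): an exponential-link point process
  `λ(t) = λ₀ exp(κ_s∗I_s + κ_ds∗I_d + Σ η_A(t-t̂_i))` fitted by concave
  maximum likelihood;
* spike-timing evaluation (`adgif.metrics`): the chance-corrected
  coincidence rate Γ, intrinsic reliability R and the scaled rate Γ/R;
* in-silico characterizations (`adgif.experiments`): critical frequency,
  dendritic gain modulation of the f–I curve, spike- and burst-triggered
  average input currents.

## Worked example

```python
import numpy as np
from adgif import (default_ground_truth, ProtocolConfig, generate_recordings,
                   fit_twocompartment, fit_glm)
from adgif.pipeline import evaluate_twocomp_heldout, evaluate_glm_heldout

# synthetic "experiment": 7 repetitions of the 72-s frozen-noise protocol,
# with 60 pA of unfrozen somatic noise playing the role of intrinsic noise
rec = generate_recordings(default_ground_truth(),
                          ProtocolConfig(seed=1), trial_noise_sigma=60.0)

two = fit_twocompartment(rec)       # staged regression + grid search
glm = fit_glm(rec)                  # passive control, maximum likelihood

rep_two = evaluate_twocomp_heldout(two.model, rec)
rep_glm = evaluate_glm_heldout(glm.model, rec, seed=1)
print(f"held-out Γ (full model):    {rep_two.averaged_gamma:.3f}")
print(f"held-out Γ (passive GLM):   {rep_glm.averaged_gamma:.3f}")
print(f"intrinsic reliability R:    {rep_two.intrinsic_r:.3f}")
```

Output:

```
held-out Γ (full model):    0.660
held-out Γ (passive GLM):   0.515
intrinsic reliability R:    0.601
```

Read: on the held-out half of the recording, the two-compartment model
places 66% of spikes within ±4 ms of the reference trains (after chance
correction), while the passive GLM reaches only 52%; the synthetic cell's
own trial-to-trial reproducibility is 60%.  The active-dendrite model
predicts spike times better than the passive control — the ordering the
model family was built to test.

A command-line interface mirrors the library:
`adgif protocol`, `adgif fit twocomp`, `adgif evaluate`,
`adgif experiment critfreq`, `adgif pipeline` (see `adgif --help`).

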