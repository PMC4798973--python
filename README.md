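# aurorab

Models of the bistable Aurora B kinase–phosphatase system in mitosis,
for quantitative cell biologists and modellers: mass-action ODE models of
two-component kinase autoactivation, steady-state and hysteresis analysis
of the coupled kinase–phosphatase system, a 1-D reaction–diffusion model
of chromatin-bound and soluble kinase that produces trigger waves and
kinetochore activity gradients, and a multi-start least-squares
parameter-estimation tool exercised on synthetic data.

## The model

Aurora B (with its INCENP activator fragment) is treated as a single
enzymatic species with a partially active form A and an active form A*.
Activation proceeds through two routes:

* *cis* — slow intramolecular autophosphorylation, `A → A*` at rate
  `kcis` (7.29·10⁻⁶ s⁻¹);
* *trans* — Michaelis–Menten phosphorylation of A by A*
  (`kcata = 2.7·10⁻² s⁻¹`, `KMa = 51 µM`).

A phosphatase dephosphorylates free A* with Michaelis–Menten kinetics,
and a fluorogenic peptide chemosensor (`kcat = 19 s⁻¹`, `KM = 320 µM`)
reports activity. The positive feedback through the trans route makes
the coupled system bistable: above ≈3.9 µM total kinase, a window of
phosphatase concentrations supports two stable steady states (high and
low activity) separated by an unstable threshold, with hysteresis under
slow phosphatase ramps. The spatial model adds chromatin binding sites
(10 µM bound kinase at the centromere, 1.5 µM along arms), diffusion of
the soluble pool (`D = 1 µm²/s`) and an inhibitor dose model, producing
activation waves that spread from the centromere after inhibitor washout
and activity gradients along the centromere–kinetochore axis.

See `docs/methods.md` for the full model description, parameter tables,
numerical choices and limitations.

## Worked example

```python
import numpy as np
from aurorab import OneSiteParams, find_steady_states, bistability_threshold
from aurorab.coupled import bistable_ppase_interval

params = OneSiteParams.defaults()

print(f"bistability threshold: {bistability_threshold(params):.2f} uM")
lo, hi = bistable_ppase_interval(params, Atot=8.0)
print(f"bistable phosphatase window at 8 uM kinase: {lo:.3f}-{hi:.3f} uM")
for state, stability in find_steady_states(params, Atot=8.0, PPase_total=0.45):
    print(f"  {stability:8s} active fraction {state.active_kinase / 8.0:.3f}")
```

prints

```
bistability threshold: 3.88 uM
bistable phosphatase window at 8 uM kinase: 0.390-0.471 uM
  stable   active fraction 0.007
  unstable active fraction 0.184
  stable   active fraction 0.460
```

i.e. at 8 µM total kinase and 0.45 µM phosphatase the mixture can rest in
either a low-activity state (0.7% active) or a high-activity state (46%
active, counting free plus complex-engaged active kinase), separated by
an unstable threshold at 18% — which state it reaches depends on its
history, the signature read out in two-preparation experiments.

Fitting synthetic data back to the model:

```python
from aurorab.fitting import recover_parameters

report = recover_parameters({"noise_cv": 0.0, "seed": 1},
                            {"n_starts": 20, "seed": 1})
print({k: f"{v:+.2%}" for k, v in report["relative_error"].items()})
```

recovers `kcis`, `KMa` and `kcata` to well within 1% on noiseless data.

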