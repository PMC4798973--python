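# Methods

`aurorab` models the Aurora B kinase–phosphatase system of mitotic cells:
a kinase that activates itself through two parallel routes — a slow
intramolecular (*cis*) autophosphorylation and an intermolecular (*trans*)
Michaelis–Menten reaction in which active kinase phosphorylates partially
active kinase — coupled to a phosphatase that dephosphorylates the free
active form. Units are fixed package-wide: concentrations in µM, time in
seconds, space in µm.

## Homogeneous models

### Species and reactions

The one-site model tracks eight species: partially active kinase `A`,
active kinase `A*`, the trans-activation complex `[AA*]`, the
chemosensor complexes `[SA*]`, the phosphatase complex `[A*PPase]`, free
chemosensor substrate `S` and product `P`, and free phosphatase. The
reactions are

```
A            → A*                      (cis, first order, kcis)
A + A*       ⇌ [AA*] → A* + A*         (trans, kfa / kra / kcata)
S + A*       ⇌ [SA*] → P + A*          (chemosensor, kf / kr / kcat)
A* + PPase   ⇌ [A*PPase] → A + PPase   (dephosphorylation, kfp / krp / kcatp)
```

Kinase engaged in a complex is protected from dephosphorylation, and the
partially active kinase has no chemosensor activity. Three totals are
conserved exactly (kinase, chemosensor, phosphatase); the integrator
validates them after every run.

The default constant set (`OneSiteParams.defaults()`) is the reference
characterization: `kcat = 19 s⁻¹`, `KM = 320 µM` (55 µM for the
custom-synthesized sensor), `kf = 50 µM⁻¹s⁻¹`, `kfa = 0.1 µM⁻¹s⁻¹`,
`KMa = 51 µM`, `kcata = 2.7·10⁻² s⁻¹`, `kcis = 7.29·10⁻⁶ s⁻¹`,
`kfp = 0.6 µM⁻¹s⁻¹`, `KMp = 1.95 µM`, `kcatp = 2.4·10⁻² s⁻¹`.
Dissociation rates are never stored: they are derived as
`kr = kf·KM − kcat` (and analogues), which keeps every Michaelis triple
internally consistent; explicitly supplied values must agree to 0.1%.

### Integration

The reference integrator is classic fixed-step RK4 at `dt = 0.02 s` with
self-validation (conservation to 10⁻⁶ µM, no concentration below
−10⁻⁹ µM; negative round-off is clipped to zero and logged). The 0.02 s
step is appropriate for the substrate-free systems, whose fastest rate is
the trans-complex turnover (≈5 s⁻¹); with chemosensor present the complex
turnover is `kr ≈ 1.6·10⁴ s⁻¹` and explicit stepping needs `dt ≲ 10⁻⁴ s`.
All long-horizon and stiff runs therefore use the adaptive backend
(LSODA via `scipy.integrate.solve_ivp`, `rtol = 10⁻⁸`), which the test
suite validates against the RK4 reference to better than 10⁻⁶ µM.

### Steady states and bistability

At steady state the two Michaelis complexes equilibrate exactly, and the
activation/deactivation balance plus the conservation laws reduce the
coupled system to one explicit relation `Ptot(A*)`: the total phosphatase
at which a given free active-kinase level is stationary. Steady states at
a prescribed phosphatase total are roots of `Ptot(A*) = Ptot` (sign scan
over 4000 points plus Brent refinement); bistability is exactly a fold
(non-monotonicity) of `Ptot(A*)`, which yields sharp phosphatase windows
and kinase thresholds without grid artifacts. Stability is classified by
the Jacobian eigenvalues of the reduced three-species dynamics; a
saddle-node tangency is conservatively classified monostable. An
independent dynamic-relaxation oracle (long ODE runs from ≥20 initial
active fractions) cross-checks the finder in the tests; relaxation
horizons of 3·10⁵ s are needed near bifurcation "ghosts" where
critical slowing makes 5·10⁴ s insufficient.

With the default constants the bistability threshold is ≈3.9 µM total
kinase, and at 8 µM the bistable phosphatase window is ≈0.39–0.47 µM —
consistent with two-preparation experiments that show both-high
convergence at 0.25 µM, persistent separation at 0.45 µM and both-low
convergence at 0.5 µM phosphatase.

### Protocols

* **Two-preparation scan** (`steady_state_scan`): 'initially high' starts
  from fully active kinase; 'initially low' treats the ATP-free
  phosphatase preincubation as completed dephosphorylation (all kinase
  partially active, full phosphatase present). Reported activity counts
  free `A*` plus complex-engaged `A*`.
* **Pulse protocol** (`simulate_with_pulses`): instantaneous additions of
  active kinase that also increase the total. The reference protocol
  settles the 8 µM / 0.47 µM mixture for 2·10⁴ s and spaces additions
  2000 s apart — each sub-threshold addition relaxes back to within ~2%
  of total kinase, i.e. visually back to the low state, before the next.
  The cumulative additions lower the separatrix, and the 0.3/0.4/0.5 µM
  sequence switches on the third addition. This protocol detail matters:
  the 0.5 µM addition lands within ~10% of the saddle point, so with
  multi-hour spacing (complete relaxation) the first switching addition
  moves to 0.6 µM.
* **Hysteresis ramps** (`hysteresis_loop`): stepwise phosphatase
  increments with per-step equilibration, reference cycle time 100 h
  (which LSODA makes cheap). Branch values adjacent to the saddle-node
  jump converge only in the infinitely slow limit; quasi-steadiness is
  therefore validated away from the jump. Loops collapse when compared at
  matched dephosphorylation capacity `kcatp·PPase`; the residual
  deviation reflects kinase sequestered in phosphatase complexes, which
  scales with the absolute phosphatase level — the same effect drifts the
  bistability threshold by ≈0.2–0.3 µM under a twofold `kcatp` rescale.

## Enzyme kinetics utilities

Fluorescence is converted through linear standard curves (default slopes
6520 and 15000 cps/µM for substrate and product; background defaults to
0 since the instrument background is not characterized). Initial rates
use the sub-10%-conversion window. Michaelis–Menten constants come from
a direct nonlinear fit; Lineweaver–Burk and Hanes–Woolf linearizations
are computed as diagnostics only — they weight noise pathologically and
are never authoritative.

## Two-phosphosite model

The sequential model has three kinase forms (`A`, `A#`, `A##`), four
kinase–kinase Michaelis reactions, two sensor reactions and an optional
reverse-order dephosphorylation branch (`A## → A# → A`, both steps with
`lf = 0.6 µM⁻¹s⁻¹`, `lr = 5.9 s⁻¹`, `lcat = 0.12 s⁻¹`). In the fitted
constant set the `A·A##` catalytic rate is 7-fold the `A·A#` rate with
equal Michaelis constants. The limiting-case set makes the `A# + A#`
conversion ~500-fold faster, reducing the intermediate to a trace
(<0.5% of total kinase) and collapsing the model onto the one-site
description. The residual product-curve discrepancy is 3–6% of total
substrate, largest at 1.5 µM kinase where the curve is steepest: at trace
concentrations the second-order `A# + A#` conversion briefly throttles
the effective kinase, lagging the one-site curve by ~2–3% in time.
Scaling the conversion rate a further 10×/100× shrinks the discrepancy
monotonically (1.1%/0.4%), which is the defining property of the limit.
Sensor complexes are assumed not to be dephosphorylated (complexed
kinase is protected, as in the one-site model).

## Spatial model

### Structure

One spatial dimension, two axes examined independently: the
centromere–kinetochore axis (±1.25 µm) and the chromosome arm (±3 µm).
Soluble species (`A`, `A*`, `[AA*]`, `[A*PPase]`, phosphatase) diffuse
with `D = 1 µm²/s` under no-flux boundaries; chromatin-bound kinase
(`B`, `B*`), every complex containing a bound partner, free binding
sites and the chromatin-anchored substrate are immobile. Binding uses
`koff = 0.014 s⁻¹` and `KD = 4.8 nM` (`kon = koff/KD ≈ 2.9 µM⁻¹s⁻¹`).
Bound kinase reacts with soluble kinase at the full rates; bound–bound
trans phosphorylation is sterically limited, `kfb = 0.01·kfa`, with
`krb = kfb·KMa − kcata` so the bound-pair Michaelis constant equals
`KMa` (the linear-regime trans flux is then unchanged and only the
saturation behaviour differs). The method of lines with species
interleaved per grid point gives a banded Jacobian (band = species
count) integrated with LSODA; an explicit RK4 path with a CFL guard
(`dt ≤ dx²/2D`) serves as a validation reference.

### Binding-site profiles and loading

The profiles are parametric synthetic stand-ins for deconvolved
microscopy curves, constrained by the estimated bound-kinase levels: a
flat-topped peak of 10 µM at the centroid falling to ~2 µM at the
metaphase outer kinetochore (±0.7 µm) and to ~0 at the domain edge
(centromere axis), or relaxing to the 1.5 µM arm plateau (arm axis). The
inner-centromere average matches the calibrated average bound
concentration: from the measured partition (75% of cellular kinase
bound, soluble pool 8.6 nM, cell volume 5800 µm³, total centromere
volume 23 µm³) the identity `f·C_sol·V_cell = (1−f)·C_bound·V_cent`
gives `C_bound ≈ 6.4 µM`. Because these are *bound kinase*
concentrations, the underlying site capacity is larger by the inverse
equilibrium occupancy `C_sol/(C_sol+KD) ≈ 0.64`; simulations initialize
free sites at `profile/0.64`, and the physiological uniform loading is
the profile integral plus the soluble pool. With these numbers the
two-compartment equilibrium reproduces the 75%/25% bound/soluble
partition. Prometaphase (unstretched) geometry compresses the metaphase
profile 1.75-fold — `p'(x) = 1.75·p(1.75x)`, conserving total sites and
scaling the peak to 17.5 µM — corresponding to interkinetochore
distances of 0.8 µm vs 1.4 µm.

### Inhibitor dose model

An ATP-competitive Aurora B inhibitor attenuates both autoactivation
routes exponentially: `kcis, kcata → (kcis, kcata)·exp(−z/0.33)` with
dose `z` in µM; the 0.33 µM constant sits inside the published
sensitivity range 0.19–0.55 µM. The trans-complex dissociation rate is
held fixed (the inhibitor blocks catalysis, not complex turnover). The
no-bistability control variant instead raises `kcis` to 7.3·10⁻⁴ s⁻¹,
which removes the fold from the physiological concentration range while
keeping autoactivation and dephosphorylation intact.

### Cellular scenarios and their phosphatase levels

Cellular phosphatase kinetics are not measured; the package follows the
matched values `KMp = 0.16 µM` with `kcatp` as in vitro, and exposes
them as parameters. Two regimes matter, and they need different
phosphatase concentrations:

* **Inhibitor titration scans** (`cell_hysteresis_scan`,
  `kinetochore_gradient`): phosphatase 0.1 µM on the centromere axis.
  From an all-active start the centromeric pool holds its high state at
  zero dose and collapses with increasing dose, while the washout branch
  (all-inactive start) stays low — history dependence at low and
  intermediate dose. In the fast-cis variant both branches coincide once
  relaxed; note that at the 1000 s default horizon the variant has not
  finished relaxing (1/kcis = 1370 s), so steady-state comparisons use
  longer horizons.
* **Washout trigger waves** (`simulate_wave`): phosphatase 0.012 µM.
  Regime analysis with the homogeneous reduction shows why: the arm
  bistable window at the 1.5 µM arm level is ≈0.0085–0.0149 µM
  phosphatase, and centromere self-ignition (monostable-high at the
  ~10 µM local level) requires <0.059 µM. Only inside that intersection
  does the washout scenario nucleate at the centromere and propagate
  into bistable arms; at 0.1 µM phosphatase the centromere cannot ignite
  and the arms cannot sustain a front at all.

### Wave timing and its limits

`half_max_time_profile` reproduces the experimental analysis: per
position, the first time the substrate phosphorylation crosses 50% of
its final plateau, offset so the centromere crossing defines t = 0, with
an ordinary least-squares line through (distance, t50). In the bistable
model the front crosses the arm at ≈230 s/µm with R² ≈ 0.89; the
fast-cis variant activates on a spatially uniform fuse, giving a flat,
lag-then-plateau profile (slope ≈100 s/µm, lower R²). Two structural
features of the model keep the bistable front from being perfectly
linear: the conserved, diffusing phosphatase is progressively engaged in
Michaelis complexes by the activated region (engaged fraction
`B*/(KMp+B*) ≈ 0.9` behind the front), which destabilizes the low state
ahead; and the soluble active-kinase bath pre-seeds the arms. Both
accelerate the front toward the domain edge. A perfectly constant-speed
trigger wave would require a phosphatase reservoir that is not depleted
by the front — for example, continuous phosphatase turnover — which the
model deliberately does not include.

### Known limitations

* The chromatin-bound pool exchanges with the soluble pool every
  ~70 s (koff). Because the local reaction rates (10⁻³–10⁻² s⁻¹) are
  comparable to or slower than this exchange, spatial contrast in the
  *activation ratio* along the short centromere–kinetochore axis is
  smoothed within minutes; the model therefore produces graded, not
  step-like, kinetochore activity profiles at steady state. Stretching
  still lowers activity (metaphase < prometaphase) and the fast-cis
  variant still tracks concentration, but a persistent steep
  subdomain boundary would require slower chromatin exchange or locally
  anchored phosphatase, neither of which is part of this model.
* Profiles are smooth parametric stand-ins; any measured profile can be
  substituted through `BindingProfile`.
* The model is deterministic (no molecular noise) and one-dimensional;
  centromere stretching enters only through the profile transform.

## Parameter estimation

The score is `f(θ) = Σ_i Σ_j (D_ij − c_i(t_ij, θ))²/σ_ij` with each
experiment span-normalized (`D_max − D_min`) and `σ_ij = T_i`, the number
of points of experiment `i`, so each experiment contributes O(1)
regardless of sampling density. All experiments share rate constants and
differ in initial conditions. Optimization is multi-start
Levenberg–Marquardt in log₁₀-parameter space (positivity by
construction), with starts sampled log-uniformly in [10⁻⁸, 10³] (natural
units) and rejection-sampled into the physically consistent region
(derived dissociation rates ≥ 0). Because the numerical Jacobian must
stay above the ODE-solver noise floor, the finite-difference step is
fixed at 10⁻⁴ in log space. Every start is scored and the best-scoring
quarter (at least five) is polished by LM, and the incumbent gets one
LM restart; the fraction of polished starts
finishing within 1% of the best score is reported as a global-minimum
heuristic. Solver failures at a trial θ yield a large finite penalty so
optimization continues; excursions outside the bounds are pushed back by
a graded penalty.

On noiseless self-generated data (progress curves at 0.16/0.5/1.5 µM
kinase with 20 µM sensor, plus the 4 µM substrate-free activation
course) the default 20-start fit recovers {kcis, KMa, kcata} to better
than 1%. KMa and kcata lie on a shallow ridge — at 4 µM kinase the trans
reaction is far from saturation, so only their ratio is strongly
constrained — which is why the tight LM tolerances and the calibrated
difference step matter.

## Synthetic data

Generators are pure functions of (configuration, seed): with zero noise
they return exactly the model curves. Fluorimetry-like concentration
data get multiplicative Gaussian noise of configurable CV (default 2%);
FRET-like normalized fields get additive Gaussian noise on the
per-position min–max normalized signal. Optional raw-fluorescence
rendering uses the standard-curve slopes. These generators emulate
shapes, scales and noise character of the real assays but not
instrument drift, photobleaching or cell-to-cell variability — passing
recovery tests demonstrate identifiability under the model's own
assumptions, not robustness to model misspecification.

## Problem sizes used in the tests

The test suite and acceptance script run on one CPU in minutes by using:
homogeneous scans at the full protocol resolution; spatial grids of
`dx = 0.05–0.1 µm` (validated against finer grids during development);
hysteresis ramps of 40–60 steps over the reference 100 h cycle; and a
20-start recovery fit. The steady-state relaxation oracle uses a 10×10
concentration grid with 20 initial conditions per cell and 3·10⁵ s
horizons.
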