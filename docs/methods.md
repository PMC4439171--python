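# Methods

## Model structure and assumptions

The package chains three deterministic stages — intraperitoneal
pharmacokinetics, an instantaneous sigmoid firing-rate circuit, and a
first-order temperature ODE — and treats all stochasticity as measurement
noise on the group temperature series.  The key assumptions are:

- Drug kinetics are linear and dose-proportional; a single absorption
  (τ_u) and elimination (τ_d) constant suffice.  The closed-form
  bi-exponential is used everywhere; the ODE integration route exists as an
  independent check.  Near-confluent constants (|τ_u − τ_d| < 10⁻⁶ τ_u)
  switch to the limiting form D·(t/τ_u)·e^(−t/τ_u) to avoid catastrophic
  cancellation, so equal constants are handled exactly rather than
  rejected.  Note the roles of the two constants are *not* interchangeable:
  swapping them preserves the curve's shape but scales its amplitude by
  τ_u/τ_d.  τ_u is always the absorption constant.
- Circuit nodes are memoryless rate units; all dynamics live in the
  pharmacokinetics and in the temperature relaxation (τ_T ≈ 89 min).
- The antagonist SB-334867 has no pharmacokinetics of its own: each SB dose
  is a constant reparametrization (w_S, w_Exc, w_Inh, w_HD) over the whole
  recording.
- Both injections (pretreatment at −30 min, treatment at 0 min) deliver the
  same stress amplitude w_S.

## Parameters

Fixed constants (config section `pk.*`, `circuit.*`, `thermo.*`):

| name | default | units | meaning |
|---|---|---|---|
| τ_u | 8.25 | min | Meth absorption |
| τ_d | 57.5 | min | Meth elimination |
| τ_s | 10 | min | injection-stress decay (treated as fixed, not fitted) |
| τ_T | 89.2 | min | temperature relaxation |
| T₀ | 37 | °C | baseline temperature |
| γ_Exc, γ_Inh, γ_HD | −0.357, −1.335, −3.69 | conc-scale | basal excitabilities |
| w_Exc→Med, w_Inh→Med, w_HD→SPN | 9.89, 6.38, 5.66 | °C | projection weights |
| γ_SPN | −3.35 | °C | SPN basal offset |

SB-affected sensitivities default to the vehicle generating truth
(w_S = 1.2, w_Exc = 0.85, w_Inh = 0.66, w_HD = 0.70 per mg/kg); per-SB-dose
values live in `synth.scenario`.

**Baseline recentring.** With the constants above the resting SPN drive is
≈ −0.51 °C, which would put the resting temperature below T₀ while observed
baselines sit at T₀.  By default a constant offset is subtracted so the
drive is exactly zero at rest (equivalent to recalibrating γ_SPN);
`circuit.raw_gamma_spn: true` restores the verbatim offset.  The offset is
computed with the inhibition cap released, so failure scenarios keep the
tonic effect of disinhibition.  P_SPN is not rectified: negative drive
legitimately models below-baseline temperature (the ~3 °C hypothermia that
blocking the tonic excitatory pathway, w_Exc→Med·σ(γ_Exc) ≈ 3.25 °C, would
produce).

**Model variants.** `base` and `gamma_hd` share identical dynamics; the
variant label only decides whether w_HD or γ_HD is treated as SB-dependent
during fitting.  For small sensitization shifts the two parametrizations
produce nearly identical activation curves (within 0.01 activity when
matched at the half-activation point for a ~4% slope change); for large
shifts they differ in slope versus displacement, although both can fit the
same temperature data because HD activity saturates over the relevant
concentration range.  `extended` routes the inhibitory tone onto HD through
the Inhib node: P_HD = σ(w_HD[M] + γ_HD − w_Inh_HD·P_Inh).  w_Inh_HD is not
identifiable from the data used here and defaults to 5.0, strong enough to
keep HD silent at 5 mg/kg under vehicle parameters.  The inhibition-failure
scenario applies a hard ceiling (`inhib_cap`) to P_Inh — a bound on maximal
activity, not a rescaling.

The failure scenario's default circuit uses the extended variant with
w_Inh = 1.5 (other entries at vehicle defaults).  This vehicle-like
parametrization was chosen so that the intact circuit shows only a minor
response to 3 mg/kg while capping Inhib at 50% or 0% uncovers progressively
stronger hyperthermia; only the ordering and monotonicity of the peaks are
asserted, never particular temperatures.

## Numerical choices

- **Integrator.** Classical RK4 with fixed step dt = 0.1 min (the ODE is
  linear and non-stiff).  Because the equation is linear in T, each RK4
  step is an affine map whose forcing coefficients are precomputed from the
  drive arrays; the scalar recursion is evaluated with a C-level linear
  filter, making a full trajectory cost a few hundred microseconds — the
  property that makes MCMC over the full model cheap.  The stress input is
  discontinuous at the injection times; these instants land on step
  boundaries (integer injection times, dt dividing their offsets) and the
  drive is sampled one-sidedly (right-limit at a step's left node,
  left-limit at its right node), so no RK4 step straddles a jump and the
  method keeps its accuracy (refining dt tenfold moves trajectories by
  < 10⁻⁴ °C).  Output is linearly interpolated onto the requested grid.
- **Fitting grid.** i = −50, −48, …, 180 min (116 points); integration
  starts at −50 min with T = T₀ (the start of the displayed data window;
  the initial condition is not otherwise constrained by the protocol).
- **σ floor.** Group SDs are floored at 0.05 °C inside the likelihood to
  avoid singular weights when a group's SD vanishes at some time point.
- **Priors.** Improper flat on the support: sensitivities and time
  constants nonnegative, w_S and γ_HD unconstrained — the posterior is
  proportional to the likelihood alone.
- **Sampler.** Random-walk Metropolis–Hastings with diagonal Gaussian
  proposals.  During burn-in the global proposal scale is driven toward a
  25–40% acceptance rate and the relative scales are shaped by the running
  chain spread; adaptation is frozen at the end of burn-in so the retained
  (thinned) chain satisfies detailed balance.  Defaults: 50 000 steps,
  10 000 burn-in, thin 10; the recovery studies and tests use 12 000–20 000
  steps, which the chain diagnostics (acceptance ≈ 0.3, split-half
  agreement) show is ample for these 1–4-dimensional posteriors.  A run
  warns if the post-burn-in acceptance rate leaves [0.1, 0.6].
- **Ensemble summaries.** The "standard error" of a parameter is the
  posterior standard deviation of its ensemble — the reading required for
  z-testing ensemble means.  Because the likelihood weights residuals by
  the group SD (not the SEM), posteriors are ≈ √n wider than the sampling
  error of the group mean; the z-tests inherit this conservatism.

## Synthetic data

The generator emulates the telemetry study design: pretreatment (vehicle /
SB 10 / SB 30 mg/kg) at −30 min crossed with treatment (saline / Meth 1, 5,
10 mg/kg) at 0 min, n = 7 animals per group, samples every 2 min from −50
to 180 min, baseline 37 °C.  Each animal is the noiseless trajectory plus a
constant baseline offset (SD 0.2 °C) and AR(1) noise (innovation SD 0.3 °C,
lag-1 coefficient 0.5, stationary start) — telemetric residuals are smooth,
so iid noise would be unrealistically informative.  Group mean and SD are
empirical across animals; the SEM is recorded alongside but inference
consumes the SD.

The default AR(1) noise deliberately violates the iid likelihood, so
recovery under defaults measures robustness to that misspecification.  An
exactly matched mode (`NoiseSpec.iid()`: AR coefficient 0, no offsets) is
used for the strict recovery studies.

The per-SB-dose generating truths are calibrated so the *vehicle* series
reproduces the reported response pattern — slight short-lived saline bumps,
a mild early peak near 38.2–38.5 °C for 1 mg/kg around an hour
post-injection, a delayed rise for 5 mg/kg, and a robust ~39.5–40 °C
response for 10 mg/kg — and so the SB truths follow the reported orderings
(w_Exc and w_Inh fall with SB dose, w_HD rises, w_S drops from vehicle with
little difference between the two SB doses).  Exact values are
configuration, not estimates.

What the generator does **not** emulate: between-animal variance structure
beyond a constant offset, circadian drift, missing samples, or
heterogeneous group sizes.  Passing recovery tests therefore demonstrate
the estimator's correctness and calibration under the stated noise model,
not performance on raw animal telemetry.

## Recovery studies

`scripts/acceptance.py` re-estimates each time constant from one synthetic
group by single-parameter MCMC with everything else held at the generating
truth (Meth-5/vehicle group for τ_u, τ_d, τ_T; saline–saline for τ_s), and
verifies the no-injection baseline fixed point.  The joint 4-parameter fits
recover each scenario's (w_S, w_Exc, w_Inh, w_HD) within a few posterior
SD, and the three SB scenarios' posterior clouds separate cleanly at the
2-SD level in the (w_Exc, w_Inh) and (w_S, w_HD) projections.

## Known limitations

- τ_u is only weakly identified by a single intermediate-dose group: the
  excitatory and inhibitory nodes saturate near the concentration peak, so
  the early rise carries limited information.  The τ_u posterior from one
  Meth-5 group (SD-weighted likelihood, n = 7) has an SD of ~2 min and a
  mildly left-heavy shape (very fast absorption is hard to exclude), so its
  posterior mean scatters by roughly ±1 min around a slight low bias across
  noise realizations.  Joint fitting of several doses, or SEM weighting,
  sharpens it; both are available through the library API.
- The sampler is a plain adaptive random-walk chain — adequate for these
  low-dimensional, unimodal posteriors, but no replacement for gradient or
  ensemble methods in higher dimensions (a cross-check against an
  affine-invariant ensemble sampler is part of the test suite).
- Real-data reproduction (the fitted curves of the original telemetry
  study) is out of scope: the deposited per-animal workbook can be read via
  `read_series_xlsx`, but no fitted parameter values for it are shipped.
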