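# meththerm

A mechanistic model of body-temperature responses to methamphetamine (Meth)
in rats, the stress of intraperitoneal injection, and pretreatment with the
orexin-1 receptor antagonist SB-334867 — together with the Bayesian
machinery to fit the model to group temperature telemetry and to test which
circuit parameters the antagonist changes.

It is aimed at researchers in thermoregulation and psychostimulant
pharmacology who want to decompose complex temperature responses into
interpretable circuit components, and at anyone who needs a compact,
fully-testable example of MCMC data assimilation for an ODE model.

## The model

Three stages, all in minutes / mg/kg / °C:

**Pharmacokinetics.** An intraperitoneal dose *D* at *t* = 0 is absorbed and
eliminated through a two-compartment linear system,

```
d[Mp]/dt = -[Mp]/τu          [Mp](0) = D
d[M]/dt  =  [Mp]/τu - [M]/τd  [M](0) = 0
⇒  [M](t) = D (τu/τd - 1)⁻¹ (e^(-t/τu) - e^(-t/τd)),  t > 0
```

Each injection (drug or vehicle) also delivers a stress input
S(t, t₀) = e^(-(t-t₀)/τs) for t > t₀.

**Circuit.** Three Meth-sensitive rate populations pass their drive through
σ(x) = (1 + tanh x)/2: an excitatory node Exc (which also receives both
stress inputs), an inhibitory node Inhib, and a high-dose-activated node HD.
Exc and Inhib compete at a medullary relay, and the sympathetic premotor
output adds the HD contribution:

```
P_Exc = σ(w_S S(t,-30) + w_S S(t,0) + w_Exc [M] + γ_Exc)
P_Inh = σ(w_Inh [M] + γ_Inh)
P_HD  = σ(w_HD [M] + γ_HD)
P_Med = w_Exc→Med P_Exc - w_Inh→Med P_Inh
P_SPN = P_Med + w_HD→SPN P_HD + γ_SPN
```

**Thermodynamics.** Temperature relaxes toward the SPN drive:
τ_T dT/dt = P_SPN(t) - (T - T₀).

**Inference.** The four SB-affected sensitivities W = (w_S, w_Exc, w_Inh,
w_HD) are sampled by random-walk Metropolis–Hastings from the posterior

```
log p(W | {T_i}) = -Σ_i (T_i - T(W, i))² / 2σ_i²
```

where T_i, σ_i are group mean and SD on a 2-min grid from -50 to 180 min.
One W is fitted jointly to all four Meth-dose groups of each SB dose
(vehicle / 10 / 30 mg/kg); parameter differences between SB doses are then
assessed with two-sample z-tests on the posterior ensembles.  Two model
variants probe the mechanism of HD sensitization (basal-tone parametrization
γ_HD; an extended circuit where Inhib inhibits HD), and an
inhibition-failure scenario caps the maximal Inhib activity to show how a
mild dose becomes dangerous when inhibition degrades.

## Worked example

```python
import numpy as np
from meththerm import (FixedModel, InjectionSchedule, MCMCSettings,
                       mcmc_sample, run_inhibition_failure, simulate_temperature)
from meththerm.synthetic_data import (DEFAULT_SCENARIO, DesignSpec, NoiseSpec,
                                      generate_group)

fixed = FixedModel()          # published constants + vehicle weights
design = DesignSpec()         # 2-min sampling, injections at -30 and 0 min

for dose in (0, 1, 5, 10):    # dose-response of the noiseless model
    traj = simulate_temperature(InjectionSchedule(meth_dose=dose),
                                fixed.circuit, fixed.pk, fixed.thermo,
                                design.times)
    k = np.argmax(traj.temp)
    print(f"Meth {dose:>2} mg/kg: peak {traj.temp[k]:.2f} C at {traj.times[k]:+.0f} min")

# recover the absorption time constant from one synthetic group
series, _ = generate_group(DEFAULT_SCENARIO[0.0], design,
                           NoiseSpec(noise_sd=0.3, ar1=0.0, baseline_sd=0.0),
                           sb_dose=0.0, meth_dose=5.0,
                           rng=np.random.default_rng(11))
ens = mcmc_sample([series], fixed, {"tau_u": 12.0},
                  MCMCSettings(n_steps=20_000, burn_in=5_000, seed=11))
print(f"tau_u posterior: {ens.mean()['tau_u']:.2f} +/- {ens.se()['tau_u']:.2f} min")

_, peaks = run_inhibition_failure()   # 3 mg/kg with capped Inhib activity
print(peaks.to_string(index=False))
```

prints

```
Meth  0 mg/kg: peak 37.86 C at +20 min
Meth  1 mg/kg: peak 38.50 C at +56 min
Meth  5 mg/kg: peak 39.30 C at +122 min
Meth 10 mg/kg: peak 39.77 C at +150 min
tau_u posterior: 8.40 +/- 1.54 min
 fraction  peak_temp_c  peak_time_min
      1.0    37.697545          138.0
      0.5    38.713946           62.0
      0.0    40.594460           86.0
```

Saline gives only a small stress bump; 1 mg/kg a mild early peak; 5 mg/kg a
*delayed* rise (Inhib masks Exc until the drug is partly eliminated);
10 mg/kg a robust response through HD.  The MCMC recovers the generating
absorption constant (8.25 min) from noisy group data.  In the failure
scenario an intact circuit barely responds to 3 mg/kg, while halving or
silencing the inhibitory population turns the same dose into strong,
potentially life-threatening hyperthermia — the temperatures shown are the
actual model output for the default scenario.

A command-line interface mirrors the pipeline:
`meththerm synth|simulate|fit|ztest|curves|failure --out DIR [--config cfg.yaml]`.

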