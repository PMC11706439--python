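# baroloop

Closed-loop, pulsatile lumped-parameter (0D) models of the human
circulation — one-chamber and four-chamber variants — coupled to an
Ursino-type baroreflex, with local and variance-based (Sobol) global
sensitivity analysis.

The package is aimed at cardiovascular modellers who want to study how
short-term neural regulation reshapes parameter influence on clinically
measurable outputs (pressures, cardiac output, heart period), e.g. as a
precursor to model personalisation.

## The model in brief

Passive vascular beds are CRC Windkessels, `dP_k/dt = (Q_k − Q_{k+1})/C_k`
with Ohmic inter-compartment flows; valves are diodes (resistance `r_val`
forward, `1000 r_val` reverse).  Heart chambers are time-varying elastances
`P = E(t) V` with the double-cosine activation
`E(t) = (E_max − E_min) e(t; τ_es, τ_ep) + E_min`.

The baroreflex senses arterial pressure through a pole–zero filter
(`τ_p dP̃/dt = P_art + τ_z dP_art/dt − P̃`), transduces it into an afferent
firing rate `f_cs` (sigmoid around the set-point `P_n`), splits it into
antagonistic sympathetic (`f_es`, exponential) and vagal (`f_ev`, sigmoid)
arcs, and drives each effector θ through a delayed static characteristic and
first-order kinetics, `dΔθ/dt = (σ_θ(t − D_θ) − Δθ)/τ_θ`,
`θ = θ_0 + Δθ`.  Heart period and ventricular contractility update
beat-to-beat (held within a beat, promoted at beat onset); systemic
resistance and — in the four-chamber model — venous unstressed volume act
continuously.  The whole system is a delay-differential equation in the
compartment pressures, the filtered pressure and the effector states,
integrated by a compiled fixed-step RK4 with Hermite history interpolation
(an adaptive `solve_ivp` reference integrator cross-validates it).

Sensitivity analysis: relative local sensitivities
`Ŝ_ij = (θ_i/ŷ_j) ∂y_j/∂θ_i` by central differences, and Sobol first/total
order indices (`S1` by the Saltelli estimator, `ST` by the Jansen estimator)
from a scrambled-Sobol QMC design of `K(n+2)` model runs over a ±10% box,
with bootstrap confidence intervals.  See `docs/methods.md` for details and
numerical choices.

## Worked example

```python
import baroloop as bl

# regulated one-chamber model at the built-in base parameter values
params = bl.default_parameters("1ch", regulated=True)
traj = bl.simulate(params, bl.SimulationConfig(t_end=150.0))

print("steady heart period     :", round(traj.trailing_mean("tau_held"), 4), "s")
print("steady max LV elastance :", round(traj.trailing_mean("e_lvmax_held"), 4), "mmHg/ml")
print("steady systemic resist. :", round(traj.trailing_mean("r_sys_t"), 4), "mmHg*s/ml")

outputs = bl.extract_outputs(traj)
print("cardiac output          :", round(outputs["co"], 2), "ml/s")
print("arterial pressure range :", round(outputs["p_art_min"], 1), "-",
      round(outputs["p_art_max"], 1), "mmHg")
```

prints

```
steady heart period     : 0.9071 s
steady max LV elastance : 2.4823 mmHg/ml
steady systemic resist. : 2.3785 mmHg*s/ml
cardiac output          : 40.02 ml/s
arterial pressure range : 84.1 - 110.6 mmHg
```

Starting from the 0.58 s base heart period, the reflex settles the loop near
its 92 mmHg set-point by lengthening the heart period to ~0.91 s and raising
contractility and systemic resistance — the regulated operating point that
the equivalent-unregulated comparison protocol then freezes into an
unregulated parameter set:

```python
equivalent, overrides = bl.derive_unregulated_equivalent(params)
print(overrides)   # {'tau_hr0': 0.9071, 'e_lvmax': 2.4823, 'r_sys': 2.3785}
```

A scaled-down global sensitivity analysis of that unregulated model
(9 parameters, K·(9+2) model runs):

```python
from baroloop.sensitivity import run_gsa
res = run_gsa(equivalent, k=512, seed=1)
print(res.to_frame("s1").round(3))        # parameters x outputs
```

## Command line

```bash
baroloop simulate   --model 4ch --regulated --out-dir out/
baroloop equivalent --model 1ch --regulated
baroloop lsa        --model 1ch --regulated
baroloop gsa        --model 1ch --unregulated -K 2048 --seed 1
baroloop converge   --model 1ch --unregulated -K 1000
baroloop fixtures   -n 5 --seed 3
```

Every command writes CSV artifacts plus a JSON run manifest and is
byte-reproducible for a given seed and config.  A YAML config (sections
`model`, `mechanical`, `baroreflex`, `simulation`, `sensitivity`) can
override any named parameter; unknown keys are rejected.  Sample budgets
above K = 8192 need `--allow-long` (the full published 150k-sample sweeps
are cluster-scale).

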