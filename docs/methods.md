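# Methods

`baroloop` implements two closed-loop, pulsatile lumped-parameter (0D) models
of the human circulation — a one-chamber (1CH) and a four-chamber (4CH)
variant — coupled to an Ursino-type baroreflex, together with the local and
variance-based (Sobol) sensitivity-analysis machinery used to study them.
This note records the model, the numerical choices, and the design decisions
taken where the problem was genuinely open.

## The mechanical models

Each passive compartment is a linear compliance `C` with Ohmic resistances
`R` between nodes (pressure ↔ voltage, flow ↔ current):

    dP_k/dt = (Q_k − Q_{k+1}) / C_k,      Q_k = (P_{k−1} − P_k) / R_k.

Heart valves are diodes with Ohmic behaviour under both biases: resistance
`r_val` forward, `1000 r_val` reverse; both branches vanish at zero pressure
gradient, so the flow is continuous.

Heart chambers are time-varying elastances `P = E(t) (V − V0)` with the
double-cosine activation

    E(t) = (E_max − E_min) e(t) + E_min,

where `e(t)` rises as a half-cosine on `[0, τ_es)`, falls on `[τ_es, τ_ep)`
and is zero for the rest of the cycle.  Timing is stored as *fractions* of
the current heart period (ventricles 0.30/0.45, atria 0.92/0.96/1.00), so
regulated changes of the heart period rescale systole consistently.  Atrial
systole spans the cycle boundary; activation is evaluated on the shifted,
wrapped cycle coordinate.

All chamber unstressed volumes are zero.  This allows the chamber volume
states to be eliminated: `dP/dt = (E′/E) P + E (Q_in − Q_out)`.  In the 4CH
model the atria share their pressure node with the adjacent venous
compliance (`P_RA = P_V`, `P_LA = P_pulV`); the merged node obeys

    dP/dt = E/(1 + C E) (Q_in + q_un − Q_out) + E′/(E (1 + C E)) P,

where `q_un` is the stressed-volume injection from unstressed-volume
regulation (zero except at the systemic venous node of the regulated 4CH).

**1CH topology**: LV → aortic valve → arterial compliance → systemic
resistance → venous compliance → mitral valve → LV.
**4CH topology**: the same systemic loop with the RA merged into the venous
node, plus RV, pulmonary arterial compliance, pulmonary resistance, and the
LA merged into the pulmonary venous node.

## The baroreflex

Arterial pressure is the carotid-sinus surrogate.  The arc is:

1. *Afferent filter*: `τ_p dP̃/dt = P_art + τ_z dP_art/dt − P̃` (real pole
   2.076 s, real zero 6.37 s).  `dP_art/dt` is taken from the assembled
   right-hand side, not from numerical differencing.
2. *Afferent firing*: a sigmoid of `P̃` around the set-point `P_n = 92 mmHg`
   bounded by (2.52, 47.78) spikes/s.
3. *Efferent arcs*: sympathetic `f_es` (exponential decay in `f_cs`) and
   vagal `f_ev` (rising sigmoid), acting antagonistically.
4. *Delayed statics*: each sympathetic effector applies
   `σ = G ln(f_es(t−D) − f_es,min + 1)` (zero below threshold, continuously);
   the vagal heart-period pathway is linear, `σ = G f_ev(t−D)`.
5. *Effector dynamics*: first-order relaxation
   `dΔθ/dt = (σ − Δθ)/τ_θ`; the absolute value is `θ_0 + Δθ`.

Effectors: heart period (sympathetic + vagal contributions, *summed*),
maximal LV (and, in 4CH, RV) elastance, systemic resistance, and (4CH only)
venous unstressed volume.  Systemic resistance and unstressed volume act
continuously; heart period and contractility act beat-to-beat: their values
are *held* within a beat and promoted to `θ_0 + Δθ(t_b)` at each beat onset.

The beat promotion is expressible as a smooth ODE — a normalised-Gaussian
bump (width σ = 1e−3 s, configurable) replacing the Dirac impulse, after
which the held state relaxes to the target with residual `exp(−area)`
(area 40 ⇒ residual ≈ 4e−18).  `baroloop.baroreflex.beat_promotion_rate`
implements and tests exactly this form.  The production integrator applies
the promotion in its exact bump-limit form (`held ← θ_0 + Δθ(t_b)`) at the
beat event instead of resolving the stiff layer: the beat time is known in
closed form (`t_b + τ_held`, since the held period is constant within a
beat), the two formulations agree to the promotion tolerance by
construction, and the event form removes a σ-scale stiffness from every
beat.

### Unstressed-volume regulation sign

The venous unstressed volume is written `V_un = V_un,init + Δθ_Vun`, with
gain `G = −199 ml·s/spikes`: sympathetic drive makes `Δθ_Vun` negative,
shrinking the unstressed pool and *injecting* stressed volume
(`q_un = −dΔθ_Vun/dt`).  The conserved quantity of the regulated 4CH loop is
therefore total stressed volume + `Δθ_Vun`, monitored every run.  The
opposite sign reading is dynamically unstable (a pressure drop would then
withdraw stressed volume — positive feedback), which fixes the convention.

## Initial conditions and total blood volume

All passive pressures start at the mean circulatory filling pressure
(mcfp: 8 mmHg 1CH, 6 mmHg 4CH), the filtered afferent pressure at mcfp, and
all effector deviations at zero.  The closed loop conserves total volume, so
the initial state fixes the operating point of the *unregulated-volume*
(1CH) loop.  The tables define every rate constant but not the total
volume; the package treats the initial LV volume as an explicit structural
constant:

* **1CH**: `v_lv_init = 164 ml` (total stressed volume ≈ 260 ml), identified
  once from the published regulated steady-state operating point
  (τ_HR = 0.906 s, E_LVmax = 2.48, R_sys = 2.386) and then frozen.  The
  uniform stopped-state prescription (V_LV = mcfp/E_LVmin = 133 ml, total
  230 ml) gives an operating point ≈ 6% away; the steady state is a function
  of the conserved total volume only, not of its initial distribution
  (asserted in the tests).
* **4CH**: the exactly uniform stopped state (V_LV = mcfp/E_LVmin = 100 ml,
  total ≈ 500 ml).  Unstressed-volume regulation actively exchanges volume
  with the reservoir, which makes the 4CH operating point only weakly
  (≈1% per 40 ml) sensitive to this choice — no calibration is needed, and
  all four published steady-state effector values are reproduced to <1%.

## Integration

The production integrator (`baroloop._engine`, numba-compiled) uses
fixed-step classical RK4 (default `dt = 5e−4 s` for single runs, `1e−3` to
`4e−3` for sensitivity sweeps, validated by step-halving) with:

* cubic-Hermite interpolation of the stored afferent-pressure history for
  the delayed terms (locally 4th-order, matching the step order; history
  before t = 0 is the constant initial state; delayed times move
  monotonically, so lookups are O(1) with per-channel index hints);
* beat events at their analytically known times, with step truncation so
  events and sample times are hit exactly;
* a volume-conservation projection at each beat: all stressed volumes are
  linear in the pressures, so one uniform pressure rescaling restores the
  conserved total exactly.  Without it, RK4 on the eliminated (log-linear)
  ventricular states leaks O(h⁴) volume per step, and because the 1CH
  operating point tracks total volume the leak becomes a secular output
  error; with it, outputs at `dt = 2e−3` agree with the converged values to
  <0.3% and the conserved total drifts < 1e−5 relative over 300 s.

An independent adaptive reference (`baroloop.reference`) integrates the same
system with `scipy.integrate.solve_ivp` (RK45, tolerances 1e−6) by the
classic method of steps (segment length capped below the shortest delay so
delayed lookups always fall in completed history).  Engine and reference
agree to 0.02–0.6% on all four variants over the startup transient; the
reference is one to two orders of magnitude slower and exists for
validation.

Steady state is declared at a fixed horizon (150 s model time for 1CH,
300 s for 4CH, past the slowest effector settling: time constants ≤ 20 s,
delays ≤ 5 s) plus a cycle-to-cycle periodicity check on arterial pressure;
trailing-window means change < 0.2% on doubling the horizon.  Sensitivity
sweeps use shorter horizons (60 s unregulated, 100 s regulated), likewise
validated by the doubling property.

## Clinical outputs

Over the final complete cardiac cycle: cardiac output (LV stroke volume /
that cycle's period, ml/s), heart period, max/min LV volume, and max/min
pressures per compartment — 10 outputs for 1CH, 16 for 4CH.  Cycle extrema
are tracked at every integrator step (not from the sampled trajectory).
Unregulated analyses drop the heart period from the output list (it is
constant there).

## Regulated → unregulated comparison protocol

The regulated model is run to steady state; the mean of the final 200
samples (2 s at the 0.01 s sampling interval — more than one full beat) of
each effector's absolute value overrides the corresponding base value of an
unregulated parameter set.  At defaults this yields τ_HR,0 = 0.907,
E_LVmax,0 = 2.482, R_sys,0 = 2.379 (1CH) and R_sys,0 = 2.385,
τ_HR,0 = 0.908, E_LVmax,0 = 2.486, E_RVmax,0 = 2.039 (4CH), matching the
published protocol values within 1%.  The "final 200 time points" are read
as 200 trailing samples at the fixed sampling interval; the window is
configurable.  For the 4CH model the trailing mean of the unstressed volume
is recorded in the returned parameter set for bookkeeping; the unregulated
dynamics contain no unstressed-volume coupling (only its rate ever enters
the equations), so it does not alter the model.

## Sensitivity analysis

**Local**: relative sensitivities `(θ_i/y_j) ∂y_j/∂θ_i` at the base point by
central differences (relative step 1e−4), with a Richardson step-halving
consistency check (<1% disagreement required).  Outputs at machine zero are
flagged and left unscaled rather than dropped.  A display normalisation
divides each output column of |Ŝ| by its maximum.

**Global**: Sobol indices over a ±10% box around the base vector.
Scrambled-Sobol QMC design (`scipy.stats.qmc`), `K(n+2)` model evaluations;
first-order indices by the Saltelli (2010) estimator on *centred* outputs
(centring leaves the estimator unbiased but removes an `E[Y]²/Var(Y)`
variance term that is crippling for clinical outputs whose mean is much
larger than their spread), total-order indices by the Jansen (1999)
estimator (shift-invariant).  95% confidence intervals by percentile
bootstrap over the K design rows, resampled jointly across the (A, B, AB_i)
blocks to preserve the estimator pairing.  Negative MC-noise estimates are
retained in stored results and clipped only for heatmap rendering.
Non-finite runs inside the box are imputed with the base-point output and
counted; a failure rate above 1% aborts.  Bounds for negative-gain
parameters are ordered numerically so samplers always see low < high.

The convergence driver runs the GSA over a schedule of (K, B) pairs and
records index ± CI for selected (parameter, output) pairs; on the additive
closed-form oracle the CI half-width shrinks ~K^(−1/2).  The full published
schedule (100 → 150 000 samples) is provided but is cluster-scale work; the
shipped studies are desk-scale (K ≤ 8192, guarded in the CLI by
`--allow-long`).

### The free-parameter sets (36 / 9 / 51 / 22)

The perturbed sets are not uniquely determined by their published
dimensions; the package publishes this reconciliation:

* structural everywhere (never perturbed): mcfp*, τ_initV (= 0),
  V_unV,init (= 0), v_lv_init;
* unregulated analyses drop τ_HR,0, mirroring the removal of heart period
  from their output list;
* the regulated 4CH drops every cardiac timing fraction (timing
  perturbations destabilise the four-chamber analysis);
* τ_S2A (base 1.0 τ) can never move +10% within the cycle, and τ_S1A
  (0.96 τ) would overlap it, so neither is ever perturbed;
* *mcfp is perturbable only in the unregulated 4CH, where total blood
  volume is a genuine free input and is needed to reach the printed count.

Resulting sets: 1CH regulated = 10 mechanical + 26 baroreflex = 36; 1CH
unregulated = 9 mechanical; 4CH regulated = 19 mechanical + 32 baroreflex =
51; 4CH unregulated = mcfp + 8 elastances + 3 timing fractions + 4 valves +
6 circulation = 22.  `ModelParameters.free_parameter_order` is the exact
ordered list per variant.

## Known limitations

* The LV pressure minimum of these equations forms at end-relaxation, where
  `P_min ≈ E_LVmin · V_min`; its variance over the ±10% box therefore
  carries an irreducible E_LVmin share (first-order index ≈ 0.5) that caps
  the E_LVmax share near 0.33.  Published figures for this entry that
  exceed this bound cannot be produced by the equations as implemented
  here; the corresponding min-LV-*volume* entry evaluates to 0.63
  (unregulated) and 0.44 (regulated).
* With the published gains, baroreflex compensation of a perturbed base
  systemic resistance is shared between the resistance, heart-period and
  contractility channels (static loop gain ≈ 3.8, roughly 40% through the
  resistance channel); the heart-side channels restore pressure *by cutting
  cardiac output*, so the total-order influence of R_sys on CO is damped
  only ≈ 2× by regulation in this implementation.
* No inertial elements, nonlinear compliances, valve dynamics beyond the
  Ohmic diode, respiratory or neurotransmitter modulation; rest state only.
* The models are deterministic; all randomness lives in the QMC design and
  bootstrap, controlled by a single seed.
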