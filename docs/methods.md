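# Methods

## Model

The cell is reduced to two isopotential compartments.  All quantities are
dimensionless; time is in model time units (read as milliseconds when the
action-potential spectral peak ω = 2π·0.25 rad/unit is interpreted as
250 Hz).  The somatic and dendritic membrane potentials obey

```
C_m,S dV_S/dt = −G_m,S (V_S − E_L) − (G_C/p)(V_S − V_D)
                − G_Na m_S∞(V_S)(V_S − E_Na) − G_K,S n_S (V_S − E_K) + I_S
C_m,D dV_D/dt = −G_m,D (V_D − E_L) − (G_C/(1−p))(V_D − V_S)
                − G_Ca m_D (V_D − E_Ca) − G_K,D n_D (V_D − E_K)
```

with Morris–Lecar-style gating

```
m_S∞(V) = ½(1 + tanh((V + 0.01)/0.15))                      (instantaneous)
dn_S/dt = φ (n_S∞ − n_S) cosh((V_S + 0.04)/0.1),  n_S∞ = ½(1 + tanh((V_S + 0.04)/0.1))
dm_D/dt = φ (m_D∞ − m_D) cosh((V_D − 0.07)/0.1),  m_D∞ = ½(1 + tanh((V_D − V_1D)/V_2D))
dn_D/dt = φ (n_D∞ − n_D) cosh(V_D/0.1),           n_D∞ = ½(1 + tanh(V_D/0.1))
```

φ = 0.2.  Defaults: `G_Na = 11.0`, `G_K,S = 14.0`, `G_Ca = 0.89`,
`G_K,D = 0.44`, `E_Na = E_Ca = 1.0`, `E_K = −0.7`, `E_L = −0.5`,
`V_1D = 0.07`, `V_2D = 0.1`.  The gate time constants use
`1/cosh(x/slope)` with the slope equal to the activation slope (not the
canonical `2·slope`); the canonical variant was evaluated and rejected
because it destroys the reference firing behaviours (no sustained firing at
the distal exemplar, spurious plateau at the proximal one).  The dendritic
`m_D` time-constant constants stay at (0.07, 0.1) when neuromodulation
scales `V_1D`/`V_2D`; the option `tie_tau_to_activation` ties them instead.

`p = 0.168` is the somatic share of total membrane area.  The PIC is the
`G_Ca m_D (V_D − E_Ca)` term; a plateau potential is the regenerative,
sustained opening of `m_D`.

## Cable inversion and validity

Given `r_N`, `τ_m` and the VA triple, the conductances follow from DC
divider relations, `C_m,D` from the AC attenuation at ω, and `C_m,S` from
the requirement that −1/τ_m be an eigenvalue of the passive system.  The
closed form is eigenvalue-exact: the forward circuit computation recovers
(VA, r_N, τ_m) to machine precision, and the test suite asserts the round
trip at 1e−6 over a 21³ grid.

A VA triple is *invalid* (nonphysiological) when

* a denominator degenerates (`va_sd_dc·va_ds_dc = 1`, or `va_sd_dc` or
  `va_sd_ac` is 0),
* any conductance is non-positive,
* the `C_m,D` radicand is negative — equivalently the AC attenuation is
  weaker than the DC attenuation,
* no positive `C_m,S` exists, **or** the pinned eigenvalue −1/τ_m is not the
  slowest mode of the resulting system (the sampled cell would not have τ_m
  as its system time constant).

## Numerical integration

Sweep workloads make explicit adaptive solvers impractical: near the
validity boundary `C_m,D` → 0 and at depolarised `V_D` the cosh gate rates
reach ~10³, forcing explicit steps below 1e−4 time units.  The default
integrator is therefore a fixed-step Strang-split exponential scheme:

1. half-step exact relaxation of each gate toward its target at frozen
   voltages (`x ← x∞ + (x − x∞) e^{−r h/2}`), which also keeps gates in
   [0, 1] unconditionally;
2. full-step exact update of the voltage pair: with gates frozen the
   (V_S, V_D) subsystem is linear, `dv/dt = M v + b`, and the 2×2 matrix
   exponential is evaluated in closed form (eigenvalues are real because the
   off-diagonal coupling is positive).  The instantaneous somatic activation
   `m_S∞` is evaluated at a half-step predictor (midpoint), making the
   scheme second order; the stimulus is sampled at the step midpoint;
3. half-step gate relaxation.

Default step `h = 0.05`, output sampling 0.1.  On the worked-example cable
tuples the spike times agree with an adaptive Dormand–Prince 5(4) run at
rtol 1e−8 / atol 1e−10 (and with an independent LSODA integration in the
tests) to within 0.34 time units over the full 3500-unit protocol, and
halving `h` moves spike times by < 0.1.  The adaptive pair remains available
via `simulate_ramp(..., method="dp54")`.

## Protocols

* Current clamp: symmetric triangle, peak 2.5, total duration 3000 (rise and
  fall 1500 each), preceded by 500 units of settling at zero stimulus.  The
  initial state is (E_L, E_L) with gates at their steady states.
* Voltage clamp: triangular somatic command from rest (E_L) to 0.3 and back
  over 3000 units.  The clamp current includes the capacitive term.  The
  leak reference `I_leak` is a companion run with `G_Ca = 0`, so
  `I_PIC = I_S − I_leak` is exactly zero when the PIC is blocked; the PIC is
  inward (negative) during activation and metrics are reported on its
  magnitude.  The command apex 0.3 spans the PIC half-activation (0.07) with
  a wide margin.

## Event detection and classification

**Spikes.**  Firing recruits through graded action potentials: at
recruitment the somatic spike peaks can sit as low as −0.16 while the
between-spike minima of plateau-driven firing rise to −0.09, so no fixed
voltage threshold separates spikes from non-spikes across the parameter
space.  Spikes are therefore detected as voltage peaks with local prominence
≥ 0.15 within a 50-time-unit window (the window keeps the slow ramp
response from registering), with a 2-unit refractory guard.  A classic
threshold-crossing detector remains available (`spike_mode="crossing"`).

**Plateau.**  An epoch with `m_D ≥ 0.5` sustained for ≥ 10 time units.  The
duration guard rejects the brief per-spike `m_D` excursions driven by
somatic spikes; the regenerative plateau jump is sharp (a few time units) so
the threshold choice inside (0.4, 0.9) does not move onsets materially.

**Characteristic indices.**  With `t_rec` the first spike time, `I_rec` the
stimulus at `t_rec`, and `t_cross` the descending-limb time at which the
stimulus falls back to `I_rec`:

* `TTP` = plateau onset − `t_rec` (0 when no plateau; negative when the
  plateau precedes spiking, the distal-PIC situation);
* `TES` = last spike − `t_cross`;
* `DSF` = 1/ISI of the spike pair spanning `t_cross` minus 1/(first
  ascending ISI); −F_asc if firing ceased before `t_cross`.

**Decision logic.**  No spikes (or an invalid cable / failed integration) →
nonphysiological.  No plateau → Type I, or Type II when firing dies more
than the TES tolerance before `t_cross`.  Plateau at or before recruitment
(TTP ≤ 2) → Type III.  Delayed plateau (TTP > 2) → Type IV: *fully
hysteretic* when the plateau outlasts `t_cross` and TES exceeds its
tolerance, *partially hysteretic* when the plateau deactivates before
`t_cross` (or sustained firing is absent).  The canonical sign signatures —
I (0,0,0), II (0,−,0), III (0,0,+), IV_full (+,+,+), IV_partial (+,+,≤0) —
are reported alongside, with snapping tolerances: TTP 2 (a numerical guard),
TES 70 (≈ two recruitment-level interspike intervals — the graded onset and
dying tails extend the apparent train by about one ISI at each end), DSF 12%
of F_asc (the final stretching ISI of any dying train biases the descending
frequency low by 5–14%).  The time and frequency tolerances were calibrated
once on the four published worked examples and then frozen.

## Grids and sweeps

The VA cube is sampled cell-centered (points `(i+½)/N` per axis): each point
represents an equal-volume cell, so label counts estimate region volume
fractions; grids that include the endpoints 0 and 1 put a large mass of
points (26% at N = 21) on degenerate cube faces that are invalid by
construction and bias the nonphysiological fraction upward by over ten
percentage points.  Default production resolution 21³; fractions converge to
within ~1 percentage point between 21³ and 41³.

The anatomical mapping uses the printed exponential decay constants η (five
reconstructed cells per VA factor); the physiological VA triple at path
distance `d` is the mean over cells of `exp(−d/η)` (the mean of the curves,
not the exponential of the mean η).  The default distance grid is 0–2000 μm
at 5 μm steps.

Neuromodulation scales `(G_Ca, V_1D, V_2D)` by fractional deltas; the
excitatory direction is `G_Ca`↑, `V_1D`↓, `V_2D`↑ (lowering the PIC onset
voltage and raising its amplitude under voltage clamp, which the test suite
asserts).  Robustness curves count fully hysteretic points **along the
physiological VA curve** (the dendritic PIC locations) by default: that
count collapses in both neuromodulation directions — ~100% for inhibitory
changes, 65–85% for excitatory ones at the published magnitudes — while on
the whole cube the Type IV volume shifts toward stronger coupling and can
even grow under excitatory scaling.  The whole-cube basis remains available
(`basis="cube"`).

## Known limitations and discrepancies

* **Partially hysteretic Type IV** occupies, at most, a thin shell around
  the fully hysteretic region.  At the published worked-example coordinates
  (0.96, 0.57, 0.81) — printed to two decimals — the model produces
  overlapping F–I curves and no sustained plateau (max `m_D` = 0.396), i.e.
  Type I behaviour, and no ramp duration between 1500 and 10000 or
  neighbouring coordinate within ±0.01 changes that.  The class is
  implemented and reachable in principle (delayed plateau deactivating
  before the descending recruitment crossing) but is not observed on the
  default grids.
* **Type IV distance interval.**  The mean-curve scan gives 135–510 μm.
  The reference interval 88–685 μm is wider; scanning the five per-cell
  curves and taking the union gives 95–885 μm, bracketing it — the exact
  endpoints depend on how the physiological spread across cells is folded
  in, and on the recruitment-time convention (threshold-crossing detection
  moves the upper endpoint to ~390 μm, graded-onset detection to ~510 μm).
  The mean-curve reading is the default; per-cell scans are available via
  `EtaProfile`.
* **Single-parameter robustness floor.**  The weakest single-parameter ±20%
  effects (excitatory `G_Ca`↑ and `V_2D`↑) reduce the location count by
  ~65% rather than the 70% reference floor; all other directions reach
  76–100%.
* The model collapses all somatic inward/outward currents into one pair and
  places the PIC on a single equivalent dendrite; rate adaptation (the
  presumed Type II mechanism), multi-branch PIC distributions, channel
  noise and temperature effects are out of scope.  The synthetic trace
  generator used for detector tests produces stereotyped triangular pulses
  and square plateau windows — it validates event bookkeeping exactly but
  says nothing about dynamical realism; that burden falls on the solver
  cross-checks and the reproduction of the published worked examples.
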