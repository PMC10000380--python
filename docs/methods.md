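# Methods

## Scope and model structure

`oxyloop` simulates closed-loop oxygen titration for a respiratory-distress
patient. The plant is a series composition of linear lumped blocks:

```
u --> 1/(tau s+1) --> [input delay] --> TF_N TF_T TF_B TF_A' --> [transport delay] --> TF_BO2 --> y
```

* **Oxygen cylinder/valve** — first-order lag `1/(tau s + 1)`; `tau = RC` of the
  supply-line analogue, default 0.50 s.
* **Airway cascade** — four unity-DC second-order sections
  `1/(LC s^2 + RC s + 1)` for the nasal cavity, trachea, bronchi, and alveoli,
  derived from the electrical analogy of a Weibel-type 24-generation
  morphometric model. Respiratory distress stiffens the alveolar walls
  (compliance down by 10^2–10^3); the "infected" alveolar section carries the
  correspondingly reduced coefficients (s² coefficient 1.0e-10 vs 6.72e-8
  healthy).
* **Gas exchange** — the third-order rational block
  `TF_BO2 = (20 s^2 + 200 s + 62)/(s^3 + 110 s^2 + 350 s + 67)` describing the
  capillary-blood oxygen response; DC gain 62/67 ≈ 0.925, so an uncontrolled
  drive never reaches a commanded level above 92.5% of the drive.
* **Transport delays** — pure dead times (0.25–0.75 s physiologically) at the
  supply input and between the airway and gas-exchange blocks, realised as
  exact integer-sample shifts; the frequency domain uses the exact phase term
  `e^{-j w d}`. No Padé approximation anywhere.

## Airway morphometry

Per generation `z` with `n = 2^z` branches, diameter `d`, length `l`, total
cross-section `s`, velocity `u`:

* `R = (8 mu l / (pi r^4)) / n` — the tabulated per-generation resistance is
  the **parallel** combination of the `n` identical Poiseuille branches
  (verified against the first rows of the source table, which only match with
  the `/n`).
* `L = rho l / s` with the **total** area (no `/n`).
* `C = l s / (rho n u^2)`.

Computation is in cgs; pressure converts to cm H2O (980.665 dyn/cm² each) and
volume to litres, so the conversion multiplies R and L by 1000/980.665 and C
by its inverse. The air constants (`mu = 1.81e-4` P, `rho = 1.225e-3` g/cm³,
i.e. air near room temperature) are not stated in the source table; these
standard values reproduce its R and L columns within a few percent.

Known table anomalies, shipped verbatim and excluded from formula tests: the
generation-0 compliance is ~10x below the formula value; several deep
generations print R at one significant figure (hence "at least 20 of 24 rows
within 10%" rather than all 24); the section table's bronchi `LC` column
(1.44e-5, used by the canonical equations) disagrees with its own `L*C`
product (1.35e-5); the nasal s-coefficient is 2.165 in the equation but 2.156
as the `R*C` product. The printed equation coefficients are canonical for
simulation; the table path exists for validation.

## Gas exchange: ODEs vs the rational block

The three-compartment exchange (alveolar air, lung tissue, capillary blood)
gives a coupling matrix whose rows sum to zero: pure exchange conserves a
uniform potential, so the autonomous matrix is singular and its characteristic
polynomial has no constant term. The published rational block has a nonzero
denominator constant (67), which therefore cannot arise from the autonomous
ODEs alone; it implies an input coupling. The package keeps the rational block
verbatim as the canonical simulation element and provides the ODE path with an
explicit input-coupling gain `k_in` (default `k_AA`) for time-domain
experiments, labelled non-canonical.

The four published reciprocal time constants (0.2429, 4.76, 15.87, 88.88 1/s)
are canonical. `derive_rate_constants` exposes a unit-scale factor because no
single convention maps the parameter table onto all four: with scale 0.1 and
the mid-range blood diffusion rate (8.0e-12 L/s of the printed 6.7–10e-12
range) the tissue and blood rates match (15.873, 88.889); the alveolar pair
does not. The sum of the four rates (109.75) equals the rational block's s²
denominator coefficient (110) within 0.25% — the structural consistency check
the package recomputes.

## Controllers

All controllers run at the plant step (1 ms, zero-order hold).

* **PID baseline** — parallel form on `r - y` with clamping anti-windup,
  output limited to [0, 200] % of supply scale. The source names a PID
  baseline but gives no gains; the shipped tuning (kp=0.8, ki=0.25, kd=0.4)
  was hand-fitted once on the composite plant for a fast but visibly
  overshooting response (~1.8% at r=95), the behaviour the comparison study
  attributes to it.
* **Plain MRAC (MIT rule)** — `u = r*theta`, `dtheta/dt = -gamma*e*ym` with
  `e = y - ym`; reference model `1/(s^2 + 2.5 s + 1)` (unity DC, poles -0.5
  and -2) driven by the commanded set-point so the target trajectory is fixed.
  Linearized about the tracking equilibrium the adaptation is an integrator of
  gain `gamma*ym*r*K_dc ≈ 8.3e3*gamma` in series with the plant, whose
  dominant pole sits at ~0.2 rad/s. The shipped sweep grid
  `gamma ∈ {1e-5, 2e-5, 5e-5, 1e-4}` places the adaptation crossover at
  0.08–0.8 rad/s: mildly underdamped through strongly oscillatory, which is
  the regime the comparison study describes for this controller.
* **SFPIMRAC** — the fuzzy gain `m(e, de)` replaces `gamma*e`
  (`dtheta/dt = -m*ym`), and the output uses the modulated set-point
  `u = r'*theta`, `r' = r + (r - y)` clipped to [0, 100]. The incremental
  reading of the adaptation law is used: the literal memoryless form
  `theta = -m*ym` (available behind `literal=True`) forces `u = 0` at zero
  error and cannot hold a flow, contradicting the intended "maintain the same
  flow" behaviour at equilibrium.

Sign conventions: `e = y - ym` throughout; positive error (output above the
reference) produces positive `m` and decreases `theta` (less oxygen). The
set-point modulation is written `r' = r + (r - y)`, which inflates the command
during undershoot and deflates it during overshoot, leaving the steady-state
target untouched (`r' = r` exactly at `y = r`).

## Fuzzy engine

Five equal-base triangular membership functions with 50% overlap on
[-100, 100] for `e` and `de` (% SpO2 units; inputs clamped, not rescaled, at
the span) and on [-1, 1] for `m`; centers at the span quartiles. Inference is
Mamdani min/min/max with centroid defuzzification on a 601-point grid. Two
choices the source leaves open are pinned here and tested:

* **Edge triangles keep their full base** in the centroid integral (the grid
  extends half a base beyond the output span; the result is clamped to
  [-1, 1]). Truncating at the span would cap |m| at 5/6 and a fully saturated
  error could never command full-strength adaptation.
* **Input scaling.** The rule table and universes define the surface shape,
  not its loop gain, and the source is silent on how the % SpO2 signals meet
  the universes. With unit input gains the composed loop has an
  adaptation-loop gain of ~83/s against a plant with a 5 s dominant lag — a
  relay that limit-cycles. The fuzzy system therefore carries an input gain
  pair; the bare system defaults to (1, 1) and the SFPIMRAC configuration sets
  `e_gain = 1.3e-3`, `de_gain = 3.0e-3`, chosen by loop shaping (small-signal
  surface slope 0.0146 per unit input puts the adaptation crossover at
  ~0.15 rad/s with a phase-lead zero at ~0.43 rad/s, ≈45° phase margin). These
  values were fixed from the frequency-domain analysis and then verified in
  simulation.

The 25-rule table is shipped verbatim, including its deliberate asymmetry (the
PM/PB rows are not mirror images of the NM/NB rows).

## Simulation engine and metrics

Single global fixed step (default 1 ms), explicit loop, exact ZOH
discretization per block. Each airway biquad is discretized separately: the
composite order-11 polynomial spans ~21 decades of coefficient magnitude and
is unusable as one state-space realization, while each factor is well scaled
(the fastest mode, the stiffened alveolar resonance at 1e5 rad/s, decays
within a step at 1 ms, and halving the step changes the final-5-s closed-loop
mean by <0.1%). Delays round to the nearest sample. Optional Gaussian
measurement noise is the only randomness and requires a seed.

Metrics: overshoot relative to the final commanded level (clipped at 0),
settling time as the first instant after which |y - r| stays within 2% of r
to the end of the horizon (NaN when the horizon ends outside the band),
10–90% rise time, steady-state error as |r - mean(y)| over the final 5 s, and
IAE. Scenario horizons (60 s for tracking and robustness runs, 100 s for the
load event with the 95→80→95 s drop at t=40–60 s, 40 s open loop) were chosen
to contain settling of every shipped loop.

The stability-margin routine reports an infinite margin with a NaN crossover
frequency when a crossover does not exist, following the usual control-toolbox
convention; the composite patient model's open-loop gain is below unity at all
frequencies (DC gain 62/67), so its phase margin is infinite and its gain
margin is finite and positive (≈45 dB at the -180° crossing near 47 rad/s).

## What the scenarios do and do not show

The shipped scenarios exercise the model under the published study conditions:
set-points 90/95% SpO2, cylinder time constants 0.25–1.0 s, input and
gas-transport delays 0.30/0.50/0.70 s, three gas-exchange parameter variants,
and a 20 s set-point/load drop. The plant is linear and time-invariant with a
fixed reference model; passing tests demonstrate the controller's behaviour on
this idealized plant, not on a real patient — no SpO2 sensor dynamics or
quantization, no saturation nonlinearity of hemoglobin binding, no
ventilation–perfusion heterogeneity, no inter-patient parameter spread beyond
the three printed variants. The "load variation" is implemented as the
described set-point drop; an additive output disturbance is available via the
scenario `disturbance` field.

## Known limitations

* The gas-exchange ODE path and the canonical rational block are not two views
  of one model (see above); only the rational block is used in closed loop.
* The MRAC sweep grid and the PID tuning are this package's documented
  choices; the source prints neither.
* Margins with dead time are computed on a log frequency grid (1e-4–1e8 rad/s,
  20k points) with root refinement; systems whose first crossover lies outside
  that window would need the window widened.
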