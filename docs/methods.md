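# Methods

## The equation class and the cost model

Every system handled here is of the linear form

    du_i/dt = a_i(t) · u_i + b_i(t),        a_i = −1 + (coupling sums),

with `a` and `b` functions of all units' activations.  The package's cost
model counts coefficient evaluations: in connectionist networks `a` and `b`
are weighted sums over the full state, so one evaluation is O(N²) while a
stepper's own arithmetic is O(N).  All three fixed-step methods use exactly
one evaluation per step; the driver asserts this by construction
(`n_coefficient_evaluations == n_steps`).

Updates are synchronous (Jacobi): the coefficients for *all* units are
computed from the state snapshot at the step start, then all units advance
together.  A sequential (Gauss–Seidel) update would change the method being
measured.

## The steppers

- **Euler**: `u + (a∘u + b)·dt`.  First order; conditionally stable
  (`|1 + a·dt| ≤ 1` per unit).
- **Modified RK4**: the classical `k1…k4` recurrence with `a, b` frozen at
  the step start; only the state argument moves in the inner stages.  On
  genuinely constant coefficients one step reproduces the degree-4 Taylor
  polynomial of the exact propagator applied to `(u + b/a)`; on varying
  coefficients the freezing limits it to first order globally.
- **Semi-analytical (SAM)**: exact solution of the frozen equation,
  evaluated as `u·G + b·dt·φ1(a·dt)`, `G = e^{a·dt}`,
  `φ1(z) = (e^z − 1)/z`.  Exact for constant coefficients at any `dt`
  (the composition property `n` steps of `dt` = one step of `n·dt` holds to
  rounding); on varying coefficients the error is purely the
  coefficient-freezing error, and the decaying modes are propagated
  unconditionally stably.

Numerical choices: all arithmetic is double precision.  `φ1` switches to the
truncated series `1 + z/2 + z²/6` for `|z| < 10⁻⁸` so `a = 0` is handled
exactly (`u + b·dt`) with no division by zero; elsewhere `expm1` keeps the
quotient accurate.  The final step of a run is shortened to land on `t_end`
exactly, because errors are measured at a fixed stop time.  A non-finite
activation aborts the run naming the step and unit (benchmark sweeps catch
this and record the cell as diverged instead of aborting the sweep).

## Step doubling and the adaptive driver

The local error at state `u` is estimated by comparing one full step of
`dt` with two half steps (the half-step path re-evaluates the coefficients
at the midpoint); the estimate is `max_i |u₂ − u₁|`.  Because the evaluator
is pure and the full step and first half step start from the identical
`(t, u)`, the step-start evaluation is shared — two fresh evaluations per
estimate.

The adaptive driver accepts the two-half-step state when the estimate is at
or below the user's target and rescales
`dt ← dt · clip((target/estimate)^{1/2}, 0.2, 5)` after every attempt.  The
exponent 1/2 matches a first-order method's doubled-step estimate; the
safety clip and the growth cap are standard controller practice, not part
of the measured methods.  The first attempt spans the whole interval, so an
exact method (SAM on constant coefficients) finishes in one accepted step.
A step underflow below `10⁻¹⁵·(t_end − t0)` aborts as a stiffness signal.

## The Interacting-Neighbors network

### Provenance of the couplings

The IN model's layer counts (8+8+36+9+10+36 = 107), its six fit parameters
(`B=20, M=10, S=2, tao=19.5, alpha=0.75, C=0.5`), the stimulus protocol
(operand nodes at `B`, stimuli absent after `t=0`), the stop time
(`t = 0.1`), and the worked answer (7×8 → 56) are fixed by the model's
published description.  The exact coupling equations are **reconstructed**
here within the interactive-activation family the model descends from; the
reconstruction is constrained to reproduce the published behaviour
(correct retrieval of the worked problem at the printed parameters within
the stated stop time) but is not a transcription of the original code.
Conclusions about the *integrators* transfer to any system of this class;
conclusions about fine details of the retrieval dynamics should not be read
off this network.

### Equations

Operand nodes only decay (`a = −1, b = 0`); the stimulus lives in the
initial condition.  Every other unit follows the interactive-activation law

    du/dt = −u + [net]⁺ · (M − u)      ⇔      a = −1 − [net]⁺,  b = M·[net]⁺,

with `[x]⁺ = max(x, 0)`: excitation drives the unit toward the ceiling `M`
at a rate set by its rectified net input.  Net inputs:

- **semantic {i,j}** (conjunctive gating):
  `net = tao · ([o1_i]⁺[o2_j]⁺ + [o1_j]⁺[o2_i]⁺)` (single product for
  ties).  Only the presented problem's node receives input; with `B = 20`
  its initial net is `tao·B² ≈ 7.8·10³`, so it saturates within
  `t ≈ 10⁻³` — this is the stiff layer, and `tao` is the time-scale gain
  that sets how fast the network commits.
- **response p** (candidate answer `i·j`):
  `net = S · Σ_q alpha^{dist(p,q)} [s_q]⁺ + alpha·([tens_d]⁺ + [units_e]⁺)
  − C · Σ_{q≠p} [r_q]⁺`, where `dist` is the operand-grid L1 distance
  between problems.  `S` is the semantic→response association strength,
  `alpha` both the neighbourhood gradient (table neighbours get
  `alpha^1, alpha^2, …` of the association) and the digit-cooperation
  weight, `C` the lateral competition.
- **digit nodes**: weight-1 collection of every response carrying that
  digit, closing the cooperation loop between answers that share a tens or
  units digit.

All signals entering coupling sums are half-rectified.  The layout order is
fixed (operand1 2–9, operand2 2–9, semantic pairs lexicographic by
(min,max), tens 0–8, units 0–9, responses in semantic order) so
trajectories and CSV exports are bitwise reproducible.

### Readout and options

The answer is the value of the maximally activated response node at the
fixed stop time, ties broken toward the smaller value.  A
threshold-crossing readout over a sampled trajectory is available but off
by default, as is additive Gaussian drive noise with an explicit seed (the
benchmark must be deterministic).

## The benchmark

Accuracy of a run is `error = Σ|u_n − u_r| / 36` over the 36 response
fields at the stop time, against a cached fine-step reference (default
method `sam`).  Problem sizes are chosen to run on one CPU in minutes:
the default *desk scale* uses reference `dt = 10⁻⁷` and step grid
`{1, 0.5, 0.25}×10⁻ʲ, j = 4…6` (nine cells per method); the original-scale
sweep (`dt_ref = 10⁻⁹`, `j = 4…7`) is available behind `--paper-scale` and
takes hours.  Near the smallest swept steps the measured error approaches
the reference's own error floor, so convergence assertions use the
asymptotic tail rather than strict global monotonicity.  Wall time is
recorded around the stepping loop only (monotonic clock) and is never
asserted — it is hardware- and implementation-dependent.

Empirical orders are least-squares log–log slopes of error against `dt`
over finite-error records.

## What the tests do and do not show

The fixture systems (constant-coefficient problems with closed forms, the
time-varying scalar `a = −1 + sin t, b = cos t` with a scipy cross-check)
validate the steppers against independent oracles.  The IN runs validate
the full pipeline on a realistic coupled system.  On this network all
three methods converge at first order to a common solution, and the
worked answer is method-independent.

One published qualitative claim is *not* reproduced by this
reconstruction: the semi-analytical method's response-field error is not
below Euler's at matched `dt` (it is ≈25% larger across the desk-scale
grid).  The mechanism is structural: for shunting units
(`a = −1 − net`, `b = M·net`) the coefficient-freezing error
`(dt²/2)(ȧu + ḃ) = (dt²/2)·ṅet·(M − u)` and Euler's additional
propagation term `(dt²/2)·a·u̇` carry opposite signs while a unit tracks
its moving equilibrium, so Euler's local error partially cancels the
freezing error that SAM and RK4m carry in full.  Reproducing the published
ordering evidently depends on coupling details outside what this
reconstruction can recover; a controlled stiffness experiment (conjunction
gain ×3) does reproduce the published coarse-end phenomenon — Euler
diverging at `dt = 10⁻⁴` while SAM remains accurate — without changing the
mid-grid ordering, and was therefore not adopted.  The corresponding
acceptance test is left failing rather than weakened.

## Known limitations

- Only the linear-form class is supported — no general right-hand sides,
  no implicit solvers; stiff systems beyond Euler's stability limit are
  reported as diverged cells, not solved.
- The adaptive driver is an extension for target-error use, not part of
  the benchmarked method set; its controller constants are conventional.
- The IN couplings are a documented reconstruction (above); psychometric
  fits (response-time and error distributions over all 64 problems) are
  out of scope.
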