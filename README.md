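# linform

Fixed-step integrators for the coupled rate equations of connectionist and
dynamic-field models, with the Interacting-Neighbors (IN) network of
single-digit multiplication retrieval as a built-in, fully coupled test
system, and a work-precision benchmark comparing the methods.

## The problem

Connectionist and dynamic-field models describe the activation `u_i(t)` of
each unit by a first-order rate equation in *linear form*,

    du_i/dt = a_i(t) · u_i + b_i(t),

where the coefficient vectors `a` (which carries a spontaneous decay,
`a = −1 + …`) and `b` are weighted sums over the other units' activations.
Evaluating those coupling sums dominates the cost of a simulation step, so a
useful method must get by on **one coefficient evaluation per step**.  Three
steppers satisfy that constraint:

- **Euler (`euler`)** — `u ← u + (a·u + b)·dt`;
- **modified RK4 (`rk4m`)** — the classical fourth-order Runge–Kutta
  recurrence with `a, b` frozen at the step start (only the state is updated
  in the inner stages `k2, k3, k4`);
- **semi-analytical (`sam`)** — exact propagation of the frozen linear
  equation, `u ← (u + b/a)·e^{a·dt} − b/a`, evaluated in the stable form
  `u·G + b·dt·φ1(a·dt)` with gain `G = e^{a·dt}` and `φ1(z) = (e^z − 1)/z`,
  so `a = 0` needs no special casing.

On top of the fixed-step drivers the package provides step-doubling local
error estimation and a target-error adaptive driver.

The IN model is a nonlinear connectionist network of multiplication fact
retrieval: 107 units across two operand fields (digits 2–9), 36 semantic
problem nodes, tens and units digit fields, and 36 candidate-answer nodes
that cooperate through shared digits and compete laterally.  Its published
fit parameters are `B=20, M=10, S=2, tao=19.5, alpha=0.75, C=0.5`;
presenting 7×8 and integrating to `t = 0.1` retrieves the answer 56.

## Worked example

```sh
$ linform simulate --system in --problem 7x8 --method sam --dt 1e-5 --t-end 0.1
answer: 56
INFO linform: method=sam dt=1e-05 steps=10000 evaluations=10000 wall=0.454s
```

The network was integrated for 10000 steps with exactly one coefficient
evaluation each, and the maximally activated response node at `t = 0.1`
carries the answer value 56 — the correct product.  The same run in Python:

```python
from linform import (build_network, initial_state, integrate,
                     readout_answer, ProblemInput, IntegratorSpec)

net = build_network()                                  # published parameters
u0 = initial_state(net, ProblemInput(7, 8))            # operand nodes at B=20
res = integrate(net, u0, 0.1, IntegratorSpec("sam", 1e-5))
print(readout_answer(res, net))                        # -> 56
```

A single-row work-precision sweep (step sizes `1, 0.5, 0.25 × 10⁻⁴` against
a `dt = 10⁻⁶` reference):

```sh
$ linform benchmark --j-min 4 --j-max 4 --dt-ref 1e-6 --out wp.csv
euler: empirical order 1.027
rk4m: empirical order 1.034
sam: empirical order 1.033
```

with `wp.csv` recording per (method, dt) the mean absolute response-field
error against the reference, the step/evaluation counters and the wall time:

```
method,dt,error,n_steps
euler,0.0001,0.0013461609728369498,1000
euler,5e-05,0.0006637024676158282,2000
...
```

All three methods converge at first order on the fully coupled network —
freezing the coefficients over a step limits every one-evaluation scheme to
order one globally; they differ only in the error constant (and, for stiff
couplings, in stability: the exponential step is unconditionally stable on
the decaying modes it freezes).  The full grid of the study is
`--j-min 4 --j-max 6` with reference `dt = 10⁻⁷` (desk scale, minutes), or
`--paper-scale` for `j = 4…7` against `dt = 10⁻⁹` (hours).

## Layout

- `linform.integrators` — steppers, fixed-step driver, step doubling,
  adaptive driver, and the `CoefficientEvaluator` system contract.
- `linform.in_model` — the 107-unit IN network, problem encoding, answer
  readout, layout export.
- `linform.benchmark` — response-field error metric, cached reference
  solutions, dt grids, work-precision sweeps, order estimation, plotting.
- `linform.systems` — small fixture systems (`fixture:decay`,
  `fixture:driven`, `fixture:scalar_tv`) with known solutions.
- `linform.cli` — the `linform simulate` / `linform benchmark` commands
  (YAML config supported; flags override the config).

See `docs/methods.md` for the model equations, parameter roles, numerical
choices and known limitations.
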