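"""Fixed-step integrators for coupled rate equations in linear form.

Connectionist and dynamic-field models describe each unit's activation by a
first-order rate equation

    du_i/dt = a_i(t) * u_i + b_i(t),

where the coefficient vectors ``a`` and ``b`` are weighted sums over the
activations of all other units (and ``a`` carries a spontaneous decay term,
``a = -1 + ...``).  Evaluating those weighted sums is the dominant cost of a
simulation step, so all three steppers here consume exactly one coefficient
evaluation per step:

``euler_step``
    the plain forward-Euler update ``u + (a*u + b)*dt``;
``modified_rk4_step``
    the classical fourth-order Runge-Kutta recurrence with ``a`` and ``b``
    frozen at the step start — only the state is updated inside the
    sub-stages, so no re-evaluation of the coupling sums is needed;
``sam_step``
    the semi-analytical step: exact propagation of the frozen linear
    equation, ``u <- (u + b/a)*exp(a*dt) - b/a``, evaluated in the
    phi1 form that is regular at ``a = 0``.

:func:`integrate` drives any of them with a synchronous (Jacobi) update: one
coefficient evaluation per step from the current state snapshot, then all
units advance together.  :func:`step_doubling_error` and
:func:`adaptive_integrate` add standard step-doubling local-error estimation
and target-error step-size control on top of the same steppers.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from typing import Callable, Protocol, runtime_checkable

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "StateVector",
    "CoefficientPair",
    "CoefficientEvaluator",
    "IntegratorSpec",
    "SimulationResult",
    "IntegrationDivergedError",
    "METHODS",
    "euler_step",
    "modified_rk4_step",
    "sam_step",
    "gain",
    "phi1",
    "integrate",
    "step_doubling_error",
    "adaptive_integrate",
]

#: The three supported fixed-step methods.
METHODS = ("euler", "rk4m", "sam")

#: below this |a*dt| the phi1 kernel switches to its Taylor series
_PHI1_SERIES_THRESHOLD = 1e-8


class IntegrationDivergedError(RuntimeError):
    """A state entry became non-finite during integration.

    Attributes
    ----------
    step : int
        Index of the step at which the divergence was detected.
    t : float
        Simulated time at detection.
    unit : int
        Index of the first offending unit.
    """

    def __init__(self, step: int, t: float, unit: int):
        self.step = step
        self.t = t
        self.unit = unit
        super().__init__(
            f"non-finite activation in unit {unit} at step {step} (t={t:g}); "
            "the step size is likely too large for this system"
        )


@dataclass
class StateVector:
    """Activations of all units at one instant of simulated time."""

    values: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("state must be a 1-D vector of unit activations")
        if not np.all(np.isfinite(self.values)):
            bad = int(np.flatnonzero(~np.isfinite(self.values))[0])
            raise ValueError(f"non-finite activation in unit {bad}")

    @property
    def n_units(self) -> int:
        return self.values.size

    def copy(self) -> "StateVector":
        return StateVector(self.values.copy(), self.t)


@dataclass(frozen=True)
class CoefficientPair:
    """Per-unit coefficient vectors (a, b) of the linear-form equation."""

    a: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "a", np.asarray(self.a, dtype=float))
        object.__setattr__(self, "b", np.asarray(self.b, dtype=float))
        if self.a.shape != self.b.shape:
            raise ValueError("a and b must have the same length")


@runtime_checkable
class CoefficientEvaluator(Protocol):
    """The system contract: maps (t, state values) to coefficient vectors.

    Implementations must be pure in their arguments — the same ``(t, u)``
    always yields the same ``(a, b)`` — because the drivers rely on one
    evaluation per step and the step-doubling estimator shares the
    step-start evaluation between the full-step and half-step paths.
    """

    n_units: int

    def evaluate(self, t: float, u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return the coefficient vectors ``(a, b)`` for state ``u`` at time ``t``."""
        ...


@dataclass(frozen=True)
class IntegratorSpec:
    """A fixed-step method selection: which stepper, and its step size."""

    method: str
    dt: float

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; expected one of {METHODS}")
        if not self.dt > 0:
            raise ValueError("dt must be positive")


@dataclass
class SimulationResult:
    """Outcome of one integration run.

    ``n_coefficient_evaluations == n_steps`` for every fixed-step run — the
    defining economy of all three methods.  ``wall_time_s`` is informational
    only (measured around the stepping loop, monotonic clock).
    """

    final_state: StateVector
    n_steps: int
    n_coefficient_evaluations: int
    wall_time_s: float
    trajectory: list[tuple[float, np.ndarray]] | None = None


def _check_lengths(u: np.ndarray, a: np.ndarray, b: np.ndarray) -> None:
    if not (u.shape == a.shape == b.shape):
        raise ValueError(
            f"length mismatch: u has {u.shape}, a has {a.shape}, b has {b.shape}"
        )


def euler_step(u: np.ndarray, a: np.ndarray, b: np.ndarray, dt: float) -> np.ndarray:
    """One forward-Euler step: ``u + (a*u + b)*dt`` elementwise."""
    u = np.asarray(u, dtype=float)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    _check_lengths(u, a, b)
    return u + (a * u + b) * dt


def modified_rk4_step(u: np.ndarray, a: np.ndarray, b: np.ndarray, dt: float) -> np.ndarray:
    """One coefficient-frozen fourth-order Runge-Kutta step.

    The classical RK4 recurrence is applied with ``a`` and ``b`` held at their
    step-start values; only the state argument is updated for the inner
    stages:

        k1 = a*u + b
        k2 = a*(u + k1*dt/2) + b
        k3 = a*(u + k2*dt/2) + b
        k4 = a*(u + k3*dt)   + b
        u  <- u + dt*(k1 + 2*k2 + 2*k3 + k4)/6

    On genuinely constant coefficients this reproduces the degree-4 Taylor
    polynomial of the exact exponential propagator.
    """
    u = np.asarray(u, dtype=float)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    _check_lengths(u, a, b)
    k1 = a * u + b
    k2 = a * (u + k1 * (dt / 2)) + b
    k3 = a * (u + k2 * (dt / 2)) + b
    k4 = a * (u + k3 * dt) + b
    return u + (dt / 6) * (k1 + 2 * k2 + 2 * k3 + k4)


def phi1(z: np.ndarray) -> np.ndarray:
    """The exponential-integrator kernel ``(exp(z) - 1)/z``, regular at 0.

    For ``|z|`` below 1e-8 the truncated series ``1 + z/2 + z**2/6`` is used,
    so ``z = 0`` is handled exactly (phi1(0) = 1); elsewhere ``expm1``
    keeps the quotient fully accurate.
    """
    z = np.asarray(z, dtype=float)
    small = np.abs(z) < _PHI1_SERIES_THRESHOLD
    # avoid 0/0 in the masked-out branch
    safe = np.where(small, 1.0, z)
    return np.where(small, 1.0 + z / 2 + z * z / 6, np.expm1(safe) / safe)


def gain(a: np.ndarray, dt: float) -> np.ndarray:
    """The per-unit signal gain ``G = exp(a*dt)`` of the semi-analytical step."""
    if not dt > 0:
        raise ValueError("dt must be positive")
    a = np.asarray(a, dtype=float)
    with np.errstate(over="ignore"):
        g = np.exp(a * dt)
    if not np.all(np.isfinite(g)):
        bad = int(np.flatnonzero(~np.isfinite(g))[0])
        raise OverflowError(f"gain overflow in unit {bad}: a*dt = {a[bad] * dt:g}")
    return g


def sam_step(u: np.ndarray, a: np.ndarray, b: np.ndarray, dt: float) -> np.ndarray:
    """One semi-analytical step: exact propagation of the frozen equation.

    Per unit this is the closed-form solution of ``du/dt = a*u + b`` with
    constant coefficients,

        u(t+dt) = (u + b/a) * exp(a*dt) - b/a,

    computed in the numerically stable form ``u*G + b*dt*phi1(a*dt)`` with
    ``G = exp(a*dt)``, so ``a = 0`` reduces smoothly to ``u + b*dt`` with no
    division by zero.
    """
    u = np.asarray(u, dtype=float)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    _check_lengths(u, a, b)
    z = a * dt
    em = np.expm1(z)
    small = np.abs(z) < _PHI1_SERIES_THRESHOLD
    safe = np.where(small, 1.0, z)
    phi = np.where(small, 1.0 + z / 2 + z * z / 6, em / safe)
    return u * (em + 1.0) + b * dt * phi


_STEPPERS: dict[str, Callable[[np.ndarray, np.ndarray, np.ndarray, float], np.ndarray]] = {
    "euler": euler_step,
    "rk4m": modified_rk4_step,
    "sam": sam_step,
}


def _n_fixed_steps(span: float, dt: float) -> int:
    # number of steps needed to cover `span` with step dt, robust to the
    # float wobble of span/dt when dt divides span exactly
    ratio = span / dt
    return max(1, int(np.ceil(ratio * (1.0 - 1e-12))))


def integrate(
    system: CoefficientEvaluator,
    u0: StateVector,
    t_end: float,
    spec: IntegratorSpec,
    sample_every: int | None = None,
) -> SimulationResult:
    """Advance ``system`` from ``u0`` to ``t_end`` with a fixed step.

    Each step evaluates the coefficients once from the current state snapshot
    (synchronous/Jacobi update), then applies the selected stepper to all
    units simultaneously.  The final step is shortened so the run lands on
    ``t_end`` exactly.  If ``sample_every`` is set, every k-th state (plus the
    initial and final states) is recorded in the trajectory.

    Raises
    ------
    IntegrationDivergedError
        If any unit's activation becomes non-finite mid-run.
    """
    span = t_end - u0.t
    if span <= 0:
        raise ValueError("t_end must lie strictly after the initial time")
    if spec.dt > span * (1 + 1e-12):
        raise ValueError("dt must not exceed the integration span")
    stepper = _STEPPERS[spec.method]
    n_steps = _n_fixed_steps(span, spec.dt)

    u = u0.values.copy()
    t0 = u0.t
    trajectory: list[tuple[float, np.ndarray]] | None = None
    if sample_every is not None:
        if sample_every < 1:
            raise ValueError("sample_every must be a positive integer")
        trajectory = [(t0, u.copy())]

    tic = time.perf_counter()
    t = t0
    debug = logger.isEnabledFor(logging.DEBUG)
    # a diverging run overflows to inf right before the abort; keep it silent
    err_ctx = np.errstate(over="ignore", invalid="ignore")
    with err_ctx:
      for k in range(n_steps):
        h = spec.dt if k < n_steps - 1 else t_end - t
        a, b = system.evaluate(t, u)
        u = stepper(u, a, b, h)
        if debug:
            logger.debug(
                "step %d t=%g h=%g |u|max=%g", k, t, h, float(np.max(np.abs(u)))
            )
        if not np.all(np.isfinite(u)):
            bad = int(np.flatnonzero(~np.isfinite(u))[0])
            raise IntegrationDivergedError(step=k, t=t, unit=bad)
        t = t0 + (k + 1) * spec.dt if k < n_steps - 1 else t_end
        if trajectory is not None and ((k + 1) % sample_every == 0 or k == n_steps - 1):
            trajectory.append((t, u.copy()))
    wall = time.perf_counter() - tic

    return SimulationResult(
        final_state=StateVector(u, t_end),
        n_steps=n_steps,
        n_coefficient_evaluations=n_steps,
        wall_time_s=wall,
        trajectory=trajectory,
    )


def step_doubling_error(
    system: CoefficientEvaluator,
    u: StateVector,
    dt: float,
    spec: IntegratorSpec,
) -> tuple[np.ndarray, float]:
    """Step-doubling local-error estimate at the current state.

    Takes one full step of size ``dt`` and, independently, two half steps of
    ``dt/2`` (the half-step path re-evaluates the coefficients at the
    midpoint), and returns the two-half-step state together with the
    max-norm difference ``max_i |u2_i - u1_i|`` as the local error estimate.

    Because the evaluator is pure and the full step and the first half step
    start from the identical ``(t, u)``, the step-start evaluation is shared
    between the two paths.
    """
    if not dt > 0:
        raise ValueError("dt must be positive")
    stepper = _STEPPERS[spec.method]
    a, b = system.evaluate(u.t, u.values)
    u1 = stepper(u.values, a, b, dt)
    uh = stepper(u.values, a, b, dt / 2)
    a2, b2 = system.evaluate(u.t + dt / 2, uh)
    u2 = stepper(uh, a2, b2, dt / 2)
    if not (np.all(np.isfinite(u1)) and np.all(np.isfinite(u2))):
        bad_arr = u2 if not np.all(np.isfinite(u2)) else u1
        bad = int(np.flatnonzero(~np.isfinite(bad_arr))[0])
        raise IntegrationDivergedError(step=0, t=u.t, unit=bad)
    err = float(np.max(np.abs(u2 - u1)))
    return u2, err


#: step-size growth/shrink clip of the adaptive controller
_ADAPT_CLIP = (0.2, 5.0)
#: controller exponent: the steppers are (at most) first order on varying
#: coefficients, so the doubled-step estimate scales as dt**2 and the
#: correction uses exponent 1/2
_ADAPT_EXPONENT = 0.5


def adaptive_integrate(
    system: CoefficientEvaluator,
    u0: StateVector,
    t_end: float,
    target_local_error: float,
    method: str = "sam",
) -> SimulationResult:
    """Integrate with step-doubling step-size control.

    The user sets a target local error instead of a fixed step.  Each attempt
    takes one full step and two half steps; the two-half-step state is
    accepted when the step-doubling estimate is at or below the target.
    After every attempt the step is rescaled by
    ``clip((target/estimate)**0.5, 0.2, 5)``.  The trajectory records the
    accepted states.

    Raises
    ------
    RuntimeError
        If the step size underflows below ``1e-15 * (t_end - t0)`` — a
        stiffness signal for this explicit family.
    """
    if not target_local_error > 0:
        raise ValueError("target_local_error must be positive")
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    span = t_end - u0.t
    if span <= 0:
        raise ValueError("t_end must lie strictly after the initial time")

    t = u0.t
    u = u0.copy()
    dt = span  # first attempt: one giant step (exact methods accept it)
    dt_floor = 1e-15 * span
    trajectory: list[tuple[float, np.ndarray]] = [(t, u.values.copy())]
    n_accepted = 0
    n_evals = 0

    tic = time.perf_counter()
    while t_end - t > 1e-15 * span:
        h = min(dt, t_end - t)
        u2, est = step_doubling_error(system, u, h, IntegratorSpec(method, h))
        n_evals += 2  # step-start evaluation shared between the two paths
        if est <= target_local_error:
            t = t + h
            u = StateVector(u2, t)
            trajectory.append((t, u2.copy()))
            n_accepted += 1
        if est == 0.0:
            factor = _ADAPT_CLIP[1]
        else:
            factor = float(np.clip((target_local_error / est) ** _ADAPT_EXPONENT, *_ADAPT_CLIP))
        dt = h * factor
        if dt < dt_floor:
            raise RuntimeError(
                f"adaptive step size underflow (dt={dt:g} < {dt_floor:g}) at t={t:g}; "
                "the problem appears too stiff for this explicit method"
            )
    wall = time.perf_counter() - tic

    return SimulationResult(
        final_state=StateVector(u.values, t_end),
        n_steps=n_accepted,
        n_coefficient_evaluations=n_evals,
        wall_time_s=wall,
        trajectory=trajectory,
    )
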