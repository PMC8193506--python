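"""Driver behaviour: fixed-step integration, step doubling, adaptive control."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from linform import (
    IntegrationDivergedError,
    IntegratorSpec,
    StateVector,
    adaptive_integrate,
    euler_step,
    integrate,
    modified_rk4_step,
    sam_step,
    step_doubling_error,
)
from linform.systems import ConstantSystem, TimeVaryingSystem, get_fixture


@pytest.fixture(scope="module")
def scalar_tv():
    """The time-varying scalar fixture: a(t) = -1 + sin t, b(t) = cos t."""
    return get_fixture("scalar_tv")


@pytest.fixture(scope="module")
def scalar_tv_reference(scalar_tv):
    """High-accuracy final value at t = 1 from scipy (independent route)."""
    sol = solve_ivp(
        lambda t, y: (-1 + np.sin(t)) * y + np.cos(t),
        (0.0, 1.0),
        [0.0],
        method="DOP853",
        rtol=1e-12,
        atol=1e-14,
    )
    return float(sol.y[0, -1])


def run(system, u0_values, t_end, method, dt, **kw):
    return integrate(system, StateVector(np.atleast_1d(np.asarray(u0_values, float))),
                     t_end, IntegratorSpec(method, dt), **kw)


def test_sam_exact_on_constant_system_at_any_dt():
    """A SAM run on frozen coefficients hits the closed form regardless of dt."""
    sys = ConstantSystem([-1.0], [0.0])
    res = run(sys, [1.0], 1.0, "sam", 0.5)
    assert res.final_state.values[0] == pytest.approx(np.exp(-1.0), rel=1e-14)
    res = run(sys, [1.0], 1.0, "sam", 1.0)
    assert res.final_state.values[0] == pytest.approx(np.exp(-1.0), rel=1e-14)


@pytest.mark.parametrize(
    "method,stepper", [("euler", euler_step), ("rk4m", modified_rk4_step), ("sam", sam_step)]
)
def test_single_step_run_equals_stepper(method, stepper, scalar_tv):
    u0 = np.array([0.4])
    dt = 0.05
    res = run(scalar_tv, u0, dt, method, dt)
    a, b = scalar_tv.evaluate(0.0, u0)
    np.testing.assert_array_equal(res.final_state.values, stepper(u0, a, b, dt))
    assert res.n_steps == 1


def test_final_partial_step_lands_on_t_end(scalar_tv):
    """dt that does not divide the span: last step is shortened, not overshot."""
    res = run(scalar_tv, [0.0], 1.0, "euler", 0.3)
    assert res.final_state.t == 1.0
    assert res.n_steps == 4  # 0.3 + 0.3 + 0.3 + 0.1


def test_exact_division_does_not_add_a_spurious_step(scalar_tv):
    res = run(scalar_tv, [0.0], 0.1, "euler", 1e-3)
    assert res.n_steps == 100


def test_cost_model_one_evaluation_per_step(scalar_tv):
    """The defining economy: every method evaluates coefficients once per step."""
    for method in ("euler", "rk4m", "sam"):
        res = run(scalar_tv, [0.0], 1.0, method, 1e-2)
        assert res.n_coefficient_evaluations == res.n_steps == 100


def test_euler_first_order_error_halves_with_dt(scalar_tv, scalar_tv_reference):
    """Halving dt halves Euler's final-state error (ratio 2.0 +- 10%)."""
    errs = []
    for dt in (1e-3, 5e-4):
        res = run(scalar_tv, [0.0], 1.0, "euler", dt)
        errs.append(abs(res.final_state.values[0] - scalar_tv_reference))
    assert errs[0] / errs[1] == pytest.approx(2.0, rel=0.10)


def test_all_methods_converge_to_scipy_reference(scalar_tv, scalar_tv_reference):
    """Errors at dt and dt/4 both small and decreasing, for all three methods."""
    for method in ("euler", "rk4m", "sam"):
        e_coarse = abs(
            run(scalar_tv, [0.0], 1.0, method, 1e-3).final_state.values[0]
            - scalar_tv_reference
        )
        e_fine = abs(
            run(scalar_tv, [0.0], 1.0, method, 2.5e-4).final_state.values[0]
            - scalar_tv_reference
        )
        assert e_fine < e_coarse < 1e-2
        assert e_fine < 1e-3


def test_trajectory_sampling_includes_endpoints(scalar_tv):
    res = run(scalar_tv, [0.2], 1.0, "sam", 0.1, sample_every=3)
    ts = [t for t, _ in res.trajectory]
    assert ts[0] == 0.0
    assert ts[-1] == 1.0
    np.testing.assert_allclose(ts[1], 0.3)


def test_divergence_aborts_with_step_index():
    """Euler far beyond its stability limit must abort, naming the unit."""
    sys = ConstantSystem([1e3], [0.0])  # explosive growth, overflows mid-run
    with pytest.raises(IntegrationDivergedError) as exc:
        run(sys, [1.0], 400.0, "euler", 1.0)
    assert exc.value.unit == 0


def test_dt_larger_than_span_rejected(scalar_tv):
    with pytest.raises(ValueError):
        run(scalar_tv, [0.0], 0.1, "euler", 0.2)


def test_unknown_method_rejected():
    with pytest.raises(ValueError, match="unknown method"):
        IntegratorSpec("rk45", 0.1)


# --- step doubling -----------------------------------------------------------


def test_step_doubling_zero_estimate_when_sam_is_exact():
    sys = ConstantSystem([-1.0, -2.0], [0.0, 3.0])
    u = StateVector(np.array([1.0, 0.5]))
    _, est = step_doubling_error(sys, u, 0.4, IntegratorSpec("sam", 0.4))
    assert est == pytest.approx(0.0, abs=1e-15)


def test_step_doubling_euler_hand_value():
    """Constant a=-1: full step 0.90, two half steps 0.95^2; estimate 0.0025."""
    sys = ConstantSystem([-1.0], [0.0])
    u = StateVector(np.array([1.0]))
    u2, est = step_doubling_error(sys, u, 0.1, IntegratorSpec("euler", 0.1))
    assert u2[0] == pytest.approx(0.9025, rel=1e-14)
    assert est == pytest.approx(0.0025, rel=1e-12)


def test_step_doubling_estimate_nonnegative(scalar_tv):
    for dt in (0.01, 0.1, 0.5):
        for method in ("euler", "rk4m", "sam"):
            _, est = step_doubling_error(
                scalar_tv, StateVector(np.array([0.3])), dt, IntegratorSpec(method, dt)
            )
            assert est >= 0.0


# --- adaptive integration ----------------------------------------------------


def test_adaptive_takes_one_giant_step_on_constant_coefficients():
    """SAM is exact on frozen coefficients, so the first full-span attempt
    has estimate 0 and is accepted outright."""
    sys = ConstantSystem([-1.0], [0.5])
    res = adaptive_integrate(sys, StateVector(np.array([2.0])), 5.0, 1e-8, method="sam")
    assert res.n_steps == 1
    expected = (2.0 + 0.5 / -1.0) * np.exp(-5.0) + 0.5
    assert res.final_state.values[0] == pytest.approx(expected, rel=1e-12)


def test_adaptive_accepted_estimates_respect_target(scalar_tv):
    """Replaying step doubling over the accepted trajectory reproduces the
    acceptance rule: every accepted step's estimate is at or below target."""
    target = 1e-7
    res = adaptive_integrate(scalar_tv, StateVector(np.array([0.0])), 1.0, target, "euler")
    traj = res.trajectory
    assert len(traj) >= 2
    for (t0, v0), (t1, _) in zip(traj[:-1], traj[1:]):
        _, est = step_doubling_error(
            scalar_tv, StateVector(v0.copy(), t0), t1 - t0, IntegratorSpec("euler", t1 - t0)
        )
        assert est <= target * (1 + 1e-12)


def test_adaptive_tighter_target_never_less_accurate(scalar_tv, scalar_tv_reference):
    errs = []
    for target in (1e-5, 1e-7):
        res = adaptive_integrate(scalar_tv, StateVector(np.array([0.0])), 1.0, target,
                                 method="euler")
        errs.append(abs(res.final_state.values[0] - scalar_tv_reference))
    assert errs[1] <= errs[0]


def test_adaptive_lands_on_t_end(scalar_tv):
    res = adaptive_integrate(scalar_tv, StateVector(np.array([0.1])), 1.0, 1e-6, "sam")
    assert res.final_state.t == 1.0
    assert res.trajectory[-1][0] == pytest.approx(1.0, rel=1e-12)
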