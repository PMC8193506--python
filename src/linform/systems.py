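"""Reference systems for testing and benchmarking the steppers.

These are small coefficient evaluators in the linear form
``du/dt = a(t)*u + b(t)``: constant-coefficient problems with known closed
forms, and a smooth time-varying scalar problem used for convergence-order
measurements.  Each is registered under a name so the CLI can address them
as ``fixture:<name>``.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

__all__ = ["ConstantSystem", "TimeVaryingSystem", "get_fixture", "FIXTURES"]


class ConstantSystem:
    """Constant-coefficient system: a and b fixed vectors.

    The semi-analytical step is exact on this system for any step size, which
    makes it the canonical correctness fixture.
    """

    def __init__(self, a, b):
        self.a = np.atleast_1d(np.asarray(a, dtype=float))
        self.b = np.atleast_1d(np.asarray(b, dtype=float))
        if self.a.shape != self.b.shape:
            raise ValueError("a and b must have the same length")
        self.n_units = self.a.size

    def evaluate(self, t: float, u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return self.a, self.b

    def exact(self, u0: np.ndarray, t: float) -> np.ndarray:
        """Closed-form solution at time t from state u0 at time 0."""
        u0 = np.asarray(u0, dtype=float)
        out = np.empty_like(u0)
        nz = self.a != 0
        out[nz] = (u0[nz] + self.b[nz] / self.a[nz]) * np.exp(self.a[nz] * t) - (
            self.b[nz] / self.a[nz]
        )
        out[~nz] = u0[~nz] + self.b[~nz] * t
        return out


class TimeVaryingSystem:
    """State-independent but time-varying coefficients a(t), b(t).

    Scalar by default; used for empirical-order measurements where the
    coefficient variation is what the frozen-coefficient methods get wrong.
    """

    def __init__(
        self,
        a_fn: Callable[[float], float],
        b_fn: Callable[[float], float],
        n_units: int = 1,
    ):
        self.a_fn = a_fn
        self.b_fn = b_fn
        self.n_units = n_units

    def evaluate(self, t: float, u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        a = np.full(self.n_units, self.a_fn(t), dtype=float)
        b = np.full(self.n_units, self.b_fn(t), dtype=float)
        return a, b


def _scalar_decay() -> ConstantSystem:
    return ConstantSystem([-1.0], [0.0])


def _scalar_driven() -> ConstantSystem:
    return ConstantSystem([-2.0], [4.0])


def _scalar_tv() -> TimeVaryingSystem:
    # a(t) = -1 + sin t keeps the decay convention; b(t) = cos t drives it
    return TimeVaryingSystem(lambda t: -1.0 + np.sin(t), lambda t: np.cos(t))


FIXTURES: dict[str, Callable[[], object]] = {
    "decay": _scalar_decay,
    "driven": _scalar_driven,
    "scalar_tv": _scalar_tv,
}


def get_fixture(name: str):
    """Instantiate a named fixture system."""
    try:
        return FIXTURES[name]()
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURES)}"
        ) from None
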