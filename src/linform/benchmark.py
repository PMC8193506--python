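"""Work-precision benchmarking of the three steppers on the IN network.

The accuracy of a run is summarised by the mean absolute deviation of the 36
response-field activations from a fine-step reference solution at the stop
time:

    error = sum_i |u_n,i - u_r,i| / 36     (i over the response block)

The sweep integrates the network once per (method, dt) over a geometric step
grid, measures this error against a cached reference, and records the cost
counters, yielding the method-comparison table (error vs number of
coefficient evaluations / wall time).

Two scales are built in: the desk scale (reference dt 1e-7, step exponents
4..6), which runs in minutes on one CPU and preserves the qualitative
method ordering, and the full scale (reference dt 1e-9, exponents 4..7),
which is hours on commodity hardware.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .in_model import (
    INNetwork,
    INParameters,
    ProblemInput,
    build_network,
    initial_state,
    response_indices,
)
from .integrators import (
    METHODS,
    IntegrationDivergedError,
    IntegratorSpec,
    SimulationResult,
    StateVector,
    integrate,
)

__all__ = [
    "BenchmarkConfig",
    "WorkPrecisionRecord",
    "response_error",
    "reference_solution",
    "clear_reference_cache",
    "dt_grid",
    "work_precision_sweep",
    "convergence_order",
    "records_to_dataframe",
    "save_records",
    "plot_work_precision",
]

logger = logging.getLogger(__name__)

CSV_HEADER = "method,dt,error,n_steps,n_evaluations,wall_time_s,status"


@dataclass(frozen=True)
class BenchmarkConfig:
    """Sweep configuration; defaults are the desk-scale study conditions."""

    j_min: int = 4
    j_max: int = 6
    dt_multipliers: tuple[float, ...] = (1.0, 0.5, 0.25)
    dt_ref: float = 1e-7
    t_end: float = 0.1
    methods: tuple[str, ...] = ("euler", "rk4m", "sam")
    problem: ProblemInput = field(default_factory=lambda: ProblemInput(7, 8))
    reference_method: str = "sam"
    params: INParameters = field(default_factory=INParameters)

    def __post_init__(self) -> None:
        if self.j_min > self.j_max:
            raise ValueError("j_min must not exceed j_max")
        for m in self.methods:
            if m not in METHODS:
                raise ValueError(f"unknown method {m!r}")
        grid = dt_grid(self.j_min, self.j_max, self.dt_multipliers)
        if not self.dt_ref < min(grid):
            raise ValueError("dt_ref must be smaller than the smallest swept dt")

    @classmethod
    def paper_scale(cls, **kwargs) -> "BenchmarkConfig":
        """The full-scale sweep: dt_ref = 1e-9, exponents 4..7."""
        kwargs.setdefault("j_min", 4)
        kwargs.setdefault("j_max", 7)
        kwargs.setdefault("dt_ref", 1e-9)
        return cls(**kwargs)


@dataclass(frozen=True)
class WorkPrecisionRecord:
    """One benchmark point: a method at one step size."""

    method: str
    dt: float
    error: float
    n_steps: int
    n_evaluations: int
    wall_time_s: float
    status: str = "ok"


def response_error(
    u_n: StateVector, u_r: StateVector, response_idx: Sequence[int]
) -> float:
    """Mean absolute response-field deviation between two states.

    Sum of |u_n - u_r| over the response indices, divided by the number of
    response fields (36 for the IN network).  A scaled L1 metric on the
    response block: symmetric, triangle inequality, zero iff the blocks are
    equal.
    """
    if u_n.values.shape != u_r.values.shape:
        raise ValueError("states have different lengths")
    idx = np.asarray(response_idx, dtype=int)
    if idx.size == 0:
        raise ValueError("response index list is empty")
    return float(np.sum(np.abs(u_n.values[idx] - u_r.values[idx])) / idx.size)


def dt_grid(
    j_min: int, j_max: int, multipliers: Sequence[float] = (1.0, 0.5, 0.25)
) -> list[float]:
    """The swept step sizes: m * 10**-j for each exponent and multiplier, descending."""
    if j_min > j_max:
        raise ValueError("j_min must not exceed j_max")
    if len(multipliers) == 0:
        raise ValueError("multipliers must be nonempty")
    values = sorted(
        {m * 10.0**-j for j in range(j_min, j_max + 1) for m in multipliers},
        reverse=True,
    )
    return values


_reference_cache: dict[tuple, StateVector] = {}


def clear_reference_cache() -> None:
    _reference_cache.clear()


def reference_solution(
    network: INNetwork,
    problem: ProblemInput,
    dt_ref: float,
    t_end: float,
    method: str = "sam",
) -> StateVector:
    """Fine-step reference state at t_end, cached per configuration.

    The cache key includes the network parameters, so sweeping several dt
    values (or methods) against the same reference computes it once.
    """
    p = network.params
    key = (
        (p.B, p.M, p.S, p.tao, p.alpha, p.C),
        (problem.operand1, problem.operand2),
        float(dt_ref),
        float(t_end),
        method,
    )
    if key not in _reference_cache:
        logger.info(
            "computing reference: method=%s dt_ref=%g t_end=%g", method, dt_ref, t_end
        )
        res = integrate(
            network, initial_state(network, problem), t_end, IntegratorSpec(method, dt_ref)
        )
        _reference_cache[key] = res.final_state
    ref = _reference_cache[key]
    return StateVector(ref.values.copy(), ref.t)


def work_precision_sweep(
    config: BenchmarkConfig, network: INNetwork | None = None
) -> list[WorkPrecisionRecord]:
    """Run every (method, dt) cell of the sweep and measure the response error.

    Divergent cells (non-finite state mid-run) are recorded with
    ``error = inf`` and ``status = "diverged"`` rather than aborting the
    sweep.
    """
    network = network or build_network(config.params)
    ref = reference_solution(
        network, config.problem, config.dt_ref, config.t_end, config.reference_method
    )
    idx = response_indices(network)
    u0 = initial_state(network, config.problem)
    grid = dt_grid(config.j_min, config.j_max, config.dt_multipliers)

    records: list[WorkPrecisionRecord] = []
    for method in config.methods:
        for dt in grid:
            try:
                res = integrate(network, u0, config.t_end, IntegratorSpec(method, dt))
                err = response_error(res.final_state, ref, idx)
                rec = WorkPrecisionRecord(
                    method, dt, err, res.n_steps, res.n_coefficient_evaluations,
                    res.wall_time_s,
                )
            except IntegrationDivergedError as exc:
                logger.warning("diverged: method=%s dt=%g (%s)", method, dt, exc)
                rec = WorkPrecisionRecord(
                    method, dt, float("inf"), exc.step + 1, exc.step + 1, 0.0,
                    status="diverged",
                )
            logger.info(
                "method=%-5s dt=%-8g error=%-12.4g steps=%-8d wall=%.3fs",
                rec.method, rec.dt, rec.error, rec.n_steps, rec.wall_time_s,
            )
            records.append(rec)
    return records


def convergence_order(records: Sequence[WorkPrecisionRecord]) -> dict[str, float]:
    """Empirical order per method: least-squares log-log slope of error vs dt.

    Only finite, positive errors enter the fit; at least three such points
    per method are required.
    """
    out: dict[str, float] = {}
    for method in sorted({r.method for r in records}):
        pts = [
            (r.dt, r.error)
            for r in records
            if r.method == method and np.isfinite(r.error) and r.error > 0
        ]
        if len(pts) < 3:
            raise ValueError(
                f"need at least 3 finite-error records for {method}, got {len(pts)}"
            )
        dts, errs = map(np.asarray, zip(*pts))
        slope = np.polyfit(np.log(dts), np.log(errs), 1)[0]
        out[method] = float(slope)
    return out


def records_to_dataframe(records: Sequence[WorkPrecisionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.method, r.dt, r.error, r.n_steps, r.n_evaluations, r.wall_time_s, r.status)
            for r in records
        ],
        columns=CSV_HEADER.split(","),
    )


def save_records(records: Sequence[WorkPrecisionRecord], path) -> None:
    """Write the sweep table as CSV (header: method,dt,error,...,status)."""
    records_to_dataframe(records).to_csv(path, index=False)


def plot_work_precision(records: Sequence[WorkPrecisionRecord], path) -> None:
    """Log-log wall-time vs error scatter per method (informational)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4.5))
    df = records_to_dataframe(records)
    for method, grp in df[df.status == "ok"].groupby("method"):
        ax.loglog(grp.error, grp.wall_time_s, "o-", label=method)
    ax.set_xlabel("response-field error")
    ax.set_ylabel("wall time (s)")
    ax.legend()
    ax.grid(True, which="both", alpha=0.3)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
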