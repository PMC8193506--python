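"""The Interacting-Neighbors (IN) network of single-digit multiplication retrieval.

The IN model is a nonlinear connectionist model of how adults retrieve
single-digit products (e.g. 7 x 8).  Candidate answers are in
cooperative/competitive interaction, which is what produces the classic
behavioural effects (problem size, fives, ties).  Here the model serves as a
realistic, fully coupled 107-unit test system for the linear-form
integrators: every unit obeys ``du/dt = a(t)*u + b(t)`` with ``a`` and ``b``
functions of the other units' (half-rectified) activations, and
``a = -1 + ...`` carrying the spontaneous decay.

Architecture (107 units, in fixed layout order):

==============  =====  ==========================================================
layer           count  meaning
==============  =====  ==========================================================
operand1        8      first-operand input nodes, labels 2..9
operand2        8      second-operand input nodes, labels 2..9
semantic        36     one node per unordered problem {i, j}, 2 <= i <= j <= 9
tens            9      tens digit of candidate answers, labels 0..8
units           10     units digit of candidate answers, labels 0..9
response        36     one candidate-answer node per problem, value i*j
==============  =====  ==========================================================

Dynamics.  Operand nodes carry the stimulus in their initial condition
(value ``B``) and decay freely afterwards (``a = -1``, ``b = 0``).  Every
other unit follows the interactive-activation law

    du/dt = -u + [net]+ * (M - u),

i.e. excitation drives the unit toward the activation ceiling ``M`` at a
rate set by its rectified net input, while the spontaneous decay (rate 1)
pulls it back to rest.  In linear form this is ``a = -1 - [net]+`` and
``b = M * [net]+``: the coefficients are strongly state-dependent, which is
exactly what makes the network a demanding integration benchmark.

Net inputs (``[x]+ = max(x, 0)`` throughout):

* semantic node {i, j}: conjunctive operand gating,
  ``net = tao * ([o1_i]+ [o2_j]+ + [o1_j]+ [o2_i]+)`` (one product for
  ties) — only problems whose *both* operands are present light up, at a
  rate set by the time-scale gain ``tao``;
* response node for problem p: association from the semantic layer with an
  operand-distance gradient, cooperation from its answer's digit nodes, and
  lateral competition from the other candidates,
  ``net = S * sum_q alpha**dist(p,q) [s_q]+
        + alpha * ([tens_d]+ + [units_e]+) - C * sum_{q != p} [r_q]+``,
  where dist is the operand-grid L1 distance between problems (dist 0 is
  the problem's own semantic node) and (d, e) are the digits of p's answer;
* digit node: collects (weight 1) every response node whose answer carries
  that digit, closing the cooperation loop between candidates that share a
  tens or units digit — the neighbourhood-consistency channel.

With the published fit parameters, presenting 7 x 8 drives the semantic
node {7, 8} to saturation within the run, the candidate 56 wins the
response competition, and the network has settled on its answer by t = 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .integrators import SimulationResult, StateVector

__all__ = [
    "INParameters",
    "INNetwork",
    "ProblemInput",
    "LAYER_SIZES",
    "build_network",
    "initial_state",
    "coefficients",
    "readout_answer",
    "response_indices",
    "layout_table",
    "dump_layout",
    "NoisyDriveEvaluator",
]

#: layer sizes in layout order: operand1, operand2, semantic, tens, units, response
LAYER_SIZES = (8, 8, 36, 9, 10, 36)
N_UNITS = sum(LAYER_SIZES)  # 107

OPERAND_RANGE = range(2, 10)


@dataclass(frozen=True)
class INParameters:
    """The six parameters of the IN model, defaulting to the published fit.

    B      input strength: initial activation of the two operand nodes.
    M      activation ceiling of the interactive-activation units.
    S      semantic -> response association strength.
    tao    time-scale gain of the operand -> semantic conjunction.
    alpha  neighbourhood gradient (per unit of operand distance) and
           digit -> response cooperation weight.
    C      lateral competition between response nodes.
    """

    B: float = 20.0
    M: float = 10.0
    S: float = 2.0
    tao: float = 19.5
    alpha: float = 0.75
    C: float = 0.5

    def __post_init__(self) -> None:
        for name in ("B", "M", "S", "tao", "alpha", "C"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"parameter {name} must be finite")
        if not self.tao > 0:
            raise ValueError("tao must be positive")
        if self.B == 0:
            raise ValueError("B must be nonzero")


@dataclass(frozen=True)
class ProblemInput:
    """A multiplication problem with operands in 2..9."""

    operand1: int
    operand2: int

    def __post_init__(self) -> None:
        for name, v in (("operand1", self.operand1), ("operand2", self.operand2)):
            if v not in OPERAND_RANGE:
                raise ValueError(f"{name} must be in [2, 9], got {v}")

    @classmethod
    def parse(cls, text: str) -> "ProblemInput":
        """Parse '7x8' (also accepts '7*8' or '7,8')."""
        for sep in ("x", "X", "*", ","):
            if sep in text:
                p1, p2 = text.split(sep)
                return cls(int(p1), int(p2))
        raise ValueError(f"cannot parse problem {text!r}; expected e.g. '7x8'")


def _semantic_pairs() -> list[tuple[int, int]]:
    return [(i, j) for i in OPERAND_RANGE for j in OPERAND_RANGE if i <= j]


def _pair_distance(p: tuple[int, int], q: tuple[int, int]) -> int:
    """Operand-grid L1 distance between unordered problems (best pairing)."""
    (i, j), (k, l) = p, q
    return min(abs(i - k) + abs(j - l), abs(i - l) + abs(j - k))


class INNetwork:
    """The 107-unit IN network as a coefficient evaluator.

    The linear part of every net input is assembled once into a 107x107
    matrix; the only non-matrix term is the conjunctive operand gating of
    the semantic layer (a gather-multiply over precomputed index arrays).
    One coefficient evaluation therefore touches every coupling exactly
    once, and :meth:`evaluate` is pure in ``(t, u)``.
    """

    def __init__(self, params: INParameters):
        self.params = params
        self.n_units = N_UNITS

        pairs = _semantic_pairs()
        self.semantic_pairs = pairs
        # layout: operand1, operand2, semantic, tens, units, response
        self.operand1_index = {d: d - 2 for d in OPERAND_RANGE}
        self.operand2_index = {d: 8 + d - 2 for d in OPERAND_RANGE}
        sem0 = 16
        self.semantic_index = {p: sem0 + k for k, p in enumerate(pairs)}
        tens0 = sem0 + 36
        self.tens_index = {d: tens0 + d for d in range(9)}
        units0 = tens0 + 9
        self.units_index = {d: units0 + d for d in range(10)}
        resp0 = units0 + 10
        self.response_index = {p: resp0 + k for k, p in enumerate(pairs)}
        #: answer value carried by each response node, in layout order
        self.response_answers = np.array([i * j for (i, j) in pairs], dtype=int)
        self._sem0 = sem0
        self._resp0 = resp0

        p = params
        # linear net-input couplings
        W = np.zeros((N_UNITS, N_UNITS))
        for pair, r_idx in self.response_index.items():
            answer = pair[0] * pair[1]
            # semantic associations with the operand-distance gradient
            for other, s_idx in self.semantic_index.items():
                W[r_idx, s_idx] += p.S * p.alpha ** _pair_distance(pair, other)
            # digit cooperation (both directions)
            W[r_idx, self.tens_index[answer // 10]] += p.alpha
            W[r_idx, self.units_index[answer % 10]] += p.alpha
            W[self.tens_index[answer // 10], r_idx] += 1.0
            W[self.units_index[answer % 10], r_idx] += 1.0
            # lateral competition among candidate answers
            for other_idx in self.response_index.values():
                if other_idx != r_idx:
                    W[r_idx, other_idx] -= p.C
        self._W = W

        # conjunctive operand gating of the semantic layer: index arrays for
        # [o1_i][o2_j] and the transposed product [o1_j][o2_i] (zero-weighted
        # for ties so the conjunction is counted once)
        self._conj_i1 = np.array([self.operand1_index[i] for (i, j) in pairs])
        self._conj_i2 = np.array([self.operand2_index[j] for (i, j) in pairs])
        self._conj_j1 = np.array([self.operand1_index[j] for (i, j) in pairs])
        self._conj_j2 = np.array([self.operand2_index[i] for (i, j) in pairs])
        self._conj_cross = np.array([0.0 if i == j else 1.0 for (i, j) in pairs])
        self._conj_gain = p.tao

    def evaluate(self, t: float, u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Coefficient vectors (a, b) at state ``u``; pure in (t, u)."""
        if u.shape != (self.n_units,):
            raise ValueError(
                f"state length {u.shape} does not match network size ({self.n_units},)"
            )
        v = np.maximum(u, 0.0)
        net = self._W @ v
        net[self._sem0 : self._sem0 + 36] += self._conj_gain * (
            v[self._conj_i1] * v[self._conj_i2]
            + self._conj_cross * v[self._conj_j1] * v[self._conj_j2]
        )
        np.maximum(net, 0.0, out=net)
        a = -1.0 - net
        b = self.params.M * net
        return a, b


def build_network(params: INParameters | None = None) -> INNetwork:
    """Build the 107-unit IN network with the given (default: published) parameters."""
    return INNetwork(params or INParameters())


def initial_state(network: INNetwork, problem: ProblemInput) -> StateVector:
    """Stimulus encoding: all units zero except the two operand nodes at B.

    The input stimuli are assumed absent after t = 0, so the stimulus lives
    entirely in the initial condition (operand nodes decay freely).
    """
    u = np.zeros(network.n_units)
    u[network.operand1_index[problem.operand1]] = network.params.B
    u[network.operand2_index[problem.operand2]] = network.params.B
    return StateVector(u, 0.0)


def coefficients(network: INNetwork, t: float, u: StateVector) -> tuple[np.ndarray, np.ndarray]:
    """Convenience wrapper over :meth:`INNetwork.evaluate` taking a StateVector."""
    return network.evaluate(t, u.values)


def response_indices(network: INNetwork) -> list[int]:
    """Indices of the 36 response nodes, a contiguous block at the end of the layout."""
    return list(range(network._resp0, network.n_units))


def readout_answer(
    result: SimulationResult,
    network: INNetwork,
    threshold: float | None = None,
) -> int:
    """The network's answer: value of the maximally active response node.

    Ties are broken toward the smaller answer value.  If ``threshold`` is
    given and the result carries a trajectory, the answer of the first
    response node to cross the threshold is returned instead (falling back
    to the final-state argmax if none crosses).
    """
    idx = response_indices(network)
    answers = network.response_answers

    if threshold is not None and result.trajectory is not None:
        for t, values in result.trajectory:
            resp = values[idx]
            crossed = np.flatnonzero(resp >= threshold)
            if crossed.size:
                return int(answers[crossed].min())

    resp = result.final_state.values[idx]
    if not np.all(np.isfinite(resp)):
        raise ValueError("response activations are non-finite; run diverged")
    best = resp == resp.max()
    return int(answers[best].min())


def layout_table(network: INNetwork) -> pd.DataFrame:
    """The network layout as a table: index, layer, label, answer_value."""
    rows: list[tuple[int, str, str, str]] = []
    for d, k in network.operand1_index.items():
        rows.append((k, "operand1", str(d), ""))
    for d, k in network.operand2_index.items():
        rows.append((k, "operand2", str(d), ""))
    for (i, j), k in network.semantic_index.items():
        rows.append((k, "semantic", f"{i}x{j}", ""))
    for d, k in network.tens_index.items():
        rows.append((k, "tens", str(d), ""))
    for d, k in network.units_index.items():
        rows.append((k, "units", str(d), ""))
    for (i, j), k in network.response_index.items():
        rows.append((k, "response", f"{i}x{j}", str(i * j)))
    df = pd.DataFrame(rows, columns=["index", "layer", "label", "answer_value"])
    return df.sort_values("index").reset_index(drop=True)


def dump_layout(network: INNetwork, path: str | Path) -> None:
    """Write the layout table as CSV with header index,layer,label,answer_value."""
    layout_table(network).to_csv(path, index=False)


class NoisyDriveEvaluator:
    """Wraps a coefficient evaluator with additive Gaussian noise on b.

    Off by default everywhere; provided for stochastic retrieval experiments.
    Breaks the purity contract (and hence exact step-doubling reuse), so it
    is only meant for plain fixed-step runs with an explicit seed.
    """

    def __init__(self, base, sigma: float, seed: int):
        self.base = base
        self.sigma = float(sigma)
        self.n_units = base.n_units
        self._rng = np.random.default_rng(seed)

    def evaluate(self, t: float, u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        a, b = self.base.evaluate(t, u)
        return a, b + self._rng.normal(0.0, self.sigma, size=b.shape)
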