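"""Model evaluation: gate logic, steady-state simulation, and scoring.

Gate semantics (per operator mode):

* ``minmax`` — AND is the minimum of the per-input transfer-function
  values, OR the maximum over a node's active gates.
* ``prodsum`` — AND is the product, OR the sum capped at one.
* ``boolean`` — inputs are binarized at 0.5 and combined with logical
  AND/OR; transfer-function parameters are ignored apart from gate
  presence, reproducing classical Boolean steady-state evaluation.

Simulation clamps stimulus nodes to their treatment level and inhibited
nodes (flag 1) to zero, initializes every other node at zero (no basal
activity), and iterates synchronous updates to a fixed point.
Non-convergence is a flagged outcome, never an exception; during scoring a
non-converged condition contributes squared error 1.0 per observation so
oscillating models are disfavored.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .data import Dataset, ExperimentalCondition
from .model import CFLModel
from .network import CandidateGate
from .transfer import TransferFunctionSpec, apply_edge_tf

__all__ = [
    "SimConfig",
    "SimulationResult",
    "eval_gate",
    "eval_node",
    "simulate",
    "simulate_model",
    "compute_mse",
]

OPERATOR_MODES = ("minmax", "prodsum", "boolean")


@dataclass(frozen=True)
class SimConfig:
    """Simulation controls: convergence tolerance, iteration cap, operators.

    ``max_iter`` defaults to 10x the node count when left None.
    """

    tol: float = 1e-4
    max_iter: Optional[int] = None
    operator_mode: str = "minmax"

    def __post_init__(self) -> None:
        if self.operator_mode not in OPERATOR_MODES:
            raise ValueError(f"unknown operator mode {self.operator_mode!r}")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


@dataclass
class SimulationResult:
    """Steady-state node activities for a batch of conditions."""

    node_order: Tuple[str, ...]
    x: np.ndarray                # nodes x conditions
    converged: np.ndarray        # bool per condition
    iterations: np.ndarray       # int per condition

    def value(self, node: str, condition: int = 0) -> float:
        """Predicted activity, or NaN when the condition did not converge."""
        if not self.converged[condition]:
            return float("nan")
        return float(self.x[self.node_order.index(node), condition])

    def frame(self) -> pd.DataFrame:
        """Conditions x nodes table; non-converged rows are NaN."""
        arr = self.x.T.copy()
        arr[~self.converged, :] = np.nan
        return pd.DataFrame(arr, columns=list(self.node_order))


def _edge_values(gate: CandidateGate, specs, input_values, mode: str):
    vals = []
    for (node, sign), spec in zip(gate.inputs, specs):
        if spec is None:
            raise ValueError(f"gate {gate.describe()} has an absent slot; "
                             "inactive gates must be skipped")
        x = input_values[node]
        if mode == "boolean":
            b = np.asarray(x, dtype=float) >= 0.5
            v = b.astype(float) if sign == 1 else (~b).astype(float)
            vals.append(float(v) if np.isscalar(x) else v)
        else:
            vals.append(apply_edge_tf(x, spec, sign))
    return vals


def eval_gate(gate: CandidateGate, specs: Sequence[TransferFunctionSpec],
              input_values: Dict[str, float], operator_mode: str = "minmax"):
    """Evaluate one active gate given its per-slot transfer functions."""
    if operator_mode not in OPERATOR_MODES:
        raise ValueError(f"unknown operator mode {operator_mode!r}")
    vals = _edge_values(gate, specs, input_values, operator_mode)
    if operator_mode == "prodsum":
        out = vals[0]
        for v in vals[1:]:
            out = out * v
        return out
    return min(vals) if np.isscalar(vals[0]) else np.minimum.reduce(vals)


def eval_node(output: str, gates_with_specs, input_values,
              operator_mode: str = "minmax"):
    """OR-combine the active gates of one output node.

    ``gates_with_specs`` is a sequence of (CandidateGate, specs).  A node
    with no active gates evaluates to 0 (no basal activity).
    """
    if not gates_with_specs:
        return 0.0
    gate_vals = [eval_gate(g, specs, input_values, operator_mode)
                 for g, specs in gates_with_specs]
    if operator_mode == "prodsum":
        total = gate_vals[0]
        for v in gate_vals[1:]:
            total = total + v
        return min(total, 1.0) if np.isscalar(total) else np.minimum(total, 1.0)
    return max(gate_vals) if np.isscalar(gate_vals[0]) else np.maximum.reduce(gate_vals)


# ---------------------------------------------------------------------------
# compiled batch simulation

_HILL, _LINEAR = 0, 1


def compile_model(model: CFLModel):
    """Flatten a model's active gates into index-based structures for the
    synchronous update loop (node names resolved once, not per iteration)."""
    hs = model.hypothesis
    node_order = tuple(sorted(hs.pkn.nodes))
    index = {n: i for i, n in enumerate(node_order)}
    per_node: Dict[int, List[List[Tuple[int, int, int, float, float]]]] = {}
    for output, gi, gate in model.active_gates():
        edges = []
        for (inp, sign), sid in zip(gate.inputs, hs.gate_slots(output, gi)):
            spec = model.assignment[sid]
            if spec.family == "hill":
                edges.append((index[inp], sign, _HILL, spec.n, spec.k))
            else:
                edges.append((index[inp], sign, _LINEAR, spec.slope, 0.0))
        per_node.setdefault(index[output], []).append(edges)
    return node_order, index, per_node


def _batch_conditions(conditions: Sequence[ExperimentalCondition],
                      index: Dict[str, int], n_nodes: int):
    c = len(conditions)
    stim_rows: Dict[int, np.ndarray] = {}
    inhib_rows: Dict[int, np.ndarray] = {}
    for j, cond in enumerate(conditions):
        for node, v in cond.stimuli.items():
            stim_rows.setdefault(index[node], np.zeros(c))[j] = v
        for node, f in cond.inhibitors.items():
            if f:
                inhib_rows.setdefault(index[node], np.zeros(c, dtype=bool))[j] = True
    return stim_rows, inhib_rows


def simulate(model: CFLModel, condition, sim_config: SimConfig = SimConfig()
             ) -> SimulationResult:
    """Simulate one condition or a sequence of conditions to steady state."""
    conditions = [condition] if isinstance(condition, ExperimentalCondition) \
        else list(condition)
    node_order, index, per_node = compile_model(model)
    n, c = len(node_order), len(conditions)
    mode = sim_config.operator_mode
    max_iter = sim_config.max_iter or 10 * n
    stim_rows, inhib_rows = _batch_conditions(conditions, index, n)

    x = np.zeros((n, c))
    for i, row in stim_rows.items():
        x[i] = row
    for i, mask in inhib_rows.items():
        x[i, mask] = 0.0

    iterations = np.zeros(c, dtype=int)
    converged = np.zeros(c, dtype=bool)
    for it in range(1, max_iter + 1):
        new_x = x.copy()
        for ni, gates in per_node.items():
            gate_vals = []
            for edges in gates:
                edge_vals = []
                for inp, sign, fam, p1, p2 in edges:
                    xi = x[inp]
                    if mode == "boolean":
                        v = (xi >= 0.5).astype(float)
                    elif fam == _HILL:
                        xn = np.power(xi, p1)
                        kn = p2**p1
                        v = xn * (1.0 + kn) / (xn + kn)
                    else:
                        v = p1 * xi
                    if sign == -1:
                        v = 1.0 - v
                    edge_vals.append(v)
                if mode == "prodsum":
                    gv = edge_vals[0]
                    for v in edge_vals[1:]:
                        gv = gv * v
                else:
                    gv = np.minimum.reduce(edge_vals)
                gate_vals.append(gv)
            if mode == "prodsum":
                val = np.minimum(np.add.reduce(gate_vals), 1.0)
            else:
                val = np.maximum.reduce(gate_vals)
            new_x[ni] = val
        for i, row in stim_rows.items():
            new_x[i] = row
        for i, mask in inhib_rows.items():
            new_x[i, mask] = 0.0
        delta = np.abs(new_x - x).max(axis=0) if n else np.zeros(c)
        newly = (~converged) & (delta < sim_config.tol)
        iterations[newly] = it
        converged |= newly
        x = new_x
        if converged.all():
            break
    iterations[~converged] = max_iter
    return SimulationResult(node_order, x, converged, iterations)


def simulate_model(model: CFLModel, dataset: Dataset,
                   sim_config: SimConfig = SimConfig()) -> SimulationResult:
    """Simulate every condition of a dataset's design."""
    return simulate(model, dataset.conditions(), sim_config)


def compute_mse(result: SimulationResult, dataset: Dataset,
                signals: Optional[Sequence[str]] = None,
                condition_mask: Optional[np.ndarray] = None) -> float:
    """Mean squared error over non-missing observation cells.

    MSE = (1/N) sum (x_pred - x_obs)^2 with N the number of scored cells.
    ``signals`` and ``condition_mask`` restrict the computation to a subset
    of measured nodes / design rows (e.g. the error under one stimulus
    only).  Cells of non-converged conditions score squared error 1.0 and
    still count toward N.
    """
    cols = list(dataset.values.columns) if signals is None else list(signals)
    obs = dataset.values[cols].to_numpy(dtype=float)
    if condition_mask is not None:
        mask = np.asarray(condition_mask)
        if mask.dtype != bool:
            sel = np.zeros(len(obs), dtype=bool)
            sel[mask] = True
            mask = sel
    else:
        mask = np.ones(len(obs), dtype=bool)
    rows = [result.node_order.index(c) for c in cols]
    pred = result.x[rows, :].T  # conditions x cols
    present = ~np.isnan(obs) & mask[:, None]
    n = int(present.sum())
    if n == 0:
        raise ValueError("MSE undefined: no scored observation cells")
    sq = (pred - obs) ** 2
    sq[~result.converged, :] = 1.0
    return float(sq[present].sum() / n)
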