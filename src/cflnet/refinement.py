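"""Model reduction, continuous parameter refinement, and filtering.

After discrete training each model is simplified at a grid of *reduction
thresholds* (gates are removed, or 2-input AND gates replaced by one of
their 1-input sub-gates, whenever the alteration keeps the MSE within the
threshold of the unprocessed model's MSE), then its transfer-function
parameters are refined by bounded local continuous optimization (SLSQP, a
sequential quadratic programming method).  A *selection threshold* finally
picks, per model, the reduced-refined variant with the fewest fitted
parameters whose MSE stays within the threshold of the model's baseline —
the *filtered* model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .data import Dataset
from .model import CFLModel, ModelEnsemble
from .simulate import SimConfig, compute_mse, simulate
from .transfer import TransferFunctionSpec

logger = logging.getLogger(__name__)

__all__ = ["RefinementConfig", "ReductionProfile", "reduce_model",
           "refine_parameters", "build_reduction_profile", "select_filtered",
           "threshold_tradeoff_table"]

DEFAULT_GRID = (0.0, 1e-5, 5e-5, 1e-4, 5e-4, 1e-3, 5e-3, 1e-2, 5e-2)

# refinement bounds cover the discrete libraries with margin
HILL_N_BOUNDS = (1.0, 5.0)
HILL_K_BOUNDS = (0.01, 2.0)
SLOPE_BOUNDS = (0.0, 1.0)


@dataclass(frozen=True)
class RefinementConfig:
    """Reduction-threshold grid, selection threshold, optimizer controls."""

    reduction_threshold_grid: Tuple[float, ...] = DEFAULT_GRID
    selection_threshold: float = 5e-3
    optimizer_maxiter: int = 100
    optimizer_ftol: float = 1e-9

    def __post_init__(self) -> None:
        grid = self.reduction_threshold_grid
        if 0.0 not in grid:
            raise ValueError("reduction threshold grid must contain 0")
        if list(grid) != sorted(grid):
            raise ValueError("reduction threshold grid must be ascending")
        if self.selection_threshold < 0:
            raise ValueError("selection_threshold must be >= 0")


def _model_mse(model: CFLModel, conditions, dataset: Dataset,
               sim_config: SimConfig) -> float:
    return compute_mse(simulate(model, conditions, sim_config), dataset)


def reduce_model(model: CFLModel, dataset: Dataset, threshold: float,
                 sim_config: SimConfig = SimConfig()) -> CFLModel:
    """Greedy simplification capped at the unprocessed MSE + threshold.

    Candidate alterations each round: deactivate an active gate, or replace
    an active 2-input AND gate by one of its 1-input sub-gates (which keeps
    that slot's transfer function).  The alteration with the smallest
    resulting MSE is applied, provided that MSE stays within the cap; ties
    break by (output name, gate index).  Terminates when no alteration
    qualifies.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    conditions = dataset.conditions()
    current = model.copy(stage="reduced")
    if current.mse is None:
        current.mse = _model_mse(current, conditions, dataset, sim_config)
    cap = current.mse + threshold
    hs = current.hypothesis

    while True:
        candidates = []  # (mse, output, gate_index, kind_rank, assignment)
        for output, gi, gate in current.active_gates():
            slots = hs.gate_slots(output, gi)
            # (i) deactivate the gate
            trial = dict(current.assignment)
            for sid in slots:
                trial[sid] = None
            candidates.append((output, gi, 0, trial))
            # (ii) replace a 2-input AND by a 1-input sub-gate
            if gate.arity == 2:
                for (inp, sign), sid in zip(gate.inputs, slots):
                    sub = None
                    for gj, g2 in enumerate(hs.gates[output]):
                        if g2.inputs == ((inp, sign),):
                            sub = gj
                            break
                    if sub is None or current.is_gate_active(output, sub):
                        continue
                    trial = dict(current.assignment)
                    for s in slots:
                        trial[s] = None
                    trial[hs.gate_slots(output, sub)[0]] = current.assignment[sid]
                    candidates.append((output, gi, 1, trial))
        if not candidates:
            break
        scored = []
        for output, gi, kind, trial in candidates:
            m = CFLModel(hs, trial, stage="reduced")
            mse = _model_mse(m, conditions, dataset, sim_config)
            scored.append((mse, output, gi, kind, trial))
        scored.sort(key=lambda r: (r[0], r[1], r[2], r[3]))
        best = scored[0]
        if best[0] > cap:
            break
        current = CFLModel(hs, best[4], stage="reduced", seed=model.seed,
                           data_fingerprint=dataset.fingerprint())
        current.mse = best[0]
    current.stage = "reduced"
    if current.mse is None:
        current.mse = _model_mse(current, conditions, dataset, sim_config)
    current.seed = model.seed
    current.data_fingerprint = dataset.fingerprint()
    return current


def _clip(v: float, lo: float, hi: float) -> float:
    return min(max(v, lo), hi)


def refine_parameters(model: CFLModel, dataset: Dataset,
                      config: RefinementConfig = RefinementConfig(),
                      sim_config: SimConfig = SimConfig()) -> CFLModel:
    """Bounded continuous minimization of MSE over active-slot parameters.

    Topology is fixed; Hill slots contribute (n, k) with n in [1, 5] and
    k in [0.01, 2], linear slots their slope in [0, 1].  Starts from the
    current (clipped) values; never returns a model worse than its input.
    """
    conditions = dataset.conditions()
    hs = model.hypothesis
    active_slots = []
    for output, gi, _ in model.active_gates():
        active_slots.extend(hs.gate_slots(output, gi))
    incoming_mse = model.mse if model.mse is not None else \
        _model_mse(model, conditions, dataset, sim_config)
    if not active_slots:
        out = model.copy(stage="reduced_refined")
        out.mse = incoming_mse
        return out

    x0, bounds, layout = [], [], []
    for sid in active_slots:
        spec = model.assignment[sid]
        if spec.family == "hill":
            x0 += [_clip(spec.n, *HILL_N_BOUNDS), _clip(spec.k, *HILL_K_BOUNDS)]
            bounds += [HILL_N_BOUNDS, HILL_K_BOUNDS]
            layout.append((sid, "hill"))
        else:
            x0 += [_clip(spec.slope, *SLOPE_BOUNDS)]
            bounds += [SLOPE_BOUNDS]
            layout.append((sid, "linear"))

    def build(params: np.ndarray) -> CFLModel:
        assignment = dict(model.assignment)
        i = 0
        for sid, family in layout:
            if family == "hill":
                assignment[sid] = TransferFunctionSpec(
                    "hill", n=float(params[i]), k=float(params[i + 1]))
                i += 2
            else:
                assignment[sid] = TransferFunctionSpec(
                    "linear", slope=float(params[i]))
                i += 1
        return CFLModel(hs, assignment, stage="reduced_refined")

    def objective(params: np.ndarray) -> float:
        return _model_mse(build(params), conditions, dataset, sim_config)

    try:
        res = minimize(objective, np.array(x0), method="SLSQP", bounds=bounds,
                       options={"maxiter": config.optimizer_maxiter,
                                "ftol": config.optimizer_ftol})
        refined_mse = float(res.fun)
        refined = build(res.x)
    except Exception as exc:  # pragma: no cover - optimizer robustness
        logger.warning("parameter refinement failed (%s); keeping model", exc)
        refined_mse, refined = np.inf, None

    if refined is None or refined_mse > incoming_mse + 1e-12:
        out = model.copy(stage="reduced_refined")
        out.mse = incoming_mse
        return out
    refined.mse = refined_mse
    refined.seed = model.seed
    refined.data_fingerprint = dataset.fingerprint()
    return refined


@dataclass
class ReductionProfile:
    """Reduced-refined MSE and parameter count per model x grid threshold.

    ``baseline[i]`` is model i's minimum refined MSE across the grid;
    ``filter_point[i]`` the largest grid threshold whose MSE stays within
    the selection threshold of that baseline.
    """

    config: RefinementConfig
    grid: Tuple[float, ...]
    entries: Dict[Tuple[int, float], Tuple[float, int, CFLModel]]
    n_models: int

    def mse(self, model_index: int, threshold: float) -> float:
        return self.entries[(model_index, threshold)][0]

    def parameter_count(self, model_index: int, threshold: float) -> int:
        return self.entries[(model_index, threshold)][1]

    def model(self, model_index: int, threshold: float) -> CFLModel:
        return self.entries[(model_index, threshold)][2]

    def baseline(self, model_index: int) -> float:
        return min(self.mse(model_index, t) for t in self.grid)

    def filter_point(self, model_index: int,
                     selection_threshold: Optional[float] = None) -> float:
        sel = (self.config.selection_threshold if selection_threshold is None
               else selection_threshold)
        base = self.baseline(model_index)
        ok = [t for t in self.grid if self.mse(model_index, t) <= base + sel]
        return max(ok)

    def table(self) -> pd.DataFrame:
        rows = []
        for (mi, t), (mse, pc, _) in sorted(self.entries.items()):
            rows.append({"model": mi, "reduction_threshold": t,
                         "refined_mse": mse, "parameter_count": pc})
        return pd.DataFrame(rows)


def build_reduction_profile(ensemble: ModelEnsemble, dataset: Dataset,
                            config: RefinementConfig = RefinementConfig(),
                            sim_config: SimConfig = SimConfig()
                            ) -> ReductionProfile:
    """Reduce then refine every model at every grid threshold."""
    if not len(ensemble):
        raise ValueError("empty ensemble")
    entries = {}
    for mi, model in enumerate(ensemble):
        for t in config.reduction_threshold_grid:
            reduced = reduce_model(model, dataset, t, sim_config)
            refined = refine_parameters(reduced, dataset, config, sim_config)
            entries[(mi, t)] = (refined.mse, refined.parameter_count, refined)
    return ReductionProfile(config, tuple(config.reduction_threshold_grid),
                            entries, len(ensemble))


def select_filtered(profile: ReductionProfile,
                    selection_threshold: Optional[float] = None
                    ) -> ModelEnsemble:
    """Pick one filtered model per unprocessed model: fewest fitted
    parameters with MSE within the selection threshold of the baseline;
    ties go to the larger reduction threshold."""
    sel = (profile.config.selection_threshold if selection_threshold is None
           else selection_threshold)
    chosen = []
    hypothesis = None
    for mi in range(profile.n_models):
        base = profile.baseline(mi)
        eligible = [t for t in profile.grid
                    if profile.mse(mi, t) <= base + sel]
        best_t = min(eligible,
                     key=lambda t: (profile.parameter_count(mi, t),
                                    -profile.grid.index(t)))
        model = profile.model(mi, best_t).copy(stage="filtered")
        hypothesis = model.hypothesis
        chosen.append(model)
    return ModelEnsemble(hypothesis, chosen)


def threshold_tradeoff_table(profile: ReductionProfile,
                             candidate_thresholds: Optional[Sequence[float]] = None
                             ) -> pd.DataFrame:
    """Mean filtered MSE and parameter count as a function of the selection
    threshold — the curve used to choose a threshold that trades a small
    MSE increase for a real drop in model size."""
    if candidate_thresholds is None:
        candidate_thresholds = (0.0,) + tuple(
            t for t in profile.grid if t > 0) + (profile.config.selection_threshold,)
        candidate_thresholds = tuple(sorted(set(candidate_thresholds)))
    rows = []
    for sel in candidate_thresholds:
        fam = select_filtered(profile, sel)
        rows.append({
            "selection_threshold": sel,
            "mean_mse": float(np.mean([m.mse for m in fam])),
            "mean_parameter_count": float(np.mean(
                [m.parameter_count for m in fam])),
        })
    return pd.DataFrame(rows)
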