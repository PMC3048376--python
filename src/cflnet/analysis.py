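"""Ensemble analysis: what a family of trained models agrees and disagrees on.

Individual training runs return models with slightly different topologies
and parameters; the family is the object of interest.  This module
summarizes gate frequencies and sensitivities, mean/SD/CV predictions,
input-output response surfaces, cross-validation harnesses, consensus
topology comparison, and randomization-based significance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .data import Dataset, ExperimentalCondition
from .model import ModelEnsemble
from .network import HypothesisSpace
from .refinement import (RefinementConfig, build_reduction_profile,
                         select_filtered)
from .simulate import SimConfig, eval_node, simulate
from .training import GAConfig, train_family
from .transfer import gate_sensitivity

logger = logging.getLogger(__name__)

__all__ = ["PredictionSummary", "CrossValReport", "gate_frequencies",
           "ensemble_sensitivity", "ensemble_predict", "node_response_surface",
           "kfold_crossval", "holdout_crossval", "topology_distance",
           "significance_vs_null", "classify_quadrant"]

MSE_CUT_DEFAULT = 0.20
CV_CUT_DEFAULT = 0.25
ACTIVATION_FLOOR_DEFAULT = 0.1


@dataclass
class PredictionSummary:
    """Per-cell ensemble mean, standard deviation and CV (= sd/mean).

    CV is undefined (NaN) where the mean is zero; such cells are excluded
    from mean-CV summaries.
    """

    index: pd.Index
    mean: pd.DataFrame
    sd: pd.DataFrame
    cv: pd.DataFrame
    n_models: int

    def mean_cv(self) -> float:
        vals = self.cv.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size == 0:
            return float("nan")
        return float(finite.mean())


@dataclass
class CrossValReport:
    """Per-test-set fit and precision with quadrant classification."""

    entries: pd.DataFrame  # one row per test set
    mse_cut: float = MSE_CUT_DEFAULT
    cv_cut: float = CV_CUT_DEFAULT


def classify_quadrant(test_mse: float, mean_cv: float,
                      mse_cut: float = MSE_CUT_DEFAULT,
                      cv_cut: float = CV_CUT_DEFAULT) -> str:
    accurate = test_mse <= mse_cut
    precise = (not math.isnan(mean_cv)) and mean_cv <= cv_cut
    if precise and accurate:
        return "precise_accurate"
    if not precise and accurate:
        return "imprecise_accurate"
    if not precise and not accurate:
        return "imprecise_inaccurate"
    return "precise_inaccurate"


def _check_shared_space(ensemble: ModelEnsemble) -> HypothesisSpace:
    if not len(ensemble):
        raise ValueError("empty ensemble")
    return ensemble.hypothesis


def gate_frequencies(ensemble: ModelEnsemble) -> Dict[Tuple[str, int], float]:
    """Fraction of models in which each candidate gate is active."""
    hs = _check_shared_space(ensemble)
    freqs = {}
    for output, gi, _ in hs.gate_list():
        count = sum(1 for m in ensemble if m.is_gate_active(output, gi))
        freqs[(output, gi)] = count / len(ensemble)
    return freqs


def ensemble_sensitivity(ensemble: ModelEnsemble, output: str,
                         gate_index: int) -> Tuple[float, float]:
    """Mean and SD of a gate's sensitivity over the models containing it.

    For 2-input gates the per-model sensitivity is the mean of its slots'
    sensitivities.
    """
    hs = _check_shared_space(ensemble)
    slots = hs.gate_slots(output, gate_index)
    values = []
    for m in ensemble:
        if m.is_gate_active(output, gate_index):
            values.append(float(np.mean(
                [gate_sensitivity(m.assignment[sid]) for sid in slots])))
    if not values:
        raise ValueError(f"gate ({output}, {gate_index}) is active in no model")
    arr = np.array(values)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return float(arr.mean()), sd


def ensemble_predict(ensemble: ModelEnsemble,
                     conditions: Sequence[ExperimentalCondition],
                     sim_config: SimConfig = SimConfig()) -> PredictionSummary:
    """Simulate every model on every condition; per-cell mean/sd/CV over
    models whose simulation converged on that condition."""
    hs = _check_shared_space(ensemble)
    conditions = list(conditions)
    node_order = tuple(sorted(hs.pkn.nodes))
    stack = np.full((len(ensemble), len(conditions), len(node_order)), np.nan)
    for mi, model in enumerate(ensemble):
        res = simulate(model, conditions, sim_config)
        vals = res.x.T.copy()
        vals[~res.converged, :] = np.nan
        stack[mi] = vals
    counts = (~np.isnan(stack)).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.nanmean(stack, axis=0)
        sd0 = np.nanstd(stack, axis=0, ddof=0)
        # sample (ddof=1) standard deviation; 0 where only one model converged
        sd = np.where(counts > 1,
                      sd0 * np.sqrt(counts / np.maximum(counts - 1, 1)), 0.0)
        cv = np.where(mean > 0, sd / np.where(mean > 0, mean, 1.0), np.nan)
    all_nan = np.isnan(stack).all(axis=0)
    if all_nan.any():
        logger.warning("%d prediction cells undefined (no converged model)",
                       int(all_nan.sum()))
    idx = pd.RangeIndex(len(conditions))
    cols = list(node_order)
    return PredictionSummary(
        idx,
        pd.DataFrame(mean, index=idx, columns=cols),
        pd.DataFrame(sd, index=idx, columns=cols),
        pd.DataFrame(cv, index=idx, columns=cols),
        len(ensemble),
    )


def node_response_surface(ensemble: ModelEnsemble, output: str,
                          input_grid: Dict[str, Sequence[float]],
                          operator_mode: str = "minmax") -> PredictionSummary:
    """Response of one node's gates over a grid of clamped input values.

    Only the output node's own gates are evaluated — there is no upstream
    simulation; inputs of its gates not named in the grid are held at 0.
    A 21 x 21 grid over two inputs yields 441 evaluation points.
    """
    hs = _check_shared_space(ensemble)
    if output not in hs.gates:
        raise ValueError(f"node {output} has no candidate gates")
    gate_inputs = {n for g in hs.gates[output] for n, _ in g.inputs}
    unknown = set(input_grid) - gate_inputs
    if unknown:
        raise ValueError(f"grid inputs {sorted(unknown)} are not inputs of "
                         f"{output}'s gates")
    names = sorted(input_grid)
    mesh = np.meshgrid(*[np.asarray(input_grid[n], dtype=float)
                         for n in names], indexing="ij")
    points = np.stack([m.ravel() for m in mesh], axis=1)
    per_model = np.empty((len(ensemble), len(points)))
    for mi, model in enumerate(ensemble):
        gates_with_specs = []
        for gi, gate in enumerate(hs.gates[output]):
            if model.is_gate_active(output, gi):
                specs = [model.assignment[sid]
                         for sid in hs.gate_slots(output, gi)]
                gates_with_specs.append((gate, specs))
        for pi, point in enumerate(points):
            values = dict(zip(names, point))
            for extra in gate_inputs - set(names):
                values[extra] = 0.0
            per_model[mi, pi] = eval_node(output, gates_with_specs, values,
                                          operator_mode)
    mean = per_model.mean(axis=0)
    sd = per_model.std(axis=0, ddof=1) if len(ensemble) > 1 \
        else np.zeros(len(points))
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(mean > 0, sd / np.where(mean > 0, mean, 1.0), np.nan)
    idx = pd.MultiIndex.from_arrays(points.T, names=names)
    return PredictionSummary(
        idx,
        pd.DataFrame({output: mean}, index=idx),
        pd.DataFrame({output: sd}, index=idx),
        pd.DataFrame({output: cv}, index=idx),
        len(ensemble),
    )


@dataclass(frozen=True)
class PipelineConfigLite:
    """Training/refinement budget used inside cross-validation harnesses."""

    ga: GAConfig = GAConfig()
    n_runs: int = 5
    refinement: Optional[RefinementConfig] = None
    sim: SimConfig = SimConfig()


def _train_and_filter(hs: HypothesisSpace, dataset: Dataset,
                      cfg: PipelineConfigLite) -> ModelEnsemble:
    fam = train_family(hs, dataset, cfg.ga, cfg.n_runs, "all", cfg.sim)
    if cfg.refinement is not None:
        profile = build_reduction_profile(fam, dataset, cfg.refinement, cfg.sim)
        fam = select_filtered(profile)
    return fam


def _ensemble_test_mse(fam: ModelEnsemble, dataset: Dataset,
                       test_cells: List[tuple], sim_config: SimConfig) -> dict:
    """Fit of the ensemble-mean prediction (and per-model MSEs) on held-out cells."""
    conditions = dataset.conditions()
    summary = ensemble_predict(fam, conditions, sim_config)
    obs, pred = [], []
    per_model_sq = [[] for _ in fam.models]
    per_cell_cv = []
    for mi, model in enumerate(fam):
        res = simulate(model, conditions, sim_config)
        for row, col in test_cells:
            o = float(dataset.values.at[row, col])
            p = res.value(col, row)
            per_model_sq[mi].append(1.0 if math.isnan(p) else (p - o) ** 2)
    for row, col in test_cells:
        obs.append(float(dataset.values.at[row, col]))
        pred.append(float(summary.mean.at[row, col]))
        per_cell_cv.append(float(summary.cv.at[row, col]))
    obs, pred = np.array(obs), np.array(pred)
    cvs = np.array(per_cell_cv)
    finite_cv = cvs[np.isfinite(cvs)]
    return {
        "test_mse": float(np.mean((pred - obs) ** 2)),
        "per_model_test_mse": [float(np.mean(sq)) for sq in per_model_sq],
        "mean_cv": float(finite_cv.mean()) if finite_cv.size else float("nan"),
    }


def kfold_crossval(hs: HypothesisSpace, dataset: Dataset, folds: int,
                   pipeline_config: PipelineConfigLite = PipelineConfigLite(),
                   seed: int = 0, mse_cut: float = MSE_CUT_DEFAULT,
                   cv_cut: float = CV_CUT_DEFAULT) -> CrossValReport:
    """k-fold cross-validation over observation cells.

    Non-missing cells are partitioned into ``folds`` disjoint subsets; for
    each fold a family is trained on the complement and scored on the
    held-out cells.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    cells = dataset.observation_cells()
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(cells))
    assignments = np.array_split(order, folds)
    if any(len(a) == 0 for a in assignments):
        raise ValueError(f"cannot partition {len(cells)} cells into {folds} "
                         "nonempty folds")
    rows = []
    for fi, idxs in enumerate(assignments):
        test_cells = [cells[i] for i in idxs]
        train_ds = dataset.mask_cells(test_cells)
        fam = _train_and_filter(hs, train_ds, pipeline_config)
        train_mse = float(np.mean([m.mse for m in fam]))
        scores = _ensemble_test_mse(fam, dataset, test_cells,
                                    pipeline_config.sim)
        rows.append({
            "fold": fi,
            "n_test_cells": len(test_cells),
            "training_mse": train_mse,
            "test_mse": scores["test_mse"],
            "mean_cv": scores["mean_cv"],
            "quadrant": classify_quadrant(scores["test_mse"],
                                          scores["mean_cv"], mse_cut, cv_cut),
        })
    return CrossValReport(pd.DataFrame(rows), mse_cut, cv_cut)


def holdout_crossval(hs: HypothesisSpace, dataset: Dataset, signal: str,
                     stimulus: str,
                     pipeline_config: PipelineConfigLite = PipelineConfigLite(),
                     activation_floor: float = ACTIVATION_FLOOR_DEFAULT,
                     mse_cut: float = MSE_CUT_DEFAULT,
                     cv_cut: float = CV_CUT_DEFAULT) -> dict:
    """Hold out one signal under one stimulus (all inhibitor treatments).

    Eligibility requires the signal to be at least partially activated
    (>= ``activation_floor``) under the held-out stimulus and under some
    other stimulus; otherwise the held-out cells carry no signal to predict
    or no training signal remains.
    """
    if signal not in dataset.values.columns:
        raise ValueError(f"{signal} is not a measured column")
    if stimulus not in dataset.treatments.columns:
        raise ValueError(f"{stimulus} is not a treatment column")
    stim_on = dataset.treatments[stimulus].to_numpy() > 0
    obs = dataset.values[signal]
    held = obs[stim_on & obs.notna()]
    other = obs[~stim_on & obs.notna()]
    if held.empty or held.max() < activation_floor:
        raise ValueError(
            f"({signal}, {stimulus}) ineligible: signal not activated "
            f"(>= {activation_floor}) under the held-out stimulus")
    if other.empty or other.max() < activation_floor:
        raise ValueError(
            f"({signal}, {stimulus}) ineligible: signal not activated "
            f"(>= {activation_floor}) under any other stimulation condition")
    test_cells = [(int(i), signal) for i in obs.index[stim_on & obs.notna()]]
    train_ds = dataset.mask_cells(test_cells)
    fam = _train_and_filter(hs, train_ds, pipeline_config)
    scores = _ensemble_test_mse(fam, dataset, test_cells, pipeline_config.sim)
    return {
        "signal": signal,
        "stimulus": stimulus,
        "n_test_cells": len(test_cells),
        "training_mse": float(np.mean([m.mse for m in fam])),
        "test_mse": scores["test_mse"],
        "per_model_test_mse": scores["per_model_test_mse"],
        "mean_cv": scores["mean_cv"],
        "quadrant": classify_quadrant(scores["test_mse"], scores["mean_cv"],
                                      mse_cut, cv_cut),
    }


def _consensus_edges(ensemble: ModelEnsemble, frequency_cut: float) -> set:
    """Designated-node edges of gates above the frequency cut, obtained by
    projecting each frequent gate input through the compressed network."""
    hs = ensemble.hypothesis
    designated = hs.pkn.designated
    freqs = gate_frequencies(ensemble)
    edges = set()
    for (output, gi), f in freqs.items():
        if f <= frequency_cut:
            continue
        gate = hs.gates[output][gi]
        for node, sign in gate.inputs:
            if node in designated and output in designated:
                edges.add((node, output, sign))
    return edges


def topology_distance(ensemble_a: ModelEnsemble, ensemble_b: ModelEnsemble,
                      frequency_cut: float = 0.25) -> float:
    """Symmetric-difference fraction of the two consensus edge sets.

    The consensus set of a family is the designated-node projection of all
    gates present in more than ``frequency_cut`` of its models.
    """
    da = ensemble_a.hypothesis.pkn.designated
    db = ensemble_b.hypothesis.pkn.designated
    if not (da & db):
        raise ValueError("ensembles share no designated nodes")
    ea = _consensus_edges(ensemble_a, frequency_cut)
    eb = _consensus_edges(ensemble_b, frequency_cut)
    union = ea | eb
    if not union:
        return 0.0
    return len(ea ^ eb) / len(union)


def jarque_bera_statistic(sample: Sequence[float]) -> float:
    """JB = m/6 (S^2 + (K-3)^2 / 4) from sample skewness and kurtosis."""
    x = np.asarray(sample, dtype=float)
    m = len(x)
    s = stats.skew(x, bias=True)
    k = stats.kurtosis(x, fisher=False, bias=True)
    return float(m / 6.0 * (s**2 + (k - 3.0) ** 2 / 4.0))


def significance_vs_null(real_mses: Sequence[float],
                         null_mses: Sequence[float],
                         method: str = "auto",
                         jb_alpha: float = 0.001) -> List[float]:
    """One-sided p-values for real models against a null MSE distribution.

    ``zscore``: normal tail probability P(null <= real) from the null mean
    and sd.  ``empirical``: fraction of null MSEs <= the real MSE, reported
    as the conservative bound 1/len(null) when no null model scores as low.
    ``auto``: a Jarque-Bera normality check on the null sample selects the
    branch (normal at level ``jb_alpha`` -> zscore, else empirical).
    """
    null = np.asarray(null_mses, dtype=float)
    if null.size == 0:
        raise ValueError("null sample is empty")
    if method == "auto":
        jb = jarque_bera_statistic(null)
        p_norm = float(stats.chi2.sf(jb, df=2))
        method = "zscore" if p_norm >= jb_alpha else "empirical"
        logger.info("JB=%.3g (p=%.3g) -> %s branch", jb, p_norm, method)
    out = []
    if method == "zscore":
        mu, sd = null.mean(), null.std(ddof=0)
        if sd <= 1e-12 * max(abs(mu), 1e-30):  # constant null up to roundoff
            raise ValueError("degenerate null: zero standard deviation")
        for r in real_mses:
            out.append(float(stats.norm.cdf((r - mu) / sd)))
    elif method == "empirical":
        for r in real_mses:
            count = int((null <= r).sum())
            out.append(count / null.size if count else 1.0 / null.size)
    else:
        raise ValueError(f"unknown method {method!r}")
    return out
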