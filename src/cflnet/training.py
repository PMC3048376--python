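"""Discrete genetic-algorithm training of the hypothesis space.

Each genome assigns one allele in {0..7} to every transfer-function slot
(0 = absent, 1..7 = library member).  A generational GA with elitism,
tournament selection, uniform crossover and per-locus mutation minimizes
the model's mean squared error against the data.  Repeated independent
runs followed by removal of logically redundant gates yield a family of
*unprocessed* models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple, Union

import numpy as np

from .data import Dataset
from .model import CFLModel, ModelEnsemble
from .network import HypothesisSpace
from .simulate import SimConfig, compute_mse, simulate, simulate_model
from .transfer import ALPHABET_SIZE, LIBRARIES

logger = logging.getLogger(__name__)

__all__ = ["GAConfig", "decode", "fitness", "run_ga",
           "remove_redundant_gates", "train_family"]


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm hyperparameters.

    Defaults are standard small-alphabet GA settings sized to hypothesis
    spaces of a few tens to ~170 slots; ``mutation_rate`` None means one
    expected mutation per genome (1/h).
    """

    population_size: int = 50
    max_generations: int = 500
    stall_generations: int = 100
    elite_count: int = 2
    mutation_rate: Optional[float] = None
    tournament_size: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if not 0 <= self.elite_count < self.population_size:
            raise ValueError("elite_count must be < population_size")
        if self.mutation_rate is not None and not 0 < self.mutation_rate < 1:
            raise ValueError("mutation_rate must lie in (0, 1)")
        if self.tournament_size < 1:
            raise ValueError("tournament_size must be >= 1")


def decode(genome: np.ndarray, hs: HypothesisSpace) -> CFLModel:
    """Map an allele vector to a model: slot i -> library member genome[i]."""
    genome = np.asarray(genome, dtype=np.int64)
    if genome.shape != (hs.h,):
        raise ValueError(f"genome length {genome.shape} != slot count {hs.h}")
    if genome.min(initial=0) < 0 or genome.max(initial=0) >= ALPHABET_SIZE:
        raise ValueError("allele out of range 0..7")
    assignment = {}
    for allele, sid in zip(genome, hs.slots):
        lib = LIBRARIES[hs.slot_library[sid]]
        assignment[sid] = lib[int(allele)]
    return CFLModel(hs, assignment, stage="discrete")


def fitness(genome: np.ndarray, hs: HypothesisSpace, dataset: Dataset,
            sim_config: SimConfig = SimConfig()) -> float:
    """MSE of the decoded model against the dataset."""
    model = decode(genome, hs)
    return compute_mse(simulate_model(model, dataset, sim_config), dataset)


def run_ga(hs: HypothesisSpace, dataset: Dataset,
           ga_config: GAConfig = GAConfig(),
           sim_config: SimConfig = SimConfig()) -> CFLModel:
    """One seeded GA run; returns the best-ever model (stage ``discrete``).

    The returned model carries its MSE, seed and, as ``fitness_trace``, the
    best-so-far MSE per generation (monotone nonincreasing by elitism).
    """
    rng = np.random.default_rng(ga_config.seed)
    h = hs.h
    pop_size = ga_config.population_size
    mut_rate = ga_config.mutation_rate or (1.0 / max(h, 1))
    conditions = dataset.conditions()

    cache: dict = {}

    def score(genome: np.ndarray) -> float:
        key = genome.tobytes()
        if key not in cache:
            model = decode(genome, hs)
            cache[key] = compute_mse(simulate(model, conditions, sim_config),
                                     dataset)
        return cache[key]

    pop = rng.integers(0, ALPHABET_SIZE, size=(pop_size, h), dtype=np.int64)
    fits = np.array([score(g) for g in pop])
    best_idx = int(np.argmin(fits))
    best_genome, best_fit = pop[best_idx].copy(), float(fits[best_idx])
    trace = [best_fit]
    stall = 0
    for _ in range(ga_config.max_generations):
        order = np.argsort(fits, kind="stable")
        elites = pop[order[:ga_config.elite_count]]
        n_children = pop_size - ga_config.elite_count
        # tournament selection of parent pairs
        children = np.empty((n_children, h), dtype=np.int64)
        for i in range(n_children):
            parents = []
            for _ in range(2):
                contenders = rng.integers(0, pop_size, size=ga_config.tournament_size)
                parents.append(pop[contenders[np.argmin(fits[contenders])]])
            mask = rng.random(h) < 0.5
            child = np.where(mask, parents[0], parents[1])
            mut = rng.random(h) < mut_rate
            if mut.any():
                # mutate to a uniformly random *different* allele
                shift = rng.integers(1, ALPHABET_SIZE, size=int(mut.sum()))
                child = child.copy()
                child[mut] = (child[mut] + shift) % ALPHABET_SIZE
            children[i] = child
        pop = np.vstack([elites, children])
        fits = np.array([score(g) for g in pop])
        gen_best = int(np.argmin(fits))
        if fits[gen_best] < best_fit - 1e-12:
            best_fit = float(fits[gen_best])
            best_genome = pop[gen_best].copy()
            stall = 0
        else:
            stall += 1
        trace.append(best_fit)
        if stall >= ga_config.stall_generations:
            break
    model = decode(best_genome, hs)
    model.mse = best_fit
    model.seed = ga_config.seed
    model.data_fingerprint = dataset.fingerprint()
    model.fitness_trace = trace
    return model


def remove_redundant_gates(model: CFLModel, dataset: Optional[Dataset] = None,
                           sim_config: SimConfig = SimConfig()) -> CFLModel:
    """Deactivate AND gates subsumed by another gate of the same output.

    A gate whose (input, sign) set is a superset of another active gate's is
    logically redundant under OR combination — e.g. in "(B AND C) OR B",
    the AND term never exceeds the B term.  Applied to a fixed point; the
    result is stage ``unprocessed`` with its MSE recomputed when a dataset
    is supplied.
    """
    out = model.copy(stage="unprocessed")
    changed = True
    while changed:
        changed = False
        for output, gates in out.hypothesis.gates.items():
            active = [(gi, g) for gi, g in enumerate(gates)
                      if out.is_gate_active(output, gi)]
            for gi, g in active:
                gset = set(g.inputs)
                for gj, g2 in active:
                    if gj == gi or not out.is_gate_active(output, gj):
                        continue
                    if set(g2.inputs) < gset:
                        for sid in out.hypothesis.gate_slots(output, gi):
                            out.assignment[sid] = None
                        changed = True
                        break
    if dataset is not None:
        out.mse = compute_mse(simulate_model(out, dataset, sim_config), dataset)
        out.data_fingerprint = dataset.fingerprint()
    return out


def _derive_seeds(master_seed: int, n: int) -> list:
    ss = np.random.SeedSequence(master_seed)
    return [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(n)]


def train_family(hs: HypothesisSpace, dataset: Dataset,
                 ga_config: GAConfig = GAConfig(), n_runs: int = 20,
                 keep_rule: Union[str, Tuple[str, float]] = "all",
                 sim_config: SimConfig = SimConfig()) -> ModelEnsemble:
    """Run the GA ``n_runs`` times with derived seeds; return the family
    of unprocessed models surviving ``keep_rule``.

    keep rules: ``"all"``; ``"within_sd"`` keeps models with
    MSE <= mean + 1 sd of the family; ``("within_margin", x)`` keeps
    MSE <= best * (1 + x).
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    seeds = _derive_seeds(ga_config.seed, n_runs)
    models = []
    for s in seeds:
        cfg = GAConfig(ga_config.population_size, ga_config.max_generations,
                       ga_config.stall_generations, ga_config.elite_count,
                       ga_config.mutation_rate, ga_config.tournament_size,
                       seed=s)
        trained = run_ga(hs, dataset, cfg, sim_config)
        models.append(remove_redundant_gates(trained, dataset, sim_config))
    mses = np.array([m.mse for m in models])
    if keep_rule == "all":
        keep = np.ones(len(models), dtype=bool)
    elif keep_rule == "within_sd":
        keep = mses <= mses.mean() + mses.std(ddof=0)
    elif isinstance(keep_rule, tuple) and keep_rule[0] == "within_margin":
        keep = mses <= mses.min() * (1.0 + keep_rule[1])
    else:
        raise ValueError(f"unknown keep_rule {keep_rule!r}")
    kept = [m for m, k in zip(models, keep) if k]
    if not kept:
        raise ValueError("keep_rule eliminated every model")
    if len(kept) < len(models):
        logger.info("keep_rule %r retained %d of %d models",
                    keep_rule, len(kept), len(models))
    return ModelEnsemble(hs, kept)
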