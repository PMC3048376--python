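"""Shared fixtures: example networks, datasets, and small trained families."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")

from cflnet.data import Dataset, ExperimentalCondition
from cflnet.model import CFLModel, ModelEnsemble
from cflnet.network import PKN, compress, expand
from cflnet.synth import (example_dataset, example_ground_truth, example_pkn,
                          simulate_dataset)
from cflnet.training import GAConfig, remove_redundant_gates, run_ga
from cflnet.transfer import TransferFunctionSpec


# --- Boolean truth-table oracle -------------------------------------------
# Canonical Boolean reading of a signed digraph: every non-stimulus node is
# the OR over its incoming edges of the (sign-adjusted) source value;
# stimuli are the inputs; sources without inputs are False.

def boolean_truth_table(pkn: PKN):
    """Map each stimulus assignment to the designated nodes' Boolean values."""
    order = _topological(pkn)
    table = {}
    stimuli = sorted(pkn.stimuli)
    for bits in itertools.product([False, True], repeat=len(stimuli)):
        values = dict(zip(stimuli, bits))
        for node in order:
            if node in pkn.stimuli:
                continue
            ins = [(s, sign) for s, t, sign in pkn.edges if t == node]
            v = False
            for s, sign in ins:
                sv = values.get(s, False)
                v = v or (sv if sign == 1 else not sv)
            values[node] = v
        table[bits] = {n: values.get(n, False) for n in sorted(pkn.designated)}
    return table


def _topological(pkn: PKN):
    import networkx as nx
    g = nx.DiGraph()
    g.add_nodes_from(pkn.nodes)
    g.add_edges_from((s, t) for s, t, _ in pkn.edges)
    return list(nx.topological_sort(g))


def random_acyclic_pkn(rng, n_nodes=8, n_stimuli=2, n_designated=3,
                       inhib_frac=0.3) -> PKN:
    """Random signed DAG with random roles, for oracle-based properties."""
    names = [f"n{i}" for i in range(n_nodes)]
    edges = set()
    for j in range(n_stimuli, n_nodes):
        k = int(rng.integers(1, min(j, 3) + 1)) if j else 0
        for s in rng.choice(j, size=min(k, j), replace=False):
            sign = -1 if rng.random() < inhib_frac else 1
            edges.add((names[int(s)], names[j], sign))
    stimuli = frozenset(names[:n_stimuli])
    pool = [n for n in names[n_stimuli:]]
    designated = rng.choice(len(pool), size=min(n_designated, len(pool)),
                            replace=False)
    measured = frozenset(pool[int(i)] for i in designated)
    return PKN(frozenset(names), frozenset(edges), stimuli,
               frozenset(), measured)


# --- example toy ----------------------------------------------------------

@pytest.fixture(scope="session")
def toy_pkn():
    return example_pkn()


@pytest.fixture(scope="session")
def toy_hs(toy_pkn):
    return expand(compress(toy_pkn), "all_pairs")


@pytest.fixture(scope="session")
def toy_truth(toy_hs):
    return example_ground_truth(toy_hs)


@pytest.fixture(scope="session")
def toy_dataset():
    return example_dataset()


# --- tiny chain network for fast unit tests --------------------------------

@pytest.fixture(scope="session")
def chain_setup():
    """S -> A -> B plus a spurious S -> B edge; off-grid generating k."""
    pkn = PKN(frozenset({"S", "A", "B"}),
              frozenset({("S", "A", 1), ("A", "B", 1), ("S", "B", 1)}),
              stimuli=frozenset({"S"}), measured=frozenset({"A", "B"}))
    hs = expand(compress(pkn))
    truth = CFLModel(hs, {
        "A|0|S": TransferFunctionSpec("linear", slope=0.8),
        "B|0|A": TransferFunctionSpec("hill", n=3.0, k=0.45),
    }, stage="discrete")
    conditions = [ExperimentalCondition({"S": v}, {})
                  for v in (0.0, 0.25, 0.5, 0.75, 1.0)]
    dataset = simulate_dataset(truth, conditions)
    return pkn, hs, truth, dataset


@pytest.fixture(scope="session")
def toy_family(toy_hs, toy_dataset):
    """Small trained family on the example toy (3 runs, modest GA budget)."""
    cfg = GAConfig(population_size=30, max_generations=120,
                   stall_generations=30, seed=11)
    models = []
    for seed in (11, 12, 13):
        m = run_ga(toy_hs, toy_dataset,
                   GAConfig(population_size=30, max_generations=120,
                            stall_generations=30, seed=seed))
        models.append(remove_redundant_gates(m, toy_dataset))
    return ModelEnsemble(toy_hs, models)
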