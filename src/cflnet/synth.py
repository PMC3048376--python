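"""Synthetic benchmarks: networks, ground-truth models, in-silico data, nulls.

Everything the training workflow consumes can be generated here with a
seed: random signed DAGs with experimental roles, ground-truth quantitative
logic models (on or off the discrete library grid), simulated datasets with
optional truncated-Gaussian noise, and the null controls used for
significance testing — value-permuted data, degree-preserving network
randomizations, and edge removal/addition perturbations.

The module also ships a hand-authored 15-node example network
(:func:`example_pkn`) emulating a growth-factor / inflammatory signaling
toy: two stimuli, two druggable kinases, six measured readouts, and a
branch that is only *partially* activated by one stimulus — the situation
where graded (fuzzy) logic recovers a topology that Boolean logic misses.
The example is synthetic: structurally inspired by classic toy networks of
this kind, not a transcription of any published map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .data import Dataset, ExperimentalCondition, full_factorial_design
from .model import CFLModel
from .network import PKN, HypothesisSpace, compress, expand
from .simulate import SimConfig, simulate
from .transfer import LIBRARIES, TransferFunctionSpec

logger = logging.getLogger(__name__)

__all__ = ["GeneratorConfig", "make_toy_pkn", "make_ground_truth_model",
           "simulate_dataset", "randomize_data", "randomize_network",
           "perturb_pkn", "perturb_pkn_batch",
           "example_pkn", "example_ground_truth", "example_dataset"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the random network/data generator.

    Defaults emulate a 15-species toy: two stimuli, two inhibitable
    kinases, six measured readouts, mildly sparse wiring with ~20%
    inhibitory edges, noise off.
    """

    node_count: int = 15
    stimulus_count: int = 2
    inhibitor_count: int = 2
    measured_count: int = 6
    edge_density: float = 0.18
    inhibitory_fraction: float = 0.2
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stimulus_count + self.inhibitor_count + self.measured_count \
                > self.node_count:
            raise ValueError("role counts exceed node_count")
        if self.stimulus_count < 1:
            raise ValueError("need at least one stimulus")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 < self.edge_density <= 1:
            raise ValueError("edge_density must lie in (0, 1]")


def make_toy_pkn(config: GeneratorConfig = GeneratorConfig()) -> PKN:
    """Random signed DAG with designated roles.

    Stimuli come first in the topological order and have no incoming
    edges; every other node draws at least one edge from an earlier node,
    which guarantees reachability from some stimulus.  Same seed, same
    network.
    """
    rng = np.random.default_rng(config.seed)
    n = config.node_count
    stimuli = [f"S{i+1}" for i in range(config.stimulus_count)]
    others = [f"N{i+1}" for i in range(n - config.stimulus_count)]
    order = stimuli + others
    edges = set()
    for pos in range(config.stimulus_count, n):
        node = order[pos]
        max_in = min(pos, 3)
        k = 1 + rng.binomial(max_in - 1, config.edge_density) if max_in > 1 else 1
        sources = rng.choice(pos, size=k, replace=False)
        for s in sources:
            sign = -1 if rng.random() < config.inhibitory_fraction else 1
            edges.add((order[int(s)], node, sign))
    # every stimulus needs at least one outgoing edge
    for i, stim in enumerate(stimuli):
        if not any(e[0] == stim for e in edges):
            target = others[int(rng.integers(len(others)))]
            edges.add((stim, target, 1))
    # roles: inhibited from upstream half of the non-stimulus nodes,
    # measured from the remainder (downstream-biased)
    non_stim = [o for o in others]
    inhibited = non_stim[:config.inhibitor_count]
    pool = [o for o in non_stim if o not in inhibited]
    measured = pool[-config.measured_count:]
    return PKN(frozenset(order), frozenset(edges),
               frozenset(stimuli), frozenset(inhibited), frozenset(measured))


def _off_grid_value(rng, lo: float, hi: float, grid: Sequence[float]) -> float:
    for _ in range(100):
        v = float(rng.uniform(lo, hi))
        if all(abs(v - g) > 1e-3 for g in grid):
            return v
    return v  # pragma: no cover


def make_ground_truth_model(pkn: PKN, seed: int = 0, off_grid: bool = False,
                            mode: str = "all_pairs",
                            hs: Optional[HypothesisSpace] = None) -> CFLModel:
    """Pick a generating model inside (or near) the hypothesis space.

    The PKN is compressed and expanded (unless an expanded space is
    supplied); each output node receives one gate, preferring 1-input
    activating gates so every measured branch can actually be driven.
    On-grid models draw library members; ``off_grid`` draws Hill k
    uniformly in [0.15, 0.75] and slopes in [0.2, 0.8] away from the
    discrete grid.
    """
    rng = np.random.default_rng(seed)
    if hs is None:
        hs = expand(compress(pkn), mode)
    assignment = {sid: None for sid in hs.slots}
    hill_grid = [0.2, 0.3, 0.4, 0.5, 0.6, 0.7]
    slope_grid = [0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8]
    for output in sorted(hs.gates):
        gates = hs.gates[output]
        simple_activating = [gi for gi, g in enumerate(gates)
                             if g.arity == 1 and g.inputs[0][1] == 1]
        if simple_activating:
            gi = int(rng.choice(simple_activating))
        else:
            gi = int(rng.integers(len(gates)))
        for sid in hs.gate_slots(output, gi):
            lib = LIBRARIES[hs.slot_library[sid]]
            if off_grid:
                if hs.slot_library[sid] == "hill":
                    k = _off_grid_value(rng, 0.15, 0.75, hill_grid)
                    assignment[sid] = TransferFunctionSpec("hill", n=3.0, k=k)
                else:
                    slope = _off_grid_value(rng, 0.2, 0.8, slope_grid)
                    assignment[sid] = TransferFunctionSpec("linear", slope=slope)
            else:
                assignment[sid] = lib[int(rng.integers(1, len(lib)))]
    model = CFLModel(hs, assignment, stage="discrete")
    model.seed = seed
    return model


def simulate_dataset(model: CFLModel,
                     design: Union[Dataset, Sequence[ExperimentalCondition]],
                     noise_sd: float = 0.0, seed: int = 0,
                     sim_config: SimConfig = SimConfig()) -> Dataset:
    """In-silico dataset: simulated measured-node activities plus optional
    truncated-Gaussian noise clipped to [0, 1]."""
    pkn = model.hypothesis.pkn
    measured = sorted(pkn.measured)
    if isinstance(design, Dataset):
        base = design
        conditions = design.conditions()
    else:
        conditions = list(design)
        stim_cols = sorted({n for c in conditions for n in c.stimuli})
        inhib_cols = sorted({n for c in conditions for n in c.inhibitors})
        base = Dataset(
            pd.DataFrame([[c.stimuli.get(s, 0.0) for s in stim_cols]
                          for c in conditions], columns=stim_cols, dtype=float),
            pd.DataFrame([[c.inhibitors.get(s, 0) for s in inhib_cols]
                          for c in conditions], columns=inhib_cols, dtype=int),
            pd.DataFrame(index=range(len(conditions)), dtype=float),
        )
    res = simulate(model, conditions, sim_config)
    bad = np.flatnonzero(~res.converged)
    if bad.size:
        raise ValueError(f"generating model failed to converge on "
                         f"condition(s) {bad.tolist()}")
    rows = [res.node_order.index(m) for m in measured]
    values = res.x[rows, :].T.copy()
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = np.clip(values + rng.normal(0.0, noise_sd, values.shape),
                         0.0, 1.0)
    return base.with_values(
        pd.DataFrame(values, columns=measured, index=range(len(conditions))))


def randomize_data(dataset: Dataset, seed: int = 0) -> Dataset:
    """Permute the non-missing observed values across cells (a seeded
    sequence of pairwise exchanges); positions and missingness stay put."""
    vals = dataset.values.copy()
    arr = vals.to_numpy()
    flat = arr.ravel()
    idx = np.flatnonzero(~np.isnan(flat))
    if idx.size < 2:
        logger.warning("fewer than 2 observed cells; randomization is a no-op")
        return dataset.with_values(vals)
    rng = np.random.default_rng(seed)
    flat[idx] = flat[idx][rng.permutation(idx.size)]
    return dataset.with_values(
        pd.DataFrame(flat.reshape(arr.shape), columns=vals.columns))


def randomize_network(pkn: PKN, method: str, seed: int = 0) -> PKN:
    """Topology null models.

    ``swap_heads`` permutes edge sources across edges (signs travel with
    the moved source); ``swap_tails`` permutes targets likewise;
    ``swap_inputs`` repeatedly exchanges the complete input sets of two
    output nodes; ``fully_random`` redraws a graph with the same node and
    edge counts in which stimuli have no incoming and at least one outgoing
    edge and every node touches at least one edge.
    """
    if len(pkn.edges) < 2:
        raise ValueError("need at least 2 edges to randomize")
    rng = np.random.default_rng(seed)
    edges = sorted(pkn.edges)

    def rebuild(new_edges) -> PKN:
        return PKN(pkn.nodes, frozenset(new_edges), pkn.stimuli,
                   pkn.inhibited, pkn.measured)

    if method in ("swap_heads", "swap_tails"):
        for _ in range(200):
            perm = rng.permutation(len(edges))
            if method == "swap_heads":
                new = [(edges[p][0], edges[i][1], edges[p][2])
                       for i, p in enumerate(perm)]
            else:
                new = [(edges[i][0], edges[p][1], edges[p][2])
                       for i, p in enumerate(perm)]
            new = [(s, t, sign) for s, t, sign in new]
            if len(set(new)) == len(edges) and all(s != t for s, t, _ in new):
                return rebuild(new)
        raise ValueError(f"could not find a duplicate-free {method} permutation")

    if method == "swap_inputs":
        edge_set = {e for e in edges}
        outputs = sorted({t for _, t, _ in edge_set})
        for _ in range(max(len(outputs), 2)):
            a, b = rng.choice(len(outputs), size=2, replace=False)
            na, nb = outputs[int(a)], outputs[int(b)]
            ins_a = {e for e in edge_set if e[1] == na}
            ins_b = {e for e in edge_set if e[1] == nb}
            moved = {(s, nb, sign) for s, _, sign in ins_a if s != nb} | \
                    {(s, na, sign) for s, _, sign in ins_b if s != na}
            edge_set = (edge_set - ins_a - ins_b) | moved
        return rebuild(edge_set)

    if method == "fully_random":
        n_edges = len(edges)
        signs = [e[2] for e in edges]
        nodes = sorted(pkn.nodes)
        targets_pool = [x for x in nodes if x not in pkn.stimuli]
        for _ in range(500):
            rng.shuffle(signs)
            new: set = set()
            # each stimulus: at least one outgoing edge
            for stim in sorted(pkn.stimuli):
                t = targets_pool[int(rng.integers(len(targets_pool)))]
                new.add((stim, t))
            # each non-stimulus node: at least one incident edge
            for node in targets_pool:
                if not any(node in (s, t) for s, t in new):
                    choices = [x for x in nodes if x != node]
                    s = choices[int(rng.integers(len(choices)))]
                    new.add((s, node))
            while len(new) < n_edges:
                s = nodes[int(rng.integers(len(nodes)))]
                t = targets_pool[int(rng.integers(len(targets_pool)))]
                if s != t:
                    new.add((s, t))
            if len(new) != n_edges:
                continue
            signed = [(s, t, signs[i]) for i, (s, t) in enumerate(sorted(new))]
            return rebuild(signed)
        raise ValueError("fully_random: constraints unsatisfiable after retries")

    raise ValueError(f"unknown randomization method {method!r}")


def perturb_pkn(pkn: PKN, fraction: float, operation: str, seed: int = 0) -> PKN:
    """Randomly remove or add ``round(fraction * |edges|)`` edges."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    edges = sorted(pkn.edges)
    count = int(round(fraction * len(edges)))
    if operation == "remove":
        drop = set(rng.choice(len(edges), size=count, replace=False).tolist())
        kept = [e for i, e in enumerate(edges) if i not in drop]
        return PKN(pkn.nodes, frozenset(kept), pkn.stimuli, pkn.inhibited,
                   pkn.measured)
    if operation == "add":
        nodes = sorted(pkn.nodes)
        targets = [x for x in nodes if x not in pkn.stimuli]
        existing = set(edges)
        added = set()
        inhib_frac = (sum(1 for e in edges if e[2] == -1) / len(edges)
                      if edges else 0.2)
        for _ in range(10000):
            if len(added) >= count:
                break
            s = nodes[int(rng.integers(len(nodes)))]
            t = targets[int(rng.integers(len(targets)))]
            sign = -1 if rng.random() < inhib_frac else 1
            e = (s, t, sign)
            if s != t and e not in existing and e not in added:
                added.add(e)
        if len(added) < count:
            raise ValueError("could not place the requested number of new edges")
        return PKN(pkn.nodes, frozenset(edges) | added, pkn.stimuli,
                   pkn.inhibited, pkn.measured)
    raise ValueError(f"unknown operation {operation!r}")


def perturb_pkn_batch(pkn: PKN, fraction: float, operation: str,
                      n: int = 90, seed: int = 0) -> List[PKN]:
    """A batch of independently perturbed networks (one per derived seed)."""
    ss = np.random.SeedSequence(seed)
    return [perturb_pkn(pkn, fraction, operation,
                        int(c.generate_state(1)[0] % (2**31)))
            for c in ss.spawn(n)]


# ---------------------------------------------------------------------------
# hand-authored example (synthetic, inspired-by not identical-to classic toys)

def example_pkn() -> PKN:
    """15-node synthetic signaling toy with a partially activated branch.

    Two stimuli (TGFA, TNFA), two inhibitable kinases (PI3K, MEK), six
    measured readouts (ERK, AKT, JNK, P38, IKB, GSK3) and intermediate
    transducers that compression removes.
    """
    edges = {
        ("TGFA", "RAS", 1), ("RAS", "MEK", 1), ("MEK", "ERK", 1),
        ("TGFA", "PI3K", 1), ("PI3K", "AKT", 1), ("PI3K", "JNK", 1),
        ("AKT", "GSK3", -1),
        ("TNFA", "TRAF2", 1), ("TRAF2", "MAP3K1", 1), ("TRAF2", "MAP3K7", 1),
        ("MAP3K7", "P38", 1), ("MAP3K1", "JNK", 1), ("MAP3K1", "IKK", 1),
        ("IKK", "IKB", -1),
    }
    nodes = {n for e in edges for n in (e[0], e[1])}
    return PKN(frozenset(nodes), frozenset(edges),
               stimuli=frozenset({"TGFA", "TNFA"}),
               inhibited=frozenset({"PI3K", "MEK"}),
               measured=frozenset({"ERK", "AKT", "JNK", "P38", "IKB", "GSK3"}))


def example_ground_truth(hs: Optional[HypothesisSpace] = None) -> CFLModel:
    """Generating model on the compressed+expanded example network.

    TGFA only partially activates the PI3K branch (linear slope 0.3), so
    AKT sits near 0.3 and JNK near 0.2 under TGFA stimulation — graded
    activities a Boolean model cannot fit without dropping the branch.
    """
    if hs is None:
        hs = expand(compress(example_pkn()), "all_pairs")
    lin, hill = LIBRARIES["linear"], LIBRARIES["hill"]
    picks = {
        "MEK|0|TGFA": lin[6],      # slope 0.7
        "PI3K|0|TGFA": lin[2],     # slope 0.3: the partially activated branch
        "ERK|0|MEK": hill[3],      # n=3, k=0.3
        "AKT|0|PI3K": hill[1],     # approximately linear
        "JNK|0|PI3K": hill[5],     # n=3, k=0.5 -> ~0.2 at input 0.3
        "JNK|1|TNFA": lin[6],
        "P38|0|TNFA": lin[5],
        "IKB|0|TNFA": lin[6],
        "GSK3|0|AKT": hill[4],
    }
    assignment = {sid: picks.get(sid) for sid in hs.slots}
    model = CFLModel(hs, assignment, stage="discrete")
    model.seed = 0
    return model


def example_dataset(noise_sd: float = 0.0, seed: int = 0) -> Dataset:
    """Full-factorial in-silico dataset from the example ground truth:
    2 stimuli on/off x 2 inhibitors +/- = 16 conditions."""
    model = example_ground_truth()
    pkn = model.hypothesis.pkn
    design = full_factorial_design(sorted(pkn.stimuli), sorted(pkn.inhibited))
    return simulate_dataset(model, design, noise_sd=noise_sd, seed=seed)
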