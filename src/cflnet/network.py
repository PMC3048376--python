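"""Prior knowledge networks: roles, compression, and hypothesis-space expansion.

A prior knowledge network (PKN) is a signed directed graph of molecular
interactions.  Before training it is (1) *compressed* so that only nodes
that are measured, perturbed, or required for logical consistency remain,
and (2) *expanded* into a hypothesis space of candidate logic gates — one
1-input gate per remaining edge plus 2-input AND gates — each gate input
carrying one discrete transfer-function slot.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Tuple

import networkx as nx

from .transfer import ALPHABET_SIZE

logger = logging.getLogger(__name__)

__all__ = [
    "PKN",
    "CandidateGate",
    "HypothesisSpace",
    "designate_roles",
    "compress",
    "expand",
    "count_search_space",
]

Edge = Tuple[str, str, int]  # (source, target, sign)


@dataclass(frozen=True)
class PKN:
    """Signed directed graph with experimental role flags.

    Roles: *stimulus* nodes are set by the experimental treatment,
    *inhibited* nodes can be clamped off by a small-molecule inhibitor,
    *measured* nodes carry observations; everything else is *intermediate*.
    A node may hold several roles (a measured stimulus, an inhibited
    measured kinase, ...).
    """

    nodes: FrozenSet[str]
    edges: FrozenSet[Edge]
    stimuli: FrozenSet[str] = frozenset()
    inhibited: FrozenSet[str] = frozenset()
    measured: FrozenSet[str] = frozenset()

    def __post_init__(self) -> None:
        for s, t, sign in self.edges:
            if sign not in (1, -1):
                raise ValueError(f"edge ({s},{t}) has sign {sign}, must be +1/-1")
            if s not in self.nodes or t not in self.nodes:
                raise ValueError(f"edge ({s},{t}) references unknown node")
        for role_set, name in ((self.stimuli, "stimulus"),
                               (self.inhibited, "inhibited"),
                               (self.measured, "measured")):
            missing = role_set - self.nodes
            if missing:
                raise ValueError(f"{name} nodes not in PKN: {sorted(missing)}")

    @property
    def designated(self) -> FrozenSet[str]:
        """Nodes carrying at least one experimental role."""
        return self.stimuli | self.inhibited | self.measured

    @property
    def intermediate(self) -> FrozenSet[str]:
        return self.nodes - self.designated

    def in_edges(self, node: str) -> List[Edge]:
        return sorted(e for e in self.edges if e[1] == node)

    def out_edges(self, node: str) -> List[Edge]:
        return sorted(e for e in self.edges if e[0] == node)

    def to_networkx(self) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph()
        g.add_nodes_from(sorted(self.nodes))
        for s, t, sign in sorted(self.edges):
            g.add_edge(s, t, sign=sign)
        return g

    def with_roles(self, stimuli, inhibited, measured) -> "PKN":
        return PKN(self.nodes, self.edges,
                   frozenset(stimuli), frozenset(inhibited), frozenset(measured))


@dataclass(frozen=True)
class CandidateGate:
    """One candidate logic gate: an AND over its (distinct) signed inputs.

    A single-input gate is the degenerate AND.  Within a model the gates of
    one output node are combined by OR.
    """

    output: str
    inputs: Tuple[Tuple[str, int], ...]

    def __post_init__(self) -> None:
        if len(self.inputs) < 1:
            raise ValueError("gate needs at least one input")
        names = [n for n, _ in self.inputs]
        if len(set(names)) != len(names):
            raise ValueError(f"gate inputs must be distinct nodes: {names}")
        for _, sign in self.inputs:
            if sign not in (1, -1):
                raise ValueError("gate input sign must be +1/-1")

    @property
    def arity(self) -> int:
        return len(self.inputs)

    def describe(self) -> str:
        parts = []
        for name, sign in self.inputs:
            parts.append(name if sign == 1 else f"NOT {name}")
        return f"{' AND '.join(parts)} -> {self.output}"


def _slot_id(output: str, gate_index: int, input_node: str) -> str:
    return f"{output}|{gate_index}|{input_node}"


@dataclass
class HypothesisSpace:
    """Expanded candidate gate set with one transfer-function slot per input.

    ``w`` is the number of candidate gates, ``h`` the number of slots
    (h >= w, equal iff all gates have one input).  Each slot draws from an
    8-state alphabet (absent + 7 library transfer functions); slots whose
    input is a stimulus node use the linear library, all others the Hill
    library.  The discrete search space therefore has 8^h points.
    """

    pkn: PKN
    gates: Dict[str, Tuple[CandidateGate, ...]]
    mode: str = "all_pairs"
    slots: Tuple[str, ...] = field(init=False)
    slot_library: Dict[str, str] = field(init=False)

    def __post_init__(self) -> None:
        slots: List[str] = []
        library: Dict[str, str] = {}
        for output in sorted(self.gates):
            for gi, gate in enumerate(self.gates[output]):
                for input_node, _ in gate.inputs:
                    sid = _slot_id(output, gi, input_node)
                    slots.append(sid)
                    library[sid] = ("linear" if input_node in self.pkn.stimuli
                                    else "hill")
        self.slots = tuple(slots)
        self.slot_library = library

    @property
    def w(self) -> int:
        return sum(len(v) for v in self.gates.values())

    @property
    def h(self) -> int:
        return len(self.slots)

    @property
    def alphabet_size(self) -> int:
        return ALPHABET_SIZE

    def gate_list(self) -> List[Tuple[str, int, CandidateGate]]:
        """All gates as (output, gate_index, gate), in slot order."""
        out = []
        for output in sorted(self.gates):
            for gi, gate in enumerate(self.gates[output]):
                out.append((output, gi, gate))
        return out

    def gate_slots(self, output: str, gate_index: int) -> List[str]:
        gate = self.gates[output][gate_index]
        return [_slot_id(output, gate_index, n) for n, _ in gate.inputs]

    def slot_index(self, sid: str) -> int:
        return self.slots.index(sid)


def designate_roles(pkn: PKN, dataset) -> PKN:
    """Flag PKN nodes with the roles implied by a dataset's columns."""
    stimuli = set(dataset.treatments.columns)
    inhibited = set(dataset.inhibitors.columns)
    measured = set(dataset.values.columns)
    unmatched = sorted((stimuli | inhibited | measured) - pkn.nodes)
    if unmatched:
        raise ValueError(
            f"dataset columns with no matching PKN node: {unmatched}")
    return pkn.with_roles(stimuli, inhibited, measured)


def _on_cycle(node: str, edges: FrozenSet[Edge]) -> bool:
    g = nx.DiGraph()
    g.add_edges_from((s, t) for s, t, _ in edges)
    if node not in g:
        return False
    if g.has_edge(node, node):
        return True
    for comp in nx.strongly_connected_components(g):
        if node in comp:
            return len(comp) > 1
    return False


def compress(pkn: PKN) -> PKN:
    """Remove intermediate nodes that do not alter input-output logic.

    An intermediate node is spliced out — each (upstream, downstream) edge
    pair replaced by a direct edge whose sign is the product of the two —
    when it has a single incoming edge, or a single outgoing *positive*
    edge.  A multi-input node with one negative out-edge is retained: under
    OR semantics NOT(A OR B) is not (NOT A) OR (NOT B), so splicing there
    would change the truth table.  Nodes with no inputs or no outputs are
    dropped outright.  Intermediates lying on cycles are conservatively
    retained.  Self-loops created by splicing are discarded; the process
    iterates to a fixed point.
    """
    nodes = set(pkn.nodes)
    edges = set(pkn.edges)
    changed = True
    while changed:
        changed = False
        for node in sorted(nodes):
            if node in pkn.designated:
                continue
            ins = [e for e in edges if e[1] == node and e[0] != node]
            outs = [e for e in edges if e[0] == node and e[1] != node]
            if _on_cycle(node, frozenset(edges)):
                continue
            removable = (
                len(outs) == 0
                # a source intermediate is stuck at 0; dropping it is only
                # neutral when none of its out-edges is inverting
                or (len(ins) == 0 and all(s == 1 for _, _, s in outs))
                or len(ins) == 1
                or (len(outs) == 1 and outs[0][2] == 1)
            )
            if not removable:
                continue
            for (u, _, s_in), (_, w, s_out) in itertools.product(ins, outs):
                if u != w:
                    edges.add((u, w, s_in * s_out))
            edges -= {e for e in edges if e[0] == node or e[1] == node}
            nodes.discard(node)
            changed = True
    return PKN(frozenset(nodes), frozenset(edges),
               pkn.stimuli, pkn.inhibited, pkn.measured)


def expand(pkn: PKN, mode: str = "all_pairs") -> HypothesisSpace:
    """Expand a compressed PKN into candidate gates.

    ``all_pairs``: one 1-input gate per edge (activating or inhibitory) and
    one 2-input AND gate per unordered pair of distinct-source edges into
    the same output.

    ``inhibitory_only``: one 1-input gate per *activating* edge, no
    standalone inhibitory gates, and one "A AND NOT B" gate per
    (activating, inhibitory) pair — an inhibition is only meaningful in
    conjunction with an activation unless the output is constitutively
    active.
    """
    if mode not in ("all_pairs", "inhibitory_only"):
        raise ValueError(f"unknown expansion mode {mode!r}")
    gates: Dict[str, Tuple[CandidateGate, ...]] = {}
    for output in sorted(pkn.nodes):
        incoming = [(s, sign) for s, t, sign in sorted(pkn.edges) if t == output]
        if not incoming:
            continue
        out_gates: List[CandidateGate] = []
        if mode == "all_pairs":
            for s, sign in incoming:
                out_gates.append(CandidateGate(output, ((s, sign),)))
            for (a, sa), (b, sb) in itertools.combinations(incoming, 2):
                if a == b:
                    continue
                out_gates.append(CandidateGate(output, ((a, sa), (b, sb))))
        else:
            activating = [(s, sign) for s, sign in incoming if sign == 1]
            inhibitory = [(s, sign) for s, sign in incoming if sign == -1]
            for s, sign in activating:
                out_gates.append(CandidateGate(output, ((s, sign),)))
            for (a, sa), (b, sb) in itertools.product(activating, inhibitory):
                if a == b:
                    continue
                out_gates.append(CandidateGate(output, ((a, sa), (b, sb))))
            if inhibitory and not activating:
                logger.warning(
                    "node %s has only inhibitory inputs; no candidate gates "
                    "under inhibitory_only expansion", output)
        if out_gates:
            gates[output] = tuple(out_gates)
    return HypothesisSpace(pkn=pkn, gates=gates, mode=mode)


def count_search_space(hs: HypothesisSpace) -> Tuple[int, int, int]:
    """Return (gate count w, slot count h, per-slot alphabet size 1+a).

    The discrete optimization problem has (1+a)^h points.
    """
    return hs.w, hs.h, hs.alphabet_size
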