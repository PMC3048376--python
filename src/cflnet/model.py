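"""Quantitative logic models and model ensembles.

A model is an assignment of each hypothesis-space slot to a transfer
function or to "absent".  A gate is active iff none of its slots is absent;
an AND gate with any absent slot is wholly inactive, keeping the
genome <-> topology map unambiguous.  Models carry a workflow stage tag
(discrete -> unprocessed -> reduced -> reduced_refined -> filtered), their
mean squared error against a fingerprinted dataset, and seed provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .network import CandidateGate, HypothesisSpace
from .transfer import TransferFunctionSpec

__all__ = ["CFLModel", "ModelEnsemble", "STAGES"]

STAGES = ("discrete", "unprocessed", "reduced", "reduced_refined", "filtered")


@dataclass
class CFLModel:
    hypothesis: HypothesisSpace
    assignment: Dict[str, Optional[TransferFunctionSpec]]
    stage: str = "discrete"
    mse: Optional[float] = None
    seed: Optional[int] = None
    data_fingerprint: Optional[str] = None

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        unknown = set(self.assignment) - set(self.hypothesis.slots)
        if unknown:
            raise ValueError(f"assignment references unknown slots: {sorted(unknown)}")
        for sid in self.hypothesis.slots:
            self.assignment.setdefault(sid, None)

    def is_gate_active(self, output: str, gate_index: int) -> bool:
        """Active iff none of the gate's slots is absent."""
        return all(self.assignment[sid] is not None
                   for sid in self.hypothesis.gate_slots(output, gate_index))

    def active_gates(self) -> List[Tuple[str, int, CandidateGate]]:
        return [(o, gi, g) for o, gi, g in self.hypothesis.gate_list()
                if self.is_gate_active(o, gi)]

    @property
    def parameter_count(self) -> int:
        """Fitted parameters over active gates: 2 per Hill slot, 1 per linear."""
        total = 0
        for output, gi, _ in self.active_gates():
            for sid in self.hypothesis.gate_slots(output, gi):
                total += self.assignment[sid].parameter_count
        return total

    def genome(self) -> np.ndarray:
        """Discrete allele vector; requires every spec to carry a library index."""
        alleles = np.zeros(self.hypothesis.h, dtype=np.int64)
        for i, sid in enumerate(self.hypothesis.slots):
            spec = self.assignment[sid]
            if spec is None:
                alleles[i] = 0
            elif spec.discrete_index is None:
                raise ValueError(f"slot {sid} holds an off-library spec; "
                                 "no genome representation")
            else:
                alleles[i] = spec.discrete_index
        return alleles

    def copy(self, **changes) -> "CFLModel":
        new = CFLModel(self.hypothesis, dict(self.assignment), self.stage,
                       self.mse, self.seed, self.data_fingerprint)
        for k, v in changes.items():
            setattr(new, k, v)
        return new


@dataclass
class ModelEnsemble:
    """A family of models sharing one hypothesis space."""

    hypothesis: HypothesisSpace
    models: List[CFLModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        for m in self.models:
            if m.hypothesis is not self.hypothesis:
                if m.hypothesis.slots != self.hypothesis.slots:
                    raise ValueError("ensemble models must share one hypothesis space")

    def __len__(self) -> int:
        return len(self.models)

    def __iter__(self):
        return iter(self.models)

    @property
    def stage(self) -> Optional[str]:
        stages = {m.stage for m in self.models}
        return stages.pop() if len(stages) == 1 else None

    def mses(self) -> List[float]:
        return [m.mse for m in self.models]
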