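"""Transfer functions for constrained fuzzy logic gates.

Every edge of a trained logic model carries a quantitative input->output map.
Two families are used:

* a *normalized Hill* function  f(x) = x^n (1 + k^n) / (x^n + k^n), which
  satisfies f(0) = 0 and f(1) = 1 for any Hill coefficient ``n`` and
  midpoint ``k`` (the EC50 of the dose-response curve), and
* a *linear* map f(x) = slope * x with zero intercept, used for edges whose
  source is an experimental stimulus (stimuli enter the model at saturating
  0/1 levels, where a normalized Hill function would collapse to Boolean
  behaviour).

During the discrete training phase each edge is restricted to a small
library of transfer functions plus the "absent" state, giving 8 states per
slot: absent, an approximately linear Hill member (n = 1.01, k = 68.5098)
and six sigmoidal members (n = 3, k in 0.2 .. 0.7) for ordinary edges, or
absent plus seven slopes (0.2 .. 0.8) for stimulus edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "TransferFunctionSpec",
    "HILL_LIBRARY",
    "LINEAR_LIBRARY",
    "LIBRARIES",
    "ALPHABET_SIZE",
    "hill_tf",
    "linear_tf",
    "apply_edge_tf",
    "gate_sensitivity",
]


@dataclass(frozen=True)
class TransferFunctionSpec:
    """One edge's quantitative input->output map.

    Exactly the fields of the declared family are set: Hill specs carry
    ``n`` and ``k``; linear specs carry ``slope``.  ``discrete_index``
    records the library member (1..7) a discrete-phase spec came from and
    is dropped once parameters are refined continuously.
    """

    family: str
    n: Optional[float] = None
    k: Optional[float] = None
    slope: Optional[float] = None
    discrete_index: Optional[int] = None

    def __post_init__(self) -> None:
        if self.family == "hill":
            if self.n is None or self.k is None or self.slope is not None:
                raise ValueError("hill spec requires n and k only")
            if self.n < 1:
                raise ValueError(f"Hill coefficient n must be >= 1, got {self.n}")
            if self.k <= 0:
                raise ValueError(f"Hill midpoint k must be > 0, got {self.k}")
        elif self.family == "linear":
            if self.slope is None or self.n is not None or self.k is not None:
                raise ValueError("linear spec requires slope only")
            if not 0.0 <= self.slope <= 1.0:
                raise ValueError(f"slope must lie in [0, 1], got {self.slope}")
        else:
            raise ValueError(f"unknown transfer-function family {self.family!r}")

    @property
    def parameter_count(self) -> int:
        """Number of fitted parameters: 2 for Hill (n, k), 1 for linear."""
        return 2 if self.family == "hill" else 1

    def evaluate(self, x):
        if self.family == "hill":
            return hill_tf(x, self.n, self.k)
        return linear_tf(x, self.slope)


def _check_unit_interval(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError(f"{name} must lie in [0, 1]")
    return arr


def hill_tf(x, n: float, k: float):
    """Normalized Hill function x^n (1 + k^n) / (x^n + k^n).

    Monotone nondecreasing in ``x`` with the exact anchors f(0) = 0 and
    f(1) = 1; ``k`` is the midpoint (EC50) and ``n`` the sharpness.
    Accepts scalars or arrays; values outside [0, 1] raise.
    """
    if n < 1:
        raise ValueError(f"Hill coefficient n must be >= 1, got {n}")
    if k <= 0:
        raise ValueError(f"Hill midpoint k must be > 0, got {k}")
    arr = _check_unit_interval(x, "x")
    xn = np.power(arr, n)
    kn = k**n
    out = xn * (1.0 + kn) / (xn + kn)
    return float(out) if np.isscalar(x) else out


def linear_tf(x, slope: float):
    """Linear transfer function slope * x with zero intercept."""
    if not 0.0 <= slope <= 1.0:
        raise ValueError(f"slope must lie in [0, 1], got {slope}")
    arr = _check_unit_interval(x, "x")
    out = slope * arr
    return float(out) if np.isscalar(x) else out


def apply_edge_tf(x, spec: TransferFunctionSpec, sign: int):
    """Evaluate one edge: the transfer function, inverted for inhibition.

    A negative interaction is the transfer function subtracted from one, so
    an inhibitor at full activity drives its target's contribution to zero.
    """
    if spec is None:
        raise ValueError("cannot evaluate an absent transfer function; "
                         "inactive gates must be skipped by the caller")
    if sign not in (1, -1):
        raise ValueError(f"sign must be +1 or -1, got {sign}")
    t = spec.evaluate(x)
    return t if sign == 1 else 1.0 - t


def gate_sensitivity(spec: TransferFunctionSpec) -> float:
    """Sensitivity of one transfer function: 1 - EC50 (Hill), 0.5*slope (linear).

    Higher sensitivity means the output responds at lower input levels.
    Hill members with k > 1 (the approximately linear library member) are
    floored at 0.
    """
    if spec is None:
        raise ValueError("absent transfer function has no sensitivity")
    if spec.family == "hill":
        if spec.k > 1.0:
            logger.debug("hill k=%g > 1; sensitivity floored at 0", spec.k)
            return 0.0
        return 1.0 - spec.k
    return 0.5 * spec.slope


# Discrete-phase libraries.  Index 0 is the "absent" state in both; indices
# 1..7 are ordered ascending in k (Hill, after the near-linear member) and in
# slope (linear) so the allele <-> parameter map is stable across versions.
HILL_LIBRARY: tuple = (
    None,
    TransferFunctionSpec("hill", n=1.01, k=68.5098, discrete_index=1),
    TransferFunctionSpec("hill", n=3.0, k=0.2, discrete_index=2),
    TransferFunctionSpec("hill", n=3.0, k=0.3, discrete_index=3),
    TransferFunctionSpec("hill", n=3.0, k=0.4, discrete_index=4),
    TransferFunctionSpec("hill", n=3.0, k=0.5, discrete_index=5),
    TransferFunctionSpec("hill", n=3.0, k=0.6, discrete_index=6),
    TransferFunctionSpec("hill", n=3.0, k=0.7, discrete_index=7),
)

LINEAR_LIBRARY: tuple = (
    None,
    TransferFunctionSpec("linear", slope=0.2, discrete_index=1),
    TransferFunctionSpec("linear", slope=0.3, discrete_index=2),
    TransferFunctionSpec("linear", slope=0.4, discrete_index=3),
    TransferFunctionSpec("linear", slope=0.5, discrete_index=4),
    TransferFunctionSpec("linear", slope=0.6, discrete_index=5),
    TransferFunctionSpec("linear", slope=0.7, discrete_index=6),
    TransferFunctionSpec("linear", slope=0.8, discrete_index=7),
)

LIBRARIES = {"hill": HILL_LIBRARY, "linear": LINEAR_LIBRARY}

#: states per genome slot: 7 transfer functions + absent
ALPHABET_SIZE = 8
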