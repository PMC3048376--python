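"""Perturbation-response datasets.

A dataset couples an experimental design — one row per condition, each a
combination of stimulus levels and inhibitor flags — with the measured node
values for that condition, normalized to [0, 1].  Missing observations are
NaN and are excluded from every error computation.
"""

from __future__ import annotations

import hashlib
import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

__all__ = ["Dataset", "ExperimentalCondition", "full_factorial_design"]


@dataclass(frozen=True)
class ExperimentalCondition:
    """One experimental condition: stimulus levels and inhibitor flags."""

    stimuli: Dict[str, float]
    inhibitors: Dict[str, int]

    def __post_init__(self) -> None:
        for node, v in self.stimuli.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"stimulus {node}={v} outside [0, 1]")
        for node, f in self.inhibitors.items():
            if f not in (0, 1):
                raise ValueError(f"inhibitor flag {node}={f} must be 0 or 1")


@dataclass
class Dataset:
    """Experimental design plus observed node values.

    ``treatments``: conditions x stimulus nodes, values in [0, 1].
    ``inhibitors``: conditions x inhibited nodes, flags in {0, 1}.
    ``values``: conditions x measured nodes, values in [0, 1] or NaN.
    ``da_times``: optional acquisition-time columns kept for provenance only.
    All frames share one index (one row per condition); no two rows may have
    an identical treatment + inhibitor combination.
    """

    treatments: pd.DataFrame
    inhibitors: pd.DataFrame
    values: pd.DataFrame
    da_times: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        n = len(self.treatments)
        if len(self.inhibitors) != n or len(self.values) != n:
            raise ValueError("design and value tables must have equal row counts")
        self.treatments = self.treatments.astype(float).reset_index(drop=True)
        self.inhibitors = self.inhibitors.astype(int).reset_index(drop=True)
        self.values = self.values.astype(float).reset_index(drop=True)
        if self.da_times is not None:
            self.da_times = self.da_times.reset_index(drop=True)
        t = self.treatments.to_numpy()
        if t.size and (np.nanmin(t) < 0 or np.nanmax(t) > 1):
            raise ValueError("treatment values must lie in [0, 1]")
        iv = self.inhibitors.to_numpy()
        if iv.size and not np.isin(iv, (0, 1)).all():
            raise ValueError("inhibitor flags must be 0 or 1")
        v = self.values.to_numpy()
        finite = v[~np.isnan(v)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("observed values must lie in [0, 1] or be missing")
        design = pd.concat([self.treatments, self.inhibitors], axis=1)
        if design.duplicated().any():
            dup = design[design.duplicated()].index.tolist()
            raise ValueError(f"duplicate experimental conditions at rows {dup}")

    @property
    def n_conditions(self) -> int:
        return len(self.treatments)

    @property
    def n_obs(self) -> int:
        """Count of non-missing observation cells."""
        return int(self.values.notna().to_numpy().sum())

    def conditions(self) -> List[ExperimentalCondition]:
        out = []
        for i in range(self.n_conditions):
            out.append(ExperimentalCondition(
                stimuli={c: float(self.treatments.at[i, c])
                         for c in self.treatments.columns},
                inhibitors={c: int(self.inhibitors.at[i, c])
                            for c in self.inhibitors.columns},
            ))
        return out

    def with_values(self, values: pd.DataFrame) -> "Dataset":
        """Copy of this dataset with the observation table replaced."""
        return Dataset(self.treatments.copy(), self.inhibitors.copy(),
                       values.copy(),
                       None if self.da_times is None else self.da_times.copy())

    def mask_cells(self, cells) -> "Dataset":
        """Copy with the given (row, column-name) observation cells set missing."""
        vals = self.values.copy()
        for row, col in cells:
            vals.at[row, col] = np.nan
        return self.with_values(vals)

    def observation_cells(self) -> List[tuple]:
        """All non-missing (row, column-name) cells, in stable order."""
        cells = []
        for col in self.values.columns:
            for row in self.values.index[self.values[col].notna()]:
                cells.append((int(row), col))
        return cells

    def fingerprint(self) -> str:
        """Stable content hash used to stamp model scores with their data."""
        h = hashlib.sha256()
        for frame in (self.treatments, self.inhibitors, self.values):
            h.update(",".join(frame.columns).encode())
            h.update(np.ascontiguousarray(frame.to_numpy(dtype=float)).tobytes())
        return h.hexdigest()[:16]


def full_factorial_design(stimuli: List[str], inhibitors: List[str],
                          stimulus_levels=(0.0, 1.0)) -> Dataset:
    """Full factorial design: every stimulus-level combination crossed with
    every inhibitor on/off combination.  Returns a Dataset with an empty
    observation table (no measured columns)."""
    rows_t, rows_i = [], []
    for levels in itertools.product(stimulus_levels, repeat=len(stimuli)):
        for flags in itertools.product((0, 1), repeat=len(inhibitors)):
            rows_t.append(dict(zip(stimuli, levels)))
            rows_i.append(dict(zip(inhibitors, flags)))
    treatments = pd.DataFrame(rows_t, columns=stimuli, dtype=float)
    inhibitor_df = pd.DataFrame(rows_i, columns=inhibitors, dtype=int)
    values = pd.DataFrame(index=range(len(rows_t)), dtype=float)
    return Dataset(treatments, inhibitor_df, values)
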