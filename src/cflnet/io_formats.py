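"""Interchange formats: SIF networks, MIDAS-dialect CSV, JSON model archives.

SIF: one interaction per line, ``source sign target`` with sign 1 or -1,
whitespace- or tab-delimited; ``#`` starts a comment.  Duplicate records
collapse to one edge.

MIDAS dialect: a comma-separated UTF-8 table with a mandatory header.
``TR:<node>`` columns are stimulus levels in [0, 1], ``TR:<node>:i``
inhibitor flags in {0, 1}, ``DV:<node>`` measured values in [0, 1] (missing
token ``NA``) and ``DA:<node>`` optional acquisition times carried for
provenance only.

Model archives are JSON with explicit slot identifiers
``<output>|<gate-index>|<input>`` so trained families are human-diffable
and stable across runs.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .data import Dataset
from .model import CFLModel, ModelEnsemble
from .network import PKN, CandidateGate, HypothesisSpace
from .transfer import TransferFunctionSpec

__all__ = ["read_sif", "write_sif", "read_midas", "write_midas",
           "save_ensemble", "load_ensemble"]

PathLike = Union[str, Path]


def read_sif(path: PathLike) -> PKN:
    """Parse a SIF file into a PKN (roles unset)."""
    nodes, edges = set(), set()
    for lineno, raw in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.split()
        if len(fields) != 3:
            raise ValueError(
                f"{path}:{lineno}: expected 3 fields 'source sign target', "
                f"got {len(fields)}")
        source, sign_text, target = fields
        try:
            sign = int(sign_text)
        except ValueError:
            raise ValueError(f"{path}:{lineno}: sign {sign_text!r} is not an integer")
        if sign not in (1, -1):
            raise ValueError(f"{path}:{lineno}: sign must be 1 or -1, got {sign}")
        nodes.update((source, target))
        edges.add((source, target, sign))
    return PKN(frozenset(nodes), frozenset(edges))


def write_sif(pkn: PKN, path: PathLike) -> None:
    """Write a PKN's edges as SIF; isolated nodes appear as a comment."""
    lines = [f"{s}\t{sign}\t{t}" for s, t, sign in sorted(pkn.edges)]
    isolated = pkn.nodes - {n for e in pkn.edges for n in (e[0], e[1])}
    if isolated:
        lines.append("# isolated nodes: " + " ".join(sorted(isolated)))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""),
                          encoding="utf-8")


def _classify_column(name: str) -> tuple:
    if name.startswith("TR:"):
        rest = name[3:]
        if rest.endswith(":i"):
            return "inhibitor", rest[:-2]
        return "treatment", rest
    if name.startswith("DV:"):
        return "value", name[3:]
    if name.startswith("DA:"):
        return "time", name[3:]
    raise ValueError(f"unknown MIDAS column prefix in {name!r} "
                     "(expected TR:, TR:..:i, DV: or DA:)")


def read_midas(path: PathLike) -> Dataset:
    """Read a MIDAS-dialect CSV into a Dataset."""
    raw = pd.read_csv(path, na_values=["NA"], keep_default_na=False,
                      encoding="utf-8")
    treatments, inhibitors, values, times = {}, {}, {}, {}
    for col in raw.columns:
        role, node = _classify_column(col)
        series = pd.to_numeric(raw[col], errors="coerce")
        bad = series.isna() & raw[col].notna() & (raw[col].astype(str) != "NA")
        if bad.any():
            row = int(bad.idxmax())
            raise ValueError(f"{path}: non-numeric cell {raw[col][row]!r} "
                             f"in column {col}, row {row}")
        if role == "treatment":
            treatments[node] = series
        elif role == "inhibitor":
            inhibitors[node] = series
        elif role == "value":
            finite = series.dropna()
            out_of_range = finite[(finite < 0) | (finite > 1)]
            if len(out_of_range):
                row = int(out_of_range.index[0])
                raise ValueError(
                    f"{path}: value {out_of_range.iloc[0]} outside [0, 1] "
                    f"in column {col}, row {row}")
            values[node] = series
        else:
            times[node] = series
    n = len(raw)
    return Dataset(
        pd.DataFrame(treatments, index=range(n), dtype=float),
        pd.DataFrame(inhibitors, index=range(n)).fillna(0).astype(int),
        pd.DataFrame(values, index=range(n), dtype=float),
        pd.DataFrame(times, index=range(n)) if times else None,
    )


def write_midas(dataset: Dataset, path: PathLike) -> None:
    """Write a Dataset as MIDAS-dialect CSV (missing values as ``NA``)."""
    out = {}
    for col in dataset.treatments.columns:
        out[f"TR:{col}"] = dataset.treatments[col]
    for col in dataset.inhibitors.columns:
        out[f"TR:{col}:i"] = dataset.inhibitors[col]
    if dataset.da_times is not None:
        for col in dataset.da_times.columns:
            out[f"DA:{col}"] = dataset.da_times[col]
    for col in dataset.values.columns:
        out[f"DV:{col}"] = dataset.values[col]
    pd.DataFrame(out).to_csv(path, index=False, na_rep="NA", encoding="utf-8")


# ---------------------------------------------------------------------------
# model archive

def _spec_to_json(spec: TransferFunctionSpec):
    if spec is None:
        return None
    return {"family": spec.family, "n": spec.n, "k": spec.k,
            "slope": spec.slope, "discrete_index": spec.discrete_index}


def _spec_from_json(obj):
    if obj is None:
        return None
    return TransferFunctionSpec(obj["family"], n=obj["n"], k=obj["k"],
                                slope=obj["slope"],
                                discrete_index=obj["discrete_index"])


def save_ensemble(ensemble: ModelEnsemble, path: PathLike) -> None:
    """Archive an ensemble (hypothesis space + models) as JSON."""
    hs = ensemble.hypothesis
    pkn = hs.pkn
    doc = {
        "format": "cflnet-ensemble/1",
        "pkn": {
            "nodes": sorted(pkn.nodes),
            "edges": sorted(list(e) for e in pkn.edges),
            "stimuli": sorted(pkn.stimuli),
            "inhibited": sorted(pkn.inhibited),
            "measured": sorted(pkn.measured),
        },
        "expansion_mode": hs.mode,
        "gates": {
            output: [list(map(list, g.inputs)) for g in gates]
            for output, gates in hs.gates.items()
        },
        "models": [
            {
                "stage": m.stage,
                "mse": m.mse,
                "seed": m.seed,
                "data_fingerprint": m.data_fingerprint,
                "assignment": {sid: _spec_to_json(spec)
                               for sid, spec in m.assignment.items()},
            }
            for m in ensemble
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1), encoding="utf-8")


def load_ensemble(path: PathLike) -> ModelEnsemble:
    """Load a JSON ensemble archive; unknown slot ids raise an integrity error."""
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    if doc.get("format") != "cflnet-ensemble/1":
        raise ValueError(f"{path}: not a cflnet ensemble archive")
    p = doc["pkn"]
    pkn = PKN(frozenset(p["nodes"]),
              frozenset(tuple(e) for e in p["edges"]),
              frozenset(p["stimuli"]), frozenset(p["inhibited"]),
              frozenset(p["measured"]))
    gates = {
        output: tuple(CandidateGate(output, tuple((n, s) for n, s in inputs))
                      for inputs in gate_list)
        for output, gate_list in doc["gates"].items()
    }
    hs = HypothesisSpace(pkn=pkn, gates=gates,
                         mode=doc.get("expansion_mode", "all_pairs"))
    known = set(hs.slots)
    models = []
    for mj in doc["models"]:
        unknown = set(mj["assignment"]) - known
        if unknown:
            raise ValueError(
                f"{path}: archive references slot ids absent from the "
                f"hypothesis space: {sorted(unknown)}")
        m = CFLModel(hs, {sid: _spec_from_json(s)
                          for sid, s in mj["assignment"].items()},
                     stage=mj["stage"], mse=mj["mse"], seed=mj["seed"],
                     data_fingerprint=mj.get("data_fingerprint"))
        models.append(m)
    return ModelEnsemble(hs, models)
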