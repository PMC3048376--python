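"""End-to-end pipeline: preprocess -> train -> reduce/refine/filter -> report.

Configuration is a TOML file with sections ``io``, ``expand``, ``sim``,
``ga``, ``reduction`` and ``analysis``; every key has a default and unknown
keys are rejected.  All randomness flows from one master seed; every
artifact is stamped with the configuration hash and the derived seeds so a
rerun with the same configuration reproduces the family exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .analysis import ensemble_predict, ensemble_sensitivity, gate_frequencies
from .io_formats import read_midas, read_sif, save_ensemble, write_sif
from .network import compress, count_search_space, designate_roles, expand
from .refinement import (RefinementConfig, build_reduction_profile,
                         select_filtered, threshold_tradeoff_table)
from .simulate import SimConfig
from .training import GAConfig, train_family

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "load_config", "run_pipeline"]

_SECTION_KEYS = {
    "io": {"pkn", "data", "outdir"},
    "expand": {"mode"},
    "sim": {"tol", "max_iter", "operator_mode"},
    "ga": {"population_size", "max_generations", "stall_generations",
           "elite_count", "mutation_rate", "tournament_size", "n_runs",
           "keep_rule"},
    "reduction": {"threshold_grid", "selection_threshold",
                  "optimizer_maxiter", "optimizer_ftol"},
    "analysis": {"frequency_cut"},
}


@dataclass
class PipelineConfig:
    pkn_path: str = ""
    data_path: str = ""
    outdir: str = "cflnet_run"
    expand_mode: str = "all_pairs"
    sim: SimConfig = field(default_factory=SimConfig)
    ga: GAConfig = field(default_factory=GAConfig)
    n_runs: int = 20
    keep_rule: str = "all"
    refinement: RefinementConfig = field(default_factory=RefinementConfig)
    frequency_cut: float = 0.25
    seed: int = 0

    def digest(self) -> str:
        blob = json.dumps({
            "pkn": self.pkn_path, "data": self.data_path,
            "expand": self.expand_mode,
            "sim": dataclasses.asdict(self.sim),
            "ga": dataclasses.asdict(self.ga),
            "n_runs": self.n_runs, "keep_rule": self.keep_rule,
            "reduction": dataclasses.asdict(self.refinement),
            "frequency_cut": self.frequency_cut, "seed": self.seed,
        }, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def load_config(path, seed: Optional[int] = None,
                outdir: Optional[str] = None) -> PipelineConfig:
    """Parse a TOML pipeline configuration; unknown keys are an error."""
    raw = tomllib.loads(Path(path).read_text(encoding="utf-8"))
    for section, table in raw.items():
        if section == "seed":
            continue
        if section not in _SECTION_KEYS:
            raise ValueError(f"unknown config section [{section}]")
        unknown = set(table) - _SECTION_KEYS[section]
        if unknown:
            raise ValueError(f"unknown keys in [{section}]: {sorted(unknown)}")
    io = raw.get("io", {})
    ga = raw.get("ga", {})
    sim = raw.get("sim", {})
    red = raw.get("reduction", {})
    cfg = PipelineConfig(
        pkn_path=io.get("pkn", ""),
        data_path=io.get("data", ""),
        outdir=outdir or io.get("outdir", "cflnet_run"),
        expand_mode=raw.get("expand", {}).get("mode", "all_pairs"),
        sim=SimConfig(tol=sim.get("tol", 1e-4),
                      max_iter=sim.get("max_iter"),
                      operator_mode=sim.get("operator_mode", "minmax")),
        ga=GAConfig(
            population_size=ga.get("population_size", 50),
            max_generations=ga.get("max_generations", 500),
            stall_generations=ga.get("stall_generations", 100),
            elite_count=ga.get("elite_count", 2),
            mutation_rate=ga.get("mutation_rate"),
            tournament_size=ga.get("tournament_size", 3),
            seed=seed if seed is not None else raw.get("seed", 0)),
        n_runs=ga.get("n_runs", 20),
        keep_rule=ga.get("keep_rule", "all"),
        refinement=RefinementConfig(
            reduction_threshold_grid=tuple(red.get(
                "threshold_grid",
                RefinementConfig().reduction_threshold_grid)),
            selection_threshold=red.get("selection_threshold", 5e-3),
            optimizer_maxiter=red.get("optimizer_maxiter", 100),
            optimizer_ftol=red.get("optimizer_ftol", 1e-9)),
        frequency_cut=raw.get("analysis", {}).get("frequency_cut", 0.25),
        seed=seed if seed is not None else raw.get("seed", 0),
    )
    return cfg


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full workflow and write all artifacts to the run directory."""
    if not Path(config.pkn_path).exists():
        raise FileNotFoundError(f"PKN file not found: {config.pkn_path}")
    if not Path(config.data_path).exists():
        raise FileNotFoundError(f"dataset file not found: {config.data_path}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    digest = config.digest()
    logger.info("pipeline run %s -> %s", digest, outdir)

    pkn = read_sif(config.pkn_path)
    dataset = read_midas(config.data_path)
    pkn = designate_roles(pkn, dataset)
    compressed = compress(pkn)
    write_sif(compressed, outdir / "compressed.sif")
    hs = expand(compressed, config.expand_mode)
    w, h, alphabet = count_search_space(hs)
    (outdir / "search_space.json").write_text(json.dumps({
        "config_digest": digest, "seed": config.seed,
        "gates_w": w, "slots_h": h, "alphabet_size": alphabet,
        "search_space_log10": h * np.log10(alphabet),
    }, indent=1))

    ga = dataclasses.replace(config.ga, seed=config.seed)
    keep = config.keep_rule
    family = train_family(hs, dataset, ga, config.n_runs, keep, config.sim)
    save_ensemble(family, outdir / "unprocessed.json")

    profile = build_reduction_profile(family, dataset, config.refinement,
                                      config.sim)
    profile.table().to_csv(outdir / "reduction_profile.csv", index=False)
    threshold_tradeoff_table(profile).to_csv(
        outdir / "threshold_tradeoff.csv", index=False)
    filtered = select_filtered(profile)
    save_ensemble(filtered, outdir / "filtered.json")

    freqs = gate_frequencies(filtered)
    rows = []
    for (output, gi), f in sorted(freqs.items()):
        gate = hs.gates[output][gi]
        row = {"gate": gate.describe(), "frequency": f,
               "sensitivity_mean": np.nan, "sensitivity_sd": np.nan}
        if f > 0:
            mean, sd = ensemble_sensitivity(filtered, output, gi)
            row["sensitivity_mean"], row["sensitivity_sd"] = mean, sd
        rows.append(row)
    pd.DataFrame(rows).to_csv(outdir / "gate_report.csv", index=False)

    summary = ensemble_predict(filtered, dataset.conditions(), config.sim)
    fit = dataset.values.copy()
    fit.columns = [f"obs:{c}" for c in fit.columns]
    for c in dataset.values.columns:
        fit[f"pred:{c}"] = summary.mean[c]
        fit[f"sd:{c}"] = summary.sd[c]
    fit.to_csv(outdir / "fit_vs_data.csv", index=False)

    (outdir / "run_manifest.json").write_text(json.dumps({
        "config_digest": digest,
        "seed": config.seed,
        "n_unprocessed": len(family),
        "n_filtered": len(filtered),
        "unprocessed_mse": [m.mse for m in family],
        "filtered_mse": [m.mse for m in filtered],
        "filtered_parameter_counts": [m.parameter_count for m in filtered],
        "run_seeds": [m.seed for m in family],
    }, indent=1))
    return outdir
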