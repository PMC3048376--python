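"""Ensemble predictions and response surfaces.

A family of trained models gives not a single prediction but a
distribution: the mean is the prediction, the SD/CV flags where the data
leave the models unconstrained.  The response surface evaluates one node's
gates over a 21x21 grid of its input values (441 combinations).
"""

import numpy as np

from cflnet.analysis import ensemble_predict, node_response_surface
from cflnet.data import ExperimentalCondition
from cflnet.model import ModelEnsemble
from cflnet.network import compress, expand
from cflnet.synth import example_dataset, example_pkn
from cflnet.training import GAConfig, remove_redundant_gates, run_ga

hs = expand(compress(example_pkn()))
dataset = example_dataset()
models = [remove_redundant_gates(
    run_ga(hs, dataset, GAConfig(population_size=30, max_generations=120,
                                 stall_generations=30, seed=s)), dataset)
    for s in range(4)]
family = ModelEnsemble(hs, models)

conds = [ExperimentalCondition({"TGFA": 1.0, "TNFA": 0.0}, {}),
         ExperimentalCondition({"TGFA": 1.0, "TNFA": 1.0}, {})]
summary = ensemble_predict(family, conds)
print("ensemble predictions (mean +/- sd) under TGFA and TGFA+TNFA:")
for node in ("AKT", "JNK", "ERK"):
    for i, label in enumerate(("TGFA", "TGFA+TNFA")):
        print(f"  {node:4s} [{label:9s}] "
              f"{summary.mean.at[i, node]:.3f} +/- {summary.sd.at[i, node]:.3f}")

axis = np.linspace(0, 1, 21)
surf = node_response_surface(family, "JNK", {"PI3K": axis, "TNFA": axis})
print(f"\nJNK response surface: {len(surf.mean)} grid points; "
      f"max mean {surf.mean['JNK'].max():.3f}, "
      f"max sd {surf.sd['JNK'].max():.3f}")
# A small SD across the surface means the family agrees on the JNK
# transfer functions; large SD regions are not pinned down by the design.
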