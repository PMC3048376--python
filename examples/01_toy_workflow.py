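"""Full workflow on the 15-node toy: compress, expand, train, filter.

Builds the bundled synthetic signaling network (2 stimuli, 2 druggable
kinases, 6 phospho-readouts), simulates a noise-free in-silico dataset
from the known generating model, trains a small family of fuzzy logic
models with the discrete GA, then reduces/refines/filters them.
"""

from cflnet.model import ModelEnsemble
from cflnet.network import compress, count_search_space, expand
from cflnet.refinement import (RefinementConfig, build_reduction_profile,
                               select_filtered)
from cflnet.synth import example_dataset, example_pkn
from cflnet.training import GAConfig, remove_redundant_gates, run_ga
from cflnet.analysis import ensemble_sensitivity, gate_frequencies

pkn = example_pkn()
dataset = example_dataset()
print(f"PKN: {len(pkn.nodes)} nodes, {len(pkn.edges)} edges; "
      f"dataset: {dataset.n_conditions} conditions, {dataset.n_obs} observations")

compressed = compress(pkn)
hs = expand(compressed, "all_pairs")
w, h, a = count_search_space(hs)
print(f"compressed to {len(compressed.nodes)} nodes; expanded to w={w} "
      f"candidate gates, h={h} slots -> {a}^{h} = {a**h:,} genomes")

ga = GAConfig(population_size=30, max_generations=120, stall_generations=30)
models = []
for seed in range(4):
    m = run_ga(hs, dataset, GAConfig(population_size=30, max_generations=120,
                                     stall_generations=30, seed=seed))
    models.append(remove_redundant_gates(m, dataset))
family = ModelEnsemble(hs, models)
print("unprocessed MSEs:", [round(m.mse, 5) for m in family])

cfg = RefinementConfig(reduction_threshold_grid=(0.0, 1e-4, 1e-3, 5e-3, 5e-2))
profile = build_reduction_profile(family, dataset, cfg)
filtered = select_filtered(profile)
print("filtered MSEs:  ", [round(m.mse, 5) for m in filtered])
print("parameter counts:", [m.parameter_count for m in filtered])

print("\nconsensus gates (frequency, sensitivity mean +/- sd):")
for (output, gi), f in sorted(gate_frequencies(filtered).items()):
    if f > 0.25:
        gate = hs.gates[output][gi]
        mean, sd = ensemble_sensitivity(filtered, output, gi)
        print(f"  {gate.describe():24s} freq={f:.2f} "
              f"sensitivity={mean:.2f}+/-{sd:.2f}")
# A frequency of 1.0 means every model in the family uses the gate; the
# sensitivity (1 - EC50 for Hill, slope/2 for linear) says how little input
# activity is needed to drive the output.
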