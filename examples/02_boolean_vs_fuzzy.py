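"""Why graded logic matters: a branch only partially activated.

In the toy's generating model TGFA drives PI3K with a linear gain of 0.3,
so AKT sits near 0.30 and JNK near 0.20 under TGFA stimulation.  A Boolean
model must predict 0 or 1 for those readouts: including the TGFA->PI3K
gate costs more error than dropping it, so Boolean training removes the
true interaction.  Fuzzy training keeps it.
"""

from cflnet.network import compress, expand
from cflnet.refinement import reduce_model
from cflnet.simulate import SimConfig
from cflnet.synth import example_dataset, example_pkn
from cflnet.training import GAConfig, remove_redundant_gates, run_ga

hs = expand(compress(example_pkn()))
dataset = example_dataset()
branch = "PI3K|0|TGFA"
ga = dict(population_size=30, max_generations=120, stall_generations=30)
boolean = SimConfig(operator_mode="boolean")

kept_fuzzy = kept_boolean = 0
n = 5
for seed in range(n):
    m = remove_redundant_gates(
        run_ga(hs, dataset, GAConfig(seed=seed, **ga)), dataset)
    m = reduce_model(m, dataset, 0.0)
    kept_fuzzy += m.assignment[branch] is not None

    b = run_ga(hs, dataset, GAConfig(seed=seed, **ga), boolean)
    b = reduce_model(b, dataset, 0.0, boolean)
    kept_boolean += b.assignment[branch] is not None

print(f"TGFA->PI3K retained by fuzzy training:   {kept_fuzzy}/{n} runs")
print(f"TGFA->PI3K retained by Boolean training: {kept_boolean}/{n} runs")
# Fuzzy logic recovers the true topology because it can model the graded
# 0.3/0.2 activities; the Boolean approximation misattributes them to noise.
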