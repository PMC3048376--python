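# cflnet — constrained fuzzy logic models of signaling networks

`cflnet` turns a **prior knowledge network** (PKN: a signed directed graph
of protein interactions) plus a **perturbation–response dataset**
(stimulus × inhibitor conditions with measured node activities normalized
to [0, 1]) into an **ensemble of quantitative logic models**, and then
tells you what that ensemble agrees on.

It is aimed at systems biologists who have phosphoproteomic (or similar)
readouts under combinatorial stimulation/inhibition and a literature-derived
interaction map, and want a trained, reduced, interpretable logic model —
not a single fit, but a family whose spread quantifies identifiability.

## The model

Each interaction is a **transfer function**. An ordinary edge uses the
normalized Hill function

    f(x) = x^n (1 + k^n) / (x^n + k^n),       f(0) = 0,  f(1) = 1

with Hill coefficient `n` (sharpness) and midpoint `k` (the EC50). An edge
leaving a stimulus uses a linear map `f(x) = slope · x` (stimuli enter at
saturating 0/1 levels, where a normalized Hill function degenerates to
Boolean behaviour). Inhibition is `1 − f(x)`. Gates combine inputs with
AND = min and OR = max (a product/capped-sum variant and a pure Boolean
mode are also available). Node activities are the synchronous fixed point
of these updates; fit is the mean squared error (MSE) over all non-missing
observation cells.

Training is a six-step workflow:

1. **Compress** the PKN: intermediate nodes not needed for input–output
   logic are spliced out.
2. **Expand** into a hypothesis space: one candidate gate per edge plus
   2-input AND gates (all pairs, or only inhibitory-containing pairs),
   one discrete transfer-function slot per gate input. Each slot has 8
   states (absent + 7 library members), so the search space is `8^h`.
3. **Train**: repeated runs of a discrete genetic algorithm minimize MSE,
   giving a family of *unprocessed* models (logically redundant gates
   removed).
4. **Reduce** each model at a grid of *reduction thresholds*: gates are
   removed or simplified while the MSE stays within the threshold.
5. **Refine**: transfer-function parameters become continuous and are
   re-optimized (SLSQP) at fixed topology.
6. **Filter**: per model, pick the reduced-refined variant with the fewest
   parameters whose MSE stays within the *selection threshold* (default
   5·10⁻³) of the baseline.

The ensemble layer reports gate frequencies, gate sensitivities
(1 − EC50 for Hill, slope/2 for linear), mean/SD/CV predictions, response
surfaces, k-fold and signal/stimulus-holdout cross-validation, consensus
topology distances, and empirical/z-score significance against randomized
data and randomized networks.

## Worked example

The bundled 15-node synthetic toy (`cflnet.synth.example_pkn`) has two
stimuli (TGFA, TNFA), two inhibitable kinases (PI3K, MEK) and six measured
readouts. Its generating model drives PI3K with a linear gain of only 0.3,
so AKT and JNK sit near 0.30/0.20 under TGFA — graded values a Boolean
model cannot fit.

```bash
python examples/02_boolean_vs_fuzzy.py
```

prints

```
TGFA->PI3K retained by fuzzy training:   5/5 runs
TGFA->PI3K retained by Boolean training: 0/5 runs
```

i.e. Boolean training consistently deletes the true interaction (a model
that includes it predicts (1, 1) against the graded observations
(0.32, 0.19) and scores MSE 0.56, versus 0.07 without it), while the fuzzy
models keep it with the correct gain. `examples/03_parameter_recovery.py`
shows the reduce-then-refine step recovering an off-grid Hill midpoint:

```
discrete GA best: MSE=0.0008692, k=0.5 (grid member)
filtered model:  MSE=3.52e-09, k=0.4501 (refined, true value 0.45)
topology: ['A -> B', 'S -> A']
```

The other example scripts cover the full pipeline
(`01_toy_workflow.py`), ensemble prediction and 441-point response
surfaces (`04`), randomization null controls (`05`) and cross-validation
(`06`). A thin CLI wraps the same calls:

```bash
cflnet preprocess --pkn pkn.sif --data data.csv --out compressed.sif
cflnet train --pkn pkn.sif --data data.csv --runs 20 --seed 1 --out fam.json
cflnet refine --ensemble fam.json --data data.csv --out filtered.json
```

Networks are SIF text (`source sign target`, sign ∈ {1, −1}); datasets are
MIDAS-dialect CSV (`TR:<node>` stimulus, `TR:<node>:i` inhibitor flag,
`DV:<node>` measured value, `NA` missing); ensembles are JSON archives.

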