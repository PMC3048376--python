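# Methods

## Model and semantics

A model assigns each slot of the hypothesis space either a transfer
function or "absent". A gate is active only when *all* of its slots are
non-absent; this keeps the genome↔topology map unambiguous (the 1-input
fallback of a 2-input AND gate is explored explicitly during reduction,
not implicitly through partial assignment). Gate evaluation:

* per input: `f(x)` (Hill or linear), inverted to `1 − f(x)` for negative
  interactions;
* AND across a gate's inputs: `min` (default) or product (`prodsum` mode);
* OR across a node's active gates: `max` (default) or sum capped at 1;
* `boolean` mode binarizes inputs at 0.5 and applies logical AND/OR,
  ignoring transfer-function parameters apart from gate presence. This
  reproduces classical Boolean steady-state evaluation (checked against an
  exhaustive truth-table oracle on small acyclic models).

### Discrete libraries

Ordinary (Hill) slots: absent; an approximately linear member
(n = 1.01, k = 68.5098, numerically stable and indistinguishable from the
identity on [0, 1] to within 0.005); six sigmoids (n = 3,
k ∈ {0.2, …, 0.7}). Stimulus (linear) slots: absent;
slope ∈ {0.2, …, 0.8}. Both alphabets have 8 states, so the discrete
problem has 8^h points for h slots. Library order is fixed (ascending k /
slope) so allele↔parameter mappings are stable across versions.

### Simulation

The update scheme is a design choice of this package: synchronous
fixed-point iteration from an all-zero state (no basal activity), stimuli
clamped to their treatment level, inhibited nodes with flag 1 clamped to
0, tolerance 1e-4, iteration cap 10× the node count. cFL updates are
continuous and in practice contractive on the acyclic networks used here;
cyclic models that oscillate simply fail to converge. A non-converged
condition is a *flagged outcome*: its predictions are undefined and each
affected observation contributes squared error 1.0 to the MSE, so
oscillating models are selected against during training rather than
raising exceptions.

Inhibitor semantics are "activity clamped to zero". Whether the measured
phospho-level of a chemically inhibited kinase should instead be compared
against its computed (possibly nonzero) phosphorylation is a genuine
modeling ambiguity; we use the activity reading throughout.

## Compression

Intermediate (role-free) nodes are spliced out when this provably cannot
change input–output Boolean logic: nodes with one incoming edge, nodes
with one *positive* outgoing edge, dead ends, and input-free nodes whose
out-edges are all positive. Each (upstream, downstream) pair becomes a
direct edge with the product sign; self-loops created by splicing are
dropped; the procedure iterates to a fixed point. Two deliberate
retentions:

* a multi-input node with a single **negative** out-edge is kept — by De
  Morgan, `NOT(A OR B)` is not `(NOT A) OR (NOT B)`, so splicing there
  would alter the truth table (the brute-force truth-table oracle in the
  test suite is the guard for the whole rule);
* nodes on cycles are conservatively kept, since the truth-table oracle
  is only defined for acyclic regions.

## Expansion

Two modes, both limited to 2-input AND gates (higher arities rarely make
biological sense — a six-input AND would require six simultaneously active
receptors — and they inflate the search space):

* `all_pairs`: a 1-input gate per edge (activating *and* inhibitory) plus
  an AND gate per unordered pair of distinct-source edges;
* `inhibitory_only`: 1-input gates for activating edges only, plus
  "A AND NOT B" gates per (activating, inhibitory) pair. A standalone
  inhibitory gate asserts the output is active whenever the input is off,
  i.e. constitutive activity, which is usually not observed; the AND form
  expresses inhibition of an activation instead.

## Training

Generational GA over allele vectors in {0..7}^h: elitism (2), tournament
selection (size 3), uniform crossover, per-locus mutation to a uniformly
random different allele at rate 1/h, population 50, at most 500
generations, stop after 100 without improvement. These are ordinary
small-alphabet GA settings sized for h ≈ 60–170; the bundled toys
(h ≈ 3–11) are trained with reduced budgets (population 20–30, 40–120
generations, stall 15–30), which the recovery experiments in the test
suite show to be ample at that scale. Fitness values are cached per
genome within a run. All randomness flows from explicit seeds; a family's
run seeds are derived from the master seed via `SeedSequence.spawn`, so
ensembles are a pure function of (hypothesis space, data, config, seed).

After each run, AND gates whose (input, sign) set is a superset of another
active gate's are deactivated (under max-OR the dominated term can never
win), yielding *unprocessed* models.

## Reduction, refinement, filtering

Reduction is a greedy non-exhaustive search. Candidate alterations are
gate deactivation and replacement of a 2-input AND by one of its 1-input
sub-gates (keeping that slot's transfer function, and only when the
hypothesis space contains that sub-gate and it is currently inactive).
Each round applies the candidate with the lowest resulting MSE, accepted
while MSE ≤ *unprocessed* MSE + threshold — the cumulative cap is
anchored at the unprocessed model, which matches the filter-point
semantics (the alternative, judging each step against the current model,
would let long chains of small degradations through). Ties break
deterministically by (output name, gate index, alteration kind).

Refinement fixes the topology and minimizes MSE over all active-slot
parameters with SLSQP: Hill n ∈ [1, 5], k ∈ [0.01, 2], slope ∈ [0, 1],
starting from the current values clipped into bounds (the near-linear
library member's k = 68.5 starts at the k = 2 bound). Both n and k are
refined. If the optimizer fails or returns a worse point, the incoming
model is kept — refinement never worsens a model.

The default reduction-threshold grid {0, 1e-5, 5e-5, 1e-4, 5e-4, 1e-3,
5e-3, 1e-2, 5e-2} spans the decades over which filter points typically
move; tests and the acceptance script use a 5-point subset covering the
same decades to keep runtimes short. The per-model baseline for
filtering is the *minimum* refined MSE over the grid (robust when the
refinement landscape is rugged; it coincides with the threshold-0 MSE
otherwise). The filtered model is the fewest-parameter variant within the
selection threshold (default 5e-3) of that baseline, ties to the larger
threshold. When topology is *interpreted* (e.g. asking whether a specific
edge survived training), models are first reduced at threshold 0, which
prunes gates that feed no measured node and hence were never constrained
by the data.

## Ensemble statistics

Gate frequency is the fraction of models with the gate active. Gate
sensitivity is 1 − k for Hill slots (floored at 0 for k > 1) and
slope/2 for linear slots; a 2-input gate's sensitivity is the mean of its
slots'. Ensemble spread uses the sample (ddof = 1) standard deviation;
CV = sd/mean is undefined (reported missing, excluded from mean-CV
summaries) where the mean is 0. Response surfaces evaluate only the
profiled node's gates with inputs clamped to the grid — no upstream
simulation; grid-external gate inputs are held at 0.

Cross-validation: k-fold partitions the non-missing observation *cells*;
holdout removes one signal under one stimulus across all inhibitor
conditions, requiring the signal to be at least partially activated
(≥ 0.1; the notion "partially activated" needs a number and 0.1 is our
choice) both under the held-out stimulus and under some other one. Test
sets are classified into accuracy/precision quadrants with cutoffs
MSE > 0.20 and CV > 0.25.

Significance against null MSE distributions: the z-score branch assumes a
normal null; a Jarque–Bera check (JB = m/6·(S² + (K−3)²/4), χ²₂ tail,
α = 0.001) decides automatically between it and the empirical fraction of
nulls at or below the real score, which is reported as the conservative
bound 1/n when no null scores as low.

## Synthetic benchmarks

The generator produces random signed DAGs (stimuli first in topological
order, every non-stimulus node wired to an earlier node, hence reachable
from a stimulus), ground-truth models inside the hypothesis space (or
near it: off-grid draws k ∈ [0.15, 0.75], slope ∈ [0.2, 0.8] away from
the grid), and noise-free or truncated-Gaussian-noised datasets clipped
to [0, 1]. Noise defaults to 0 — the toy comparisons are about structural
identifiability, not measurement error; 0.1 is a realistic level for
bead-based phospho-assays when robustness to noise is the question.

The hand-authored 15-node example network is synthetic: it emulates the
*shape* of classic growth-factor/inflammatory toys (two stimuli, two
druggable kinases, six readouts, a partially activated branch with gain
0.3 putting AKT/JNK near 0.30/0.20) without transcribing any published
map. What passing on it shows: the workflow recovers topology and
parameters when the generating process is (near) the hypothesis space and
the design spans the response range. What it does not show: behaviour
under model misspecification, biological noise structure, or feedback —
real data have all three.

Null controls: data randomization permutes the non-missing values across
cells (positions and missingness fixed); network randomization permutes
edge sources ("swap heads", signs travel with the moved endpoint),
targets ("swap tails"), exchanges whole input sets between output nodes
("swap inputs"), or redraws a size-matched random graph in which stimuli
keep no in-edges and ≥ 1 out-edge and every node stays connected. Edge
perturbation removes or adds `round(fraction·|E|)` edges (additions avoid
duplicates and never target a stimulus).

## Known limitations

* Cycles: compression is conservative and simulation may legitimately not
  converge; no asynchronous or ODE semantics.
* Reduction is greedy, not exhaustive; with rugged landscapes different
  thresholds can in principle yield non-nested topologies.
* The GA offers no optimality certificate (the exhaustive-enumeration
  cross-check in the tests is only feasible for very small h).
* Multi-timepoint data are carried (DA columns) but not modeled: one
  steady-state value per condition.
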