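"""Cross-validation: k-fold over cells and signal/stimulus holdout.

k-fold checks whether the models generalize at all; the holdout harness
asks the harder question the ensemble statistics are built for — can the
family predict a signal it never saw under one stimulus, and does the
ensemble spread (CV) flag the prediction as trustworthy or not?
Each test set lands in an accuracy/precision quadrant using the cutoffs
MSE > 0.20 (inaccurate) and CV > 0.25 (imprecise).
"""

from cflnet.analysis import PipelineConfigLite, holdout_crossval, kfold_crossval
from cflnet.network import compress, expand
from cflnet.synth import example_dataset, example_pkn
from cflnet.training import GAConfig

hs = expand(compress(example_pkn()))
dataset = example_dataset()
budget = PipelineConfigLite(
    ga=GAConfig(population_size=20, max_generations=50,
                stall_generations=15, seed=0),
    n_runs=3)

report = kfold_crossval(hs, dataset, folds=4, pipeline_config=budget, seed=0)
print("4-fold cross-validation:")
print(report.entries[["fold", "n_test_cells", "training_mse", "test_mse",
                      "quadrant"]].to_string(index=False))

entry = holdout_crossval(hs, dataset, signal="JNK", stimulus="TNFA",
                         pipeline_config=budget)
print(f"\nholdout JNK under TNFA: test MSE {entry['test_mse']:.3f}, "
      f"mean CV {entry['mean_cv']:.3f} -> {entry['quadrant']}")
# Test MSE close to the training MSE means the family is predictive, not
# overfit; the quadrant tells whether the held-out prediction could have
# been trusted a priori.
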