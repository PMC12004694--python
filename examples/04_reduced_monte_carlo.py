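"""Run a reduced Monte Carlo benchmark and print the per-figure table.

Runs 150 replicates x 1,000 observations of the variable-total study for
five parametric families under all three truth mechanisms, and prints the
median [95% simulation interval] estimates for the 100-kcal reallocation.
The headline design uses 10,000 replicates; medians and intervals are
already stable at a few hundred.
"""

import codasub as cs
from codasub.study import ExperimentConfig, figure_table, summarise

truths = {k: cs.default_truth(k, "variable") for k in ("linear", "log2", "ilr")}
config = ExperimentConfig(
    scenario="variable",
    families=("2A", "2B", "2Bprime", "2C", "2Cprime"),
    n_datasets=150,
    n_obs=1000,
    master_seed=2024,
)
results = cs.run(config, truths)
summary = summarise(results, truths)

print("median [95% SI] estimate of the 100-kcal carb-for-protein effect (mmol/l)")
print("columns: true data-generating mechanism\n")
print(figure_table(summary, delta=100.0).to_string())

print(
    "\nReading guide: a family is unbiased under a mechanism when the truth "
    "row sits inside its interval.  2B (nutrient density, no total "
    "adjustment) is biased everywhere; 2B' rescues it only under the linear "
    "truth; 2C is biased even under its own log2 truth, while the "
    "all-components 2C' is not."
)
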