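"""The full evaluation grid: models x lesion/patient x all/DRE-negative.

For each cell the grid reports the apparent AUC, the bootstrap
optimism-corrected AUC and the Venkatraman-Begg permutation p-value
against the clinical model.  The DRE-negative subset probes whether a
model's performance survives removing the strongest clinical signal.
"""

from radiorisk.evaluation import ExperimentConfig
from radiorisk.pipeline import run_cohort_analysis
from radiorisk.synthetic import CohortConfig

config = CohortConfig(n_patients=40, lesion_count_probs={1: 1.0}, seed=3)
experiment = ExperimentConfig(model_ids=(1, 2, 5), n_boot=100, n_perm=300, seed=0)
df, results = run_cohort_analysis(config, experiment)

cols = ["model", "level", "subset", "n", "n_pos", "auc", "oc_auc", "p_vs_model1"]
print(results[cols].round(3).to_string(index=False))
print("\nReading: radiomics models (2, 5) should stay stable on the "
      "DRE-negative subset while the clinical model (1) degrades when "
      "DRE carries most of the clinical signal.")
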