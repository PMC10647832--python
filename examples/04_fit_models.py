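"""Fit the clinical and lesion-radiomics models on a synthetic cohort.

Model 1 uses the four pre-biopsy clinical inputs; Model 2 selects lesion
radiomic features by the adaptive LASSO (tumor volume HRS6 is always
forced in) and refits an unpenalized logistic model on the selection.
"""

from radiorisk.evaluation import roc_auc
from radiorisk.modeling import ModelSpec, fit_model
from radiorisk.pipeline import build_analysis_table
from radiorisk.synthetic import CohortConfig, generate_cohort

cases = generate_cohort(CohortConfig(n_patients=40,
                                     lesion_count_probs={1: 1.0}, seed=3))
df = build_analysis_table(cases)
y = df["low_risk"].astype(int)
print(f"cohort: {len(df)} lesions, {y.sum()} low risk")

for mid in (1, 2):
    model = fit_model(ModelSpec(mid, seed=0), df)
    auc = roc_auc(model.predict_lesion(df), y).auc
    print(f"\nModel {mid}: variables = {model.variables}")
    print(f"  apparent AUC = {auc:.3f}")
    if model.selected:
        print(f"  adaptive LASSO selected {len(model.selected)} of "
              f"{len(model.spec.penalized_pool)} pool features")
print("\n(apparent AUC is optimistic; see 05_evaluate_grid.py for the "
      "bootstrap-corrected version)")
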