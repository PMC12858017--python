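"""Per-SOC classifiers with imbalance correction and Bayesian tuning.

Trains one random forest and one decision tree per SOC on interaction
features, with SMOTE+Tomek resampling of the training split and a short
Gaussian-process hyperparameter search, then compares the two model
kinds with a paired t-test.
"""

import pvsignal as pv
from pvsignal.modeling import DESK_SEARCH_SPACE

world = pv.generate_world(pv.SyntheticConfig(seed=7))
matrix = pv.filter_confidence(world.interactions)          # scores < 0.4 -> 0
_, labels = pv.label_signals(world.reports, drugs=matrix.drug_ids)

settings = pv.RunSettings(
    space=DESK_SEARCH_SPACE, n_trials=5, cv_folds=3, seed=7,
)
result = pv.run_all_socs(matrix, labels, settings)

frame = result.metrics_frame()
cols = ["soc", "model_kind", "roc_auc", "accuracy", "f1", "mcc"]
print(frame[frame["trainable"]][cols].round(3).to_string(index=False))

pooled = result.pooled["forest"]
print(f"\npooled forest test cells: TN {pooled['pct_tn']:.1f}%  "
      f"TP {pooled['pct_tp']:.1f}%  FN {pooled['pct_fn']:.1f}%  "
      f"FP {pooled['pct_fp']:.1f}%")

cmp = result.comparison["roc_auc"]
print(f"forest vs tree ROC AUC paired t-test: t = {cmp['statistic']:.2f}, "
      f"p = {cmp['pvalue']:.4f} (n = {cmp['n']} SOCs)")
print("\nPlanted SOCs separate well; null SOCs hover near chance - their")
print("labels are pure Poisson reporting noise with no mechanistic signal.")
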