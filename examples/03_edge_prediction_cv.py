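"""Per-relation edge prediction with 5-fold remove-and-rebuild CV.

Each fold holds out 20% of the relation's edges, re-closes, re-walks and
re-embeds the remaining graph, fits a logistic regression on concatenated
endpoint embeddings against type-constrained negatives, and scores the
held-out edges.  The destroyed-structure null shows the floor.
"""
from kgwalk import (SyntheticSpec, crossvalidate_property, destroy_signal,
                    generate, scaled_down_eval_params)

kg, _ = generate(SyntheticSpec(seed=0))
params = scaled_down_eval_params()

report = crossvalidate_property(kg, "hasTarget", params, seed=0)
print("hasTarget (drug -> protein), planted block structure:")
for fold in report.folds:
    print(f"  fold {fold.fold}: F={fold.f_measure:.3f} "
          f"AUC={fold.rocauc:.3f} leakage={fold.leakage}")
print(f"  mean:  F={report.mean_f:.3f} AUC={report.mean_auc:.3f}")

null = destroy_signal(kg, "hasTarget", seed=7)
null_report = crossvalidate_property(null, "hasTarget", params, seed=0)
print(f"\nendpoint-rewired null: mean AUC={null_report.mean_auc:.3f}")
print("High AUC on the planted graph and chance-level AUC on the null "
      "show the model reads real neighborhood signal, not an artifact.")
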