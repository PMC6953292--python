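"""Small variable-recovery study on synthetic data.

Each replicate draws a fresh dataset from the generator, picks the UST
penalty by cross-validation, fits, and scores the selected variables against
the planted support: TPR = fraction of planted variables recovered
(relative to min(k, #selected)), TNR = fraction of irrelevant variables
correctly excluded.
"""

from mspls import SimulationConfig, run_study

study = run_study(
    SimulationConfig(n=60, p=(120, 120, 30), k=(6, 6, 6)),
    replicates=10,
    folds=10,
    seed=42,
)

print(study.records[["tpr_X1", "tpr_X2", "tnr_X1", "tnr_X2", "of_X3", "lambda1"]]
      .round(3).to_string())
a = study.aggregates
print(f"\nmeans over {study.replicates} replicates: "
      f"TPR=({a['mean_tpr_X1']:.2f}, {a['mean_tpr_X2']:.2f})  "
      f"TNR=({a['mean_tnr_X1']:.3f}, {a['mean_tnr_X2']:.3f})  "
      f"OF(X3)={a['mean_of_X3']:.1f}")
print("High TPR with TNR near 1 means cross-validated soft thresholding "
      "recovers the planted variables while excluding noise.")
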