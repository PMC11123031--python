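"""Hyperparameter search with median-rule pruning.

Random search over a small gradient-boosted-tree space: each trial runs up
to 4 CV iterations and is pruned when its running median MCC falls below
that of previously completed trials at the same step.  The objective is the
median MCC, matching how the best configuration is picked for the final
evaluation run.
"""

from pathpair import ResultsStore, SimConfig, build_pair_dataset, simulate, tune

metabolites, membership, _ = simulate(
    SimConfig(n_metabolites=200, n_pathways=4, seed=2)
)
ds = build_pair_dataset(metabolites, membership)

space = {
    "n_estimators": {"type": "int", "low": 20, "high": 200},
    "max_depth": {"type": "int", "low": 2, "high": 8},
    "learning_rate": {"type": "float", "low": 0.03, "high": 0.3, "log": True},
}

with ResultsStore() as store:
    best = tune(
        space, ds, kind="gbt", n_trials=8, cv_per_trial=4, store=store, seed=0
    )
    trials = store.query(
        "SELECT trial_id, median_mcc, pruned FROM trials ORDER BY trial_id"
    )

print(trials.to_string(index=False))
print("\nbest parameters:", best)
# Pruned trials stopped early; the winner has the highest median MCC.
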