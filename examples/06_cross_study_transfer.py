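"""Train on one synthetic cohort, predict the other.

Both cohorts share the same latent dynamics parameters, so a theory model
tuned on the small study should generalize to the large one with little
loss — the cross-study analogue of the within-study estimate.
"""

from habitdyn import ModelSpec, TuningBudget, cross_dataset_evaluate, default_config, generate_study

study1 = generate_study(default_config("study1"), seed=3)
study2 = generate_study(default_config("study2"), seed=4)

result = cross_dataset_evaluate(
    study1.logs, study1.surveys, study2.logs, study2.surveys,
    ModelSpec("theory"), k=9, seed=0,
    budget=TuningBudget("random", steps=200, seed=0),
)

print("parameters tuned on study 1:",
      {k: round(v, 3) for k, v in result.tuned_params.items()})
m = result.metrics
print(f"transfer AUC on study 2: {m.auc:.3f}")
print(f"accuracy {m.accuracy:.3f}, TPR {m.tpr:.3f}, FPR {m.fpr:.3f} "
      f"at threshold {m.threshold:.3f}")
# An AUC close to the within-study value (~0.74) means the tuned dynamics
# parameters, not cohort-specific quirks, carry the predictive signal.
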