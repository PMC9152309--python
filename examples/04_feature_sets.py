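"""Build the five competing feature sets for one-step-ahead prediction.

Every row predicts one participant-day from information available before
that day; the target is 1 when the behavior is *absent* (the event an
adaptive reminder system wants to catch).
"""

from habitdyn import ModelSpec, build_feature_table, default_config, generate_study

study = generate_study(default_config("study1", n_participants=6), seed=5)

for name in ("survey", "past_br", "past_br7", "weighted_br", "theory"):
    spec = ModelSpec(name, gamma=0.9)
    table = build_feature_table(study.logs, study.surveys, spec)
    print(f"\n{name}: {len(table)} rows, features {spec.feature_names}")
    print(table.head(3).to_string(index=False))
# 'theory' carries only the two computed latent quantities (habit strength
# and accessibility); the others carry self-reports or past-behavior rates
# plus the reminder / lab-session schedule.
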