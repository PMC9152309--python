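# Methods

## Latent dynamics

Habit strength `HS` and memory accessibility `Acc` are deterministic
functions of a participant's observable history. Both updates are
convex-bounded: for parameters in [0, 1] the habit update maps [0, 1] into
itself without clamping, while the accessibility update can exceed 1 only
when `AGP_beh + AGP_rem > 1` and both gains fire on one day, so it is
clamped. Clamping matters in practice because the random search draws
every parameter independently from U(0,1).

Time steps are calendar days: the prediction target is day-level, and the
abstract "steps" of the dynamics become days as soon as the model touches
study data. The context cue defaults to 1 (the constant-context
simplification appropriate for bathroom-bound toothbrushing) but is
overridable per day. Any procedure that plausibly brings the behavior to
mind — app reminders, emailed surveys, laboratory visits — counts as a
reminder for the accessibility update, all with the same gain `AGP_rem`;
in the data model this is `rem OR lab`.

**Missing days freeze the state.** A missing day means the sensor record
is unusable, not that the participant did nothing; applying decay would
fabricate a signal from absent data. The alternative (decay-only) was
considered and rejected for that reason. In the synthetic generator the
*latent* trajectory advances through missing days on the true behavior —
the recording fails, not the person — which makes the freeze rule an
approximation that the recovery experiments must (and do) tolerate.

## Feature sets

All features for predicting day *t* use information available before *t*;
the reminder/lab indicators of day *t* itself are allowed because they are
part of the intervention schedule and known in advance. The leakage test
in the suite enforces exactly this: deleting all behavior and survey data
from day ≥ *t* leaves day-*t* features unchanged.

- Survey features are carried forward from the most recent completed
  survey (the daily imputation rule has to be invented; last observation
  carried forward is the least creative choice).
- Rate features exclude missing days from numerator and denominator; when
  no past day is observed they fall back to the baseline self-reported
  prior-week rate, which also seeds day 1 for the discounted rate.
- The discounted rate keeps the denominator *t−1* of its defining formula
  (equivalently, the count of observed past days under missingness) even
  though this shrinks the feature as *t* grows; fidelity to the printed
  definition wins over normalizing by `Σγ^k`.
- Theory features start at `HS_1 = (SRBAI−1)/6` and `Acc_1 = 1` (a freshly
  persuaded user has the behavior maximally in mind). A missing baseline
  SRBAI defaults to `HS_1 = 0` with a warning — a new behavior has no
  habit — and is configurable.

## Classifier

Plain maximum-likelihood logistic regression (scikit-learn, `penalty=None`,
lbfgs, tol 1e−10) for every feature set, so comparisons isolate the
features. Quasi-separation is flagged (`converged=False`, triggered by
exhausted iterations or coefficients beyond ±100 log-odds) rather than
fatal; an opt-in ridge term exists solely to stabilize tiny inner-fold
fits and is off by default everywhere. Feature importance is the
standardized-coefficient magnitude |coef|·SD(feature), reported as ratios;
other conventions (permutation importance, likelihood-ratio decomposition)
would be defensible — this one is cheap, deterministic, and matches how
the ratio of habit strength to accessibility influence is usually quoted.

## Evaluation protocol

Outer folds are balanced random partitions of *participants* (9 folds of
4 for the small design, 5 folds of 15 for the large one). Inside each
outer round, one training fold — the next fold in cyclic order, a
deterministic, rotation-free choice — serves as the tuning test set and
the remaining k−2 train the candidates; full inner rotation (average AUC
over all k−1 inner splits) is available via a flag but is not the
default, trading a noisier tuning signal for a k−2× cheaper search. Ties
in the search go to the earliest step, making results reproducible under
a fixed seed.

ROC/AUC and all threshold metrics are computed on predictions pooled
across outer folds (per-fold tuned parameters are retained separately);
pooling is assumed over fold-averaging of curves. Thresholds maximize
Youden's J = TPR − FPR, with ties broken toward lower FPR. McNemar tests
use the continuity-corrected χ²(1) statistic on discordant pairs, with
each model's correctness judged at its *own* optimal threshold, on the
intersection of rows all models predicted; no multiple-testing correction
is applied across the pairwise matrix. Cross-study transfer tunes by
grouped k-fold on the entire training study (pooled out-of-fold AUC),
refits on all of it, and scores the held-out study once.

## Synthetic cohorts

The generator's premise is the theory's own causal claim: behavior
probability is logistic in the latent state,
`P(Beh) = σ(−1.1 + 3.0·HS + 1.0·Acc + 0.8·u_i)` with `u_i ~ N(0,1)` a
stable individual effect. True dynamics parameters default to HDP = 0.10,
HGP = 0.20, ADP = 0.28, AGP_beh = 0.13, AGP_rem = 0.26. Initial habit
strength is Beta(1, 5) — participants were recruited precisely because
the target session was not yet habitual — and the behavior-model weights
were fixed once so that the large-cohort brushing prevalence lands near
the ~63 % such interventions observe (the generated cohorts come out
around 61–64 %). Surveys are noisy clipped readouts of the latent state
(SRBAI = 1 + 6·HS + ε on the 1–7 scale, σ = 0.5 by default); attitudes
track a stable participant-level latent value and carry no dynamic
signal. Reminder schedules mirror the two designs: daily for week 1 plus
alternate days in week 2 (small design), and intro/lab sessions plus two
emailed surveys (large design). Days go missing independently with
probability 0.05. Reproducibility is per participant: stream *i* is
seeded by `(seed, i)`, so a participant's data are invariant to cohort
size.

What passing tests on these cohorts shows: the pipeline is internally
consistent — features leak nothing, grouped folds isolate participants,
the search recovers generative habit parameters (mean tuned HDP/HGP
within ±0.15 of truth over 5 seeds at n = 75 × 21), and the theory
feature set wins when surveys are noisy *because the generator makes the
theory true*. What it does not show: anything about real behavior, where
the generative process is unknown, context varies, and surveys may carry
information the latent state lacks.

## Numerical choices and problem sizes

Dynamics equivalence is asserted to 1e−12 against literal transcriptions
of the update equations; vectorized and scalar simulation paths agree to
the same tolerance. AUC is checked exactly (including tie credit) against
brute-force pair counting up to n = 200. The package's own analyses run
at the emulated study sizes — 36 and 75 participants × 21 days, 1000-step
random search, 100-step γ grid — which keeps a full five-model comparison
under a minute and the complete parameter-recovery experiment a few
minutes on one core.

## Known limitations

Episode preprocessing begins at timestamped episodes; raw accelerometer
processing is upstream device-software territory. Bin boundaries use a
half-open convention and the 0:00–5:00 bin is attributed to the previous
evening; both conventions are stated rather than derivable. The McNemar
correctness pairing and the ROC pooling rule are protocol assumptions
(flagged above). Alternative habit-learning recurrences, survey
psychometrics, and cue inference from context data are out of scope.
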