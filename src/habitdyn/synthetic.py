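"""Synthetic toothbrushing-intervention studies.

Generates datasets with the statistical structure the analysis pipeline
assumes — without any real sensor data — so that every downstream stage
(feature building, nested cross-validation, model comparison, parameter
recovery) can be exercised and tested end to end.

The generative model is the latent habit model itself: each participant
carries a habit-strength / accessibility state evolving under the true
dynamics parameters, and the probability of performing the behavior on a
day is a logistic function of that state plus a stable individual effect::

    P(Beh_t = 1) = sigmoid(b0 + w_hs * HS_t + w_acc * Acc_t + w_ind * u_i)

This makes the theory-based feature set informative *by construction* —
which is the working premise being probed, not a claim about real data.
Weekly surveys are noisy readouts of the latent state (SRBAI tracks HS on
the 1-7 scale); missingness hides a day's recorded behavior but does not
interrupt the latent dynamics (the sensor fails, not the person).

Two preset configurations emulate the two intervention designs:

* ``study1`` — 36 participants, 21 days, reminders daily in week 1 and on
  alternate days in week 2, none afterward; an introduction meeting on
  day 1; surveys at baseline and each week's end.
* ``study2`` — 75 participants, 21 days, an introduction session (day 1)
  and a laboratory intervention session (day 8), two emailed surveys in
  the follow-up (days 14 and 21).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import AccessParams, HabitParams, step_accessibility, step_habit

__all__ = [
    "BehaviorCoefs",
    "SyntheticConfig",
    "SyntheticStudy",
    "PrevalenceReport",
    "default_config",
    "generate_study",
    "prevalence_report",
]


@dataclass(frozen=True)
class BehaviorCoefs:
    """Log-odds weights of the latent-state behavior model."""

    intercept: float = -1.1
    weight_hs: float = 3.0
    weight_acc: float = 1.0
    weight_individual: float = 0.8


@dataclass(frozen=True)
class SyntheticConfig:
    n_participants: int
    n_days: int
    habit_params: HabitParams = HabitParams(hdp=0.10, hgp=0.20)
    access_params: AccessParams = AccessParams(adp=0.28, agp_beh=0.13, agp_rem=0.26)
    beh_coefs: BehaviorCoefs = BehaviorCoefs()
    hs0_beta: tuple[float, float] = (1.0, 5.0)
    reminder_schedule: tuple[int, ...] = ()
    lab_schedule: tuple[int, ...] = ()
    survey_days: tuple[int, ...] = ()
    survey_noise_sd: float = 0.5
    p_missing: float = 0.05
    label: str = "custom"

    def __post_init__(self) -> None:
        if self.n_participants <= 0 or self.n_days <= 0:
            raise ValueError("n_participants and n_days must be positive")
        if not 0.0 <= self.p_missing < 1.0:
            raise ValueError("p_missing must lie in [0, 1)")
        if len(self.reminder_schedule) not in (0, self.n_days):
            raise ValueError("reminder_schedule must have one entry per day")
        if len(self.lab_schedule) not in (0, self.n_days):
            raise ValueError("lab_schedule must have one entry per day")


@dataclass
class SyntheticStudy:
    """Generated logs + surveys plus the latent truth behind them."""

    logs: pd.DataFrame      # participant_id, day, beh (NaN = missing), cue, rem, lab
    surveys: pd.DataFrame   # participant_id, day, srbai, att_*, self_report_rate
    truth: pd.DataFrame     # participant_id, day, beh_true, hs, acc, effect
    config: SyntheticConfig = field(repr=False)
    seed: int = 0


def default_config(study: str, **overrides) -> SyntheticConfig:
    """Preset emulating one of the two intervention designs.

    Keyword overrides replace individual fields (e.g. ``survey_noise_sd=2.0``
    for a noisy-survey scenario).
    """
    if study == "study1":
        n_days = 21
        # daily reminders in week 1, alternate days (9, 11, 13) in week 2
        rem = [1 if d <= 7 or d in (9, 11, 13) else 0 for d in range(1, n_days + 1)]
        base = dict(
            n_participants=36,
            n_days=n_days,
            reminder_schedule=tuple(rem),
            lab_schedule=tuple(1 if d == 1 else 0 for d in range(1, n_days + 1)),
            survey_days=(1, 7, 14, 21),
            label="study1",
        )
    elif study == "study2":
        n_days = 21
        # baseline intro (day 1), lab intervention session (day 8),
        # two emailed follow-up surveys acting as reminders (days 14, 21)
        base = dict(
            n_participants=75,
            n_days=n_days,
            reminder_schedule=tuple(1 if d in (14, 21) else 0 for d in range(1, n_days + 1)),
            lab_schedule=tuple(1 if d in (1, 8) else 0 for d in range(1, n_days + 1)),
            survey_days=(1, 8, 14, 21),
            label="study2",
        )
    else:
        raise ValueError(f"unknown study preset {study!r}; expected 'study1' or 'study2'")
    base.update(overrides)
    return SyntheticConfig(**base)


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


def generate_study(config: SyntheticConfig, seed: int) -> SyntheticStudy:
    """Draw one study.

    Reproducibility contract: the same ``(config, seed)`` yields identical
    output, and each participant's stream is seeded by
    ``(seed, participant_index)`` so individual trajectories do not depend
    on cohort size.
    """
    t = config.n_days
    rem_sched = np.array(config.reminder_schedule or [0] * t)
    lab_sched = np.array(config.lab_schedule or [0] * t)
    c = config.beh_coefs
    hp, ap = config.habit_params, config.access_params

    log_rows, survey_rows, truth_rows = [], [], []
    for i in range(config.n_participants):
        rng = np.random.default_rng([int(seed), i])
        pid = f"{config.label}_p{i + 1:03d}"
        hs = float(rng.beta(*config.hs0_beta))
        acc = 1.0
        effect = float(rng.standard_normal())
        latent_att_inst = float(np.clip(5.0 + rng.standard_normal(), 1.0, 7.0))
        latent_att_aff = float(np.clip(4.0 + rng.standard_normal(), 1.0, 7.0))
        beh_hist: list[int] = []
        # baseline self-report of the prior week's behavior rate: a weak
        # habit means the behavior was rarely performed before the study
        base_rate = float(np.clip(hs + 0.1 * rng.standard_normal(), 0.0, 1.0))

        for day in range(1, t + 1):
            rem = int(rem_sched[day - 1])
            lab = int(lab_sched[day - 1])
            if day in config.survey_days:
                if day == 1:
                    rate = base_rate
                else:
                    window = beh_hist[-7:]
                    rate = float(np.mean(window)) if window else base_rate
                survey_rows.append(
                    {
                        "participant_id": pid,
                        "day": day,
                        "srbai": float(
                            np.clip(1.0 + 6.0 * hs + config.survey_noise_sd * rng.standard_normal(), 1.0, 7.0)
                        ),
                        "att_instrumental": float(
                            np.clip(latent_att_inst + config.survey_noise_sd * rng.standard_normal(), 1.0, 7.0)
                        ),
                        "att_affective": float(
                            np.clip(latent_att_aff + config.survey_noise_sd * rng.standard_normal(), 1.0, 7.0)
                        ),
                        "self_report_rate": rate,
                    }
                )
            p = _sigmoid(c.intercept + c.weight_hs * hs + c.weight_acc * acc + c.weight_individual * effect)
            beh = int(rng.random() < p)
            beh_hist.append(beh)
            missing = bool(rng.random() < config.p_missing)
            log_rows.append(
                {
                    "participant_id": pid,
                    "day": day,
                    "beh": np.nan if missing else beh,
                    "cue": 1,
                    "rem": rem,
                    "lab": lab,
                }
            )
            truth_rows.append(
                {
                    "participant_id": pid,
                    "day": day,
                    "beh_true": beh,
                    "p_beh": p,
                    "hs": hs,
                    "acc": acc,
                    "effect": effect,
                }
            )
            # latent state advances on the *actual* behavior: missingness is a
            # recording failure, not a gap in the participant's life
            rem_eff = 1 if (rem or lab) else 0
            hs = step_habit(hs, beh, 1, hp)
            acc = step_accessibility(acc, beh, rem_eff, ap)

    return SyntheticStudy(
        logs=pd.DataFrame(log_rows),
        surveys=pd.DataFrame(survey_rows),
        truth=pd.DataFrame(truth_rows),
        config=config,
        seed=int(seed),
    )


@dataclass
class PrevalenceReport:
    """Case balance of a study under the non-brushing-positive coding."""

    n_observations: int       # predictable rows: days 2..T with observed outcome
    n_positive: int           # non-brushing days
    n_negative: int           # brushing days
    participant_rates: pd.Series  # per-participant observed brushing rate
    daily_rate: pd.Series     # brushing rate per day across participants

    @property
    def positive_fraction(self) -> float:
        return self.n_positive / self.n_observations

    @property
    def negative_fraction(self) -> float:
        return self.n_negative / self.n_observations


def prevalence_report(study: SyntheticStudy) -> PrevalenceReport:
    """Summarize case counts the way the prediction task will see them."""
    logs = study.logs
    if logs.empty:
        raise ValueError("empty study")
    predictable = logs[(logs["day"] >= 2) & logs["beh"].notna()]
    n_pos = int((predictable["beh"] == 0).sum())
    n_neg = int((predictable["beh"] == 1).sum())
    observed = logs[logs["beh"].notna()]
    return PrevalenceReport(
        n_observations=len(predictable),
        n_positive=n_pos,
        n_negative=n_neg,
        participant_rates=observed.groupby("participant_id")["beh"].mean(),
        daily_rate=observed.groupby("day")["beh"].mean(),
    )
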