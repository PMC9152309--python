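"""Feature construction for one-step-ahead prediction of non-brushing.

Five competing feature sets, all predicting the *absence* of the target
behavior on the next day (non-brushing is the positive class — the event an
adaptive intervention wants to detect):

``survey``
    Last-observed weekly self-reports (behavioral automaticity SRBAI,
    instrumental and affective attitude, on their 1-7 scales) plus same-day
    lab-session and reminder indicators.
``past_br``
    Cumulative past behavior rate since the study start, plus lab/reminder.
    The self-reported prior-week rate seeds the first day.
``past_br7``
    Behavior rate over the last 7 days; with fewer than 7 past days it
    falls back to the full-history rate.
``weighted_br``
    Temporally discounted behavior count
    ``sum_i B_i * gamma**(t-i) / (t-1)``; the discount ``gamma`` is a tuned
    hyperparameter.
``theory``
    Only the two computed latent quantities — habit strength and memory
    accessibility — obtained by running the dynamics recurrences over the
    participant's observed history.  Initial habit strength is the baseline
    SRBAI rescaled to [0, 1]; initial accessibility is 1 (a freshly
    persuaded user has the behavior maximally in mind).

Features for predicting day ``t`` use only information available before
``t`` — behavior through day ``t-1``, surveys completed by day ``t-1`` —
plus the day-``t`` reminder/lab indicators, which are part of the
intervention schedule and hence known in advance.  Missing behavior days
are excluded from rate numerators and denominators and freeze the dynamics
state.  Days with a missing next-day outcome produce no row.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .dynamics import AccessParams, HabitParams, simulate_arrays

__all__ = [
    "ModelSpec",
    "MODEL_NAMES",
    "past_br",
    "past_br7",
    "weighted_br",
    "theory_features",
    "build_feature_table",
    "StudyArrays",
]

MODEL_NAMES = ("survey", "past_br", "past_br7", "weighted_br", "theory")

ModelName = Literal["survey", "past_br", "past_br7", "weighted_br", "theory"]

#: default dynamics parameters (near the values tuning typically selects);
#: used when a theory spec is built without explicit parameters
DEFAULT_HABIT_PARAMS = HabitParams(hdp=0.10, hgp=0.20)
DEFAULT_ACCESS_PARAMS = AccessParams(adp=0.28, agp_beh=0.13, agp_rem=0.26)


@dataclass(frozen=True)
class ModelSpec:
    """Names a feature set and carries its tunable parameters."""

    name: ModelName
    gamma: float | None = None
    habit_params: HabitParams | None = None
    access_params: AccessParams | None = None

    def __post_init__(self) -> None:
        if self.name not in MODEL_NAMES:
            raise ValueError(f"unknown model {self.name!r}; expected one of {MODEL_NAMES}")
        if self.name == "weighted_br":
            g = self.gamma if self.gamma is not None else 1.0
            if not 0.0 < g <= 1.0:
                raise ValueError(f"gamma must lie in (0, 1], got {g!r}")
            object.__setattr__(self, "gamma", g)
        if self.name == "theory":
            if self.habit_params is None:
                object.__setattr__(self, "habit_params", DEFAULT_HABIT_PARAMS)
            if self.access_params is None:
                object.__setattr__(self, "access_params", DEFAULT_ACCESS_PARAMS)

    @property
    def is_tunable(self) -> bool:
        return self.name in ("weighted_br", "theory")

    def with_params(self, **kwargs) -> "ModelSpec":
        return replace(self, **kwargs)

    @property
    def feature_names(self) -> list[str]:
        if self.name == "survey":
            return ["srbai", "att_instrumental", "att_affective", "lab", "rem"]
        if self.name == "theory":
            return ["hs", "acc"]
        return [{"past_br": "br", "past_br7": "br7", "weighted_br": "wbr"}[self.name], "lab", "rem"]


# ---------------------------------------------------------------------------
# scalar reference implementations (the vectorized table builder must agree)
# ---------------------------------------------------------------------------

def past_br(history: Sequence[float | None], init_rate: float) -> float:
    """Mean of the observed past behavior indicators; ``init_rate`` if none."""
    obs = [b for b in history if b is not None and not (isinstance(b, float) and np.isnan(b))]
    if not obs:
        return float(init_rate)
    return float(np.mean(obs))


def past_br7(history: Sequence[float | None], init_rate: float) -> float:
    """Behavior rate over the last 7 days (full-history rate when shorter)."""
    if len(history) < 7:
        return past_br(history, init_rate)
    window = history[-7:]
    obs = [b for b in window if b is not None and not (isinstance(b, float) and np.isnan(b))]
    if not obs:
        return past_br(history, init_rate)
    return float(np.mean(obs))


def weighted_br(
    history: Sequence[float | None], t: int, gamma: float, init_rate: float
) -> float:
    """Discounted behavior count ``sum B_i * gamma**(t-i)`` over observed days.

    The denominator counts the observed past days (it equals ``t-1`` for a
    fully observed history, the usual definition).  Day 1 — no history —
    returns the self-reported prior-week rate.
    """
    if not 0.0 < gamma <= 1.0:
        raise ValueError(f"gamma must lie in (0, 1], got {gamma!r}")
    if t < 1:
        raise ValueError("day index t must be >= 1")
    num = 0.0
    n_obs = 0
    for i, b in enumerate(history[: t - 1], start=1):
        if b is None or (isinstance(b, float) and np.isnan(b)):
            continue
        num += float(b) * gamma ** (t - i)
        n_obs += 1
    if n_obs == 0:
        return float(init_rate)
    return num / n_obs


def theory_features(
    beh: Sequence[float | None],
    cue: Sequence[int],
    rem: Sequence[int],
    initial_srbai: float | None,
    habit_params: HabitParams = DEFAULT_HABIT_PARAMS,
    access_params: AccessParams = DEFAULT_ACCESS_PARAMS,
) -> tuple[np.ndarray, np.ndarray]:
    """Latent (HS, Acc) after each day's update for one participant.

    ``HS`` starts at ``(initial_srbai - 1) / 6`` (the 1-7 automaticity scale
    rescaled to [0, 1]) and ``Acc`` at 1.  Element ``j`` is the state after
    the day-``j+1`` update; the features predicting day ``t`` are element
    ``t-2``.  Missing behavior days freeze the state.
    """
    if initial_srbai is None:
        warnings.warn(
            "no baseline automaticity report; initial habit strength set to 0",
            stacklevel=2,
        )
        hs0 = 0.0
    else:
        if not 1.0 <= initial_srbai <= 7.0:
            raise ValueError(f"initial_srbai must lie in [1, 7], got {initial_srbai!r}")
        hs0 = (initial_srbai - 1.0) / 6.0
    b = np.array([np.nan if v is None else float(v) for v in beh])
    observed = ~np.isnan(b)
    hs, acc = simulate_arrays(
        np.nan_to_num(b)[None, :],
        np.asarray(cue, dtype=float)[None, :],
        np.asarray(rem, dtype=float)[None, :],
        observed[None, :],
        np.array([hs0]),
        np.array([1.0]),
        habit_params,
        access_params,
    )
    return hs[0], acc[0]


# ---------------------------------------------------------------------------
# vectorized study representation
# ---------------------------------------------------------------------------

@dataclass
class StudyArrays:
    """Matrix view of a study, one row per participant, one column per day.

    Precomputed once and reused across the thousands of feature rebuilds a
    parameter search performs.
    """

    pids: np.ndarray          # (n,) participant ids
    beh: np.ndarray           # (n, T) behavior, NaN = missing
    cue: np.ndarray           # (n, T)
    rem: np.ndarray           # (n, T) reminder indicator
    lab: np.ndarray           # (n, T) lab-session indicator
    observed: np.ndarray      # (n, T) bool
    in_study: np.ndarray      # (n, T) bool, False past a participant's last day
    hs0: np.ndarray           # (n,) initial habit strength in [0,1]
    init_rate: np.ndarray     # (n,) self-reported prior-week rate
    survey_locf: np.ndarray   # (n, T, 3) srbai/att_instr/att_aff carried forward

    @classmethod
    def from_frames(
        cls,
        logs: pd.DataFrame,
        surveys: pd.DataFrame | None,
        hs0_default: float = 0.0,
        init_rate_default: float = 0.0,
    ) -> "StudyArrays":
        logs = logs.copy()
        if "cue" not in logs.columns:
            logs["cue"] = 1
        logs["cue"] = logs["cue"].fillna(1)
        pids = np.array(sorted(logs["participant_id"].unique(), key=str))
        t_max = int(logs["day"].max())
        n = len(pids)
        beh = np.full((n, t_max), np.nan)
        cue = np.ones((n, t_max))
        rem = np.zeros((n, t_max))
        lab = np.zeros((n, t_max))
        in_study = np.zeros((n, t_max), dtype=bool)
        pid_index = {p: i for i, p in enumerate(pids)}
        for pid, grp in logs.groupby("participant_id"):
            i = pid_index[pid]
            days = grp["day"].to_numpy(dtype=int)
            if len(np.unique(days)) != len(days):
                raise ValueError(f"duplicate day for participant {pid!r}")
            j = days - 1
            beh[i, j] = grp["beh"].to_numpy(dtype=float)
            cue[i, j] = grp["cue"].to_numpy(dtype=float)
            rem[i, j] = grp["rem"].to_numpy(dtype=float)
            if "lab" in grp.columns:
                lab[i, j] = grp["lab"].fillna(0).to_numpy(dtype=float)
            in_study[i, j] = True
        observed = ~np.isnan(beh) & in_study

        hs0 = np.full(n, hs0_default)
        init_rate = np.full(n, init_rate_default)
        survey_locf = np.full((n, t_max, 3), np.nan)
        if surveys is not None and len(surveys):
            surveys = surveys.sort_values(["participant_id", "day"])
            no_baseline = []
            for pid, grp in surveys.groupby("participant_id"):
                if pid not in pid_index:
                    continue
                i = pid_index[pid]
                first = grp.iloc[0]
                if not np.isnan(first.get("srbai", np.nan)):
                    hs0[i] = (float(first["srbai"]) - 1.0) / 6.0
                else:
                    no_baseline.append(pid)
                if not np.isnan(first.get("self_report_rate", np.nan)):
                    init_rate[i] = float(first["self_report_rate"])
                # survey_locf[i, j] = most recent survey completed on day <= j+1,
                # i.e. the values available once day j+1 has ended
                for _, row in grp.iterrows():
                    start = int(row["day"]) - 1
                    vals = [row["srbai"], row["att_instrumental"], row["att_affective"]]
                    survey_locf[i, start:, :] = vals
                # before any survey: backfill from the earliest one
                first_day = int(grp.iloc[0]["day"])
                vals = [first["srbai"], first["att_instrumental"], first["att_affective"]]
                survey_locf[i, : first_day - 1, :] = vals
            if no_baseline:
                warnings.warn(
                    f"{len(no_baseline)} participant(s) lack a baseline automaticity "
                    "report; initial habit strength defaults to "
                    f"{hs0_default}", stacklevel=2,
                )
        return cls(
            pids=pids, beh=beh, cue=cue, rem=rem, lab=lab, observed=observed,
            in_study=in_study, hs0=hs0, init_rate=init_rate, survey_locf=survey_locf,
        )

    @property
    def n_days(self) -> int:
        return self.beh.shape[1]

    # reminders restoring accessibility include lab sessions (any procedure
    # that brings the behavior to mind)
    @property
    def rem_effective(self) -> np.ndarray:
        return np.clip(self.rem + self.lab, 0, 1)


def _rate_features(arrays: StudyArrays, kind: str, gamma: float | None) -> np.ndarray:
    """(n, T) matrix: column t-1 holds the rate feature predicting day t."""
    b = np.nan_to_num(arrays.beh) * arrays.observed
    o = arrays.observed.astype(float)
    n, t_max = b.shape
    cum_b = np.cumsum(b, axis=1)
    cum_o = np.cumsum(o, axis=1)
    out = np.empty((n, t_max))
    init = arrays.init_rate
    if kind == "br":
        for t in range(1, t_max + 1):
            if t == 1:
                out[:, 0] = init
                continue
            num, den = cum_b[:, t - 2], cum_o[:, t - 2]
            out[:, t - 1] = np.where(den > 0, num / np.maximum(den, 1), init)
    elif kind == "br7":
        full = _rate_features(arrays, "br", None)
        for t in range(1, t_max + 1):
            if t <= 8:
                out[:, t - 1] = full[:, t - 1]
                continue
            lo, hi = t - 8, t - 2  # inclusive window of the last 7 past days
            num = cum_b[:, hi] - (cum_b[:, lo - 1] if lo >= 1 else 0)
            den = cum_o[:, hi] - (cum_o[:, lo - 1] if lo >= 1 else 0)
            out[:, t - 1] = np.where(den > 0, num / np.maximum(den, 1), full[:, t - 1])
    elif kind == "wbr":
        # W_{t+1} = gamma * (W_t + B_t) over observed days only
        w = np.zeros(n)
        for t in range(1, t_max + 1):
            if t == 1:
                out[:, 0] = init
            else:
                den = cum_o[:, t - 2]
                out[:, t - 1] = np.where(den > 0, w / np.maximum(den, 1), init)
            if t <= t_max:
                w = gamma * (w + b[:, t - 1])
    else:  # pragma: no cover
        raise ValueError(kind)
    return out


def feature_matrix(
    arrays: StudyArrays, spec: ModelSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Fast path: (X, y, participant_index, day) for all predictable rows.

    Rows are participant-days ``t`` in 2..T whose day-``t`` outcome is
    observed; ``y`` is 1 for non-brushing.
    """
    n, t_max = arrays.beh.shape
    if spec.name == "theory":
        hs, acc = simulate_arrays(
            np.nan_to_num(arrays.beh), arrays.cue, arrays.rem_effective,
            arrays.observed, arrays.hs0, np.ones(n),
            spec.habit_params, spec.access_params,
        )
        feats = np.stack([hs, acc], axis=2)  # state after day t -> predicts day t+1
        feat_for_day = feats[:, :-1, :]      # columns for predicted days 2..T
    elif spec.name == "survey":
        locf = arrays.survey_locf[:, :-1, :]
        lab = arrays.lab[:, 1:, None]
        rem = arrays.rem[:, 1:, None]
        feat_for_day = np.concatenate([locf, lab, rem], axis=2)
    else:
        kind = {"past_br": "br", "past_br7": "br7", "weighted_br": "wbr"}[spec.name]
        rate = _rate_features(arrays, kind, spec.gamma)[:, 1:, None]
        lab = arrays.lab[:, 1:, None]
        rem = arrays.rem[:, 1:, None]
        feat_for_day = np.concatenate([rate, lab, rem], axis=2)

    target_mask = arrays.observed[:, 1:]  # day-t outcome observed, t = 2..T
    rows = np.argwhere(target_mask)
    pid_idx = rows[:, 0]
    day = rows[:, 1] + 2
    x = feat_for_day[pid_idx, rows[:, 1], :]
    y = 1.0 - arrays.beh[pid_idx, day - 1]
    keep = ~np.isnan(x).any(axis=1)
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} rows with undefined features", stacklevel=2
        )
    return x[keep], y[keep].astype(int), pid_idx[keep], day[keep]


def build_feature_table(
    logs: pd.DataFrame,
    surveys: pd.DataFrame | None,
    spec: ModelSpec,
    mode: str | None = None,
) -> pd.DataFrame:
    """One row per predictable participant-day, exportable for audit.

    Columns: ``participant_id``, ``day`` (the predicted day), the spec's
    feature names, and ``target`` (1 = non-brushing).  ``mode`` is an
    optional provenance tag recorded as a table attribute; the behavior
    column of ``logs`` is already the study's day-level outcome.
    """
    arrays = StudyArrays.from_frames(logs, surveys)
    x, y, pid_idx, day = feature_matrix(arrays, spec)
    table = pd.DataFrame(x, columns=spec.feature_names)
    table.insert(0, "participant_id", arrays.pids[pid_idx])
    table.insert(1, "day", day)
    table["target"] = y
    table.attrs["model"] = spec.name
    if mode is not None:
        table.attrs["mode"] = mode
    return table
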