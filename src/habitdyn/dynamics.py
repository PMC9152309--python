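"""Habit-strength and memory-accessibility dynamics.

Two coupled-but-independent recurrences track latent cognitive quantities of a
user who is learning a new daily behavior (e.g. a second toothbrushing
session):

* **Habit strength** ``HS`` grows when the behavior is executed in the
  presence of its context cue and decays otherwise::

      HS[t+1] = HS[t] - HS[t]*HDP + (1 - HS[t]) * Beh[t] * Cue[t] * HGP

* **Memory accessibility** ``Acc`` decays spontaneously and is restored by
  behavior executions and by external reminders::

      Acc[t+1] = Acc[t] - Acc[t]*ADP + (1 - Acc[t]) * (Beh[t]*AGP_beh + Rem[t]*AGP_rem)

All states and parameters live in the unit interval.  The habit update maps
[0,1] into [0,1] for any admissible parameters; the accessibility update can
overshoot 1 only when ``AGP_beh + AGP_rem > 1`` and is therefore clamped.

Under sustained performance (Beh = Cue = 1) habit strength converges
geometrically to the fixed point ``HGP / (HDP + HGP)``; with no behavior it
decays as ``HS[0] * (1 - HDP)**t``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "HabitParams",
    "AccessParams",
    "DynamicsState",
    "StepInput",
    "step_habit",
    "step_accessibility",
    "simulate_dynamics",
    "habit_fixed_point",
]


def _check_unit(value: float, name: str) -> float:
    value = float(value)
    if not 0.0 <= value <= 1.0 or not np.isfinite(value):
        raise ValueError(f"{name} must lie in [0, 1], got {value!r}")
    return value


def _check_binary(value: int, name: str) -> int:
    if value not in (0, 1, 0.0, 1.0, True, False):
        raise ValueError(f"{name} must be binary (0 or 1), got {value!r}")
    return int(value)


@dataclass(frozen=True)
class HabitParams:
    """Decay (HDP) and gain (HGP) rates of the habit-strength recurrence."""

    hdp: float
    hgp: float

    def __post_init__(self) -> None:
        _check_unit(self.hdp, "hdp")
        _check_unit(self.hgp, "hgp")


@dataclass(frozen=True)
class AccessParams:
    """Decay (ADP) and the two gain rates of the accessibility recurrence.

    ``agp_beh`` is the gain attached to a behavior execution, ``agp_rem`` the
    gain attached to an external reminder; both may act on the same day.
    """

    adp: float
    agp_beh: float
    agp_rem: float

    def __post_init__(self) -> None:
        _check_unit(self.adp, "adp")
        _check_unit(self.agp_beh, "agp_beh")
        _check_unit(self.agp_rem, "agp_rem")


@dataclass(frozen=True)
class DynamicsState:
    """Latent state (habit strength, accessibility) after a day's update."""

    hs: float
    acc: float

    def __post_init__(self) -> None:
        _check_unit(self.hs, "hs")
        _check_unit(self.acc, "acc")


@dataclass(frozen=True)
class StepInput:
    """One day's observables: behavior, cue, reminder and an observed flag.

    ``observed=False`` marks a missing day; the simulation freezes the state
    there rather than fabricating decay from unobserved behavior.
    """

    beh: int
    cue: int = 1
    rem: int = 0
    observed: bool = True

    def __post_init__(self) -> None:
        _check_binary(self.beh, "beh")
        _check_binary(self.cue, "cue")
        _check_binary(self.rem, "rem")


def step_habit(hs: float, beh: int, cue: int, params: HabitParams) -> float:
    """One habit-strength update.

    Returns ``hs - hs*HDP + (1-hs)*beh*cue*HGP``.  No clamp is needed: the
    result is a convex-bounded combination that stays in [0, 1] whenever the
    inputs do.
    """
    hs = _check_unit(hs, "hs")
    beh = _check_binary(beh, "beh")
    cue = _check_binary(cue, "cue")
    return hs - hs * params.hdp + (1.0 - hs) * beh * cue * params.hgp


def step_accessibility(acc: float, beh: int, rem: int, params: AccessParams) -> float:
    """One accessibility update, clamped to [0, 1].

    The clamp only activates when ``agp_beh + agp_rem > 1`` and both gains
    fire on the same day.
    """
    acc = _check_unit(acc, "acc")
    beh = _check_binary(beh, "beh")
    rem = _check_binary(rem, "rem")
    gain = beh * params.agp_beh + rem * params.agp_rem
    nxt = acc - acc * params.adp + (1.0 - acc) * gain
    return min(1.0, max(0.0, nxt))


def habit_fixed_point(params: HabitParams) -> float:
    """Equilibrium habit strength under sustained performance (Beh=Cue=1).

    Solves ``HS*HDP = (1-HS)*HGP`` giving ``HGP / (HDP + HGP)``.
    """
    denom = params.hdp + params.hgp
    if denom <= 0.0:
        raise ValueError("habit fixed point undefined when HDP = HGP = 0")
    return params.hgp / denom


def simulate_dynamics(
    schedule: Sequence[StepInput] | Iterable[StepInput],
    init: DynamicsState,
    hp: HabitParams,
    ap: AccessParams,
) -> list[DynamicsState]:
    """Run both recurrences over a day schedule.

    Returns one state per step: element ``t`` is the state *after* applying
    the step-``t`` input to the running state.  Missing days
    (``observed=False``) leave the state unchanged.
    """
    schedule = list(schedule)
    if not schedule:
        raise ValueError("schedule must be non-empty")
    hs, acc = init.hs, init.acc
    out: list[DynamicsState] = []
    for step in schedule:
        if step.observed:
            hs = step_habit(hs, step.beh, step.cue, hp)
            acc = step_accessibility(acc, step.beh, step.rem, ap)
        out.append(DynamicsState(hs=hs, acc=acc))
    return out


def simulate_arrays(
    beh: np.ndarray,
    cue: np.ndarray,
    rem: np.ndarray,
    observed: np.ndarray,
    hs0: np.ndarray,
    acc0: np.ndarray,
    hp: HabitParams,
    ap: AccessParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized simulation over many participants at once.

    All inputs are (n_participants, n_days) arrays except the initial states,
    which are length n_participants.  Missing days (``observed`` False) freeze
    the participant's state.  Returns (HS, Acc) arrays of shape
    (n_participants, n_days) holding the post-update state of every day,
    matching :func:`simulate_dynamics` element-wise.
    """
    beh = np.asarray(beh, dtype=float)
    n, t = beh.shape
    hs = np.asarray(hs0, dtype=float).copy()
    acc = np.asarray(acc0, dtype=float).copy()
    hs_out = np.empty((n, t))
    acc_out = np.empty((n, t))
    for j in range(t):
        obs = observed[:, j]
        hs_new = hs - hs * hp.hdp + (1.0 - hs) * beh[:, j] * cue[:, j] * hp.hgp
        gain = beh[:, j] * ap.agp_beh + rem[:, j] * ap.agp_rem
        acc_new = np.clip(acc - acc * ap.adp + (1.0 - acc) * gain, 0.0, 1.0)
        hs = np.where(obs, hs_new, hs)
        acc = np.where(obs, acc_new, acc)
        hs_out[:, j] = hs
        acc_out[:, j] = acc
    return hs_out, acc_out
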