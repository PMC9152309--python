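"""Simulate habit strength under 60 days of practice, then 60 of neglect.

Habit strength climbs toward its equilibrium HGP/(HDP+HGP) while the
behavior is performed every day, then decays geometrically once it stops.
"""

from habitdyn import (
    AccessParams,
    DynamicsState,
    HabitParams,
    StepInput,
    habit_fixed_point,
    simulate_dynamics,
)

hp = HabitParams(hdp=0.10, hgp=0.20)
ap = AccessParams(adp=0.28, agp_beh=0.13, agp_rem=0.26)

schedule = [StepInput(beh=1)] * 60 + [StepInput(beh=0)] * 60
states = simulate_dynamics(schedule, DynamicsState(hs=0.0, acc=1.0), hp, ap)

print(f"equilibrium habit strength: {habit_fixed_point(hp):.4f}")
for day in (1, 10, 30, 60, 61, 90, 120):
    s = states[day - 1]
    print(f"day {day:3d}  HS={s.hs:.4f}  Acc={s.acc:.4f}")
# HS approaches 0.6667 by day 60, then halves roughly every 7 days
# (decay factor 1-HDP=0.9 per day); Acc settles where daily behavior
# gain balances decay, then collapses once practice stops.
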