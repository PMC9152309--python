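"""Turn timestamped brushing episodes into day-level outcome records.

Episodes are binned by start time; morning brushing counts episodes in
5:00-12:00 (else 12:00-15:00), evening brushing counts 21:00-5:00 (else
19:00-21:00).  Mid-afternoon brushing never counts, and an after-midnight
brush belongs to the previous evening.
"""

import datetime as dt

from habitdyn.preprocessing import Episode, StudyMode, episodes_to_day_records

episodes = [
    Episode("p1", dt.datetime(2024, 3, 1, 7, 15)),   # morning
    Episode("p1", dt.datetime(2024, 3, 1, 22, 40)),  # late evening
    Episode("p1", dt.datetime(2024, 3, 2, 16, 0)),   # mid-day: disregarded
    Episode("p1", dt.datetime(2024, 3, 3, 0, 30)),   # counts for Mar 2 evening
    Episode("p1", dt.datetime(2024, 3, 3, 13, 0)),   # early-afternoon fallback
]

records = episodes_to_day_records(episodes, StudyMode.BRUSH_TWICE)
print("date        morning evening brushed-twice")
for r in records:
    print(f"{r.date}      {r.morning}      {r.evening}       {r.outcome}")
# Mar 1 hits both sessions (outcome 1); Mar 2's only daytime brush is
# disregarded but the 00:30 brush rescues its evening; Mar 3 gets morning
# credit via the early-afternoon fallback but no evening.
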