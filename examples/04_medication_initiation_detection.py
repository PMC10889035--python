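"""Detect therapy initiation from prescription-fill sequences.

Initiation is the first fill of a sequence where (a) the first fill falls
on a day with a PD-coded encounter, (b) at least two fills span more than
90 days within a 180-day window, and (c) the window holds more than 90
total days of pills.  Isolated evaluation fills never qualify.
"""

from pdprog import detect_medication_initiation
from pdprog.model import PrescriptionFill

# A decoy 90-day trial fill, then the true start of treatment at day 400.
fills = [
    PrescriptionFill("levodopa", 100, 90),   # single fill: never qualifies
    PrescriptionFill("levodopa", 400, 30),
    PrescriptionFill("levodopa", 445, 60),
    PrescriptionFill("levodopa", 500, 30),   # span 100 d, 120 days of pills
]
pd_coded_days = {100, 400}

day = detect_medication_initiation(fills, pd_coded_days, "levodopa")
print(f"Detected initiation day: {day}")
print("The day-100 decoy is skipped (one fill is not a sequence); the")
print("day-400 candidate meets all three criteria, so initiation = 400.")

# Without a PD-coded encounter on the first fill day nothing qualifies.
print("No PD-linked first fill ->",
      detect_medication_initiation(fills, set(), "levodopa"))
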