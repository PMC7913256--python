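"""Classify a toy cohort's exposure status under two alternative control windows.

Four subjects with hand-placed dispensing offsets show the four exposure
statuses: intermittent user (case window only), recent stopper (control
window only), continuous user (both), non-user (neither — a washout-period
dispensing does not count as exposure in any window).
"""

import datetime as dt

from crossvis import SubjectHistory, classify_cohort, load_design

design = load_design()  # case 1-50, CW1 101-150, CW2 151-200 days pre-event
event = dt.date(2012, 6, 1)

cohort = [
    SubjectHistory("pt-int", event, (30,)),        # dispensing 30 days pre-event
    SubjectHistory("pt-stop", event, (120,)),      # 120 days pre-event (in CW1)
    SubjectHistory("pt-cont", event, (30, 120)),   # in case window and CW1
    SubjectHistory("pt-wash", event, (75,)),       # washout only
]

print(f"design: case {design.case_window}, CW1 {design.control_window_1}, "
      f"CW2 {design.control_window_2} days pre-event\n")
for c in classify_cohort(cohort, design):
    print(f"{c.subject_id:8s}  CW1: {str(c.status_cw1):15s} CW2: {c.status_cw2}")

# Each line is the subject's four-way status per control window; note that
# pt-stop flips from recent stopper (CW1) to non-user (CW2) — the kind of
# cross-window change the stratification is built to expose.
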