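"""Recommend the next participant's dose mid-trial.

Four participants are on study with staggered starts; the third had a DLT at
dose level 3 before completing the window.  Everyone contributes to the
weighted likelihood: event-free participants in proportion to their observed
follow-up, the DLT participant with full weight.
"""

from titecrm import (
    DesignSpec,
    ParticipantRecord,
    TrialState,
    build_snapshots,
    recommend_dose,
)
from titecrm.io import write_report

design = DesignSpec(
    skeleton=(0.05, 0.12, 0.22, 0.35), ttl=0.25, dlt_window=168.0, n_max=21
)

state = TrialState(
    participants=(
        ParticipantRecord("P1", 1, start_day=0, last_contact_day=140),
        ParticipantRecord("P2", 2, start_day=35, last_contact_day=140),
        ParticipantRecord("P3", 3, start_day=70, last_contact_day=140, dlt_day=98),
        ParticipantRecord("P4", 2, start_day=126, last_contact_day=140),
    ),
    current_day=140,
)

rec = recommend_dose(state, design, with_interval=True)
snaps = build_snapshots(state, design)
print(write_report(rec, snaps, design))
print(
    "P3's weight is 1 despite incomplete follow-up (they had a DLT); the "
    "others carry weight t/T.  The report shows the model's unrestricted "
    "choice next to the final recommendation after escalation restrictions."
)
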