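"""Best/worst-case check: should recruitment pause?

Assume every incompletely followed participant goes on to have a DLT (worst
case), then assume none do (best case).  If the dose decision is the same
either way, nothing is gained by pausing recruitment to wait for more
follow-up.
"""

from titecrm import DesignSpec, ParticipantRecord, TrialState, pause_check

design = DesignSpec(
    skeleton=(0.05, 0.12, 0.22, 0.35), ttl=0.25, dlt_window=168.0, n_max=21
)

# several participants recruited recently: lots of unresolved follow-up
state = TrialState(
    participants=(
        ParticipantRecord("P1", 1, start_day=0, last_contact_day=200),
        ParticipantRecord("P2", 1, start_day=0, last_contact_day=200),
        ParticipantRecord("P3", 2, start_day=0, last_contact_day=200),
        ParticipantRecord("P4", 2, start_day=150, last_contact_day=200),
        ParticipantRecord("P5", 2, start_day=170, last_contact_day=200),
        ParticipantRecord("P6", 2, start_day=190, last_contact_day=200),
    ),
    current_day=200,
)

res = pause_check(state, design)
print(f"dose if all pending participants had a DLT: {res.dose_if_all_tox}")
print(f"dose if none had a DLT:                     {res.dose_if_none_tox}")
print("pause recruitment" if res.pause else "no reason to pause")
print(
    "\nThe decisions differ, so the next dose genuinely depends on outcomes "
    "still to be observed — worth pausing until more follow-up accrues."
)
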