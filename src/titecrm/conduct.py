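"""Live-trial decision engine.

Turns the event history of enrolled participants into model snapshots,
applies the escalation restrictions recommended for TiTE-CRM conduct
(initial cohort at the starting dose, no dose skipping, minimum cumulative
exposure before escalation, recruitment slots), evaluates the best/worst
case pause check, and reports the model's unrestricted choice alongside the
final recommendation so the decision is auditable — the model's dose is
never to be followed blindly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import NamedTuple, Optional, Sequence

from .design import (
    DesignSpec,
    ParticipantSnapshot,
    Posterior,
    PosteriorSummary,
    posterior_summary,
    prob_toxicity_exceeds,
)
from .weights import PartialTreatmentRule, WeightSpec, compute_weight, effective_followup

__all__ = [
    "ParticipantRecord",
    "TrialState",
    "EscalationRules",
    "StopFlag",
    "Recommendation",
    "PauseCheckResult",
    "build_snapshots",
    "recommend_dose",
    "pause_check",
    "stopping_check",
]


@dataclass(frozen=True)
class ParticipantRecord:
    """Raw event history for one participant, in days since the trial epoch.

    ``dlt_day`` is the day the DLT occurred (absent if none was observed);
    ``last_full_treatment_day`` and ``fraction_received`` feed the
    partial-treatment weighting rule when it is enabled.
    """

    participant_id: str
    dose_index: int
    start_day: float
    last_contact_day: float
    dlt_day: Optional[float] = None
    fraction_received: Optional[float] = None
    last_full_treatment_day: Optional[float] = None

    def __post_init__(self) -> None:
        pid = self.participant_id
        if self.start_day > self.last_contact_day:
            raise ValueError(
                f"participant {pid!r}: start_day {self.start_day} after "
                f"last_contact_day {self.last_contact_day}"
            )
        if self.dlt_day is not None and not (
            self.start_day <= self.dlt_day <= self.last_contact_day
        ):
            raise ValueError(
                f"participant {pid!r}: dlt_day {self.dlt_day} outside "
                f"[start_day, last_contact_day]"
            )
        if self.fraction_received is not None and not (
            0.0 <= self.fraction_received <= 1.0
        ):
            raise ValueError(
                f"participant {pid!r}: fraction_received "
                f"{self.fraction_received} outside [0, 1]"
            )
        if self.last_full_treatment_day is not None and not (
            self.start_day <= self.last_full_treatment_day <= self.last_contact_day
        ):
            raise ValueError(
                f"participant {pid!r}: last_full_treatment_day outside "
                f"[start_day, last_contact_day]"
            )


@dataclass(frozen=True)
class TrialState:
    """Event history of all enrolled participants at a decision time."""

    participants: tuple[ParticipantRecord, ...]
    current_day: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "participants", tuple(self.participants))
        for p in self.participants:
            if p.last_contact_day > self.current_day:
                raise ValueError(
                    f"participant {p.participant_id!r}: last_contact_day "
                    f"{p.last_contact_day} is after current_day {self.current_day}"
                )

    @property
    def n_enrolled(self) -> int:
        return len(self.participants)

    def highest_dose_given(self) -> int:
        if not self.participants:
            return 0
        return max(p.dose_index for p in self.participants)


@dataclass(frozen=True)
class EscalationRules:
    """Conduct restrictions layered on top of the model recommendation.

    Defaults follow common TiTE-CRM practice: the first three participants
    receive the starting dose, doses are never skipped, and escalation above
    the highest dose given so far requires at least three participants at or
    above that dose with at least three months (91 days) of exposure each.
    ``max_pending_slots`` caps the number of concurrently incompletely
    followed participants; the safety stop fires when the posterior
    probability that even the lowest dose exceeds the TTL passes
    ``safety_stop_threshold``.
    """

    no_skip: bool = True
    initial_cohort_size: int = 3
    min_exposed_participants: int = 3
    min_exposure_days: float = 91.0
    max_pending_slots: Optional[int] = None
    safety_stop_enabled: bool = True
    safety_stop_threshold: float = 0.9

    def __post_init__(self) -> None:
        if self.initial_cohort_size < 1:
            raise ValueError("initial_cohort_size must be positive")
        if self.min_exposed_participants < 1:
            raise ValueError("min_exposed_participants must be positive")
        if self.min_exposure_days <= 0:
            raise ValueError("min_exposure_days must be positive")
        if self.max_pending_slots is not None and self.max_pending_slots < 1:
            raise ValueError("max_pending_slots must be positive when set")
        if not 0.0 < self.safety_stop_threshold < 1.0:
            raise ValueError("safety_stop_threshold must lie in (0, 1)")


class StopFlag(str, Enum):
    NONE = "none"
    MAX_N_REACHED = "max_n_reached"
    TOO_TOXIC = "too_toxic"


@dataclass(frozen=True)
class Recommendation:
    """A dose decision with its full audit trail: the model's unrestricted
    choice, the restrictions that modified it, the posterior behind it, and
    any stop/pause flags."""

    dose_index: int
    model_dose_index: int
    restrictions_applied: tuple[str, ...]
    posterior: PosteriorSummary
    stop_flag: StopFlag
    pause_flag: bool


class PauseCheckResult(NamedTuple):
    pause: bool
    dose_if_all_tox: int
    dose_if_none_tox: int


def build_snapshots(
    state: TrialState,
    design: DesignSpec,
    weight_spec: WeightSpec | None = None,
    partial_rule: PartialTreatmentRule | None = None,
) -> list[ParticipantSnapshot]:
    """Model snapshots for every enrolled participant at ``state.current_day``.

    A DLT counts only if it occurred within the observation window; a DLT
    recorded after day ``T`` is treated as event-free with full follow-up.
    Follow-up is truncated at ``T`` and, when the partial-treatment rule
    applies, at the last day of full treatment.
    """
    if weight_spec is None:
        weight_spec = WeightSpec.linear()
    if partial_rule is None:
        partial_rule = PartialTreatmentRule()
    labels = design.dose_labels()
    T = design.dlt_window
    snapshots: list[ParticipantSnapshot] = []
    for p in state.participants:
        if not 1 <= p.dose_index <= design.n_doses:
            raise ValueError(
                f"participant {p.participant_id!r}: dose_index {p.dose_index} "
                f"outside the design's 1..{design.n_doses}"
            )
        tox = int(
            p.dlt_day is not None and (p.dlt_day - p.start_day) <= T
        )
        t = min(p.last_contact_day - p.start_day, T)
        last_full = (
            p.last_full_treatment_day - p.start_day
            if p.last_full_treatment_day is not None
            else t
        )
        fraction = p.fraction_received if p.fraction_received is not None else 1.0
        t_eff = effective_followup(t, min(last_full, t), fraction, tox, partial_rule)
        w = compute_weight(t_eff, T, tox, weight_spec)
        snapshots.append(
            ParticipantSnapshot(
                participant_id=p.participant_id,
                dose_index=p.dose_index,
                dose_label=float(labels[p.dose_index - 1]),
                tox=tox,
                followup=t_eff,
                weight=w,
            )
        )
    return snapshots


def _pending_count(state: TrialState, design: DesignSpec) -> int:
    """Participants still within the window without a (within-window) DLT."""
    T = design.dlt_window
    n = 0
    for p in state.participants:
        had_dlt = p.dlt_day is not None and (p.dlt_day - p.start_day) <= T
        if not had_dlt and (p.last_contact_day - p.start_day) < T:
            n += 1
    return n


def _exposure_allows_escalation(
    state: TrialState, rules: EscalationRules, from_dose: int
) -> bool:
    n = sum(
        1
        for p in state.participants
        if p.dose_index >= from_dose
        and (p.last_contact_day - p.start_day) >= rules.min_exposure_days
    )
    return n >= rules.min_exposed_participants


def stopping_check(
    snapshots: Sequence[ParticipantSnapshot],
    state: TrialState,
    design: DesignSpec,
    rules: EscalationRules,
    posterior: Posterior | None = None,
) -> StopFlag:
    """Stopping rules: maximum sample size, then the safety rule.

    The safety rule stops when the posterior probability that the lowest
    dose's DLT probability exceeds the TTL passes the configured threshold.
    """
    if state.n_enrolled >= design.n_max:
        return StopFlag.MAX_N_REACHED
    if rules.safety_stop_enabled and snapshots:
        d1 = float(design.dose_labels()[0])
        tail = prob_toxicity_exceeds(
            snapshots, d1, design.ttl, design.prior_mean, design.prior_sd,
            posterior=posterior,
        )
        if tail > rules.safety_stop_threshold:
            return StopFlag.TOO_TOXIC
    return StopFlag.NONE


def _recommend_from_snapshots(
    snapshots: Sequence[ParticipantSnapshot],
    state: TrialState,
    design: DesignSpec,
    rules: EscalationRules,
    with_interval: bool,
) -> Recommendation:
    workspace = Posterior(snapshots, design.prior_mean, design.prior_sd)
    post = posterior_summary(snapshots, design, with_interval=with_interval,
                             posterior=workspace)
    model_dose = post.mtd_index
    dose = model_dose
    restrictions: list[str] = []
    if post.all_above_target and design.mtd_rule == "highest_below":
        restrictions.append("all_doses_above_target")
    if state.n_enrolled < rules.initial_cohort_size:
        dose = design.starting_dose_index
        restrictions.append("initial_cohort")
    else:
        highest = state.highest_dose_given()
        if rules.no_skip and dose > highest + 1:
            dose = highest + 1
            restrictions.append("no_skip")
        if dose > highest and not _exposure_allows_escalation(state, rules, highest):
            dose = highest
            restrictions.append("min_exposure")
    stop = stopping_check(snapshots, state, design, rules, posterior=workspace)
    pause = (
        rules.max_pending_slots is not None
        and _pending_count(state, design) >= rules.max_pending_slots
    )
    return Recommendation(
        dose_index=dose,
        model_dose_index=model_dose,
        restrictions_applied=tuple(restrictions),
        posterior=post,
        stop_flag=stop,
        pause_flag=pause,
    )


def recommend_dose(
    state: TrialState,
    design: DesignSpec,
    weight_spec: WeightSpec | None = None,
    partial_rule: PartialTreatmentRule | None = None,
    rules: EscalationRules | None = None,
    with_interval: bool = False,
) -> Recommendation:
    """Dose recommendation for the next participant given all data so far.

    Until ``initial_cohort_size`` participants are enrolled the starting
    dose is assigned.  Afterwards the model's MTD is capped by the no-skip
    rule at one level above the highest dose administered, and escalation
    above the highest administered dose additionally requires the
    minimum-exposure rule to be satisfied.  The result carries the
    unrestricted model choice, the restrictions applied, the posterior, and
    stop/pause flags.
    """
    rules = rules if rules is not None else EscalationRules()
    snapshots = build_snapshots(state, design, weight_spec, partial_rule)
    return _recommend_from_snapshots(snapshots, state, design, rules, with_interval)


def pause_check(
    state: TrialState,
    design: DesignSpec,
    weight_spec: WeightSpec | None = None,
    partial_rule: PartialTreatmentRule | None = None,
    rules: EscalationRules | None = None,
) -> PauseCheckResult:
    """Best/worst-case recruitment-pause check.

    Scenario A assumes every incompletely followed participant goes on to
    have a DLT (toxicity indicator 1, full weight); scenario B assumes none
    do (their current weights stand).  If the two dose decisions coincide,
    nothing is gained by pausing recruitment.
    """
    rules = rules if rules is not None else EscalationRules()
    snapshots = build_snapshots(state, design, weight_spec, partial_rule)
    T = design.dlt_window
    worst = [
        ParticipantSnapshot(
            participant_id=s.participant_id,
            dose_index=s.dose_index,
            dose_label=s.dose_label,
            tox=1,
            followup=s.followup,
            weight=1.0,
        )
        if (s.tox == 0 and s.followup < T)
        else s
        for s in snapshots
    ]
    rec_worst = _recommend_from_snapshots(worst, state, design, rules, False)
    rec_best = _recommend_from_snapshots(snapshots, state, design, rules, False)
    return PauseCheckResult(
        pause=rec_worst.dose_index != rec_best.dose_index,
        dose_if_all_tox=rec_worst.dose_index,
        dose_if_none_tox=rec_best.dose_index,
    )
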