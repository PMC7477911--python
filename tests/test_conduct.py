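"""Decision-engine tests: snapshot construction, escalation restrictions,
pause and stopping rules."""

import dataclasses

import numpy as np
import pytest

from titecrm import (
    DesignSpec,
    EscalationRules,
    ParticipantRecord,
    StopFlag,
    TrialState,
    WeightSpec,
    build_snapshots,
    pause_check,
    recommend_dose,
    stopping_check,
)


def rec(pid, dose, start, last, dlt=None, **kw):
    return ParticipantRecord(
        participant_id=pid, dose_index=dose, start_day=start,
        last_contact_day=last, dlt_day=dlt, **kw,
    )


@pytest.fixture
def fig_state():
    """Four staggered participants, the third with a within-window DLT."""
    return TrialState(
        participants=(
            rec("P1", 1, 0, 140),
            rec("P2", 2, 35, 140),
            rec("P3", 3, 70, 140, dlt=98),
            rec("P4", 2, 126, 140),
        ),
        current_day=140,
    )


class TestBuildSnapshots:
    def test_just_enrolled_contributes_nothing(self, design):
        state = TrialState((rec("A", 1, 10, 10),), current_day=10)
        (s,) = build_snapshots(state, design)
        assert s.weight == 0.0 and s.tox == 0

    def test_staggered_cohort_weights(self, design, fig_state):
        snaps = build_snapshots(fig_state, design)
        by_id = {s.participant_id: s for s in snaps}
        T = design.dlt_window
        assert by_id["P3"].tox == 1 and by_id["P3"].weight == 1.0
        assert by_id["P1"].weight == pytest.approx(140 / T)
        assert by_id["P2"].weight == pytest.approx(105 / T)
        assert by_id["P4"].weight == pytest.approx(14 / T)

    def test_dlt_beyond_window_counts_as_event_free(self, design):
        T = design.dlt_window
        state = TrialState(
            (rec("A", 1, 0, T + 30, dlt=T + 10),), current_day=T + 30
        )
        (s,) = build_snapshots(state, design)
        assert s.tox == 0 and s.weight == 1.0

    def test_unknown_dose_level_names_participant(self, design):
        state = TrialState((rec("odd", 9, 0, 10),), current_day=10)
        with pytest.raises(ValueError, match="odd"):
            build_snapshots(state, design)


class TestRecommendDose:
    def test_empty_trial_gets_starting_dose(self, design):
        state = TrialState((), current_day=0)
        out = recommend_dose(state, design)
        assert out.dose_index == design.starting_dose_index
        assert "initial_cohort" in out.restrictions_applied

    def test_no_skip_caps_at_one_above_highest_given(self, design):
        # long event-free follow-up at doses 1-2 pushes the model high
        state = TrialState(
            tuple(rec(f"p{i}", 1 + i % 2, 0, 300) for i in range(8)),
            current_day=300,
        )
        out = recommend_dose(state, design)
        assert out.model_dose_index == 4
        assert out.dose_index == 3
        assert "no_skip" in out.restrictions_applied

    def test_min_exposure_blocks_escalation(self, design):
        # only two participants have 91+ days at the highest dose level
        state = TrialState(
            (
                rec("a", 1, 0, 100),
                rec("b", 2, 0, 100),
                rec("c", 2, 60, 100),
            ),
            current_day=100,
        )
        out = recommend_dose(state, design)
        assert out.dose_index == 2
        assert "min_exposure" in out.restrictions_applied

    def test_order_invariance(self, design, fig_state):
        reordered = TrialState(
            participants=tuple(reversed(fig_state.participants)),
            current_day=fig_state.current_day,
        )
        a = recommend_dose(fig_state, design)
        b = recommend_dose(reordered, design)
        assert a.dose_index == b.dose_index
        assert a.posterior.beta_hat == pytest.approx(b.posterior.beta_hat, abs=1e-12)

    def test_recommendation_carries_posterior_and_audit_fields(self, design, fig_state):
        out = recommend_dose(fig_state, design, with_interval=True)
        assert out.posterior.beta_interval is not None
        assert len(out.posterior.pi_hat) == design.n_doses
        assert isinstance(out.restrictions_applied, tuple)

    def test_pending_slot_limit_sets_pause_flag(self, design):
        rules = EscalationRules(max_pending_slots=2)
        state = TrialState(
            (rec("a", 1, 0, 10), rec("b", 1, 5, 10), rec("c", 1, 8, 10)),
            current_day=10,
        )
        out = recommend_dose(state, design, rules=rules)
        assert out.pause_flag


class TestPauseCheck:
    def test_no_pending_participants_no_pause(self, design):
        T = design.dlt_window
        state = TrialState(
            (rec("a", 1, 0, T), rec("b", 1, 0, T)), current_day=T
        )
        res = pause_check(state, design)
        assert not res.pause
        assert res.dose_if_all_tox == res.dose_if_none_tox

    def test_hypothetical_dlts_can_flip_decision(self, design):
        # several barely-followed participants: worst case de-escalates
        state = TrialState(
            (
                rec("a", 1, 0, 200),
                rec("b", 1, 0, 200),
                rec("c", 2, 0, 200),
                rec("d", 2, 150, 200),
                rec("e", 2, 170, 200),
                rec("f", 2, 190, 200),
            ),
            current_day=200,
        )
        res = pause_check(state, design)
        assert res.dose_if_all_tox < res.dose_if_none_tox
        assert res.pause

    def test_pause_rarer_with_longer_followup(self, design):
        """Nearly complete follow-up leaves little for the scenarios to flip."""
        rng = np.random.default_rng(4)
        T = design.dlt_window

        def pause_freq(mean_fu):
            hits = 0
            for _ in range(20):
                n = int(rng.integers(4, 9))
                parts = []
                for j in range(n):
                    fu = float(np.clip(rng.normal(mean_fu, 15), 1, T))
                    parts.append(rec(f"p{j}", int(rng.integers(1, 3)), 0, fu))
                state = TrialState(tuple(parts), current_day=float(T))
                hits += pause_check(state, design).pause
            return hits

        assert pause_freq(T * 0.95) <= pause_freq(T * 0.15)


class TestStoppingCheck:
    def test_max_n_reached(self, design):
        small = dataclasses.replace(design, n_max=2)
        state = TrialState((rec("a", 1, 0, 10), rec("b", 1, 0, 10)), current_day=10)
        snaps = build_snapshots(state, small)
        assert stopping_check(snaps, state, small, EscalationRules()) is StopFlag.MAX_N_REACHED

    def test_many_early_dlts_trigger_safety_stop(self, design):
        state = TrialState(
            tuple(rec(f"p{i}", 1, 0, 30, dlt=20) for i in range(6)),
            current_day=30,
        )
        out = recommend_dose(state, design)
        assert out.stop_flag is StopFlag.TOO_TOXIC

    def test_empty_trial_no_stop(self, design):
        state = TrialState((), current_day=0)
        snaps = build_snapshots(state, design)
        assert stopping_check(snaps, state, design, EscalationRules()) is StopFlag.NONE

    def test_safety_stop_can_be_disabled(self, design):
        rules = EscalationRules(safety_stop_enabled=False)
        state = TrialState(
            tuple(rec(f"p{i}", 1, 0, 30, dlt=20) for i in range(6)),
            current_day=30,
        )
        snaps = build_snapshots(state, design)
        assert stopping_check(snaps, state, design, rules) is StopFlag.NONE


class TestStateValidation:
    def test_dlt_before_start_rejected(self):
        with pytest.raises(ValueError, match="dlt_day"):
            rec("a", 1, 50, 100, dlt=40)

    def test_contact_after_current_day_rejected(self):
        with pytest.raises(ValueError, match="current_day"):
            TrialState((rec("a", 1, 0, 100),), current_day=50)
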