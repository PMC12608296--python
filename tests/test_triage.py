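import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wardtriage.context import ClinicalPriority
from wardtriage.triage import (
    AlwaysAck,
    BackendContractError,
    BackendResult,
    DelayWeights,
    Disposition,
    PromptedBackend,
    Strategy,
    SuppressionReason,
    SuppressionThresholds,
    SurrogateBackend,
    TriageParams,
    build_prompt,
    compute_delay,
    delay_gate,
    dispatch_and_escalate,
    dynamic_threshold,
    reachable_threshold,
    run_triage,
    suppress,
    validate,
)

from conftest import make_alarm, make_roster


class TestReachableThreshold:
    def test_standard_case(self):
        r = reachable_threshold(3.0, 1.2, 1.0)
        assert r.theta_x == pytest.approx(2.4)
        assert not r.degenerate

    def test_zero_speed(self):
        assert reachable_threshold(3.0, 0.0).theta_x == 0.0

    def test_degenerate_boundary_flagged(self):
        r = reachable_threshold(1.0, 1.2, 1.0)
        assert r.theta_x == 0.0 and r.degenerate


THR = SuppressionThresholds(theta_x=2.4, theta_u=0.2)


class TestSuppress:
    def test_too_far(self):
        keep, reason = suppress(make_alarm(urgency=0.9), THR, nurse_distance=5.0)
        assert not keep and reason is SuppressionReason.TOO_FAR

    def test_not_urgent(self):
        keep, reason = suppress(make_alarm(urgency=0.1), THR, nurse_distance=1.0)
        assert not keep and reason is SuppressionReason.NOT_URGENT

    def test_low_priority_fully_dependent(self):
        alarm = make_alarm(urgency=0.9, clinical=ClinicalPriority.LOW)
        keep, reason = suppress(alarm, THR, nurse_distance=1.0)
        assert not keep and reason is SuppressionReason.LOW_PRIORITY

    def test_keep_otherwise(self):
        keep, reason = suppress(make_alarm(urgency=0.9), THR, nurse_distance=1.0)
        assert keep and reason is SuppressionReason.NONE

    def test_exhaustive_grid_against_direct_rule(self):
        """Agreement with an independent three-clause evaluator on the
        full 21 x 21 x 3 grid (1323 cells)."""

        def oracle(d, u, c):
            if d > THR.theta_x:
                return SuppressionReason.TOO_FAR
            if u < THR.theta_u:
                return SuppressionReason.NOT_URGENT
            if c is ClinicalPriority.LOW:
                return SuppressionReason.LOW_PRIORITY
            return SuppressionReason.NONE

        n_cells = 0
        for d in np.linspace(0.0, 2 * THR.theta_x, 21):
            for u in np.linspace(0.0, 1.0, 21):
                for c in ClinicalPriority:
                    keep, reason = suppress(make_alarm(urgency=u, clinical=c), THR, d)
                    assert reason is oracle(d, u, c)
                    assert keep == (reason is SuppressionReason.NONE)
                    n_cells += 1
        assert n_cells == 1323


class TestDelay:
    def test_maximally_urgent_no_delay(self):
        assert compute_delay(make_alarm(urgency=1.0, workload=0.0)) == pytest.approx(0.0)

    def test_hand_computed_mid_case(self):
        """u=0.4, r=0.5, mid priority -> 0.5*0.6 + 0.25*0.5 + 0.25*1 = 0.675."""
        alarm = make_alarm(urgency=0.4, workload=0.5, clinical=ClinicalPriority.MID)
        assert compute_delay(alarm) == pytest.approx(0.675, abs=1e-12)

    def test_maximum_delay(self):
        alarm = make_alarm(urgency=0.0, workload=1.0, clinical=ClinicalPriority.MID)
        assert compute_delay(alarm) == pytest.approx(1.0)

    @settings(derandomize=True, max_examples=50)
    @given(
        u=st.floats(0, 1, allow_nan=False),
        r=st.floats(0, 1, allow_nan=False),
        du=st.floats(0, 1, allow_nan=False),
        dr=st.floats(0, 1, allow_nan=False),
    )
    def test_monotone_in_urgency_and_workload(self, u, r, du, dr):
        base = compute_delay(make_alarm(urgency=u, workload=r))
        assert compute_delay(make_alarm(urgency=min(1, u + du), workload=r)) <= base + 1e-12
        assert compute_delay(make_alarm(urgency=u, workload=min(1, r + dr))) >= base - 1e-12

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            DelayWeights(0.5, 0.5, 0.5)


class TestDelayGate:
    def test_zero_delay_always_kept(self):
        assert delay_gate(make_alarm(), 0.0, ack_window=30.0)

    def test_exceeding_horizon_discarded(self):
        assert not delay_gate(make_alarm(), 31.0, ack_window=30.0)

    def test_boundary_exactly_at_horizon_kept(self):
        assert delay_gate(make_alarm(), 30.0, ack_window=30.0)


class TestPrompt:
    def test_identical_alarms_identical_prompts(self):
        roster = make_roster(3)
        p1 = build_prompt(make_alarm(urgency=0.63), roster)
        p2 = build_prompt(make_alarm(urgency=0.63), roster)
        assert p1 == p2

    def test_template_completeness(self):
        roster = make_roster(4)
        alarm = make_alarm(urgency=0.5, distances={f"N{i+1}": float(i) for i in range(4)})
        prompt = build_prompt(alarm, roster)
        for field in ("time_s", "urgency", "clinical_priority", "ward_workload", "distance_m"):
            assert field in prompt
        for n in roster:
            assert n.nurse_id in prompt

    def test_clinical_field_mapping(self):
        prompt = build_prompt(make_alarm(clinical=ClinicalPriority.HIGH), make_roster(1))
        assert "clinical_priority=high" in prompt


class TestValidateSurrogate:
    def test_saturated_case_scores_one(self):
        alarm = make_alarm(
            urgency=1.0, clinical=ClinicalPriority.HIGH, workload=0.0, distances={"N1": 0.0}
        )
        res = validate(alarm, make_roster(1), SurrogateBackend(), theta_x=2.4)
        assert res.priority == pytest.approx(1.0, abs=1e-12)

    def test_floor_case_scores_quarter_of_mid(self):
        """u=0, mid, distance >= theta_x, r=1 -> 0.3*0.5 = 0.15."""
        alarm = make_alarm(
            urgency=0.0, clinical=ClinicalPriority.MID, workload=1.0, distances={"N1": 5.0}
        )
        res = validate(alarm, make_roster(1), SurrogateBackend(), theta_x=2.4)
        assert res.priority == pytest.approx(0.15, abs=1e-12)

    def test_equidistant_tie_breaks_by_workload_then_id(self):
        roster = make_roster(2)
        roster[0].workload_index = 5
        alarm = make_alarm(distances={"N1": 1.0, "N2": 1.0})
        res = validate(alarm, roster, SurrogateBackend(), theta_x=2.4)
        assert res.recommended == "N2"  # lower workload wins
        roster[0].workload_index = 0
        res = validate(alarm, roster, SurrogateBackend(), theta_x=2.4)
        assert res.recommended == "N1"  # then lexicographic id

    def test_contract_violations_raise(self):
        class BadRange:
            def score(self, alarm, roster, theta_x):
                return BackendResult(1.5, "N1", ("N1",), {"N1": 1.5})

        class BadNurse:
            def score(self, alarm, roster, theta_x):
                return BackendResult(0.5, "ghost", ("ghost",), {"ghost": 0.5})

        with pytest.raises(BackendContractError):
            validate(make_alarm(), make_roster(1), BadRange(), 2.4)
        with pytest.raises(BackendContractError):
            validate(make_alarm(), make_roster(1), BadNurse(), 2.4)

    def test_prompted_backend_parses_response(self):
        def complete(prompt):
            assert "urgency" in prompt
            return "priority=0.85 nurse=N2"

        res = validate(make_alarm(distances={"N1": 1.0, "N2": 2.0}),
                       make_roster(2), PromptedBackend(complete), 2.4)
        assert res.priority == pytest.approx(0.85)
        assert res.recommended == "N2"
        assert res.ranking[0] == "N2"


class TestDynamicThreshold:
    def test_high_priority_near_nurse_low_bar(self):
        alarm = make_alarm(clinical=ClinicalPriority.HIGH, workload=0.0, distances={"N1": 0.0})
        assert dynamic_threshold(alarm, 2.4) == pytest.approx(0.1, abs=1e-12)

    def test_mid_priority_busy_far_high_bar(self):
        alarm = make_alarm(clinical=ClinicalPriority.MID, workload=1.0, distances={"N1": 2.4})
        assert dynamic_threshold(alarm, 2.4) == pytest.approx(0.7, abs=1e-12)

    def test_priority_equal_to_tau_is_validated(self):
        """Escalation uses >=: priority exactly at the bar passes."""
        roster = make_roster(1)
        alarm = make_alarm(
            urgency=0.25, clinical=ClinicalPriority.MID, workload=1.0,
            distances={"N1": 2.4}, timestamp=0.0,
        )
        # surrogate: .4*.25 + .3*.5 + 0 + 0 = 0.25 ; tau = .3+.2+.2 = 0.7 -> discard
        res = run_triage([alarm], roster, TriageParams(), Strategy.PROPOSED)
        assert res.decisions[0].disposition is Disposition.VALIDATION_DISCARDED
        # with tau params making tau exactly equal the priority, it must pass
        params = TriageParams(tau_params=(0.25, 0.0, 0.0, 0.0))
        res = run_triage([alarm], roster, params, Strategy.PROPOSED)
        assert res.decisions[0].disposition is Disposition.DISPATCHED


class TestDispatchEscalate:
    def test_first_ack_dispatches_and_updates_workload(self):
        roster = {n.nurse_id: n for n in make_roster(2)}
        dispo, nurse, notified = dispatch_and_escalate(
            make_alarm(), ["N1", "N2"], roster, AlwaysAck(), 30.0, 0.0
        )
        assert dispo is Disposition.DISPATCHED and nurse == "N1"
        assert notified == ("N1",)
        assert roster["N1"].workload_index == 1

    def test_escalates_to_next_on_no_ack(self):
        class FirstDeclines:
            def acknowledges(self, nurse_id, alarm):
                return (nurse_id != "N1"), 0.0

        roster = {n.nurse_id: n for n in make_roster(2)}
        dispo, nurse, notified = dispatch_and_escalate(
            make_alarm(), ["N1", "N2"], roster, FirstDeclines(), 30.0, 0.0
        )
        assert dispo is Disposition.ESCALATED and nurse == "N2"
        assert notified == ("N1", "N2")

    def test_exhausted_ranking_is_unanswered(self):
        class NeverAck:
            def acknowledges(self, nurse_id, alarm):
                return False, 0.0

        roster = {n.nurse_id: n for n in make_roster(2)}
        dispo, nurse, notified = dispatch_and_escalate(
            make_alarm(), ["N1", "N2"], roster, NeverAck(), 30.0, 0.0
        )
        assert dispo is Disposition.UNANSWERED and nurse is None
        assert notified == ("N1", "N2")


class TestRunTriage:
    def _alarms(self, n=6):
        rng = np.random.default_rng(3)
        return [
            make_alarm(
                urgency=float(rng.uniform(0, 1)),
                workload=0.5,
                distances={"N1": float(rng.uniform(0, 5)), "N2": float(rng.uniform(0, 5))},
                timestamp=float(i * 40.0),
                alarm_id=f"A{i}",
            )
            for i in range(n)
        ]

    def test_baseline_notifies_everyone(self):
        alarms = self._alarms(5)
        roster = make_roster(4)
        res = run_triage(alarms, roster, strategy=Strategy.BASELINE)
        assert sum(res.notifications.values()) == 4 * 5
        assert all(v == 5 for v in res.notifications.values())

    def test_low_priority_stream_fully_shadow_logged(self):
        alarms = [
            make_alarm(urgency=0.9, clinical=ClinicalPriority.LOW, distances={"N1": 0.5},
                       timestamp=float(i), alarm_id=f"A{i}")
            for i in range(4)
        ]
        res = run_triage(alarms, make_roster(1), strategy=Strategy.PROPOSED)
        assert res.effective == []
        assert len(res.shadow_log) == 4
        assert all(e.reason == "low_priority" for e in res.shadow_log)

    def test_every_alarm_gets_exactly_one_disposition(self):
        alarms = self._alarms(20)
        res = run_triage(alarms, make_roster(2), strategy=Strategy.PROPOSED)
        assert len(res.decisions) == len(alarms)
        assert {d.alarm.alarm_id for d in res.decisions} == {a.alarm_id for a in alarms}

    def test_unknown_strategy_rejected(self):
        with pytest.raises(ValueError):
            run_triage(self._alarms(1), make_roster(1), strategy="magic")

    def test_caller_roster_not_mutated(self):
        roster = make_roster(2)
        run_triage(self._alarms(6), roster, strategy=Strategy.RSD)
        assert all(n.workload_index == 0 for n in roster)

    def test_determinism_identical_runs(self):
        alarms = self._alarms(15)
        r1 = run_triage(alarms, make_roster(3), strategy=Strategy.PROPOSED)
        r2 = run_triage(alarms, make_roster(3), strategy=Strategy.PROPOSED)
        assert [
            (d.alarm.alarm_id, d.disposition, d.assigned_nurse, d.priority, d.tau)
            for d in r1.decisions
        ] == [
            (d.alarm.alarm_id, d.disposition, d.assigned_nurse, d.priority, d.tau)
            for d in r2.decisions
        ]

    def test_backend_substitution_preserves_gate_dispositions(self):
        """Swapping the validation backend may change priorities and
        assignments but never suppression or delay outcomes."""

        class Contrarian:
            def score(self, alarm, roster, theta_x):
                avail = sorted(n.nurse_id for n in roster)
                return BackendResult(0.99, avail[-1], tuple(reversed(avail)),
                                     {n: 0.99 for n in avail})

        alarms = self._alarms(20)
        roster = make_roster(2)
        res_a = run_triage(alarms, roster, strategy=Strategy.PROPOSED)
        res_b = run_triage(alarms, roster, strategy=Strategy.PROPOSED, backend=Contrarian())
        gates = (Disposition.SUPPRESSED, Disposition.DELAY_DISCARDED)
        for da, db in zip(res_a.decisions, res_b.decisions):
            assert da.alarm.alarm_id == db.alarm.alarm_id
            assert (da.disposition in gates) == (db.disposition in gates)
            if da.disposition in gates:
                assert da.disposition == db.disposition
                assert da.suppression_reason == db.suppression_reason

    def test_volume_dominance(self):
        alarms = self._alarms(30)
        roster = make_roster(3)
        n_base = sum(
            run_triage(alarms, roster, strategy=Strategy.BASELINE).notifications.values()
        )
        n_rsd = len(run_triage(alarms, roster, strategy=Strategy.RSD).effective)
        n_prop = len(run_triage(alarms, roster, strategy=Strategy.PROPOSED).effective)
        assert n_prop <= n_rsd <= n_base // len(roster) * len(roster)

    def test_simultaneous_alarms_ordered_by_urgency_then_resident(self):
        a_low = make_alarm(urgency=0.3, distances={"N1": 0.5}, timestamp=5.0, alarm_id="low")
        a_high = make_alarm(urgency=0.9, distances={"N1": 0.5}, timestamp=5.0, alarm_id="high")
        res = run_triage([a_low, a_high], make_roster(1), strategy=Strategy.RSD)
        assert res.decisions[0].alarm.alarm_id == "high"
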