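"""BPA lifecycle state machine and the trial simulator."""

from datetime import date, timedelta

import numpy as np
import pytest

from ckdcdss import (BehaviorModel, TriggerState, labs_complete_time,
                     process_encounter, schedule_pharmacist_call, simulate_trial,
                     funnel, patient_arms, randomize_providers)
from ckdcdss.trigger import MAX_DISPLAYS, SequencingError

D0 = date(2018, 1, 1)


def day(n):
    return D0 + timedelta(days=n)


def fresh_state(arm="ecdss", labs_at=day(10)):
    return TriggerState(patient_id="X", arm=arm, pcp_provider_id="P1",
                        labs_complete_at=labs_at)


def pcp_visit(n, provider="P1", type_="pcp_visit"):
    return {"provider_id": provider, "occurred_at": day(n), "type": type_}


class TestLabsCompleteTime:
    def test_max_of_three(self):
        results = {"serum_creatinine": day(3), "cystatin_c": day(5), "urine_acr": day(9)}
        assert labs_complete_time(results) == day(9)

    def test_missing_analyte_none(self):
        results = {"serum_creatinine": day(3), "cystatin_c": day(5)}
        assert labs_complete_time(results) is None

    def test_same_day(self):
        results = {a: day(4) for a in ("serum_creatinine", "cystatin_c", "urine_acr")}
        assert labs_complete_time(results) == day(4)


class TestProcessEncounter:
    def test_no_display_before_labs_complete(self):
        s, ev = process_encounter(fresh_state(labs_at=day(30)), pcp_visit(20))
        assert s.displays == 0 and ev == []

    def test_no_display_for_non_pcp_provider(self):
        s, ev = process_encounter(fresh_state(), pcp_visit(20, provider="P9"))
        assert s.displays == 0 and ev == []

    def test_no_display_for_non_pcp_visit_type(self):
        s, ev = process_encounter(fresh_state(), pcp_visit(20, type_="nephrology_visit"))
        assert s.displays == 0 and ev == []

    def test_display_caps_at_three(self):
        s = fresh_state()
        for n in (20, 30, 40, 50):
            s, ev = process_encounter(s, pcp_visit(n))
        assert s.displays == MAX_DISPLAYS
        assert not ev  # fourth visit emitted nothing

    def test_signing_freezes_machine(self):
        s, ev = process_encounter(fresh_state(), pcp_visit(20),
                                  behavior={"opens": True, "signs": True})
        assert s.signed and s.signed_at == day(20)
        assert [e.kind for e in ev] == ["bpa_displayed", "bpa_opened", "smartset_signed"]
        s, ev = process_encounter(s, pcp_visit(40))
        assert ev == [] and s.displays == 1

    def test_out_of_order_encounter_raises(self):
        s, _ = process_encounter(fresh_state(), pcp_visit(20))
        with pytest.raises(SequencingError):
            process_encounter(s, pcp_visit(10))


class TestPharmacistCall:
    def _signed(self, arm):
        s, _ = process_encounter(fresh_state(arm=arm), pcp_visit(20),
                                 behavior={"opens": True, "signs": True})
        return s

    def test_due_14_days_after_signing(self):
        s, event = schedule_pharmacist_call(self._signed("ecdss_plus"))
        assert s.pharmacist_task.due_by == day(34)
        assert event.kind == "pharmacist_call_scheduled"

    def test_wrong_arm_rejected(self):
        with pytest.raises(ValueError):
            schedule_pharmacist_call(self._signed("ecdss"))

    def test_unsigned_rejected(self):
        with pytest.raises(ValueError):
            schedule_pharmacist_call(fresh_state(arm="ecdss_plus"))

    def test_double_schedule_rejected(self):
        s, _ = schedule_pharmacist_call(self._signed("ecdss_plus"))
        with pytest.raises(ValueError):
            schedule_pharmacist_call(s)


class TestStateMachineProperties:
    def test_random_streams_stay_legal(self, rng):
        """1,000 random encounter streams: displays never exceed 3, nothing
        after signing, pharmacist tasks only in eCDSS+ with due = sign + 14d."""
        for _ in range(1000):
            arm = rng.choice(["ecdss", "ecdss_plus"])
            s = fresh_state(arm=arm, labs_at=day(int(rng.integers(0, 40))))
            t = 0
            n_display_events = 0
            for _step in range(int(rng.integers(1, 10))):
                t += int(rng.integers(0, 15))
                enc = {"provider_id": rng.choice(["P1", "P9"]),
                       "occurred_at": day(t),
                       "type": rng.choice(["pcp_visit", "non_pcp_visit", "lab_only"])}
                was_signed = s.signed
                s, evs = process_encounter(
                    s, enc, behavior={"opens": rng.random() < 0.5,
                                      "signs": rng.random() < 0.5})
                n_display_events += sum(e.kind == "bpa_displayed" for e in evs)
                if was_signed:
                    assert evs == []
                assert s.displays <= MAX_DISPLAYS
                assert s.displays == n_display_events
            if s.signed and arm == "ecdss_plus":
                s2, _ = schedule_pharmacist_call(s)
                assert s2.pharmacist_task.due_by == s.signed_at + timedelta(days=14)


class TestSimulateTrial:
    @pytest.fixture()
    def arms(self, ehr):
        sizes = ehr.patients.groupby("provider_id").size().to_dict()
        return {a.provider_id: a.arm for a in randomize_providers(sizes, seed=3)}

    def test_replay_determinism(self, ehr, arms):
        bm = BehaviorModel()
        a = simulate_trial(ehr, arms, bm, seed=7)
        b = simulate_trial(ehr, arms, bm, seed=7)
        assert a == b

    def test_usual_care_emits_nothing(self, ehr, arms):
        events = simulate_trial(ehr, arms, BehaviorModel(), seed=7)
        usual = {p for p, a in patient_arms(ehr.patients, arms).items()
                 if a == "usual_care"}
        assert all(e.patient_id not in usual for e in events)

    def test_saturating_behavior_gives_full_funnel(self, ehr, arms):
        bm = BehaviorModel(p_lab_completion=1, p_pcp_visit=1, p_open=1,
                           p_sign=1, p_call_completed=1)
        events = simulate_trial(ehr, arms, bm, seed=7)
        report = funnel(events, patient_arms(ehr.patients, arms))
        for stage in ("triple_marker_completed", "pcp_visit_after_labs",
                      "bpa_opened", "smartset_signed"):
            assert report.chained[stage].pct == 100.0

    def test_zero_completion_zero_displays(self, ehr, arms):
        bm = BehaviorModel(p_lab_completion=0)
        events = simulate_trial(ehr, arms, bm, seed=7)
        assert all(e.kind == "triple_order" for e in events)

    def test_funnel_monotone(self, ehr, arms):
        events = simulate_trial(ehr, arms, BehaviorModel(), seed=11)
        report = funnel(events, patient_arms(ehr.patients, arms))
        c = report.counts
        assert (c["enrolled"] >= c["triple_marker_completed"]
                >= c["pcp_visit_after_labs"] >= c["bpa_opened"]
                >= c["smartset_signed"])

    def test_pharmacist_events_only_in_ecdss_plus(self, ehr, arms):
        events = simulate_trial(ehr, arms, BehaviorModel(), seed=11)
        by_arm = patient_arms(ehr.patients, arms)
        for e in events:
            if e.kind.startswith("pharmacist"):
                assert by_arm[e.patient_id] == "ecdss_plus"


def test_observed_behavior_rates_reproduce_funnel_counts():
    """With the observed per-stage rates and 336 intervention patients,
    expected funnel counts land near (178, 138, 102, 83)."""
    from ckdcdss import GeneratorConfig, generate_population
    # a practice large enough to enroll ~336 intervention patients
    cfg = GeneratorConfig(seed=42, n_providers=81, mean_panel_size=13,
                          frac_eligible=0.75)
    ehr = generate_population(cfg)
    sizes = ehr.patients.groupby("provider_id").size().to_dict()
    arms = {a.provider_id: a.arm for a in randomize_providers(sizes, seed=1)}
    bm = BehaviorModel(p_lab_completion=0.53, p_pcp_visit=0.775,
                       p_open=0.739, p_sign=0.814)
    events = simulate_trial(ehr, arms, bm, seed=9)
    report = funnel(events, patient_arms(ehr.patients, arms))
    n = report.counts["enrolled"]
    # binomial 3-sigma bands around the expected chain
    expect = {"triple_marker_completed": 0.53,
              "pcp_visit_after_labs": 0.53 * 0.775,
              "bpa_opened": 0.53 * 0.775 * 0.739,
              "smartset_signed": 0.53 * 0.775 * 0.739 * 0.814}
    for stage, p in expect.items():
        tol = 3 * np.sqrt(p * (1 - p) * n)
        assert abs(report.counts[stage] - p * n) < tol, stage
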