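"""Rules engine: printed-dialect examples, brute-force oracle equivalence,
monotonicity, and referral consistency."""

import numpy as np
import pytest

from ckdcdss import PatientState, recommend, referral_criteria, stratify_risk


def make_state(**kw):
    defaults = dict(age=65, sex="male", egfr_cys=45.0, acr=100.0,
                    potassium=4.2, recent_sbp=130.0,
                    active_med_classes=frozenset(), n_antihypertensive_classes=0,
                    has_diuretic=False)
    defaults.update(kw)
    return PatientState(**defaults)


class TestStratifyRisk:
    @pytest.mark.parametrize("egfr_cys,acr,expected", [
        (55, 10, "high"),    # low cystatin eGFR alone
        (70, 20, "low"),
        (70, 100, "high"),   # ACR alone suffices (and/or)
        (60, 30, "low"),     # both boundaries: neither strict clause fires
        (59.999, 30, "high"),
        (60, 30.001, "high"),
    ])
    def test_dialect(self, egfr_cys, acr, expected):
        assert stratify_risk(egfr_cys, acr) == expected

    def test_domain_error(self):
        with pytest.raises(ValueError):
            stratify_risk(0.0, 30)


class TestReferralCriteria:
    def test_low_egfr_cys(self):
        met, _ = referral_criteria(make_state(egfr_cys=25.0, acr=20.0))
        assert "egfr_cys_lt30" in met

    def test_sbp_without_diuretic_not_met(self):
        met, _ = referral_criteria(make_state(
            recent_sbp=155.0, n_antihypertensive_classes=3, has_diuretic=False))
        assert "sbp_gt150_on_3agents_with_diuretic" not in met

    def test_sbp_with_three_agents_and_diuretic(self):
        met, _ = referral_criteria(make_state(
            recent_sbp=155.0, n_antihypertensive_classes=3, has_diuretic=True))
        assert "sbp_gt150_on_3agents_with_diuretic" in met

    def test_kfre_over_3pct(self):
        met, _ = referral_criteria(make_state(kfre=0.04))
        assert "kfre_gt_3pct" in met

    @pytest.mark.parametrize("k,expect", [(5.5, False), (5.51, True)])
    def test_potassium_strictly_greater(self, k, expect):
        met, _ = referral_criteria(make_state(potassium=k, kfre=0.0001))
        assert ("k_gt_5_5" in met) is expect

    def test_missing_potassium_unassessed(self):
        met, prov = referral_criteria(make_state(potassium=None, kfre=0.0001))
        assert "k_gt_5_5" not in met
        assert "unassessed" in prov["k_gt_5_5"]

    @pytest.mark.parametrize("acr,expect", [(300.0, False), (300.01, True)])
    def test_acr_strictly_greater(self, acr, expect):
        met, _ = referral_criteria(make_state(acr=acr, kfre=0.0001))
        assert ("acr_gt_300" in met) is expect


class TestRecommend:
    def test_low_risk_only_repeat_panel(self):
        rec = recommend(make_state(egfr_cys=70.0, acr=20.0))
        assert rec.risk_tier == "low"
        assert rec.actions == frozenset({"repeat_triple_marker_6mo"})

    def test_statin_age_62_not_on_statin(self):
        rec = recommend(make_state(age=62))
        assert "statin_initiation" in rec.actions

    def test_statin_age_45_not_recommended(self):
        rec = recommend(make_state(age=45))
        assert "statin_initiation" not in rec.actions

    def test_statin_already_on_not_recommended(self):
        rec = recommend(make_state(age=62, active_med_classes=frozenset({"statin"})))
        assert "statin_initiation" not in rec.actions

    def test_acei_arb_titrate_vs_initiate(self):
        on = recommend(make_state(acr=200.0,
                                  active_med_classes=frozenset({"acei_arb"}),
                                  n_antihypertensive_classes=1))
        off = recommend(make_state(acr=200.0))
        assert "acei_arb_titrate" in on.actions and "acei_arb_initiate" not in on.actions
        assert "acei_arb_initiate" in off.actions and "acei_arb_titrate" not in off.actions

    def test_high_risk_always_education_and_bp_reminder(self):
        rec = recommend(make_state(preferred_language="Spanish"))
        assert {"bp_target_reminder", "education_ckd_general",
                "education_nsaid_avoidance", "education_diet"} <= rec.actions
        assert rec.education_language == "Spanish"

    def test_potassium_tiers(self):
        mid = recommend(make_state(potassium=5.2, kfre=0.0001))
        assert "potassium_diet_counseling" in mid.actions
        assert "potassium_diuretic_adjustment" not in mid.actions
        high = recommend(make_state(potassium=5.8, kfre=0.0001,
                                    n_antihypertensive_classes=1))
        assert {"potassium_diet_counseling",
                "potassium_diuretic_adjustment"} <= high.actions
        assert "nephrology_referral" in high.actions


# ---------------------------------------------------------------------------
# brute-force oracle: an independent, table-driven restatement of the
# published bullet-list rules, written against the text rather than the
# engine's structure


def oracle(s: PatientState):
    high = s.egfr_cys < 60 or s.acr > 30
    if not high:
        return "low", {"repeat_triple_marker_6mo"}, set()
    actions = {"bp_target_reminder", "education_ckd_general",
               "education_nsaid_avoidance", "education_diet"}
    if s.age >= 50 and "statin" not in s.active_med_classes:
        actions.add("statin_initiation")
    if s.potassium is not None and 5.0 < s.potassium <= 5.5:
        actions.add("potassium_diet_counseling")
    if s.potassium is not None and s.potassium > 5.5:
        actions |= {"potassium_diet_counseling", "potassium_diuretic_adjustment"}
    if s.acr > 30:
        actions.add("acei_arb_titrate" if "acei_arb" in s.active_med_classes
                    else "acei_arb_initiate")
    criteria = set()
    if s.egfr_cys < 30:
        criteria.add("egfr_cys_lt30")
    if s.potassium is not None and s.potassium > 5.5:
        criteria.add("k_gt_5_5")
    if s.acr > 300:
        criteria.add("acr_gt_300")
    if (s.recent_sbp is not None and s.recent_sbp > 150
            and s.n_antihypertensive_classes >= 3 and s.has_diuretic):
        criteria.add("sbp_gt150_on_3agents_with_diuretic")
    if s.kfre_5yr > 0.03:
        criteria.add("kfre_gt_3pct")
    if criteria:
        actions.add("nephrology_referral")
    return "high", actions, criteria


def random_state(rng):
    n_aht = int(rng.integers(0, 5))
    meds = set(rng.choice(["statin", "acei_arb", "beta_blocker",
                           "thiazide_diuretic", "nsaid"],
                          size=rng.integers(0, 4), replace=False))
    has_diuretic = "thiazide_diuretic" in meds and n_aht >= 1
    return PatientState(
        age=float(rng.uniform(18, 85)),
        sex=rng.choice(["female", "male"]),
        egfr_cys=float(rng.uniform(5, 120)),
        acr=float(np.exp(rng.uniform(0, 8))),
        preferred_language=rng.choice(["English", "Spanish", "Chinese"]),
        potassium=None if rng.random() < 0.1 else float(rng.uniform(3.0, 6.5)),
        recent_sbp=None if rng.random() < 0.1 else float(rng.uniform(95, 185)),
        active_med_classes=frozenset(meds),
        n_antihypertensive_classes=n_aht,
        has_diuretic=has_diuretic,
    )


def test_oracle_equivalence_10000_random_states(rng):
    for _ in range(10_000):
        s = random_state(rng)
        rec = recommend(s)
        tier, actions, criteria = oracle(s)
        assert rec.risk_tier == tier
        assert set(rec.actions) == actions, (s, rec.actions, actions)
        assert set(rec.referral_criteria_met) == criteria


def test_referral_iff_any_criterion(rng):
    for _ in range(2000):
        s = random_state(rng)
        rec = recommend(s)
        assert ("nephrology_referral" in rec.actions) == bool(rec.referral_criteria_met)


def test_monotone_worse_panel_never_improves(rng):
    """Raising ACR or lowering eGFR_Cys never flips high->low and never
    removes a referral criterion."""
    for _ in range(500):
        s = random_state(rng)
        rec = recommend(s)
        worse = PatientState(
            age=s.age, sex=s.sex,
            egfr_cys=s.egfr_cys * 0.7, acr=s.acr * 2.0,
            preferred_language=s.preferred_language, potassium=s.potassium,
            recent_sbp=s.recent_sbp, active_med_classes=s.active_med_classes,
            n_antihypertensive_classes=s.n_antihypertensive_classes,
            has_diuretic=s.has_diuretic)
        rec2 = recommend(worse)
        if rec.risk_tier == "high":
            assert rec2.risk_tier == "high"
            assert set(rec.referral_criteria_met) <= set(rec2.referral_criteria_met)
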