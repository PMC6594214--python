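"""The decision-support rules engine.

Stratifies a patient as low or high risk for CKD-related complications
from the triple-marker panel (high risk: cystatin-based eGFR below 60
mL/min/1.73m² and/or urine ACR above 30 mg/g) and, for high-risk
patients, assembles the individualized recommendation set across five
domains of CKD care: cardiovascular risk reduction, potassium
management, proteinuria management, nephrology referral, and patient
education.  Low-risk patients get exactly one action — repeat the
triple-marker panel in six months.

Every comparator lives in one :class:`RuleThresholds` object so the
inequality dialect is visible and testable.  Boundary values (eGFR_Cys
exactly 60, ACR exactly 30) satisfy neither strict clause of the
published wording; they are assigned LOW by construction.

Each emitted action carries provenance: the rule that produced it and
the input values it saw.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .renal import kfre_5yr

__all__ = [
    "RuleThresholds", "PatientState", "RecommendationSet",
    "stratify_risk", "referral_criteria", "recommend",
    "REFERRAL_CRITERIA", "HIGH_RISK_ACTIONS",
]

REFERRAL_CRITERIA = (
    "egfr_cys_lt30", "k_gt_5_5", "acr_gt_300",
    "sbp_gt150_on_3agents_with_diuretic", "kfre_gt_3pct",
)

HIGH_RISK_ACTIONS = (
    "statin_initiation", "potassium_diet_counseling",
    "potassium_diuretic_adjustment", "acei_arb_initiate", "acei_arb_titrate",
    "nephrology_referral", "bp_target_reminder", "education_ckd_general",
    "education_nsaid_avoidance", "education_diet",
)


@dataclass(frozen=True)
class RuleThresholds:
    """Comparator set for the rules engine.  All stratification and
    referral comparisons are strict, matching the published wording;
    the potassium management tiers are a conventional choice (the
    source logic names the domain but not the cutoffs)."""

    egfr_cys_high_risk: float = 60.0   # high risk iff egfr_cys <  this ...
    acr_high_risk: float = 30.0        # ... or acr > this
    egfr_cys_referral: float = 30.0    # refer iff egfr_cys < this
    potassium_referral: float = 5.5    # refer iff K > this
    acr_referral: float = 300.0        # refer iff acr > this
    sbp_referral: float = 150.0        # refer iff sbp > this on >=3 agents w/ diuretic
    min_antihypertensive_classes: int = 3
    kfre_referral: float = 0.03        # refer iff 5-yr KFRE > this
    potassium_diet_low: float = 5.0    # diet counseling iff K in (low, referral]
    statin_age: float = 50.0           # statin iff age >= this and not on one


DEFAULT_THRESHOLDS = RuleThresholds()


@dataclass
class PatientState:
    """Engine input: demographics, panel values and active treatment."""

    age: float
    sex: str
    egfr_cys: float
    acr: float
    preferred_language: str = "English"
    potassium: float | None = None
    recent_sbp: float | None = None
    active_med_classes: frozenset = frozenset()
    n_antihypertensive_classes: int = 0
    has_diuretic: bool = False
    kfre: float | None = None  # computed from egfr_cys + acr when None

    def __post_init__(self) -> None:
        if not self.egfr_cys > 0:
            raise ValueError(f"egfr_cys must be positive, got {self.egfr_cys}")
        if not self.acr > 0:
            raise ValueError(f"acr must be positive, got {self.acr}")
        if self.has_diuretic and self.n_antihypertensive_classes < 1:
            raise ValueError("has_diuretic implies at least one antihypertensive class")

    @property
    def kfre_5yr(self) -> float:
        if self.kfre is not None:
            return self.kfre
        return kfre_5yr(self.age, self.sex, self.egfr_cys, self.acr)


@dataclass
class RecommendationSet:
    risk_tier: str
    actions: frozenset
    referral_criteria_met: frozenset
    education_language: str
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.risk_tier == "low" and self.actions != frozenset({"repeat_triple_marker_6mo"}):
            raise ValueError("low-risk set must be exactly {repeat_triple_marker_6mo}")
        if ("nephrology_referral" in self.actions) != bool(self.referral_criteria_met):
            raise ValueError("nephrology_referral iff a referral criterion is met")


def stratify_risk(
    egfr_cys: float, acr: float, thresholds: RuleThresholds = DEFAULT_THRESHOLDS
) -> str:
    """Risk tier from the triple-marker panel: ``'high'`` iff
    eGFR_Cys < 60 or ACR > 30 (strict), else ``'low'``."""
    if not egfr_cys > 0:
        raise ValueError(f"egfr_cys must be positive, got {egfr_cys}")
    if not acr > 0:
        raise ValueError(f"acr must be positive, got {acr}")
    if egfr_cys < thresholds.egfr_cys_high_risk or acr > thresholds.acr_high_risk:
        return "high"
    return "low"


def referral_criteria(
    state: PatientState, thresholds: RuleThresholds = DEFAULT_THRESHOLDS
) -> tuple[frozenset, dict]:
    """Nephrology-referral criteria met, with provenance.

    A missing potassium or SBP leaves the corresponding criterion unmet
    and records it as unassessed rather than guessing.
    """
    met = set()
    prov: dict = {}
    if state.egfr_cys < thresholds.egfr_cys_referral:
        met.add("egfr_cys_lt30")
        prov["egfr_cys_lt30"] = {"egfr_cys": state.egfr_cys}
    if state.potassium is None:
        prov["k_gt_5_5"] = "unassessed: no potassium result"
    elif state.potassium > thresholds.potassium_referral:
        met.add("k_gt_5_5")
        prov["k_gt_5_5"] = {"potassium": state.potassium}
    if state.acr > thresholds.acr_referral:
        met.add("acr_gt_300")
        prov["acr_gt_300"] = {"acr": state.acr}
    if state.recent_sbp is None:
        prov["sbp_gt150_on_3agents_with_diuretic"] = "unassessed: no recent SBP"
    elif (state.recent_sbp > thresholds.sbp_referral
          and state.n_antihypertensive_classes >= thresholds.min_antihypertensive_classes
          and state.has_diuretic):
        met.add("sbp_gt150_on_3agents_with_diuretic")
        prov["sbp_gt150_on_3agents_with_diuretic"] = {
            "sbp": state.recent_sbp,
            "n_classes": state.n_antihypertensive_classes,
            "has_diuretic": state.has_diuretic,
        }
    if state.kfre_5yr > thresholds.kfre_referral:
        met.add("kfre_gt_3pct")
        prov["kfre_gt_3pct"] = {"kfre_5yr": state.kfre_5yr}
    return frozenset(met), prov


def recommend(
    state: PatientState, thresholds: RuleThresholds = DEFAULT_THRESHOLDS
) -> RecommendationSet:
    """Full recommendation set for one patient at one trigger."""
    tier = stratify_risk(state.egfr_cys, state.acr, thresholds)
    if tier == "low":
        return RecommendationSet(
            risk_tier="low",
            actions=frozenset({"repeat_triple_marker_6mo"}),
            referral_criteria_met=frozenset(),
            education_language=state.preferred_language,
            provenance={"repeat_triple_marker_6mo": "low risk tier default"},
        )

    actions = set()
    prov: dict = {"risk_tier": {"egfr_cys": state.egfr_cys, "acr": state.acr}}

    # cardiovascular risk reduction
    if state.age >= thresholds.statin_age and "statin" not in state.active_med_classes:
        actions.add("statin_initiation")
        prov["statin_initiation"] = {"age": state.age, "on_statin": False}

    # potassium management
    if state.potassium is not None:
        if state.potassium > thresholds.potassium_referral:
            actions.add("potassium_diet_counseling")
            actions.add("potassium_diuretic_adjustment")
            prov["potassium_management"] = {"potassium": state.potassium, "tier": "high"}
        elif state.potassium > thresholds.potassium_diet_low:
            actions.add("potassium_diet_counseling")
            prov["potassium_management"] = {"potassium": state.potassium, "tier": "elevated"}

    # proteinuria management
    if state.acr > thresholds.acr_high_risk:
        if "acei_arb" in state.active_med_classes:
            actions.add("acei_arb_titrate")
            prov["acei_arb_titrate"] = {"acr": state.acr, "on_acei_arb": True}
        else:
            actions.add("acei_arb_initiate")
            prov["acei_arb_initiate"] = {"acr": state.acr, "on_acei_arb": False}

    # nephrology referral
    criteria, crit_prov = referral_criteria(state, thresholds)
    prov["referral_criteria"] = crit_prov
    if criteria:
        actions.add("nephrology_referral")

    # always for high risk: BP target + the three education items
    actions.add("bp_target_reminder")
    actions.update({"education_ckd_general", "education_nsaid_avoidance",
                    "education_diet"})
    prov["education_language"] = state.preferred_language

    return RecommendationSet(
        risk_tier="high",
        actions=frozenset(actions),
        referral_criteria_met=criteria,
        education_language=state.preferred_language,
        provenance=prov,
    )
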