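"""Implementation-funnel, process-of-care and blood-pressure outcomes.

The implementation funnel follows the reach/adoption stages: enrolled →
triple-marker completed → PCP visit after results → alert opened →
orders signed → (eCDSS+) pharmacist call completed.  Each stage is
reported as numerator/denominator with the chained denominator (the
previous stage) and, where meaningful, the of-all-intervention-patients
variant.  Zero denominators yield explicit ``None`` proportions, never
division errors.

Blood-pressure outcomes use the trial conventions: baseline is the most
recent ambulatory measurement strictly before enrollment; the endpoint
is the last in-period measurement carried forward (LOCF); control is
systolic < 140 and diastolic < 90 (both strict); sustained control is a
run of two or more consecutive BP-measured visits, all controlled —
visits without a BP measurement are invisible to the run.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date

import pandas as pd

from .trigger import TrialEvent

__all__ = [
    "Proportion", "FunnelReport", "BPOutcome",
    "funnel", "patient_arms", "baseline_bp", "bp_outcomes", "process_outcomes",
]

SBP_CONTROL = 140.0
DBP_CONTROL = 90.0

FUNNEL_STAGES = ("enrolled", "triple_marker_completed", "pcp_visit_after_labs",
                 "bpa_opened", "smartset_signed", "pharmacist_call_completed")

_STAGE_EVENT = {
    "triple_marker_completed": "lab_completed",
    "pcp_visit_after_labs": "bpa_displayed",
    "bpa_opened": "bpa_opened",
    "smartset_signed": "smartset_signed",
    "pharmacist_call_completed": "pharmacist_call_completed",
}


@dataclass(frozen=True)
class Proportion:
    numerator: int
    denominator: int

    @property
    def value(self) -> float | None:
        return self.numerator / self.denominator if self.denominator else None

    @property
    def pct(self) -> float | None:
        v = self.value
        return None if v is None else round(100.0 * v, 1)

    def __post_init__(self) -> None:
        if self.numerator > self.denominator:
            raise ValueError(
                f"numerator {self.numerator} exceeds denominator {self.denominator}")


@dataclass
class FunnelReport:
    """Counts and proportions down the implementation funnel, pooled and
    per arm.  ``chained`` proportions use the previous stage as the
    denominator; ``of_all`` uses every intervention patient."""

    counts: dict
    chained: dict
    of_all: dict
    per_arm_counts: dict


def patient_arms(patients: pd.DataFrame, provider_arms: dict[str, str]) -> dict[str, str]:
    """Patients inherit their PCP's arm assignment."""
    return {
        r["patient_id"]: provider_arms.get(r["provider_id"], "usual_care")
        for _, r in patients.iterrows()
    }


def _validate_log(events: list[TrialEvent]) -> None:
    per_patient: dict[str, list[str]] = {}
    last_at: dict[str, date] = {}
    for e in events:
        kinds = per_patient.setdefault(e.patient_id, [])
        if e.patient_id in last_at and e.at < last_at[e.patient_id]:
            raise ValueError(
                f"event log not time-ordered for {e.patient_id} at {e.at}")
        last_at[e.patient_id] = e.at
        if e.kind == "bpa_displayed" and kinds.count("bpa_displayed") >= 3:
            raise ValueError(f"{e.patient_id}: more than 3 displays")
        if e.kind == "bpa_displayed" and "smartset_signed" in kinds:
            raise ValueError(f"{e.patient_id}: display after signing")
        kinds.append(e.kind)


def funnel(
    events: list[TrialEvent],
    arms_by_patient: dict[str, str],
    validate: bool = True,
) -> FunnelReport:
    """Reach/adoption funnel from an event log.

    ``arms_by_patient`` supplies the enrolled denominator: every patient
    in an intervention arm, whether or not they emitted events.
    """
    if validate:
        _validate_log(events)
    intervention = {p for p, a in arms_by_patient.items() if a in ("ecdss", "ecdss_plus")}
    reached: dict[str, set] = {stage: set() for stage in FUNNEL_STAGES}
    reached["enrolled"] = set(intervention)
    for e in events:
        for stage, kind in _STAGE_EVENT.items():
            if e.kind == kind:
                reached[stage].add(e.patient_id)

    counts = {stage: len(reached[stage]) for stage in FUNNEL_STAGES}
    chained = {}
    for prev, stage in zip(FUNNEL_STAGES, FUNNEL_STAGES[1:]):
        denom = counts["enrolled"] if stage == "triple_marker_completed" else counts[prev]
        if stage == "pharmacist_call_completed":
            # denominator: signers in the eCDSS+ arm only
            denom = len({p for p in reached["smartset_signed"]
                         if arms_by_patient.get(p) == "ecdss_plus"})
        chained[stage] = Proportion(counts[stage], denom)
    of_all = {stage: Proportion(counts[stage], counts["enrolled"])
              for stage in FUNNEL_STAGES[1:]}

    per_arm: dict[str, dict[str, int]] = {}
    for arm in sorted({a for a in arms_by_patient.values() if a != "usual_care"}):
        members = {p for p, a in arms_by_patient.items() if a == arm}
        per_arm[arm] = {stage: len(reached[stage] & members) for stage in FUNNEL_STAGES}
        per_arm[arm]["enrolled"] = len(members)
    return FunnelReport(counts, chained, of_all, per_arm)


# ---------------------------------------------------------------------------
# blood-pressure outcomes


@dataclass
class BPOutcome:
    patient_id: str
    baseline_sbp: float
    baseline_dbp: float
    endpoint_sbp: float
    endpoint_dbp: float
    controlled_at_endpoint: bool
    sustained_control: bool

    @property
    def delta_sbp(self) -> float:
        return self.endpoint_sbp - self.baseline_sbp

    @property
    def delta_dbp(self) -> float:
        return self.endpoint_dbp - self.baseline_dbp


AMBULATORY_TYPES = ("pcp_visit", "non_pcp_visit", "nephrology_visit")


def _bp_rows(encounters: pd.DataFrame, patient_id: str) -> pd.DataFrame:
    rows = encounters[
        (encounters["patient_id"] == patient_id)
        & (encounters["type"].isin(AMBULATORY_TYPES))
        & encounters["systolic_bp"].notna()
        & encounters["diastolic_bp"].notna()
    ]
    return rows.sort_values(["occurred_at", "encounter_id"])


def baseline_bp(
    encounters: pd.DataFrame, patient_id: str, enrollment_date: date
) -> tuple[float, float] | None:
    """Most recent ambulatory BP strictly before enrollment; same-day
    ties resolved by encounter id (stable, deterministic)."""
    rows = _bp_rows(encounters, patient_id)
    rows = rows[rows["occurred_at"] < enrollment_date]
    if rows.empty:
        return None
    last = rows.iloc[-1]
    return float(last["systolic_bp"]), float(last["diastolic_bp"])


def _controlled(sbp: float, dbp: float) -> bool:
    return sbp < SBP_CONTROL and dbp < DBP_CONTROL


def bp_outcomes(
    encounters: pd.DataFrame,
    patient_id: str,
    enrollment_date: date,
    period_end: date,
) -> BPOutcome | None:
    """LOCF endpoint and sustained-control status for one patient.

    Returns None (patient excluded from the BP outcome) when no baseline
    measurement exists before enrollment.
    """
    base = baseline_bp(encounters, patient_id, enrollment_date)
    if base is None:
        return None
    rows = _bp_rows(encounters, patient_id)
    in_period = rows[(rows["occurred_at"] >= enrollment_date)
                     & (rows["occurred_at"] <= period_end)]
    if in_period.empty:
        # nothing measured in-period: baseline carries forward
        end_sbp, end_dbp = base
        series: list[tuple[float, float]] = []
    else:
        last = in_period.iloc[-1]
        end_sbp, end_dbp = float(last["systolic_bp"]), float(last["diastolic_bp"])
        series = [(float(r["systolic_bp"]), float(r["diastolic_bp"]))
                  for _, r in in_period.iterrows()]

    run = best = 0
    for sbp, dbp in series:
        run = run + 1 if _controlled(sbp, dbp) else 0
        best = max(best, run)
    return BPOutcome(
        patient_id=patient_id,
        baseline_sbp=base[0], baseline_dbp=base[1],
        endpoint_sbp=end_sbp, endpoint_dbp=end_dbp,
        controlled_at_endpoint=_controlled(end_sbp, end_dbp),
        sustained_control=best >= 2,
    )


# ---------------------------------------------------------------------------
# process-of-care outcomes


def process_outcomes(
    patients: pd.DataFrame,
    medications: pd.DataFrame,
    problem_list: pd.DataFrame,
    labs: pd.DataFrame,
    index_date: date,
    period_start: date | None = None,
    albuminuria_threshold: float = 30.0,
    statin_age: float = 50.0,
) -> dict[str, Proportion]:
    """CKD recognition, ACEi/ARB for albuminuria, and statin use.

    Recognition counts a CKD code on the problem list or as a visit
    diagnosis.  Albuminuria is ACR > 30 mg/g on the most recent urine
    ACR.  Statin initiation is an order starting on/after
    ``period_start`` (when given).
    """
    from .synthetic import age_at

    pids = list(patients["patient_id"])
    n = len(pids)
    codes = problem_list.groupby("patient_id")["code"].agg(set)
    meds = medications.groupby("patient_id")["med_class"].agg(set)

    def dx(pid: str) -> set:
        return codes.get(pid, set())

    def on(pid: str, med: str) -> bool:
        return med in meds.get(pid, set())

    recognized = sum(
        1 for p in pids if dx(p) & {"ckd_problem_list", "ckd_visit_dx"})
    on_problem_list = sum(1 for p in pids if "ckd_problem_list" in dx(p))

    acr = labs[labs["analyte"] == "urine_acr"].sort_values("collected_at")
    latest_acr = acr.groupby("patient_id")["value"].last()
    albuminuric = [p for p in pids
                   if latest_acr.get(p, float("nan")) > albuminuria_threshold]
    acei_arb_albuminuric = sum(1 for p in albuminuric if on(p, "acei_arb"))

    aged = [
        p for p, b in zip(patients["patient_id"], patients["birth_date"])
        if age_at(b, index_date) >= statin_age
    ]
    statin_aged = sum(1 for p in aged if on(p, "statin"))

    initiated = 0
    if period_start is not None:
        statins = medications[medications["med_class"] == "statin"]
        initiated = statins[
            [d >= period_start for d in statins["active_from"]]
        ]["patient_id"].nunique()

    return {
        "ckd_recognized": Proportion(recognized, n),
        "ckd_on_problem_list": Proportion(on_problem_list, n),
        "acei_arb_for_albuminuria": Proportion(acei_arb_albuminuric, len(albuminuric)),
        "statin_age_50_plus": Proportion(statin_aged, len(aged)),
        "statin_initiated_in_period": Proportion(initiated, n),
    }
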