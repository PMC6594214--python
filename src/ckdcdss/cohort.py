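"""Trial cohort identification: inclusion criteria and exclusion cascade.

Inclusion requires, at the index date: age 18–80; preferred language
English, Spanish or Chinese; two outpatient creatinine-based eGFR values
in 30–59 mL/min/1.73m² at least 90 days apart with the later one inside
the 12 months before the index date; and a primary-care visit in the
past 18 months.  Automated exclusions then remove patients who are
deceased, have end-stage renal disease, are engaged with nephrology
(two or more visits in the past 12 months), are transplant recipients,
or carry a dementia diagnosis.  Manual exclusions and opt-outs are
consumed as input flag tables — the clinical judgements behind them are
not inferable from structured data.

Calendar dialect (fixed so decisions are bit-stable): "12 months" is
365 days, "18 months" is 548 days, windows are half-open [start, index)
at day granularity, the 30–59 band is inclusive on both ends, and "at
least 90 days apart" means a date difference of 90 or more days.
eGFR is always recomputed from stored creatinine results (age taken at
the collection date), never trusted from a stored eGFR column.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta

import pandas as pd

from .renal import egfr_creatinine
from .synthetic import EHRDataset, age_at

__all__ = [
    "EligibilityDecision",
    "EgfrPairEvidence",
    "find_qualifying_egfr_pair",
    "apply_automated_exclusions",
    "build_cohort",
    "CohortSummary",
]

EGFR_LOW = 30.0
EGFR_HIGH = 59.0
MIN_PAIR_GAP_DAYS = 90
RECENT_WINDOW_DAYS = 365
PCP_VISIT_WINDOW_DAYS = 548
NEPHROLOGY_VISIT_THRESHOLD = 2

ALLOWED_LANGUAGES = frozenset({"English", "Spanish", "Chinese"})

AUTOMATED_EXCLUSION_ORDER = ("deceased", "esrd", "nephrology_engaged",
                             "transplant", "dementia")


@dataclass(frozen=True)
class EgfrPairEvidence:
    """The qualifying eGFR pair backing an eligibility decision."""

    value_first: float
    date_first: date
    value_second: float
    date_second: date


@dataclass
class EligibilityDecision:
    patient_id: str
    eligible: bool
    reason_codes: list[str] = field(default_factory=list)
    evidence: EgfrPairEvidence | None = None

    def __post_init__(self) -> None:
        if self.eligible and self.reason_codes:
            raise ValueError("eligible decision cannot carry reason codes")
        if not self.eligible and not self.reason_codes:
            raise ValueError("ineligible decision needs at least one reason code")


def find_qualifying_egfr_pair(
    history: list[tuple[float, date]],
    index_date: date,
) -> EgfrPairEvidence | None:
    """Search an outpatient eGFR history for a qualifying pair.

    Both values must lie in [30, 59], the dates must differ by >= 90
    days, and the later date must fall within the 365 days strictly
    before ``index_date``.  Among qualifying pairs the one with the most
    recent later date wins, ties broken by the earlier first date.
    """
    in_range = sorted(
        ((v, d) for v, d in history if EGFR_LOW <= v <= EGFR_HIGH),
        key=lambda t: t[1],
    )
    best: EgfrPairEvidence | None = None
    for j in range(len(in_range)):
        v2, d2 = in_range[j]
        if not (index_date - timedelta(days=RECENT_WINDOW_DAYS) <= d2 < index_date):
            continue
        for i in range(j):
            v1, d1 = in_range[i]
            if (d2 - d1).days < MIN_PAIR_GAP_DAYS:
                continue
            cand = EgfrPairEvidence(v1, d1, v2, d2)
            if best is None or (cand.date_second, -cand.date_first.toordinal()) > (
                best.date_second, -best.date_first.toordinal()
            ):
                best = cand
    return best


def _outpatient_egfr_history(
    labs: pd.DataFrame, patient: pd.Series
) -> list[tuple[float, date]]:
    rows = labs[(labs["patient_id"] == patient["patient_id"])
                & (labs["analyte"] == "serum_creatinine")
                & (labs["setting"] == "outpatient")]
    out = []
    for _, r in rows.iterrows():
        when = r["collected_at"]
        egfr = egfr_creatinine(r["value"], age_at(patient["birth_date"], when),
                               patient["sex"])
        out.append((egfr, when))
    return out


def apply_automated_exclusions(
    patient: pd.Series,
    encounters: pd.DataFrame,
    problem_list: pd.DataFrame,
    index_date: date,
) -> list[str]:
    """Every automated exclusion rule the patient triggers, in canonical order."""
    codes = []
    dx = set(problem_list.loc[problem_list["patient_id"] == patient["patient_id"], "code"])
    if int(patient.get("deceased", 0)):
        codes.append("deceased")
    if "esrd" in dx:
        codes.append("esrd")
    neph = encounters[
        (encounters["patient_id"] == patient["patient_id"])
        & (encounters["type"] == "nephrology_visit")
    ]
    window_start = index_date - timedelta(days=RECENT_WINDOW_DAYS)
    n_neph = sum(1 for d in neph["occurred_at"] if window_start <= d < index_date)
    if n_neph >= NEPHROLOGY_VISIT_THRESHOLD:
        codes.append("nephrology_engaged")
    if "transplant" in dx:
        codes.append("transplant")
    if "dementia" in dx:
        codes.append("dementia")
    return codes


@dataclass
class CohortSummary:
    """Funnel counts with first-triggered-rule attribution."""

    n_screened: int
    n_initially_eligible: int
    n_auto_excluded: int
    n_manually_excluded: int
    n_distributed: int          # initially eligible minus all exclusions
    n_opted_out: int
    n_included: int
    exclusion_counts: dict[str, int]

    @property
    def auto_exclusion_rate(self) -> float:
        """Automated exclusions as a fraction of the initially eligible."""
        return self.n_auto_excluded / self.n_initially_eligible

    @property
    def retention_rate(self) -> float:
        """Included as a fraction of those surviving all exclusions."""
        return self.n_included / self.n_distributed


def build_cohort(
    ehr: EHRDataset,
    index_date: date,
    manual_exclusions: pd.DataFrame | None = None,
    opt_outs: set[str] | None = None,
) -> tuple[list[EligibilityDecision], CohortSummary]:
    """Run the full eligibility cascade over an EHR dataset.

    ``manual_exclusions`` is a table with columns ``patient_id`` and
    ``subcode`` (e.g. pregnancy, limited life expectancy, PCP
    discretion); ``opt_outs`` is a set of patient ids.  Inclusion
    criteria run first, then automated exclusions, then manual
    exclusions, then opt-outs.  The summary counts each patient once at
    the first stage that removes them; the per-patient decision retains
    every triggered reason code.
    """
    opt_outs = opt_outs or set()
    manual_map: dict[str, list[str]] = {}
    if manual_exclusions is not None and len(manual_exclusions):
        for _, r in manual_exclusions.iterrows():
            manual_map.setdefault(str(r["patient_id"]), []).append(str(r["subcode"]))

    decisions: list[EligibilityDecision] = []
    excl_counts: dict[str, int] = {}
    n_initial = n_auto = n_manual = n_opt = n_included = 0

    patients = ehr.patients.sort_values("patient_id")
    for _, patient in patients.iterrows():
        pid = patient["patient_id"]
        codes: list[str] = []

        age = age_at(patient["birth_date"], index_date)
        if not (18.0 <= age <= 80.0):
            codes.append("age_range")
        if patient["preferred_language"] not in ALLOWED_LANGUAGES:
            codes.append("language")
        history = _outpatient_egfr_history(ehr.labs, patient)
        evidence = find_qualifying_egfr_pair(history, index_date)
        if evidence is None:
            dates = sorted(d for v, d in history if EGFR_LOW <= v <= EGFR_HIGH)
            spread = (len(dates) >= 2
                      and (dates[-1] - dates[0]).days >= MIN_PAIR_GAP_DAYS)
            codes.append("no_recent_egfr" if spread else "insufficient_egfr_pair")
        pcp_window = index_date - timedelta(days=PCP_VISIT_WINDOW_DAYS)
        recent_pcp = ehr.encounters[
            (ehr.encounters["patient_id"] == pid)
            & (ehr.encounters["type"] == "pcp_visit")
        ]
        if not any(pcp_window <= d < index_date for d in recent_pcp["occurred_at"]):
            codes.append("no_recent_pcp_visit")

        initially_eligible = not codes
        if initially_eligible:
            n_initial += 1

        auto = apply_automated_exclusions(patient, ehr.encounters,
                                          ehr.problem_list, index_date)
        codes.extend(auto)
        manual = [f"manual_exclusion:{sub}" for sub in manual_map.get(pid, [])]
        codes.extend(manual)
        opted = pid in opt_outs
        if opted:
            codes.append("opt_out")

        if initially_eligible:
            if auto:
                n_auto += 1
                excl_counts[auto[0]] = excl_counts.get(auto[0], 0) + 1
            elif manual:
                n_manual += 1
                excl_counts[manual[0]] = excl_counts.get(manual[0], 0) + 1
            elif opted:
                n_opt += 1
                excl_counts["opt_out"] = excl_counts.get("opt_out", 0) + 1
            else:
                n_included += 1

        decisions.append(EligibilityDecision(
            patient_id=pid,
            eligible=not codes,
            reason_codes=codes,
            evidence=evidence if not codes else None,
        ))

    summary = CohortSummary(
        n_screened=len(patients),
        n_initially_eligible=n_initial,
        n_auto_excluded=n_auto,
        n_manually_excluded=n_manual,
        n_distributed=n_initial - n_auto - n_manual,
        n_opted_out=n_opt,
        n_included=n_included,
        exclusion_counts=excl_counts,
    )
    return decisions, summary


def decisions_to_frame(decisions: list[EligibilityDecision]) -> pd.DataFrame:
    """One row per patient; reason codes pipe-delimited."""
    rows = []
    for d in decisions:
        ev = d.evidence
        rows.append({
            "patient_id": d.patient_id,
            "eligible": int(d.eligible),
            "reason_codes": "|".join(d.reason_codes),
            "egfr_first": ev.value_first if ev else None,
            "date_first": ev.date_first if ev else None,
            "egfr_second": ev.value_second if ev else None,
            "date_second": ev.date_second if ev else None,
        })
    return pd.DataFrame(rows)
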