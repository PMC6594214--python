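"""Nephrologist weekly safety surveillance.

Four rules, with the comparators exactly as specified: creatinine-based
eGFR decline of more than 30% from the pre-enrollment baseline; urine
ACR of 1000 mg/g or more (inclusive); a nephrology referral signed more
than a configurable lag (default 90 days) before the review date with
no subsequent nephrology visit; and a discordance of more than 30%
between the creatinine- and cystatin-based eGFR on a same-panel pair.
The discordance denominator is the creatinine-based value (the
routinely reported one); both the denominator and the referral lag are
configurable because the operational convention is a local choice.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta

import pandas as pd

from .renal import egfr_creatinine, egfr_cystatin
from .synthetic import age_at

__all__ = ["SafetyConfig", "SafetyFlag", "weekly_review"]

SAFETY_RULES = ("egfr_decline_gt30pct", "acr_ge_1000",
                "referral_nonadherence", "egfr_discordance_gt30pct")


@dataclass(frozen=True)
class SafetyConfig:
    decline_fraction: float = 0.30        # strict >
    acr_threshold: float = 1000.0         # inclusive >=
    discordance_fraction: float = 0.30    # strict >
    referral_lag_days: int = 90
    discordance_denominator: str = "egfr_cr"  # or "egfr_cys"


@dataclass(frozen=True)
class SafetyFlag:
    patient_id: str
    rule: str
    detected_at: date
    values: dict

    def key(self) -> tuple:
        # one flag per (patient, rule, review week)
        return (self.patient_id, self.rule, self.detected_at.isocalendar()[:2])


def weekly_review(
    labs_window: pd.DataFrame,
    patients: pd.DataFrame,
    baselines: dict[str, float],
    referrals: list[dict],
    nephrology_visits: dict[str, list[date]],
    review_date: date,
    config: SafetyConfig = SafetyConfig(),
    previous_flags: list[SafetyFlag] | None = None,
) -> list[SafetyFlag]:
    """One weekly pass over the window's laboratory results.

    ``labs_window`` holds the results since the last review (columns
    patient_id, analyte, value, collected_at).  ``baselines`` maps
    patient_id to the most recent pre-enrollment outpatient eGFR_Cr;
    patients without one simply skip the decline rule (unassessed, not
    assumed normal).  ``referrals`` are dicts with ``patient_id`` and
    ``signed_at``.  Re-running the same week against ``previous_flags``
    emits no duplicates.
    """
    seen = {f.key() for f in (previous_flags or [])}
    flags: list[SafetyFlag] = []

    def emit(pid: str, rule: str, values: dict) -> None:
        flag = SafetyFlag(pid, rule, review_date, values)
        if flag.key() not in seen:
            seen.add(flag.key())
            flags.append(flag)

    pat = patients.set_index("patient_id")

    for pid, grp in labs_window.groupby("patient_id"):
        prow = pat.loc[pid]
        by_date: dict[date, dict[str, float]] = {}
        for _, lab in grp.iterrows():
            by_date.setdefault(lab["collected_at"], {})[lab["analyte"]] = lab["value"]
        for when, values in sorted(by_date.items()):
            age = age_at(prow["birth_date"], when)
            ecr = (egfr_creatinine(values["serum_creatinine"], age, prow["sex"])
                   if "serum_creatinine" in values else None)
            if ecr is not None and pid in baselines:
                baseline = baselines[pid]
                decline = (baseline - ecr) / baseline
                if decline > config.decline_fraction:
                    emit(pid, "egfr_decline_gt30pct",
                         {"baseline": baseline, "current": ecr, "decline": decline})
            if "urine_acr" in values and values["urine_acr"] >= config.acr_threshold:
                emit(pid, "acr_ge_1000", {"acr": values["urine_acr"]})
            if ecr is not None and "cystatin_c" in values:
                ecys = egfr_cystatin(values["cystatin_c"], age, prow["sex"])
                denom = ecr if config.discordance_denominator == "egfr_cr" else ecys
                disc = abs(ecr - ecys) / denom
                if disc > config.discordance_fraction:
                    emit(pid, "egfr_discordance_gt30pct",
                         {"egfr_cr": ecr, "egfr_cys": ecys, "discordance": disc})

    cutoff = review_date - timedelta(days=config.referral_lag_days)
    for ref in referrals:
        pid, signed_at = ref["patient_id"], ref["signed_at"]
        if signed_at >= cutoff:
            continue
        visits = nephrology_visits.get(pid, [])
        if not any(signed_at < v <= review_date for v in visits):
            emit(pid, "referral_nonadherence",
                 {"signed_at": signed_at.isoformat(),
                  "lag_days": (review_date - signed_at).days})
    return flags
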