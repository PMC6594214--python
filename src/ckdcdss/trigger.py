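"""Best-practice-advisory (BPA) lifecycle state machine and trial simulator.

The alert fires the first time the patient visits their own PCP after
all three triple-marker results are available; if the PCP does not open
and sign, it may re-fire at up to two additional PCP visits (three
display opportunities in total).  Signing freezes the machine.  In the
eCDSS+ arm, signing schedules a pharmacist phone call due within 14
days.  Hovering over the alert is not modeled as opening: "opened"
means the accept click, the countable adoption event.

:func:`simulate_trial` drives every intervention-arm patient through
order → lab completion → visits → display → open → sign → (pharmacist
call) under a behavior model whose probabilities are per-patient
eventual rates — the same denominators the implementation funnel uses.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from datetime import date, timedelta

import numpy as np

from .engine import PatientState, RuleThresholds, DEFAULT_THRESHOLDS, recommend
from .renal import egfr_cystatin
from .synthetic import EHRDataset, age_at

__all__ = [
    "TriggerState", "TrialEvent", "BehaviorModel",
    "labs_complete_time", "process_encounter", "schedule_pharmacist_call",
    "simulate_trial",
]

MAX_DISPLAYS = 3
PHARMACIST_CALL_DUE_DAYS = 14

EVENT_KINDS = (
    "triple_order", "lab_completed", "bpa_displayed", "bpa_opened",
    "smartset_signed", "pharmacist_call_scheduled", "pharmacist_call_completed",
)

TRIPLE_ANALYTES = ("serum_creatinine", "cystatin_c", "urine_acr")


@dataclass(frozen=True)
class PharmacistTask:
    due_by: date
    completed_at: date | None = None


@dataclass(frozen=True)
class TriggerState:
    """Per-patient BPA state; immutable — transitions return new states."""

    patient_id: str
    arm: str
    pcp_provider_id: str
    labs_complete_at: date | None = None
    displays: int = 0
    opened: bool = False
    signed: bool = False
    signed_at: date | None = None
    pharmacist_task: PharmacistTask | None = None
    last_event_at: date | None = None

    def __post_init__(self) -> None:
        if self.displays > MAX_DISPLAYS:
            raise ValueError(f"displays cannot exceed {MAX_DISPLAYS}")
        if self.signed and not self.opened:
            raise ValueError("signed implies opened")
        if self.pharmacist_task is not None and (
            self.arm != "ecdss_plus" or not self.signed
        ):
            raise ValueError("pharmacist task only in ecdss_plus after signing")


@dataclass(frozen=True)
class TrialEvent:
    patient_id: str
    kind: str
    at: date
    payload: dict | None = None

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")


class SequencingError(RuntimeError):
    """An encounter arrived out of chronological order."""


def labs_complete_time(results: dict[str, date], ordered_at: date | None = None) -> date | None:
    """When the triple-marker panel became complete.

    ``results`` maps analyte name to collection date (latest per analyte
    if duplicates were already collapsed upstream).  Returns the max of
    the three dates, or None while any analyte is missing.
    """
    if any(a not in results for a in TRIPLE_ANALYTES):
        return None
    return max(results[a] for a in TRIPLE_ANALYTES)


def process_encounter(
    state: TriggerState,
    encounter: dict,
    behavior: dict | None = None,
    recommendation=None,
) -> tuple[TriggerState, list[TrialEvent]]:
    """Advance the BPA machine by one encounter.

    ``encounter`` needs keys ``provider_id``, ``occurred_at``, ``type``.
    ``behavior`` flags ``opens`` / ``signs`` decide PCP behavior at a
    display.  The alert displays iff this is a PCP visit with the
    patient's own PCP, labs are complete by the visit, the set is not
    yet signed, and fewer than three displays have occurred.
    """
    behavior = behavior or {}
    when = encounter["occurred_at"]
    if state.last_event_at is not None and when < state.last_event_at:
        raise SequencingError(
            f"encounter at {when} precedes last event at {state.last_event_at}")
    events: list[TrialEvent] = []

    eligible_visit = (
        encounter["type"] == "pcp_visit"
        and encounter["provider_id"] == state.pcp_provider_id
        and state.labs_complete_at is not None
        and state.labs_complete_at <= when
        and not state.signed
        and state.displays < MAX_DISPLAYS
    )
    if not eligible_visit:
        return replace(state, last_event_at=max(when, state.last_event_at or when)), events

    payload = None
    if recommendation is not None:
        payload = {"risk_tier": recommendation.risk_tier,
                   "actions": sorted(recommendation.actions)}
    state = replace(state, displays=state.displays + 1, last_event_at=when)
    events.append(TrialEvent(state.patient_id, "bpa_displayed", when, payload))
    if behavior.get("opens"):
        state = replace(state, opened=True)
        events.append(TrialEvent(state.patient_id, "bpa_opened", when, payload))
        if behavior.get("signs"):
            state = replace(state, signed=True, signed_at=when)
            events.append(TrialEvent(state.patient_id, "smartset_signed", when, payload))
    return state, events


def schedule_pharmacist_call(state: TriggerState) -> tuple[TriggerState, TrialEvent]:
    """Create the post-signing pharmacist task (eCDSS+ only)."""
    if state.arm != "ecdss_plus":
        raise ValueError(f"pharmacist call only in ecdss_plus arm, not {state.arm}")
    if not state.signed or state.signed_at is None:
        raise ValueError("cannot schedule a pharmacist call before signing")
    if state.pharmacist_task is not None:
        raise ValueError("pharmacist call already scheduled")
    due = state.signed_at + timedelta(days=PHARMACIST_CALL_DUE_DAYS)
    task = PharmacistTask(due_by=due)
    event = TrialEvent(state.patient_id, "pharmacist_call_scheduled",
                       state.signed_at, {"due_by": due.isoformat()})
    return replace(state, pharmacist_task=task), event


@dataclass(frozen=True)
class BehaviorModel:
    """Per-patient eventual probabilities along the implementation funnel:
    completing the triple-marker labs, having a PCP visit after results,
    the PCP opening the alert, the PCP signing once opened, and (eCDSS+)
    the pharmacist call being completed."""

    p_lab_completion: float = 0.53
    p_pcp_visit: float = 0.775
    p_open: float = 0.739
    p_sign: float = 0.814
    p_call_completed: float = 0.90

    def __post_init__(self) -> None:
        for name in ("p_lab_completion", "p_pcp_visit", "p_open", "p_sign",
                     "p_call_completed"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")


def _patient_state_from_latent(gt_row, patient_row, index_date, meds_by_patient) -> PatientState:
    """Materialize the engine input from latent physiology plus the
    medication table (the engine sees real tables, not the sidecar)."""
    age = age_at(patient_row["birth_date"], index_date)
    classes = frozenset(meds_by_patient)
    n_aht = len(classes & {"acei_arb", "thiazide_diuretic", "loop_diuretic",
                           "beta_blocker", "calcium_channel_blocker"})
    return PatientState(
        age=age,
        sex=patient_row["sex"],
        egfr_cys=egfr_cystatin(gt_row["true_scys"], age, patient_row["sex"]),
        acr=gt_row["true_acr"],
        preferred_language=patient_row["preferred_language"],
        potassium=None,
        recent_sbp=None,
        active_med_classes=classes,
        n_antihypertensive_classes=n_aht,
        has_diuretic=bool(classes & {"thiazide_diuretic", "loop_diuretic"}),
    )


def simulate_trial(
    ehr: EHRDataset,
    assignments: dict[str, str],
    behavior: BehaviorModel,
    horizon_days: int = 365,
    seed: int | None = None,
    start_date: date | None = None,
    thresholds: RuleThresholds = DEFAULT_THRESHOLDS,
) -> list[TrialEvent]:
    """Run every intervention-arm patient through the BPA workflow.

    ``assignments`` maps provider_id to arm.  Usual-care patients emit
    no intervention events.  Deterministic for a fixed seed; patients
    are processed in id order and each consumes a fixed number of
    draws, so the stream is replayable.
    """
    rng = np.random.default_rng(seed)
    start = start_date or date(2017, 10, 4)
    meds = ehr.medications.groupby("patient_id")["med_class"].agg(set).to_dict()
    gt = ehr.ground_truth.set_index("patient_id")
    events: list[TrialEvent] = []

    patients = ehr.patients.sort_values("patient_id")
    for _, prow in patients.iterrows():
        pid = prow["patient_id"]
        arm = assignments.get(prow["provider_id"], "usual_care")
        if arm not in ("ecdss", "ecdss_plus"):
            continue
        draws = rng.random(4)
        events.append(TrialEvent(pid, "triple_order", start))
        if draws[0] >= behavior.p_lab_completion:
            continue
        t_complete = start + timedelta(days=int(rng.integers(7, max(8, horizon_days // 2))))
        events.append(TrialEvent(pid, "lab_completed", t_complete))

        state = TriggerState(patient_id=pid, arm=arm,
                             pcp_provider_id=prow["provider_id"],
                             labs_complete_at=t_complete)
        if draws[1] >= behavior.p_pcp_visit:
            continue
        opens = draws[2] < behavior.p_open
        signs = opens and draws[3] < behavior.p_sign

        # visits: one suffices if the PCP signs at first display; a PCP
        # who never signs keeps seeing the alert at up to MAX_DISPLAYS visits
        remaining = horizon_days - (t_complete - start).days
        n_visits = 1 if signs else MAX_DISPLAYS
        gap = max(1, remaining // (n_visits + 1))
        visit_day = t_complete
        for v in range(n_visits):
            visit_day = visit_day + timedelta(days=gap)
            rec = recommend(
                _patient_state_from_latent(gt.loc[pid], prow, visit_day,
                                           meds.get(pid, set())),
                thresholds,
            )
            state, evs = process_encounter(
                state,
                {"provider_id": prow["provider_id"], "occurred_at": visit_day,
                 "type": "pcp_visit"},
                behavior={"opens": opens and v == 0, "signs": signs},
                recommendation=rec,
            )
            events.extend(evs)
            if state.signed:
                break

        if state.signed and arm == "ecdss_plus":
            state, ev = schedule_pharmacist_call(state)
            events.append(ev)
            if rng.random() < behavior.p_call_completed:
                done = state.signed_at + timedelta(days=int(rng.integers(1, 15)))
                events.append(TrialEvent(pid, "pharmacist_call_completed", done))

    events.sort(key=lambda e: (e.at, e.patient_id, EVENT_KINDS.index(e.kind)))
    return events
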