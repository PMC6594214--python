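"""Programmatic reference fixtures.

These builders construct, at run time, small synthetic objects that
encode the reported participant flow of the trial: an event log whose
funnel counts match the implementation outcomes, and a selection-funnel
summary matching the recruitment cascade.  They exist so that the
funnel and summary code paths can be exercised against a flow whose
stage counts are known exactly; all percentages are computed by the
package, never stored.
"""

from __future__ import annotations

from datetime import date, timedelta

from .cohort import CohortSummary
from .trigger import TrialEvent

__all__ = ["reference_flow_log", "reference_selection_summary", "REFERENCE_FLOW"]

# stage counts of the observed implementation funnel (pooled over the
# two intervention arms)
REFERENCE_FLOW = {
    "enrolled": 336,
    "triple_marker_completed": 178,
    "pcp_visit_after_labs": 138,
    "bpa_opened": 102,
    "smartset_signed": 83,
}

# recruitment cascade: initially eligible -> automated exclusions ->
# clinician/protocol exclusions -> distributed -> opt-out/withdraw -> included
REFERENCE_SELECTION = {
    "initially_eligible": 995,
    "auto_excluded": 316,
    "manually_excluded": 97,   # 90 clinician + 7 protocol
    "distributed": 582,
    "opted_out_or_withdrew": 58,
    "included": 524,
}


def reference_flow_log(start: date = date(2017, 10, 4)) -> tuple[list[TrialEvent], dict[str, str]]:
    """An event log realizing the reference funnel counts.

    Returns (events, arms_by_patient).  Patients are split between the
    two intervention arms; stage membership is nested (every signer
    opened, every opener visited, ...), matching funnel monotonicity.
    """
    flow = REFERENCE_FLOW
    events: list[TrialEvent] = []
    arms: dict[str, str] = {}
    for i in range(flow["enrolled"]):
        pid = f"RF{i:04d}"
        arms[pid] = "ecdss" if i % 2 == 0 else "ecdss_plus"
        events.append(TrialEvent(pid, "triple_order", start))
        if i < flow["triple_marker_completed"]:
            t = start + timedelta(days=30)
            events.append(TrialEvent(pid, "lab_completed", t))
        if i < flow["pcp_visit_after_labs"]:
            t = start + timedelta(days=60)
            events.append(TrialEvent(pid, "bpa_displayed", t))
        if i < flow["bpa_opened"]:
            events.append(TrialEvent(pid, "bpa_opened", start + timedelta(days=60)))
        if i < flow["smartset_signed"]:
            events.append(TrialEvent(pid, "smartset_signed", start + timedelta(days=60)))
    events.sort(key=lambda e: (e.at, e.patient_id))
    return events, arms


def reference_selection_summary() -> CohortSummary:
    """The recruitment cascade as a :class:`CohortSummary`."""
    s = REFERENCE_SELECTION
    return CohortSummary(
        n_screened=s["initially_eligible"],
        n_initially_eligible=s["initially_eligible"],
        n_auto_excluded=s["auto_excluded"],
        n_manually_excluded=s["manually_excluded"],
        n_distributed=s["distributed"],
        n_opted_out=s["opted_out_or_withdrew"],
        n_included=s["included"],
        exclusion_counts={"automated": s["auto_excluded"],
                          "manual": s["manually_excluded"],
                          "opt_out": s["opted_out_or_withdrew"]},
    )
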