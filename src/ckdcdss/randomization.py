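"""Cluster-balanced block randomization of providers to trial arms.

Providers are sorted by eligible-panel size (descending, ties broken by
provider id), partitioned into consecutive blocks of ``n_arms``, and arm
labels are randomly permuted within each block.  Because every block
contributes one provider to each arm and blocks group providers of
similar panel size, the procedure balances both the number of providers
and the expected number of patients per arm — the two balance goals of
the trial design.  The final block may be short; it receives a random
subset of distinct arms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ArmAssignment", "ARMS", "randomize_providers",
           "simple_randomize", "assignment_balance_report"]

ARMS = ("usual_care", "ecdss", "ecdss_plus")


@dataclass(frozen=True)
class ArmAssignment:
    provider_id: str
    arm: str
    block_index: int


def _validate(panel_sizes: dict[str, int], n_arms: int) -> None:
    if len(panel_sizes) < n_arms:
        raise ValueError(
            f"need at least {n_arms} providers, got {len(panel_sizes)}")
    for pid, size in panel_sizes.items():
        if size < 0:
            raise ValueError(f"panel size for {pid} is negative: {size}")


def randomize_providers(
    panel_sizes: dict[str, int],
    n_arms: int = 3,
    seed: int | None = None,
    arms: tuple[str, ...] = ARMS,
) -> list[ArmAssignment]:
    """Size-sorted blocked randomization; deterministic given ``seed``.

    ``panel_sizes`` maps provider_id to the provider's eligible-panel
    size.  Input order is irrelevant: the sort on (-size, provider_id)
    is canonical.
    """
    _validate(panel_sizes, n_arms)
    if len(arms) < n_arms:
        raise ValueError("not enough arm labels for n_arms")
    rng = np.random.default_rng(seed)
    order = sorted(panel_sizes, key=lambda pid: (-panel_sizes[pid], pid))
    assignments: list[ArmAssignment] = []
    for b in range(0, len(order), n_arms):
        block = order[b: b + n_arms]
        labels = [arms[i] for i in rng.permutation(n_arms)[: len(block)]]
        for pid, arm in zip(block, labels):
            assignments.append(ArmAssignment(pid, arm, b // n_arms))
    return assignments


def simple_randomize(
    panel_sizes: dict[str, int],
    n_arms: int = 3,
    seed: int | None = None,
    arms: tuple[str, ...] = ARMS,
) -> list[ArmAssignment]:
    """Unblocked equal-probability assignment (comparison baseline)."""
    _validate(panel_sizes, n_arms)
    rng = np.random.default_rng(seed)
    return [
        ArmAssignment(pid, arms[int(rng.integers(n_arms))], -1)
        for pid in sorted(panel_sizes)
    ]


def assignment_balance_report(
    assignments: list[ArmAssignment],
    panel_sizes: dict[str, int],
    arms: tuple[str, ...] = ARMS,
) -> dict:
    """Per-arm provider and patient totals plus the worst pairwise
    patient-count gap; patient totals always conserve the grand total."""
    providers = {a: 0 for a in arms}
    patients = {a: 0 for a in arms}
    for asg in assignments:
        providers[asg.arm] += 1
        patients[asg.arm] += panel_sizes[asg.provider_id]
    counts = list(patients.values())
    max_diff = max(counts) - min(counts) if counts else 0
    return {
        "providers_per_arm": providers,
        "patients_per_arm": patients,
        "total_patients": sum(counts),
        "max_pairwise_patient_diff": max_diff,
    }
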