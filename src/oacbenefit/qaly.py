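"""Utility weights and QALY accrual.

Quality-adjusted life years are accrued monthly: a patient alive at the
end of a cycle gains ``utility / 12`` QALYs, where the current utility
weight is the age-specific general-population baseline multiplied by the
utility ratio of every nonfatal event experienced so far (the
multiplicative method for joint health states).  Time alive without a
severely disabling event is accrued in parallel as ``1/12`` life years
per cycle until the first severe stroke, severe intracranial bleed, or
permanently disabling extracranial bleed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .params import EVENT_TYPES, UtilityTable

__all__ = [
    "UtilityTable",
    "UtilityState",
    "baseline_utility",
    "apply_event_utility",
    "accrue_cycle",
    "SEVERELY_DISABLING",
]

#: (event type, severity) pairs that permanently stop the
#: disability-free life-years counter.
SEVERELY_DISABLING = frozenset({
    ("ischemic_stroke", "severe"),
    ("hemorrhagic_stroke", "severe"),
    ("other_intracranial_bleed", "severe"),
    ("extracranial_bleed", "disabling"),
})


def baseline_utility(age: float, table: UtilityTable) -> float:
    """Baseline utility weight at ``age`` (step function over age bands)."""
    return float(table.baseline(age))


@dataclass
class UtilityState:
    """Current utility weight of one patient plus the ratios applied so far.

    The invariant ``weight == baseline(age) * prod(applied_ratios)`` holds
    at all times; :meth:`weight_at` evaluates it for a given age.
    """

    table: UtilityTable
    applied_ratios: list = field(default_factory=list)

    def weight_at(self, age: float) -> float:
        w = baseline_utility(age, self.table)
        for r in self.applied_ratios:
            w *= r
        return w

    @property
    def ratio_product(self) -> float:
        p = 1.0
        for r in self.applied_ratios:
            p *= r
        return p


def _event_ratio(table: UtilityTable, event_type: str, severity: str) -> float:
    if event_type not in EVENT_TYPES:
        raise KeyError(f"unknown event type {event_type!r}")
    if event_type == "extracranial_bleed":
        if severity == "disabling":
            return float(table.extracranial_disability_ratio)
        if severity == "nondisabling":
            return 1.0
        raise KeyError(f"unknown extracranial-bleed severity {severity!r}")
    if severity not in table.severity_ratios:
        raise KeyError(f"unknown severity {severity!r} for {event_type!r}")
    return float(table.severity_ratios[severity])


def apply_event_utility(
    state: UtilityState, event_type: str, severity: str
) -> UtilityState:
    """Return the utility state after a nonfatal event.

    The new weight is the old weight times the utility ratio for the
    event type and severity; repeated events compound multiplicatively,
    so the final weight is independent of event order.
    """
    if severity == "fatal":
        raise ValueError("fatal events do not update the utility state")
    ratio = _event_ratio(state.table, event_type, severity)
    return UtilityState(
        table=state.table, applied_ratios=state.applied_ratios + [ratio]
    )


def accrue_cycle(
    weight: float, alive: bool, severely_disabled: bool = False
) -> tuple[float, float]:
    """QALY and disability-free increments for one monthly cycle.

    Returns ``(qaly_increment, disability_free_increment)`` in years:
    ``weight / 12`` QALYs if alive (0 otherwise), and ``1/12``
    disability-free life years if alive and not severely disabled.
    """
    if not alive:
        return 0.0, 0.0
    return weight / 12.0, (0.0 if severely_disabled else 1.0 / 12.0)
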