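"""Materialize per-patient automated-planning constraint protocols.

A protocol is the patient-facing table of optimization constraints: one row
per organ-at-risk rule, each with a numeric bound evaluated at the patient's
RTL and rounded to the nearest integer in its display unit (% or cGy), plus
the priority/compromise metadata and the general optimizer settings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

from .errors import DomainError
from .geometry import round_half_up
from .model import ConstraintRule, GeneralSettings, KnowledgeModel

__all__ = ["ProtocolEntry", "Protocol", "materialize_protocol", "validate_protocol"]


@dataclass(frozen=True)
class ProtocolEntry:
    """One constraint row: e.g. (liver_gtv, 'V5 < 59%', high, yes)."""

    organ: str
    metric_kind: str
    dose_gy: float | None
    bound: int
    unit: str
    priority: str
    compromise: bool

    @property
    def constraint_text(self) -> str:
        if self.metric_kind == "volume_at_dose":
            return f"V{self.dose_gy:g} < {self.bound}{self.unit}"
        label = {"mean": "Mean dose", "max": "Maximum dose"}[self.metric_kind]
        return f"{label} < {self.bound} {self.unit}"


@dataclass(frozen=True)
class Protocol:
    """Per-patient constraint protocol in model rule order."""

    patient_id: str
    rtl: float
    entries: tuple[ProtocolEntry, ...]
    general_settings: GeneralSettings = field(default_factory=GeneralSettings)

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", tuple(self.entries))
        for e in self.entries:
            if e.bound <= 0:
                raise DomainError(f"non-positive bound for {e.organ}")

    def bound(self, organ: str, metric_kind: str, dose_gy: float | None = None) -> int:
        for e in self.entries:
            if (e.organ, e.metric_kind, e.dose_gy) == (organ, metric_kind, dose_gy):
                return e.bound
        raise KeyError(f"no entry for ({organ}, {metric_kind}, {dose_gy})")


def materialize_protocol(
    model: KnowledgeModel, rtl: float, patient_id: str = "anon"
) -> Protocol:
    """Evaluate every model rule at this patient's RTL and round the bounds.

    Linear rules give intercept + shift + slope·rtl rounded half-up in the
    rule's unit; constants pass through rounding unchanged in practice.  A
    rule that evaluates to <= 0 (a degenerate tiny-target geometry) is
    clipped to 1 unit with a warning rather than emitting an impossible
    non-positive bound.
    """
    if rtl <= 0:
        raise DomainError("rtl must be positive")
    entries = []
    for rule in model.rules:
        raw = rule.evaluate(rtl)
        bound = round_half_up(raw)
        if bound <= 0:
            warnings.warn(
                f"{rule.organ} {rule.metric_label} bound {raw:.3g} <= 0 at rtl={rtl:g}; "
                "clipped to 1",
                stacklevel=2,
            )
            bound = 1
        entries.append(
            ProtocolEntry(
                organ=rule.organ,
                metric_kind=rule.metric_kind,
                dose_gy=rule.dose_gy,
                bound=bound,
                unit=rule.unit,
                priority=rule.priority,
                compromise=rule.compromise,
            )
        )
    return Protocol(
        patient_id=patient_id,
        rtl=rtl,
        entries=tuple(entries),
        general_settings=model.general_settings,
    )


def validate_protocol(
    protocol: Protocol,
    tolerance_limits: Mapping[tuple[str, str], float] | None = None,
) -> list[str]:
    """Check protocol bounds against hard clinical tolerance limits.

    ``tolerance_limits`` maps (organ, metric_kind) to the maximum acceptable
    bound in the entry's own unit.  Returns a list of human-readable
    violation messages (empty when everything is within limits); never
    mutates the protocol.
    """
    if not tolerance_limits:
        return []
    violations = []
    for e in protocol.entries:
        limit = tolerance_limits.get((e.organ, e.metric_kind))
        if limit is not None and e.bound > limit:
            violations.append(
                f"{e.organ} {e.constraint_text} exceeds hard limit {limit:g} {e.unit}"
            )
    return violations
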