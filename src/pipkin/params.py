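"""Parameter sets for the GMA system and their validation.

A :class:`ParameterSet` carries everything Eq-level flux evaluation needs:
rate constants (gamma, per flux), kinetic orders (f, per flux), enzyme
activities (mg/um^2, per enzyme group), the three influx rates
(molecules um^-2 min^-1) and the shared first-order efflux rate constant
(min^-1).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

if TYPE_CHECKING:
    from .network import PathwayModel

from .network import INFLUX_IDS


@dataclass
class ParameterSet:
    gamma: dict[str, float] = field(default_factory=dict)
    f: dict[str, float] = field(default_factory=dict)
    enzyme_activity: dict[str, float] = field(default_factory=dict)
    influx_rate: dict[str, float] = field(default_factory=dict)
    efflux_rate_constant: float = 0.0

    def copy(self) -> "ParameterSet":
        return copy.deepcopy(self)

    def rate_coefficient(self, flux_id: str, model: "PathwayModel") -> float:
        """gamma * E for one interconversion (the product entering Eq. v = gamma E x^f)."""
        fl = model.flux(flux_id)
        return self.gamma[flux_id] * self.enzyme_activity[fl.enzyme]


@dataclass
class ValidationIssue:
    severity: str  # "error" | "warning"
    message: str


def validate_parameter_set(model: "PathwayModel", params: ParameterSet) -> list[ValidationIssue]:
    """Report missing entries, non-positive gammas and negative activities.

    An empty report means the set is usable.  Zero activities are reported
    as warnings only (they are legitimate in knockout contexts).
    """
    report: list[ValidationIssue] = []
    for fl in model.interconversions:
        g = params.gamma.get(fl.id)
        if g is None:
            report.append(ValidationIssue("error", f"missing gamma for {fl.id}"))
        elif g < 0:
            report.append(ValidationIssue("error", f"negative gamma for {fl.id}: {g}"))
        elif g == 0:
            report.append(ValidationIssue("warning", f"gamma for {fl.id} is zero (knocked-out flux?)"))
        if fl.id not in params.f:
            report.append(ValidationIssue("error", f"missing kinetic order f for {fl.id}"))
    for enz in model.enzymes:
        a = params.enzyme_activity.get(enz.id)
        if a is None:
            report.append(ValidationIssue("error", f"missing activity for enzyme {enz.id}"))
        elif a < 0:
            report.append(ValidationIssue("error", f"negative activity for enzyme {enz.id}: {a}"))
        elif a == 0:
            report.append(ValidationIssue("warning", f"activity of {enz.id} is zero (knockout?)"))
    for influx in INFLUX_IDS:
        r = params.influx_rate.get(influx)
        if r is None:
            report.append(ValidationIssue("error", f"missing influx rate {influx}"))
        elif r < 0:
            report.append(ValidationIssue("error", f"negative influx rate {influx}: {r}"))
    if params.efflux_rate_constant is None:
        report.append(ValidationIssue("error", "missing shared efflux rate constant"))
    elif params.efflux_rate_constant < 0:
        report.append(ValidationIssue("error", "negative shared efflux rate constant"))
    return report
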