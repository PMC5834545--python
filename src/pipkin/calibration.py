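"""Calibration surface: steady-state target intervals, the 13-phenomenon
registry, and the adjustment score.

The adjustment score is a sum of squared *relative* deviations so that
pools spanning five orders of magnitude weigh comparably: an interval
target contributes 0 inside [low, high] and ((X - bound)/bound)^2 to the
nearest bound outside; a phenomenon contributes the squared normalized
violation of its expectation.  A perfect model scores exactly 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .dynamics import SteadyState, SteadyStateError, find_steady_state
from .network import PathwayModel
from .params import ParameterSet
from .perturb import PerturbationSpec, apply, knockout_preset, spec_from_dict


@dataclass(frozen=True)
class SteadyStateTarget:
    species: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if self.low > self.high:
            raise ValueError(f"target for {self.species}: low > high")

    def deviation(self, x: float) -> float:
        """Relative distance to the nearest bound; 0 inside the interval.

        Deviations below the steady-state solver tolerance (1e-9 relative)
        are clamped to 0 so that a model meeting a point target exactly
        scores exactly zero.
        """
        if x < self.low:
            d = (x - self.low) / self.low
        elif x > self.high:
            d = (x - self.high) / self.high
        else:
            return 0.0
        return d if abs(d) > 1e-9 else 0.0


@dataclass(frozen=True)
class RankConstraint:
    greater: str
    lesser: str

    def satisfied(self, ss: SteadyState) -> bool:
        return ss[self.greater] > ss[self.lesser]


@dataclass
class Expectation:
    kind: str
    value: float = 0.0
    tolerance: float = 0.0
    low: float = 0.0
    high: float = 0.0

    def check(self, x: float, x_basal: float) -> tuple[bool, float]:
        """(pass, normalized violation). Violation is 0 when passing."""
        pct = 100.0 * x / x_basal if x_basal > 0 else math.inf
        if self.kind == "percent_of_basal":
            miss = max(0.0, abs(pct - self.value) - self.tolerance)
            return miss == 0.0, miss / 100.0
        if self.kind == "percent_max":
            miss = max(0.0, pct - self.value)
            return miss == 0.0, miss / 100.0
        if self.kind == "percent_range":
            miss = max(0.0, self.low - pct, pct - self.high)
            return miss == 0.0, miss / 100.0
        if self.kind == "abs_range":
            if x < self.low:
                return False, (self.low - x) / max(self.low, 1e-12)
            if x > self.high:
                return False, (x - self.high) / self.high
            return True, 0.0
        if self.kind == "fold_change_min":
            fold = x / x_basal if x_basal > 0 else math.inf
            miss = max(0.0, self.value - fold) / self.value
            return miss == 0.0, miss
        raise ValueError(f"unknown expectation kind {self.kind!r}")

    def describe(self) -> str:
        if self.kind == "percent_of_basal":
            return f"{self.value:g}% of basal (+-{self.tolerance:g} pp)"
        if self.kind == "percent_max":
            return f"<= {self.value:g}% of basal"
        if self.kind == "percent_range":
            return f"{self.low:g}-{self.high:g}% of basal"
        if self.kind == "abs_range":
            return f"{self.low:g}-{self.high:g} molecules/um^2"
        if self.kind == "fold_change_min":
            return f">= {self.value:g}-fold increase"
        return self.kind


@dataclass
class PhenomenonSpec:
    id: str
    perturbation: PerturbationSpec
    readout: str
    expectation: Expectation
    title: str = ""
    note: str = ""
    known_discrepancy: bool = False
    extra_checks: list[tuple[str, Expectation]] = field(default_factory=list)


@dataclass
class PhenomenonResult:
    id: str
    expected: str
    simulated_pct: float
    simulated_abs: float
    passed: bool
    violation: float
    known_discrepancy: bool = False


@dataclass
class AdjustmentScore:
    total: float
    components: dict[str, float]

    @property
    def is_perfect(self) -> bool:
        return self.total == 0.0


# ---------------------------------------------------------------------------
# registry loading
# ---------------------------------------------------------------------------

def _expectation_from_dict(d: dict) -> Expectation:
    return Expectation(kind=d["kind"], value=float(d.get("value", 0.0)),
                       tolerance=float(d.get("tolerance", 0.0)),
                       low=float(d.get("low", 0.0)), high=float(d.get("high", 0.0)))


def _perturbation_from_entry(d: dict) -> PerturbationSpec:
    if "preset" in d:
        return knockout_preset(d["preset"])
    if "compose" in d:
        spec = knockout_preset(d["compose"][0])
        for name in d["compose"][1:]:
            spec = spec.compose(knockout_preset(name))
        return spec
    return spec_from_dict(d)


def load_targets(path: Optional[str | Path] = None
                 ) -> tuple[list[SteadyStateTarget], list[RankConstraint]]:
    if path is None:
        text = resources.files("pipkin.data").joinpath("targets.yaml").read_text()
    else:
        text = Path(path).read_text()
    doc = yaml.safe_load(text)
    targets = [SteadyStateTarget(str(sp), float(iv["low"]), float(iv["high"]))
               for sp, iv in doc["intervals"].items()]
    ranks = []
    for entry in doc.get("rank_constraints", []):
        a, b = [s.strip() for s in entry.split(">")]
        ranks.append(RankConstraint(a, b))
    return targets, ranks


def load_phenomena(path: Optional[str | Path] = None) -> list[PhenomenonSpec]:
    if path is None:
        text = resources.files("pipkin.data").joinpath("phenomena.yaml").read_text()
    else:
        text = Path(path).read_text()
    doc = yaml.safe_load(text)
    registry = []
    for d in doc:
        extra = [(str(e["readout"]), _expectation_from_dict(e["expectation"]))
                 for e in d.get("extra_checks", [])]
        registry.append(PhenomenonSpec(
            id=d["id"],
            perturbation=_perturbation_from_entry(d["perturbation"]),
            readout=str(d["readout"]),
            expectation=_expectation_from_dict(d["expectation"]),
            title=d.get("title", ""), note=d.get("note", ""),
            known_discrepancy=bool(d.get("known_discrepancy", False)),
            extra_checks=extra,
        ))
    return registry


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def run_phenomena_suite(model: PathwayModel, params: ParameterSet,
                        registry: Optional[list[PhenomenonSpec]] = None,
                        basal: Optional[SteadyState] = None
                        ) -> tuple[list[PhenomenonResult], int]:
    """Evaluate each phenomenon; returns (results, number passing).

    Results are a pure function of the parameter set and registry: each
    entry simulates its perturbed steady state against the same basal
    reference, so the outcome is order-independent.
    """
    if registry is None:
        registry = load_phenomena()
    if basal is None:
        basal = find_steady_state(model, params)
    results = []
    for ph in registry:
        perturbed = apply(params, ph.perturbation, model)
        try:
            ss = find_steady_state(model, perturbed, x0=basal.abundances)
        except SteadyStateError:
            results.append(PhenomenonResult(ph.id, ph.expectation.describe(),
                                            math.nan, math.nan, False, math.inf,
                                            ph.known_discrepancy))
            continue
        x, xb = ss[ph.readout], basal[ph.readout]
        ok, viol = ph.expectation.check(x, xb)
        for sp, exp in ph.extra_checks:
            ok2, viol2 = exp.check(ss[sp], basal[sp])
            ok, viol = ok and ok2, viol + viol2
        results.append(PhenomenonResult(
            ph.id, ph.expectation.describe(),
            100.0 * x / xb if xb > 0 else math.nan, x, ok, viol,
            ph.known_discrepancy))
    return results, sum(r.passed for r in results)


def adjustment_score(model: PathwayModel, params: ParameterSet,
                     targets: Optional[list[SteadyStateTarget]] = None,
                     phenomena: Optional[list[PhenomenonSpec]] = None,
                     basal: Optional[SteadyState] = None) -> AdjustmentScore:
    """Sum of squared relative deviations from all calibration targets."""
    if targets is None:
        targets, _ = load_targets()
    if phenomena is None:
        phenomena = load_phenomena()
    components: dict[str, float] = {}
    try:
        if basal is None:
            basal = find_steady_state(model, params)
    except SteadyStateError as exc:
        return AdjustmentScore(math.inf, {"steady_state_failure": math.inf,
                                          "diagnostic_residual": exc.residual or math.nan})
    for tgt in targets:
        components[f"pool:{tgt.species}"] = tgt.deviation(basal[tgt.species]) ** 2
    if phenomena:
        results, _ = run_phenomena_suite(model, params, phenomena, basal=basal)
        for r in results:
            components[f"phenomenon:{r.id}"] = (
                math.inf if math.isinf(r.violation) else r.violation ** 2)
    total = float(sum(components.values()))
    return AdjustmentScore(total, components)


def suite_report(results: list[PhenomenonResult]):
    """Tabular (pandas) view of a phenomena run: id, expected, simulated, pass."""
    import pandas as pd
    return pd.DataFrame([{
        "phenomenon": r.id, "expected": r.expected,
        "simulated_pct_of_basal": r.simulated_pct, "simulated_abs": r.simulated_abs,
        "passed": r.passed, "known_discrepancy": r.known_discrepancy,
    } for r in results])
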