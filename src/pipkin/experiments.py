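"""Scripted, parameter-free reproductions of the perturbation experiments.

Every experiment applies a registered perturbation preset to the reference
parameter set, finds the new steady state and reports each pool as a
percentage of the basal steady state (all comparisons are between steady
states, not transients).  The unperturbed control of any experiment is
therefore 100% across all readouts by construction.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .dynamics import SteadyState, find_steady_state
from .network import SPECIES_ORDER, PathwayModel, load_network
from .params import ParameterSet
from .perturb import PerturbationSpec, apply, knockout_preset


@dataclass
class ExperimentResult:
    experiment_id: str
    label: str
    readouts_pct: dict[str, float]          # species -> % of basal
    readouts_abs: dict[str, float]          # species -> molecules/um^2
    provenance: dict = field(default_factory=dict)
    extras: dict[str, float] = field(default_factory=dict)

    def pct(self, species: str) -> float:
        return self.readouts_pct[species]

    def abs(self, species: str) -> float:
        return self.readouts_abs[species]


class ExperimentRunner:
    """Shared machinery: one basal steady state, many perturbed ones."""

    def __init__(self, params: Optional[ParameterSet] = None,
                 model: Optional[PathwayModel] = None):
        from .synthetic import reference_fixture
        self.model = model or load_network()
        self.params = params or reference_fixture()
        self.basal = find_steady_state(self.model, self.params)
        digest = hashlib.sha256(json.dumps(
            {"gamma": self.params.gamma, "f": self.params.f,
             "E": self.params.enzyme_activity, "influx": self.params.influx_rate,
             "k_eff": self.params.efflux_rate_constant},
            sort_keys=True).encode()).hexdigest()[:16]
        self._provenance = {"params_hash": digest, "ss_tolerance": 1e-9}

    def run(self, experiment_id: str, spec: PerturbationSpec) -> ExperimentResult:
        perturbed = apply(self.params, spec, self.model)
        ss = find_steady_state(self.model, perturbed, x0=self.basal.abundances)
        return self._result(experiment_id, spec.label, ss)

    def _result(self, experiment_id: str, label: str, ss: SteadyState) -> ExperimentResult:
        pct = {sp: 100.0 * ss[sp] / self.basal[sp] for sp in SPECIES_ORDER}
        return ExperimentResult(
            experiment_id=experiment_id, label=label,
            readouts_pct=pct, readouts_abs=ss.as_dict(),
            provenance=dict(self._provenance))


# ---------------------------------------------------------------------------
# named experiments
# ---------------------------------------------------------------------------

def run_source_decomposition(runner: Optional[ExperimentRunner] = None
                             ) -> dict[str, ExperimentResult]:
    """Stop all inputs into PI(4)P and PI(4,5)P2, then re-activate them one
    at a time to test which can restore PI(4,5)P2.

    The blocked baseline keeps gamma_0->4 at 20% (instead of 0) so PI(4)P
    stays numerically away from zero.  The ``v->4`` entry carries two
    readings of its PI(4,5)P2 effect in ``extras``: percent of basal and
    percentage-point gain over the all-blocked baseline.
    """
    runner = runner or ExperimentRunner()
    names = {
        "blocked": "fig3b_block_all_PI45P2_inputs",
        "v0->45": "fig3b_only_v0_45",
        "v5->45": "fig3b_only_v5_45",
        "v->4": "fig3b_only_v_4",
        "v345->45": "fig3b_only_v345_45",
    }
    out = {key: runner.run(f"source_decomposition:{key}", knockout_preset(preset))
           for key, preset in names.items()}
    baseline = out["blocked"].readouts_pct["45"]
    for key, res in out.items():
        res.extras["pip2_gain_over_blocked_pp"] = res.readouts_pct["45"] - baseline
    return out


def run_pi5p_channeling(scale_v3: float,
                        runner: Optional[ExperimentRunner] = None) -> ExperimentResult:
    """PI(5)P route with boosted endosomal PI(3)P influx: v5->45 as the only
    direct PI(4,5)P2 source while v->3 is scaled by ``scale_v3``."""
    if scale_v3 <= 0:
        raise ValueError("scale_v3 must be positive")
    runner = runner or ExperimentRunner()
    spec = knockout_preset("pi5p_channeling", scale=scale_v3)
    return runner.run(f"pi5p_channeling:x{scale_v3:g}", spec)


def run_membrane_polarity(config: str, v345_34_mode: str = "slow",
                          pten_knockdown: Optional[float] = None,
                          runner: Optional[ExperimentRunner] = None) -> ExperimentResult:
    """Apical / basolateral membrane configuration, with slow or fast
    v345->34 and an optional PTEN knockdown fraction (e.g. 0.9833)."""
    if config not in ("apical", "basolateral"):
        raise ValueError("config must be 'apical' or 'basolateral'")
    if v345_34_mode not in ("slow", "fast"):
        raise ValueError("v345_34_mode must be 'slow' or 'fast'")
    runner = runner or ExperimentRunner()
    spec = knockout_preset(config).compose(knockout_preset(f"ship_{v345_34_mode}"))
    exp_id = f"membrane_polarity:{config}:{v345_34_mode}"
    if pten_knockdown is not None:
        spec = spec.compose(PerturbationSpec(
            enzyme_scales={"PTEN": 1.0 - pten_knockdown},
            label=f"PTEN knockdown {100 * pten_knockdown:g}%"))
        exp_id += f":pten_kd{100 * pten_knockdown:g}"
    return runner.run(exp_id, spec)


SIRNA_PANEL = ("pip5ki_ko", "pi4k_ko", "complex_ko", "sioss_up", "pip5kii_ko",
               "synj_tmem55_up", "pi3ki_ko", "pi3kii_ko")


def run_sirna_panel(upregulation_factor: float = 2.0,
                    runner: Optional[ExperimentRunner] = None,
                    tolerance_pp: float = 5.0
                    ) -> tuple[dict[str, ExperimentResult], pd.DataFrame]:
    """siRNA screen surrogate: kinases knocked out one at a time,
    phosphatases upregulated (default factor 2).

    The classification table predicts the ENaC direction from PI(4,5)P2:
    'down' if it falls more than ``tolerance_pp`` percentage points below
    basal, 'up' if it rises as much, else 'unchanged'.
    """
    runner = runner or ExperimentRunner()
    results = {}
    for name in SIRNA_PANEL:
        if name.endswith("_up"):
            spec = knockout_preset(name, factor=upregulation_factor)
        else:
            spec = knockout_preset(name)
        results[name] = runner.run(f"sirna:{name}", spec)
    rows = []
    for name, res in results.items():
        pip2 = res.readouts_pct["45"]
        if pip2 < 100.0 - tolerance_pp:
            direction = "down"
        elif pip2 > 100.0 + tolerance_pp:
            direction = "up"
        else:
            direction = "unchanged"
        rows.append({"perturbation": name, "label": res.label,
                     "PI(4,5)P2_pct": pip2, "PI(3,4)P2_pct": res.readouts_pct["34"],
                     "predicted_ENaC": direction})
    return results, pd.DataFrame(rows)


PI_DROP_MODES = ("gamma0_only", "plus_closed_transports", "full_50pct")


def run_pi_drop(mode: str, runner: Optional[ExperimentRunner] = None) -> ExperimentResult:
    """PI-supply reduction scenarios: halve v->0; additionally close v->4
    and v->3; or drive v->0 to 2% with both transports closed."""
    presets = {"gamma0_only": "pi_influx_half",
               "plus_closed_transports": "pi_drop_closed_transports",
               "full_50pct": "pi_drop_full_50pct"}
    if mode not in presets:
        raise ValueError(f"mode must be one of {PI_DROP_MODES}")
    runner = runner or ExperimentRunner()
    return runner.run(f"pi_drop:{mode}", knockout_preset(presets[mode]))


# ---------------------------------------------------------------------------
# figure-level reproduction
# ---------------------------------------------------------------------------

def _tidy(results: dict[str, ExperimentResult], readouts: tuple[str, ...]) -> pd.DataFrame:
    rows = []
    for key, res in results.items():
        for sp in readouts:
            rows.append({"experiment": res.experiment_id, "perturbation": key,
                         "species": sp, "pct_of_basal": res.readouts_pct[sp],
                         "abundance": res.readouts_abs[sp]})
    return pd.DataFrame(rows)


def reproduce(figure: str, runner: Optional[ExperimentRunner] = None) -> pd.DataFrame:
    """One tidy table per figure-level experiment suite.

    Known suites: '3a' (PI / PI4K / PIP5KI perturbations), '3b' (source
    decomposition), '3c' (small-pool perturbations), '3d' (Golgi PI(4)P
    influx), '6' (membrane polarity), '7' (siRNA panel).
    """
    runner = runner or ExperimentRunner()
    if figure == "3a":
        res = {
            "gamma->0@50%": runner.run("3a:pi_half", knockout_preset("pi_influx_half")),
            "PI4K_ko": runner.run("3a:pi4k", knockout_preset("pi4k_ko")),
            "PIP5KI@50%": runner.run("3a:pip5ki_half", knockout_preset("pip5ki_half")),
        }
        return _tidy(res, ("0", "4", "45"))
    if figure == "3b":
        return _tidy(run_source_decomposition(runner), ("4", "45"))
    if figure == "3c":
        res = {
            "MTMR@65%": runner.run("3c:mtmr", knockout_preset("mtmr_65")),
            "SYNJ_TMEM55x2": runner.run("3c:synj", knockout_preset("synj_tmem55_x2")),
            "PIKfyve_ko": runner.run("3c:pikfyve", knockout_preset("pikfyve_ko")),
        }
        return _tidy(res, ("3", "5", "35"))
    if figure == "3d":
        res = {
            "v->4@0": runner.run("3d:closed", PerturbationSpec(
                influx_scales={"v->4": 0.0}, label="v->4 closed")),
            "v->4@200%": runner.run("3d:doubled", PerturbationSpec(
                influx_scales={"v->4": 2.0}, label="v->4 doubled")),
        }
        return _tidy(res, ("4", "45"))
    if figure == "6":
        res = {}
        for config in ("apical", "basolateral"):
            for mode in ("slow", "fast"):
                res[f"{config}:{mode}"] = run_membrane_polarity(config, mode, runner=runner)
                res[f"{config}:{mode}:pten_kd"] = run_membrane_polarity(
                    config, mode, pten_knockdown=0.9833, runner=runner)
        return _tidy(res, ("345", "45", "34"))
    if figure == "7":
        _, table = run_sirna_panel(runner=runner)
        return table
    raise ValueError(f"unknown figure suite {figure!r}")
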