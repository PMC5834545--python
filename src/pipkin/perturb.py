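"""Declarative perturbations: knockouts, knockdowns, overexpression, blocking.

A :class:`PerturbationSpec` is a pure description; :func:`apply` turns a
parameter set into a new one.  Conventions:

* scaling an enzyme group scales *every* flux it catalyses, and scaling a
  component of a protein complex also scales the complex (knocking out
  PI4K or PIP5KI therefore removes the PI4K+PIP5KI+DVL flux v0->45, while
  knocking out only the complex leaves v0->4 and v4->45 intact);
* a knockout is a scale of 0 on the enzyme activity, equivalent to zeroing
  gamma because the flux is linear in E;
* absolute overrides (enzyme activities, gammas, kinetic orders) express
  presets stated as absolute values, e.g. the apical/basolateral membrane
  configurations and the slow/fast v345->34 variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Optional

import yaml

from .network import PathwayModel
from .params import ParameterSet


@dataclass(frozen=True)
class PerturbationSpec:
    enzyme_scales: dict[str, float] = field(default_factory=dict)
    gamma_scales: dict[str, float] = field(default_factory=dict)
    influx_scales: dict[str, float] = field(default_factory=dict)
    enzyme_overrides: dict[str, float] = field(default_factory=dict)
    gamma_overrides: dict[str, float] = field(default_factory=dict)
    f_overrides: dict[str, float] = field(default_factory=dict)
    label: str = ""

    def __post_init__(self) -> None:
        for d in (self.enzyme_scales, self.gamma_scales, self.influx_scales):
            for key, s in d.items():
                if s < 0:
                    raise ValueError(f"negative scale for {key}")

    def compose(self, other: "PerturbationSpec") -> "PerturbationSpec":
        """Composition multiplies scales; overrides of ``other`` win."""
        def _mul(a: dict[str, float], b: dict[str, float]) -> dict[str, float]:
            out = dict(a)
            for k, v in b.items():
                out[k] = out.get(k, 1.0) * v
            return out

        return PerturbationSpec(
            enzyme_scales=_mul(self.enzyme_scales, other.enzyme_scales),
            gamma_scales=_mul(self.gamma_scales, other.gamma_scales),
            influx_scales=_mul(self.influx_scales, other.influx_scales),
            enzyme_overrides={**self.enzyme_overrides, **other.enzyme_overrides},
            gamma_overrides={**self.gamma_overrides, **other.gamma_overrides},
            f_overrides={**self.f_overrides, **other.f_overrides},
            label=(self.label + " + " + other.label).strip(" +"),
        )

    @property
    def is_identity(self) -> bool:
        return (all(v == 1 for v in self.enzyme_scales.values())
                and all(v == 1 for v in self.gamma_scales.values())
                and all(v == 1 for v in self.influx_scales.values())
                and not self.enzyme_overrides and not self.gamma_overrides
                and not self.f_overrides)


identity = PerturbationSpec(label="identity")


def apply(params: ParameterSet, spec: PerturbationSpec,
          model: Optional[PathwayModel] = None) -> ParameterSet:
    """Return a new parameter set with the perturbation applied.

    ``model`` is needed to propagate component scaling into complexes; if
    omitted, enzyme scales act only on the named group.
    """
    new = params.copy()
    # absolute overrides first ("configure"), then scales ("perturb"), so a
    # knockout composed onto a configuration preset is not overwritten
    for enz, value in spec.enzyme_overrides.items():
        if enz not in new.enzyme_activity:
            raise KeyError(f"unknown enzyme {enz!r}")
        new.enzyme_activity[enz] = value
    for flux, value in spec.gamma_overrides.items():
        if flux not in new.gamma:
            raise KeyError(f"unknown flux {flux!r}")
        new.gamma[flux] = value
    for flux, value in spec.f_overrides.items():
        if flux not in new.f:
            raise KeyError(f"unknown flux {flux!r}")
        new.f[flux] = value
    # enzyme scaling, with complex propagation
    effective: dict[str, float] = {}
    for enz, s in spec.enzyme_scales.items():
        if enz not in new.enzyme_activity:
            raise KeyError(f"unknown enzyme {enz!r}")
        effective[enz] = effective.get(enz, 1.0) * s
        if model is not None:
            for grp in model.enzymes:
                if grp.contains(enz):
                    effective[grp.id] = effective.get(grp.id, 1.0) * s
    for enz, s in effective.items():
        new.enzyme_activity[enz] *= s
    for flux, s in spec.gamma_scales.items():
        if flux not in new.gamma:
            raise KeyError(f"unknown flux {flux!r}")
        new.gamma[flux] *= s
    for influx, s in spec.influx_scales.items():
        if influx not in new.influx_rate:
            raise KeyError(f"unknown influx {influx!r}")
        new.influx_rate[influx] *= s
    return new


# ---------------------------------------------------------------------------
# preset registry
# ---------------------------------------------------------------------------

_REGISTRY: dict[str, PerturbationSpec] | None = None


def _load_registry() -> dict[str, PerturbationSpec]:
    global _REGISTRY
    if _REGISTRY is None:
        text = resources.files("pipkin.data").joinpath("presets.yaml").read_text()
        doc = yaml.safe_load(text)
        _REGISTRY = {name: spec_from_dict(d, label=name) for name, d in doc.items()}
    return _REGISTRY


def spec_from_dict(d: dict, label: str = "") -> PerturbationSpec:
    return PerturbationSpec(
        enzyme_scales={k: float(v) for k, v in (d.get("enzyme_scales") or {}).items()},
        gamma_scales={k: float(v) for k, v in (d.get("gamma_scales") or {}).items()},
        influx_scales={k: float(v) for k, v in (d.get("influx_scales") or {}).items()},
        enzyme_overrides={k: float(v) for k, v in (d.get("enzyme_overrides") or {}).items()},
        gamma_overrides={k: float(v) for k, v in (d.get("gamma_overrides") or {}).items()},
        f_overrides={k: float(v) for k, v in (d.get("f_overrides") or {}).items()},
        label=d.get("label", label),
    )


def load_spec(path: str | Path) -> PerturbationSpec:
    """Read a perturbation spec from a YAML/JSON file."""
    doc = yaml.safe_load(Path(path).read_text())
    return spec_from_dict(doc, label=str(path))


def preset_names() -> list[str]:
    return sorted(_load_registry())


def knockout_preset(name: str, **kwargs: float) -> PerturbationSpec:
    """Look up a named preset from the registry shipped with the package.

    ``kwargs`` tune parametric presets: ``factor`` for the phosphatase
    upregulation presets (default 2), ``scale`` for the PI(5)P-channelling
    v->3 boost.
    """
    registry = _load_registry()
    if name == "synj_tmem55_up":
        factor = float(kwargs.get("factor", 2.0))
        return PerturbationSpec(enzyme_scales={"SYNJ_TMEM55": factor},
                                label=f"SYNJ/TMEM55 x{factor:g}")
    if name == "sioss_up":
        factor = float(kwargs.get("factor", 2.0))
        return PerturbationSpec(enzyme_scales={"SIOSS": factor}, label=f"SIOSS x{factor:g}")
    if name == "pi5p_channeling":
        scale = float(kwargs.get("scale", 25.0))
        base = registry["fig3b_only_v5_45"]
        return base.compose(PerturbationSpec(influx_scales={"v->3": scale},
                                             label=f"v->3 x{scale:g}"))
    if name not in registry:
        raise KeyError(f"unknown preset {name!r}; known: {preset_names()}")
    return registry[name]
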