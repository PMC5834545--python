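"""Pathway structure: species, fluxes, enzyme groups.

The network is defined as data (a YAML file shipped with the package) and
loaded into a validated :class:`PathwayModel`.  Structural expectations for
the plasma-membrane phosphoinositide map are enforced at load time: 8
species, 21 enzymatic interconversions, 3 influxes and 8 first-order
effluxes sharing one rate constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

import networkx as nx
import yaml

SPECIES_ORDER = ("0", "3", "4", "5", "34", "35", "45", "345")

#: number of species / interconversions / influxes / effluxes in the map
EXPECTED_COUNTS = (8, 21, 3, 8)

INFLUX_IDS = ("v->0", "v->4", "v->3")


class NetworkError(ValueError):
    """Structural problem in a network definition."""


@dataclass(frozen=True)
class Species:
    id: str
    name: str
    basal_abundance: float = 0.0

    def __post_init__(self) -> None:
        if self.basal_abundance < 0:
            raise NetworkError(f"species {self.id}: negative basal abundance")


@dataclass(frozen=True)
class EnzymeGroup:
    """A group of enzymes catalysing one or more fluxes.

    ``components`` lists member enzymes of a protein complex; perturbing a
    component propagates to the complex (see :mod:`pipkin.perturb`).
    """

    id: str
    components: tuple[str, ...] = ()

    def contains(self, enzyme_id: str) -> bool:
        return enzyme_id in self.components


@dataclass(frozen=True)
class FluxDef:
    id: str
    kind: str  # phosphorylation | hydrolysis | influx | efflux
    substrate: Optional[str] = None
    product: Optional[str] = None
    enzyme: Optional[str] = None
    gamma: Optional[float] = None
    f: Optional[float] = None

    @property
    def is_interconversion(self) -> bool:
        return self.kind in ("phosphorylation", "hydrolysis")


@dataclass
class PathwayModel:
    species: list[Species]
    fluxes: list[FluxDef]
    enzymes: list[EnzymeGroup]
    time_unit: str = "minute"
    _species_index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._species_index = {s.id: i for i, s in enumerate(self.species)}

    # -- lookups ---------------------------------------------------------
    def species_index(self, species_id: str) -> int:
        return self._species_index[species_id]

    def flux(self, flux_id: str) -> FluxDef:
        for fl in self.fluxes:
            if fl.id == flux_id:
                return fl
        raise KeyError(flux_id)

    def enzyme(self, enzyme_id: str) -> EnzymeGroup:
        for e in self.enzymes:
            if e.id == enzyme_id:
                return e
        raise KeyError(enzyme_id)

    @property
    def interconversions(self) -> list[FluxDef]:
        return [fl for fl in self.fluxes if fl.is_interconversion]

    @property
    def influxes(self) -> list[FluxDef]:
        return [fl for fl in self.fluxes if fl.kind == "influx"]

    @property
    def effluxes(self) -> list[FluxDef]:
        return [fl for fl in self.fluxes if fl.kind == "efflux"]

    def member_fluxes(self, enzyme_id: str) -> set[str]:
        """All interconversions an enzyme drives, directly or via a complex.

        PI4K therefore is a member of both v0->4 (direct) and v0->45
        (through the PI4K+PIP5KI+DVL complex).
        """
        direct = {fl.id for fl in self.interconversions if fl.enzyme == enzyme_id}
        via_complex = {
            fl.id
            for fl in self.interconversions
            if fl.enzyme is not None and self.enzyme(fl.enzyme).contains(enzyme_id)
        }
        return direct | via_complex

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        ids = [s.id for s in self.species]
        if len(set(ids)) != len(ids):
            raise NetworkError("duplicate species ids")
        n_sp = len(self.species)
        n_ic = len(self.interconversions)
        n_in = len(self.influxes)
        n_ef = len(self.effluxes)
        if (n_sp, n_ic, n_in, n_ef) != EXPECTED_COUNTS:
            raise NetworkError(
                "structural count mismatch: got "
                f"{n_sp} species, {n_ic} interconversions, {n_in} influxes, "
                f"{n_ef} effluxes; expected {EXPECTED_COUNTS}. "
                f"Interconversions present: {sorted(fl.id for fl in self.interconversions)}"
            )
        enzyme_ids = {e.id for e in self.enzymes}
        for fl in self.fluxes:
            for sp in (fl.substrate, fl.product):
                if sp is not None and sp not in self._species_index:
                    raise NetworkError(f"flux {fl.id}: unknown species {sp!r}")
            if fl.is_interconversion:
                if fl.substrate is None or fl.product is None:
                    raise NetworkError(f"flux {fl.id}: interconversion needs substrate and product")
                if fl.enzyme is None or fl.enzyme not in enzyme_ids:
                    raise NetworkError(f"flux {fl.id}: missing or unknown enzyme {fl.enzyme!r}")
            elif fl.kind == "influx":
                if fl.product is None:
                    raise NetworkError(f"influx {fl.id}: needs a product species")
            elif fl.kind == "efflux":
                if fl.substrate is None:
                    raise NetworkError(f"efflux {fl.id}: needs a substrate species")
                if fl.f is not None and fl.f != 1:
                    raise NetworkError(
                        f"efflux {fl.id}: effluxes are first order (f = 1), got f = {fl.f}"
                    )
            else:
                raise NetworkError(f"flux {fl.id}: unknown kind {fl.kind!r}")
        for e in self.enzymes:
            for comp in e.components:
                if comp not in enzyme_ids:
                    raise NetworkError(f"enzyme {e.id}: unknown complex component {comp!r}")
        # the interconversion graph must connect all 8 species
        g = nx.Graph()
        g.add_nodes_from(ids)
        for fl in self.interconversions:
            g.add_edge(fl.substrate, fl.product)
        if not nx.is_connected(g):
            raise NetworkError("interconversion graph is not connected over the species")

    # -- (de)serialization ----------------------------------------------
    def to_dict(self) -> dict:
        def _flux(fl: FluxDef) -> dict:
            d: dict = {"id": fl.id, "kind": fl.kind}
            if fl.substrate is not None:
                d["substrate"] = fl.substrate
            if fl.product is not None:
                d["product"] = fl.product
            if fl.enzyme is not None:
                d["enzyme"] = fl.enzyme
            if fl.gamma is not None:
                d["gamma"] = fl.gamma
            if fl.f is not None:
                d["f"] = fl.f
            return d

        return {
            "time_unit": self.time_unit,
            "species": [
                {"id": s.id, "name": s.name, "basal_abundance": s.basal_abundance}
                for s in self.species
            ],
            "enzymes": [
                {"id": e.id, **({"components": list(e.components)} if e.components else {})}
                for e in self.enzymes
            ],
            "fluxes": [_flux(fl) for fl in self.fluxes],
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def _model_from_dict(doc: dict) -> PathwayModel:
    try:
        species = [Species(str(d["id"]), d["name"], float(d.get("basal_abundance", 0.0)))
                   for d in doc["species"]]
        enzymes = [EnzymeGroup(d["id"], tuple(d.get("components", ()))) for d in doc["enzymes"]]
        fluxes = []
        for d in doc["fluxes"]:
            fluxes.append(
                FluxDef(
                    id=d["id"],
                    kind=d["kind"],
                    substrate=str(d["substrate"]) if "substrate" in d else None,
                    product=str(d["product"]) if "product" in d else None,
                    enzyme=d.get("enzyme"),
                    gamma=float(d["gamma"]) if "gamma" in d else None,
                    f=float(d["f"]) if "f" in d else None,
                )
            )
    except (KeyError, TypeError) as exc:
        raise NetworkError(f"malformed network definition: {exc!r}") from exc
    model = PathwayModel(species, fluxes, enzymes, doc.get("time_unit", "minute"))
    model.validate()
    return model


def load_network(path: Optional[str | Path] = None) -> PathwayModel:
    """Load and validate a network definition (default: the shipped map)."""
    if path is None:
        text = resources.files("pipkin.data").joinpath("network.yaml").read_text()
    else:
        text = Path(path).read_text()
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise NetworkError(f"cannot parse network file: {exc}") from exc
    if not isinstance(doc, dict):
        raise NetworkError("network file does not contain a mapping")
    return _model_from_dict(doc)
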