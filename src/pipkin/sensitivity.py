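"""Steady-state relative sensitivities and the high-sensitivity network.

For every parameter p (rate constants, kinetic orders, enzyme activities,
transport rates) and every pool X_i*, the logarithmic gain

    S[i, p] = (dX_i*/X_i*) / (dp/p)

is estimated by central finite differences around the reference steady
state, the standard local-sensitivity convention of Biochemical Systems
Theory.  Entries whose perturbed steady state cannot be found are flagged
(NaN), never silently zeroed.  Optionally every entry is recomputed at
delta/2 and flagged when the two estimates disagree by more than 20%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd

from .dynamics import CompiledSystem, SteadyStateError
from .network import INFLUX_IDS, SPECIES_ORDER, PathwayModel
from .params import ParameterSet

#: parameter handle syntax: "gamma:v0->4", "f:v0->4", "E:PI4K",
#: "influx:v->0", "k_eff"
ParamHandle = str


def parameter_handles(model: PathwayModel) -> list[ParamHandle]:
    handles = [f"gamma:{fl.id}" for fl in model.interconversions]
    handles += [f"f:{fl.id}" for fl in model.interconversions]
    handles += [f"E:{e.id}" for e in model.enzymes]
    handles += [f"influx:{i}" for i in INFLUX_IDS]
    handles.append("k_eff")
    return handles


def get_param(params: ParameterSet, handle: ParamHandle) -> float:
    kind, _, key = handle.partition(":")
    if kind == "gamma":
        return params.gamma[key]
    if kind == "f":
        return params.f[key]
    if kind == "E":
        return params.enzyme_activity[key]
    if kind == "influx":
        return params.influx_rate[key]
    if handle == "k_eff":
        return params.efflux_rate_constant
    raise KeyError(handle)


def set_param(params: ParameterSet, handle: ParamHandle, value: float) -> None:
    kind, _, key = handle.partition(":")
    if kind == "gamma":
        params.gamma[key] = value
    elif kind == "f":
        params.f[key] = value
    elif kind == "E":
        params.enzyme_activity[key] = value
    elif kind == "influx":
        params.influx_rate[key] = value
    elif handle == "k_eff":
        params.efflux_rate_constant = value
    else:
        raise KeyError(handle)


@dataclass
class SensitivityMatrix:
    values: pd.DataFrame          # rows: species, columns: parameter handles
    delta: float
    flagged: set[str] = field(default_factory=set)

    def entry(self, species: str, handle: ParamHandle) -> float:
        return float(self.values.loc[species, handle])

    def to_csv(self, path: str | Path) -> None:
        self.values.to_csv(path, float_format="%.6e")


def _steady(model: PathwayModel, params: ParameterSet, x0: np.ndarray) -> np.ndarray:
    return CompiledSystem.compile(model, params).solve_steady(x0)


def sensitivity_matrix(model: PathwayModel, params: ParameterSet,
                       delta: float = 0.01,
                       handles: Optional[list[ParamHandle]] = None,
                       consistency_check: bool = False) -> SensitivityMatrix:
    """Central-difference relative sensitivities of all pools to all parameters."""
    if handles is None:
        handles = parameter_handles(model)
    x_ref = _steady(model, params, np.array([max(s.basal_abundance, 1.0)
                                             for s in model.species]))
    flagged: set[str] = set()

    def column(h: ParamHandle, d: float) -> np.ndarray:
        p0 = get_param(params, h)
        if p0 == 0.0:
            return np.zeros(len(x_ref))  # a zeroed parameter has no relative gain
        cols = []
        for sign in (+1.0, -1.0):
            p = params.copy()
            set_param(p, h, p0 * (1.0 + sign * d))
            try:
                cols.append(_steady(model, p, x_ref))
            except SteadyStateError:
                flagged.add(h)
                return np.full(len(x_ref), np.nan)
        return (cols[0] - cols[1]) / (2.0 * d * x_ref)

    data = {}
    for h in handles:
        col = column(h, delta)
        if consistency_check and np.all(np.isfinite(col)):
            col_half = column(h, delta / 2.0)
            with np.errstate(invalid="ignore", divide="ignore"):
                denom = np.maximum(np.abs(col), np.abs(col_half))
                rel = np.abs(col - col_half) / np.where(denom > 1e-6, denom, np.inf)
            if np.any(rel > 0.20):
                flagged.add(h)
        data[h] = col
    values = pd.DataFrame(data, index=[s.id for s in model.species])
    return SensitivityMatrix(values=values, delta=delta, flagged=flagged)


# ---------------------------------------------------------------------------
# high-sensitivity network
# ---------------------------------------------------------------------------

def high_sensitivity_network(S: SensitivityMatrix, threshold: float = 1.0) -> nx.DiGraph:
    """Directed bipartite graph parameter -> species for entries |S| > threshold."""
    g = nx.DiGraph()
    for species in S.values.index:
        for handle in S.values.columns:
            s = S.values.loc[species, handle]
            if np.isfinite(s) and abs(s) > threshold:
                g.add_node(handle, kind="parameter")
                g.add_node(species, kind="species")
                g.add_edge(handle, species, weight=abs(float(s)),
                           sign=int(np.sign(s)), sensitivity=float(s))
    return g


def species_clusters(g: nx.DiGraph) -> list[set[str]]:
    """Species groups: connected components of the bipartite graph,
    projected onto species nodes (no community detection)."""
    comps = nx.connected_components(g.to_undirected())
    clusters = []
    for comp in comps:
        species = {n for n in comp if g.nodes[n].get("kind") == "species"}
        if species:
            clusters.append(species)
    return clusters


def edge_list(g: nx.DiGraph) -> pd.DataFrame:
    rows = [{"parameter": u, "species": v, "sensitivity": d["sensitivity"],
             "weight": d["weight"], "sign": d["sign"]}
            for u, v, d in g.edges(data=True)]
    return pd.DataFrame(rows, columns=["parameter", "species", "sensitivity",
                                       "weight", "sign"])


def write_graphml(g: nx.DiGraph, path: str | Path) -> None:
    nx.write_graphml(g, str(path))
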