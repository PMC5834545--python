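"""Reading and writing parameter tables, steady states and trajectories.

The parameter table is a CSV with columns
``flux_id, kind, gamma, f, enzyme_id, enzyme_activity`` — one row per
interconversion, one per influx (rate stored in the ``gamma`` column) and
a single shared efflux row (``flux_id = "v->"``).  Numbers are serialized
with 12 significant digits so that write -> read round-trips are stable in
practice.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .dynamics import SteadyState, Trajectory
from .network import INFLUX_IDS, PathwayModel
from .params import ParameterSet

EFFLUX_ROW_ID = "v->"


def _fmt(x: float) -> str:
    return f"{x:.12e}"


def write_params_csv(params: ParameterSet, model: PathwayModel, path: str | Path) -> None:
    rows = []
    for fl in model.interconversions:
        rows.append({
            "flux_id": fl.id, "kind": fl.kind,
            "gamma": _fmt(params.gamma[fl.id]), "f": _fmt(params.f[fl.id]),
            "enzyme_id": fl.enzyme, "enzyme_activity": _fmt(params.enzyme_activity[fl.enzyme]),
        })
    for influx in INFLUX_IDS:
        rows.append({"flux_id": influx, "kind": "influx",
                     "gamma": _fmt(params.influx_rate[influx]), "f": "",
                     "enzyme_id": "", "enzyme_activity": ""})
    rows.append({"flux_id": EFFLUX_ROW_ID, "kind": "efflux",
                 "gamma": _fmt(params.efflux_rate_constant), "f": _fmt(1.0),
                 "enzyme_id": "", "enzyme_activity": ""})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_params_csv(path: str | Path) -> ParameterSet:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    params = ParameterSet()
    for _, row in df.iterrows():
        fid, kind = row["flux_id"], row["kind"]
        if kind == "influx":
            params.influx_rate[fid] = float(row["gamma"])
        elif kind == "efflux":
            params.efflux_rate_constant = float(row["gamma"])
        else:
            params.gamma[fid] = float(row["gamma"])
            params.f[fid] = float(row["f"])
            enz, act = row["enzyme_id"], float(row["enzyme_activity"])
            if enz in params.enzyme_activity and not np.isclose(
                    params.enzyme_activity[enz], act, rtol=1e-9):
                raise ValueError(f"inconsistent activity for enzyme {enz!r} in {path}")
            params.enzyme_activity[enz] = act
    return params


def write_steady_state_json(ss: SteadyState, path: str | Path,
                            provenance: dict | None = None) -> None:
    doc = {
        "abundances": {s: float(v) for s, v in zip(ss.species, ss.abundances)},
        "fluxes": {k: float(v) for k, v in sorted(ss.fluxes.items())},
        "residual": float(ss.residual),
    }
    if provenance:
        doc["provenance"] = provenance
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True))


def write_trajectory_csv(traj: Trajectory, path: str | Path) -> None:
    """Tidy long format: time, species, value."""
    records = []
    for i, t in enumerate(traj.times):
        for j, sp in enumerate(traj.species):
            records.append({"time": t, "species": sp, "value": traj.states[i, j]})
    pd.DataFrame(records).to_csv(path, index=False, float_format="%.12e")


def read_trajectory_csv(path: str | Path) -> Trajectory:
    df = pd.read_csv(path, dtype={"species": str})
    times = np.array(sorted(df["time"].unique()))
    species = tuple(dict.fromkeys(df["species"].astype(str)))
    wide = df.pivot(index="time", columns="species", values="value")
    states = wide[list(species)].to_numpy()
    return Trajectory(times=times, states=states, species=species)
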