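"""Local relative sensitivities and the high-sensitivity network."""

import numpy as np
import pytest

from pipkin.network import EnzymeGroup, FluxDef, PathwayModel, Species
from pipkin.params import ParameterSet
from pipkin.sensitivity import (edge_list, high_sensitivity_network,
                                parameter_handles, sensitivity_matrix,
                                species_clusters)


@pytest.fixture()
def one_species_model():
    """dX/dt = a - b X with a = 100, b = 0.1: closed form X* = a/b."""
    model = PathwayModel(
        species=[Species("X", "X", 1000.0)],
        fluxes=[FluxDef("v->X", "influx", product="X"),
                FluxDef("vX->", "efflux", substrate="X", f=1)],
        enzymes=[],
    )
    params = ParameterSet(gamma={}, f={}, enzyme_activity={},
                          influx_rate={"v->X": 100.0}, efflux_rate_constant=0.1)
    return model, params


def test_one_species_gains_are_plus_minus_one(one_species_model):
    model, params = one_species_model
    S = sensitivity_matrix(model, params, delta=0.01,
                           handles=["influx:v->X", "k_eff"])
    # central differences carry an O(delta^2) bias (-1/(1 - delta^2))
    assert S.entry("X", "influx:v->X") == pytest.approx(1.0, abs=1e-3)
    assert S.entry("X", "k_eff") == pytest.approx(-1.0, abs=1e-3)


def test_production_and_consumption_gains_have_opposite_sign(toy_cycle):
    """In a first-order chain the substrate pool rises with its production
    rate constant and falls with its consumption rate constant."""
    model, params = toy_cycle
    params = params.copy()
    params.influx_rate = {}
    # add a small influx/efflux so the steady state is unique
    model.fluxes.append(FluxDef("v->A", "influx", product="A"))
    model.fluxes.append(FluxDef("vA->", "efflux", substrate="A", f=1))
    model.fluxes.append(FluxDef("vB->", "efflux", substrate="B", f=1))
    params.influx_rate["v->A"] = 3.0
    params.efflux_rate_constant = 0.1
    S = sensitivity_matrix(model, params, delta=0.01,
                           handles=["gamma:vA->B", "gamma:vB->A"])
    assert S.entry("A", "gamma:vA->B") < 0 < S.entry("B", "gamma:vA->B")
    assert S.entry("B", "gamma:vB->A") < 0 < S.entry("A", "gamma:vB->A")


@pytest.fixture(scope="module")
def reference_matrix(model, reference):
    return sensitivity_matrix(model, reference, delta=0.01)


def test_reference_matrix_is_mostly_insensitive(reference_matrix):
    """Robustness: the majority of |S| entries are below 1."""
    vals = np.abs(reference_matrix.values.to_numpy())
    finite = vals[np.isfinite(vals)]
    assert finite.size > 0
    assert (finite < 1.0).mean() > 0.5
    assert np.isfinite(reference_matrix.values.to_numpy()).all()


def test_matrix_reproducible(model, reference, reference_matrix):
    S2 = sensitivity_matrix(model, reference, delta=0.01)
    a = reference_matrix.values.to_numpy()
    b = S2.values.to_numpy()
    mask = np.abs(a) > 1e-6
    assert np.allclose(a[mask], b[mask], rtol=1e-6)


def test_threshold_extremes(reference_matrix):
    assert high_sensitivity_network(reference_matrix, threshold=np.inf).number_of_edges() == 0
    g0 = high_sensitivity_network(reference_matrix, threshold=0.0)
    nonzero = int((np.abs(reference_matrix.values.to_numpy()) > 0).sum())
    assert g0.number_of_edges() == nonzero


def test_network_edges_match_entries(reference_matrix):
    g = high_sensitivity_network(reference_matrix, threshold=1.0)
    df = edge_list(g)
    for _, row in df.iterrows():
        s = reference_matrix.entry(row["species"], row["parameter"])
        assert abs(s) > 1.0
        assert row["weight"] == pytest.approx(abs(s))
        assert row["sign"] == np.sign(s)


def test_high_sensitivity_clusters_cover_signalling_pools(reference_matrix):
    """|S| > 1 connects into a small number of groups; the signalling pools
    (PI(4,5)P2 cluster, PIP3/PI(3,4)P2 cluster, small 3/5-phosphate pools)
    appear among them."""
    g = high_sensitivity_network(reference_matrix, threshold=1.0)
    clusters = species_clusters(g)
    covered = set().union(*clusters) if clusters else set()
    assert {"45", "345"} <= covered
    assert 1 <= len(clusters) <= 6


def test_all_parameter_handles_enumerate(model):
    handles = parameter_handles(model)
    # 21 gammas + 21 f + 17 enzymes + 3 influxes + shared efflux
    assert len(handles) == 21 + 21 + len(model.enzymes) + 3 + 1
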