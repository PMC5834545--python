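"""Flux evaluation, trajectories, steady-state location and conservation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pipkin import find_steady_state, gma_flux, rhs, simulate
from pipkin.dynamics import CompiledSystem


class TestGmaFlux:
    @pytest.mark.parametrize("x,gamma,E,f,expected", [
        (10.0, 1.0, 1.0, 1.0, 10.0),          # linear case
        (1.0, 2.5, 0.4, 0.77, 1.0),           # x = 1 removes the power
        (760.0, 6e13, 1e-15, 0.9998, 45.54),  # fast PIP3 5-phosphatase turnover
    ])
    def test_values(self, x, gamma, E, f, expected):
        assert gma_flux(x, gamma, E, f) == pytest.approx(expected, rel=1e-3)

    def test_zero_activity_short_circuits(self):
        assert gma_flux(123.0, 5.0, 0.0, 0.8) == 0.0
        assert gma_flux(0.0, 5.0, 0.0, -1.0) == 0.0

    def test_zero_substrate_with_nonpositive_order_is_domain_error(self):
        with pytest.raises(ValueError):
            gma_flux(0.0, 1.0, 1.0, 0.0)
        assert gma_flux(0.0, 1.0, 1.0, 0.5) == 0.0

    @given(x=st.floats(1e-6, 1e6), f=st.floats(0.05, 2.0))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_substrate(self, x, f):
        assert gma_flux(x * 1.5, 2.0, 3.0, f) > gma_flux(x, 2.0, 3.0, f)


def test_rhs_vanishes_at_steady_state(model, reference, basal):
    dx = rhs(basal.abundances, model, reference)
    assert np.all(np.abs(dx) / np.maximum(basal.abundances, 1.0) < 1e-8)


def test_interconversions_conserve_total(model, reference, basal):
    # with transport off, the component sum of the RHS is exactly zero
    p = reference.copy()
    for k in p.influx_rate:
        p.influx_rate[k] = 0.0
    p.efflux_rate_constant = 0.0
    dx = rhs(basal.abundances, model, p)
    assert abs(dx.sum()) < 1e-9 * np.abs(dx).max()


def test_closed_system_conservation_along_trajectory(model, reference, basal):
    p = reference.copy()
    for k in p.influx_rate:
        p.influx_rate[k] = 0.0
    p.efflux_rate_constant = 0.0
    traj = simulate(model, p, basal.abundances * [2, 1, 0.5, 1, 1, 1, 1.5, 1], 200.0)
    totals = traj.states.sum(axis=1)
    assert np.allclose(totals, totals[0], rtol=1e-6)


class TestToyCycle:
    def test_analytic_balance(self, toy_cycle):
        model, params = toy_cycle
        sys = CompiledSystem.compile(model, params)
        assert np.allclose(sys.rhs(np.array([10.0, 20.0])), 0.0)

    def test_simulation_converges_to_analytic_point(self, toy_cycle):
        model, params = toy_cycle
        traj = simulate(model, params, [30.0, 0.0], 30.0)
        assert traj.states[-1] == pytest.approx([10.0, 20.0], rel=1e-6)

    def test_solver_finds_analytic_point(self, toy_cycle):
        model, params = toy_cycle
        ss = find_steady_state(model, params, x0=[29.0, 1.0])
        assert ss.abundances == pytest.approx([10.0, 20.0], rel=1e-9)


def test_linear_subnetwork_matches_direct_solve(model, reference):
    """With every kinetic order forced to 1 the GMA system is linear and the
    steady state must match the solution of the linear system."""
    p = reference.copy()
    for fid in p.f:
        p.f[fid] = 1.0
    sys = CompiledSystem.compile(model, p)
    n = len(model.species)
    A = np.zeros((n, n))
    for j in range(len(sys.sub)):
        A[sys.sub[j], sys.sub[j]] -= sys.c[j]
        A[sys.prod[j], sys.sub[j]] += sys.c[j]
    A -= sys.k_eff * np.eye(n)
    x_direct = np.linalg.solve(A, -sys.influx)
    ss = find_steady_state(model, p)
    assert ss.abundances == pytest.approx(x_direct, rel=1e-8)


def test_flux_balance_at_steady_state(model, reference, basal):
    """Per species: influx + production - consumption - efflux ~ 0."""
    for sp in basal.species:
        net = 0.0
        for fl in model.fluxes:
            v = basal.fluxes[fl.id]
            if fl.product == sp:
                net += v
            if fl.substrate == sp:
                net -= v
        assert abs(net) / max(basal[sp], 1.0) < 1e-8


def test_basal_trajectory_is_flat(model, reference, basal):
    traj = simulate(model, reference, basal.abundances, 1000.0)
    drift = np.abs(traj.states - basal.abundances) / np.maximum(basal.abundances, 1.0)
    assert drift.max() < 1e-6


def test_recovery_after_pip2_halving(model, reference, basal):
    """The basal point is a stable attractor: halving PI(4,5)P2 relaxes back."""
    x0 = basal.abundances.copy()
    x0[6] *= 0.5
    traj = simulate(model, reference, x0, 5000.0)
    assert traj.states[-1] == pytest.approx(basal.abundances, rel=1e-4)


def test_steady_state_independent_of_start(model, reference, basal, random_states):
    for scale in random_states:
        ss = find_steady_state(model, reference, x0=basal.abundances * scale)
        assert ss.abundances == pytest.approx(basal.abundances, rel=1e-6)


def test_conserved_total_without_transport(model, reference):
    p = reference.copy()
    for k in p.influx_rate:
        p.influx_rate[k] = 0.0
    p.efflux_rate_constant = 0.0
    x0 = np.full(8, 1000.0)
    ss = find_steady_state(model, p, x0=x0)
    assert ss.abundances.sum() == pytest.approx(x0.sum(), rel=1e-6)


def test_trajectory_non_negative(model, reference, basal):
    traj = simulate(model, reference, basal.abundances * 0.01, 500.0)
    assert traj.states.min() >= 0.0


def test_simulate_rejects_bad_inputs(model, reference):
    with pytest.raises(ValueError):
        simulate(model, reference, np.full(8, -1.0), 10.0)
    with pytest.raises(ValueError):
        simulate(model, reference, np.full(8, 1.0), -5.0)
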