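"""GMA flux evaluation, ODE right-hand side, trajectories and steady states.

Every interconversion follows the power law

    v_{i->j} = gamma_{i->j} * E_{i->j} * X_i ** f_{i->j}

with X_i in molecules/um^2 and time in minutes.  Influxes are constant
transport rates; effluxes are first order with one shared rate constant.
Steady states are located by a damped Newton search in log-abundance space
(which keeps the state positive), falling back to stiff integration
(LSODA) followed by a root-refinement pass when the direct search does not
converge.  The convergence criterion is

    max_i |dX_i/dt| * (1 min) / max(X_i, 1)  <  tol        (default 1e-9)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .network import SPECIES_ORDER, PathwayModel
from .params import ParameterSet

DEFAULT_SS_TOL = 1e-9
DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10


class SteadyStateError(RuntimeError):
    """No steady state found within the allotted effort."""

    def __init__(self, message: str, residual: float | None = None,
                 last_state: np.ndarray | None = None):
        super().__init__(message)
        self.residual = residual
        self.last_state = last_state


class IntegrationError(RuntimeError):
    def __init__(self, message: str, last_state: np.ndarray | None = None):
        super().__init__(message)
        self.last_state = last_state


def gma_flux(x_substrate: float, gamma: float, activity: float, f: float) -> float:
    """One power-law flux v = gamma * E * x**f.

    Zero activity short-circuits to zero (knockout); a zero substrate with
    f <= 0 is a domain error.
    """
    if x_substrate < 0:
        raise ValueError("negative substrate abundance")
    if activity == 0.0:
        return 0.0
    if x_substrate == 0.0:
        if f <= 0:
            raise ValueError("x = 0 with kinetic order f <= 0 is undefined")
        return 0.0
    return gamma * activity * x_substrate ** f


@dataclass
class CompiledSystem:
    """Array form of (model, params) for fast evaluation.

    ``c[j] = gamma_j * E_j`` is the lumped rate coefficient of
    interconversion j with substrate index ``sub[j]`` and product index
    ``prod[j]``.
    """

    model: PathwayModel
    flux_ids: list[str]
    sub: np.ndarray
    prod: np.ndarray
    c: np.ndarray
    f: np.ndarray
    influx: np.ndarray       # per species
    k_eff: float

    @classmethod
    def compile(cls, model: PathwayModel, params: ParameterSet) -> "CompiledSystem":
        ics = model.interconversions
        flux_ids = [fl.id for fl in ics]
        sub = np.array([model.species_index(fl.substrate) for fl in ics], dtype=int)
        prod = np.array([model.species_index(fl.product) for fl in ics], dtype=int)
        c = np.array([params.gamma[fl.id] * params.enzyme_activity[fl.enzyme] for fl in ics])
        f = np.array([params.f[fl.id] for fl in ics])
        influx = np.zeros(len(model.species))
        for fl in model.influxes:
            influx[model.species_index(fl.product)] += params.influx_rate[fl.id]
        return cls(model, flux_ids, sub, prod, c, f, influx, params.efflux_rate_constant)

    # -- evaluation ------------------------------------------------------
    def flux_values(self, x: np.ndarray) -> np.ndarray:
        xs = x[self.sub]
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            v = self.c * np.power(xs, self.f)
        return np.where(xs > 0, v, np.where(self.f > 0, 0.0, np.nan))

    def rhs(self, x: np.ndarray) -> np.ndarray:
        v = self.flux_values(x)
        dx = self.influx - self.k_eff * x
        np.subtract.at(dx, self.sub, v)
        np.add.at(dx, self.prod, v)
        return dx

    def jac(self, x: np.ndarray) -> np.ndarray:
        """d(dX/dt)/dX, analytic."""
        n = len(x)
        J = -self.k_eff * np.eye(n)
        xs = np.maximum(x[self.sub], 1e-300)
        dv = self.c * self.f * xs ** (self.f - 1.0)
        for j in range(len(self.sub)):
            J[self.sub[j], self.sub[j]] -= dv[j]
            J[self.prod[j], self.sub[j]] += dv[j]
        return J

    def residual_norm(self, x: np.ndarray) -> float:
        return float(np.max(np.abs(self.rhs(x)) / np.maximum(x, 1.0)))

    # -- steady state ----------------------------------------------------
    def solve_steady(self, x0: np.ndarray, tol: float = DEFAULT_SS_TOL,
                     max_integration_time: float = 2e5) -> np.ndarray:
        x0 = np.maximum(np.asarray(x0, dtype=float), 1e-9)

        # clipping the log-state keeps trial points finite while the Newton
        # search explores; any solution lives well inside the clip range
        def F(u):
            return self.rhs(np.exp(np.clip(u, -60.0, 60.0)))

        def Jlog(u):
            x = np.exp(np.clip(u, -60.0, 60.0))
            return self.jac(x) * x[None, :]

        sol = root(F, np.log(x0), jac=Jlog, method="hybr", options={"xtol": 1e-13})
        if sol.success:
            x = np.exp(sol.x)
            if self.residual_norm(x) < tol:
                return x
        # fall back: relax by stiff integration, then refine
        x = x0.copy()
        t_done = 0.0
        horizon = 2000.0
        while t_done < max_integration_time:
            ivp = solve_ivp(lambda t, y: self.rhs(np.maximum(y, 0.0)), (0.0, horizon), x,
                            method="LSODA", jac=lambda t, y: self.jac(np.maximum(y, 0.0)),
                            rtol=DEFAULT_RTOL, atol=DEFAULT_ATOL)
            if not ivp.success:
                raise SteadyStateError("integrator failure during relaxation",
                                       residual=self.residual_norm(x), last_state=x)
            x = np.maximum(ivp.y[:, -1], 1e-12)
            t_done += horizon
            horizon *= 2
            sol = root(F, np.log(x), jac=Jlog, method="hybr", options={"xtol": 1e-13})
            if sol.success:
                cand = np.exp(sol.x)
                if self.residual_norm(cand) < tol:
                    return cand
            if self.residual_norm(x) < tol:
                return x
        raise SteadyStateError(
            f"no steady state within t = {max_integration_time} min",
            residual=self.residual_norm(x), last_state=x)


@dataclass
class Trajectory:
    times: np.ndarray
    states: np.ndarray                      # shape (n_times, 8)
    species: tuple[str, ...] = SPECIES_ORDER
    flux_series: Optional[dict[str, np.ndarray]] = None


@dataclass
class SteadyState:
    abundances: np.ndarray                  # ordered as SPECIES_ORDER
    fluxes: dict[str, float]
    residual: float
    species: tuple[str, ...] = SPECIES_ORDER

    def __getitem__(self, species_id: str) -> float:
        return float(self.abundances[SPECIES_ORDER.index(species_id)])

    def as_dict(self) -> dict[str, float]:
        return {s: float(v) for s, v in zip(self.species, self.abundances)}


def rhs(state: np.ndarray, model: PathwayModel, params: ParameterSet) -> np.ndarray:
    """Time derivatives of all 8 pools (molecules um^-2 min^-1)."""
    return CompiledSystem.compile(model, params).rhs(np.asarray(state, dtype=float))


def _all_fluxes(sys: CompiledSystem, x: np.ndarray, params: ParameterSet) -> dict[str, float]:
    out = {fid: float(v) for fid, v in zip(sys.flux_ids, sys.flux_values(x))}
    for fl in sys.model.influxes:
        out[fl.id] = float(params.influx_rate[fl.id])
    for fl in sys.model.effluxes:
        i = sys.model.species_index(fl.substrate)
        out[fl.id] = float(sys.k_eff * x[i])
    return out


def simulate(model: PathwayModel, params: ParameterSet, x0, t_end: float,
             n_points: int = 200, rtol: float = DEFAULT_RTOL,
             atol: float = DEFAULT_ATOL, record_fluxes: bool = False) -> Trajectory:
    """Integrate the GMA system with LSODA (automatic stiff switching)."""
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    x0 = np.asarray(x0, dtype=float)
    if np.any(x0 < 0):
        raise ValueError("initial state must be non-negative")
    sys = CompiledSystem.compile(model, params)
    times = np.linspace(0.0, t_end, n_points)
    ivp = solve_ivp(lambda t, y: sys.rhs(np.maximum(y, 0.0)), (0.0, t_end), x0,
                    method="LSODA", jac=lambda t, y: sys.jac(np.maximum(y, 0.0)),
                    t_eval=times, rtol=rtol, atol=atol)
    if not ivp.success:
        raise IntegrationError(f"integration failed: {ivp.message}",
                               last_state=ivp.y[:, -1] if ivp.y.size else x0)
    states = ivp.y.T
    # clip sub-tolerance negative overshoot; anything larger is an error
    if np.any(states < -atol * 10):
        raise IntegrationError("trajectory went significantly negative", last_state=states[-1])
    states = np.maximum(states, 0.0)
    fluxes = None
    if record_fluxes:
        vals = np.array([sys.flux_values(s) for s in states])
        fluxes = {fid: vals[:, j] for j, fid in enumerate(sys.flux_ids)}
    return Trajectory(times=times, states=states, flux_series=fluxes)


def find_steady_state(model: PathwayModel, params: ParameterSet, x0=None,
                      tol: float = DEFAULT_SS_TOL) -> SteadyState:
    """Locate the steady state reached from ``x0`` (default: nominal basal)."""
    sys = CompiledSystem.compile(model, params)
    if x0 is None:
        x0 = np.array([max(s.basal_abundance, 1.0) for s in model.species])
    x = sys.solve_steady(np.asarray(x0, dtype=float), tol=tol)
    return SteadyState(abundances=x, fluxes=_all_fluxes(sys, x, params),
                       residual=sys.residual_norm(x))
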