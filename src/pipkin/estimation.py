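"""Parameter estimation: genetic-algorithm fitting and Monte-Carlo
exploration of parameter space with admissibility rules.

The GA operates on a log10 genome over a chosen set of free parameters
(kinetic orders travel linearly), with tournament selection, uniform
crossover, Gaussian log-space mutation whose scale anneals over the run,
and elitism.  Fitness is the calibration adjustment score.  Both the GA
and the Monte-Carlo search are deterministic for a fixed seed; Monte-Carlo
candidate draws are pre-generated from the master seed so the result does
not depend on evaluation order or worker count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .calibration import (AdjustmentScore, PhenomenonSpec, RankConstraint,
                          SteadyStateTarget, adjustment_score, load_targets)
from .dynamics import SteadyState, SteadyStateError, find_steady_state
from .network import INFLUX_IDS, PathwayModel
from .params import ParameterSet
from .sensitivity import ParamHandle, get_param, set_param


@dataclass
class GAConfig:
    population_size: int = 100
    generations: int = 300
    mutation_sigma: float = 0.1        # decades (or absolute, for f entries)
    mutation_rate: float = 0.15
    crossover_rate: float = 0.7
    tournament_k: int = 3
    elitism: int = 2
    bounds_decades: float = 1.5        # search box half-width around start
    f_bounds: tuple[float, float] = (0.05, 2.5)
    seed: int = 0
    anneal: bool = True                # shrink mutation scale over generations


@dataclass
class GAResult:
    best_params: ParameterSet
    best_score: float
    trace: list[float]                 # best-so-far per generation
    free_parameters: list[ParamHandle]
    seed: int


def _is_log_handle(handle: ParamHandle) -> bool:
    return not handle.startswith("f:")


def _encode(params: ParameterSet, handles: list[ParamHandle]) -> np.ndarray:
    vals = []
    for h in handles:
        v = get_param(params, h)
        vals.append(math.log10(v) if _is_log_handle(h) else v)
    return np.array(vals)


def _decode(genome: np.ndarray, base: ParameterSet,
            handles: list[ParamHandle]) -> ParameterSet:
    p = base.copy()
    for h, g in zip(handles, genome):
        set_param(p, h, 10.0 ** g if _is_log_handle(h) else float(g))
    return p


def fit_ga(model: PathwayModel, initial_params: ParameterSet,
           targets: Optional[list[SteadyStateTarget]] = None,
           phenomena: Optional[list[PhenomenonSpec]] = None,
           config: Optional[GAConfig] = None,
           free_parameters: Optional[list[ParamHandle]] = None) -> GAResult:
    """Minimize the adjustment score over the chosen free parameters.

    The starting individual is always injected into the population, so the
    best score never exceeds the score of ``initial_params``.
    """
    config = config or GAConfig()
    if free_parameters is None:
        free_parameters = ([f"gamma:{fl.id}" for fl in model.interconversions]
                           + [f"influx:{i}" for i in INFLUX_IDS])
    rng = np.random.default_rng(config.seed)
    x0 = _encode(initial_params, free_parameters)
    is_log = np.array([_is_log_handle(h) for h in free_parameters])
    lo = np.where(is_log, x0 - config.bounds_decades, config.f_bounds[0])
    hi = np.where(is_log, x0 + config.bounds_decades, config.f_bounds[1])

    def score(genome: np.ndarray) -> float:
        p = _decode(genome, initial_params, free_parameters)
        return adjustment_score(model, p, targets, phenomena).total

    n = len(free_parameters)
    pop = rng.uniform(lo, hi, size=(config.population_size, n))
    pop[0] = x0
    fitness = np.array([score(g) for g in pop])
    if not np.any(np.isfinite(fitness)):
        raise SteadyStateError("no candidate in the initial population reaches a steady state")
    order = np.argsort(fitness)
    trace = [float(fitness[order[0]])]
    best, best_fit = pop[order[0]].copy(), float(fitness[order[0]])

    for gen in range(config.generations if best_fit > 0.0 else 0):
        sigma = config.mutation_sigma
        if config.anneal:
            sigma *= max(0.05, 1.0 - gen / max(config.generations - 1, 1))
        new_pop = [pop[i].copy() for i in order[:config.elitism]]
        while len(new_pop) < config.population_size:
            # tournament selection of two parents
            parents = []
            for _ in range(2):
                idx = rng.integers(0, config.population_size, size=config.tournament_k)
                parents.append(pop[idx[np.argmin(fitness[idx])]])
            a, b = parents
            if rng.random() < config.crossover_rate:
                mask = rng.random(n) < 0.5
                child = np.where(mask, a, b)
            else:
                child = a.copy()
            mutate = rng.random(n) < config.mutation_rate
            child = child + mutate * rng.normal(0.0, sigma, size=n)
            new_pop.append(np.clip(child, lo, hi))
        pop = np.array(new_pop)
        fitness = np.array([score(g) for g in pop])
        order = np.argsort(fitness)
        if fitness[order[0]] < best_fit:
            best, best_fit = pop[order[0]].copy(), float(fitness[order[0]])
        trace.append(best_fit)
        if best_fit == 0.0:
            break

    return GAResult(best_params=_decode(best, initial_params, free_parameters),
                    best_score=best_fit, trace=trace,
                    free_parameters=list(free_parameters), seed=config.seed)


# ---------------------------------------------------------------------------
# Monte-Carlo search
# ---------------------------------------------------------------------------

@dataclass
class AdmissibilityRules:
    targets: list[SteadyStateTarget]
    rank_constraints: list[RankConstraint] = field(default_factory=list)
    influx_cap: float = 0.25           # influx < cap * receiving pool
    efflux_cap: float = 0.07           # efflux < cap * pool

    def __post_init__(self) -> None:
        if not (0 < self.influx_cap <= 1 and 0 < self.efflux_cap <= 1):
            raise ValueError("caps must lie in (0, 1]")

    @classmethod
    def default(cls) -> "AdmissibilityRules":
        targets, ranks = load_targets()
        return cls(targets=targets, rank_constraints=ranks)

    def check(self, params: ParameterSet, ss: SteadyState) -> bool:
        for tgt in self.targets:
            if tgt.deviation(ss[tgt.species]) != 0.0:
                return False
        for rc in self.rank_constraints:
            if not rc.satisfied(ss):
                return False
        influx_target = {"v->0": "0", "v->4": "4", "v->3": "3"}
        for influx, sp in influx_target.items():
            if params.influx_rate[influx] >= self.influx_cap * ss[sp]:
                return False
        # shared first-order efflux: per-pool efflux fraction equals k_eff
        if params.efflux_rate_constant >= self.efflux_cap:
            return False
        return True


@dataclass
class MonteCarloResult:
    n_tested: int
    n_admissible: int
    admissible_params: list[ParameterSet]
    admissible_scores: list[float]
    fraction: float
    fraction_ci: tuple[float, float]   # 95% Wilson interval
    ranges_decades: float
    seed: int


def _wilson_ci(k: int, n: int, z: float = 1.959964) -> tuple[float, float]:
    if n == 0:
        return (0.0, 1.0)
    p = k / n
    denom = 1 + z ** 2 / n
    centre = (p + z ** 2 / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z ** 2 / (4 * n ** 2)) / denom
    return (max(0.0, centre - half), min(1.0, centre + half))


def monte_carlo_search(model: PathwayModel, reference: ParameterSet, n: int,
                       rules: Optional[AdmissibilityRules] = None,
                       seed: int = 0, ranges_decades: float = 1.5,
                       f_range: tuple[float, float] = (0.5, 1.2),
                       score_admissible: bool = True,
                       include_reference: bool = False) -> MonteCarloResult:
    """Sample parameter sets and count those passing all admissibility rules.

    Rate constants and influxes are drawn log-uniformly within
    ``+-ranges_decades`` decades of the reference value; kinetic orders
    uniformly within ``f_range``.  Candidate draws are all generated up
    front from the master seed, making the result independent of
    evaluation order.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rules = rules or AdmissibilityRules.default()
    rng = np.random.default_rng(seed)
    gamma_ids = [fl.id for fl in model.interconversions]
    n_g, n_i = len(gamma_ids), len(INFLUX_IDS)
    log_offsets = rng.uniform(-ranges_decades, ranges_decades, size=(n, n_g + n_i))
    f_draws = rng.uniform(f_range[0], f_range[1], size=(n, n_g))

    x0 = np.array([max(s.basal_abundance, 1.0) for s in model.species])
    admissible: list[ParameterSet] = []
    scores: list[float] = []
    candidates = range(n)
    for i in candidates:
        p = reference.copy()
        if not (include_reference and i == 0):
            for j, fid in enumerate(gamma_ids):
                p.gamma[fid] = reference.gamma[fid] * 10.0 ** log_offsets[i, j]
                p.f[fid] = f_draws[i, j]
            for j, influx in enumerate(INFLUX_IDS):
                p.influx_rate[influx] = (reference.influx_rate[influx]
                                         * 10.0 ** log_offsets[i, n_g + j])
        try:
            ss = find_steady_state(model, p, x0=x0)
        except SteadyStateError:
            continue
        if rules.check(p, ss):
            admissible.append(p)
            if score_admissible:
                scores.append(adjustment_score(model, p, rules.targets,
                                               phenomena=[], basal=ss).total)
    k = len(admissible)
    return MonteCarloResult(
        n_tested=n, n_admissible=k, admissible_params=admissible,
        admissible_scores=scores, fraction=k / n, fraction_ci=_wilson_ci(k, n),
        ranges_decades=ranges_decades, seed=seed)
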