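"""pipkin: power-law (GMA) kinetics of the plasma-membrane phosphoinositide pathway.

The package models the eight phosphoinositide pools of a homogeneous
1 um^2 plasma-membrane patch as a generalized-mass-action ODE system,
locates and interrogates its steady state, applies declarative enzyme and
transport perturbations, scores parameter sets against literature-derived
calibration targets, and explores parameter space with a genetic algorithm
and Monte-Carlo sampling.
"""

from .network import (EXPECTED_COUNTS, SPECIES_ORDER, EnzymeGroup, FluxDef,
                      NetworkError, PathwayModel, Species, load_network)
from .params import ParameterSet, ValidationIssue, validate_parameter_set
from .dynamics import (CompiledSystem, SteadyState, SteadyStateError, Trajectory,
                       find_steady_state, gma_flux, rhs, simulate)
from .perturb import PerturbationSpec, apply, knockout_preset, load_spec, preset_names

__all__ = [
    "EXPECTED_COUNTS", "SPECIES_ORDER", "EnzymeGroup", "FluxDef", "NetworkError",
    "PathwayModel", "Species", "load_network",
    "ParameterSet", "ValidationIssue", "validate_parameter_set",
    "CompiledSystem", "SteadyState", "SteadyStateError", "Trajectory",
    "find_steady_state", "gma_flux", "rhs", "simulate",
    "PerturbationSpec", "apply", "knockout_preset", "load_spec", "preset_names",
    "reference_fixture",
]

__version__ = "0.1.0"


def reference_fixture() -> ParameterSet:
    """The packaged reference parameter set (see :mod:`pipkin.synthetic`)."""
    from .synthetic import reference_fixture as _rf
    return _rf()
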