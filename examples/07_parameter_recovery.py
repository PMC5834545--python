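"""Ground-truth recovery with the genetic algorithm.

Generates a synthetic scenario (3 jittered parameters, noiseless
pseudo-observations of all 8 pools), then fits those parameters back
from the reference starting point.
"""

from pipkin import load_network
from pipkin.estimation import GAConfig, fit_ga
from pipkin.sensitivity import get_param
from pipkin.synthetic import generate_scenario, reference_fixture

model = load_network()
scenario = generate_scenario(seed=13, noise_sigma=0.0, n_free_parameters=3)
result = fit_ga(model, reference_fixture(), scenario.targets, phenomena=[],
                config=GAConfig(population_size=40, generations=40, seed=17,
                                bounds_decades=0.5),
                free_parameters=scenario.free_parameters)

print(f"final adjustment score: {result.best_score:.3g}")
for handle in scenario.free_parameters:
    truth = get_param(scenario.truth, handle)
    est = get_param(result.best_params, handle)
    print(f"  {handle:16s} truth {truth:10.4g}  estimate {est:10.4g} "
          f"({100 * (est / truth - 1):+.1f}%)")

print("\nWith identifiable parameters and noiseless targets the GA recovers")
print("the truth to within a few percent; freeing the sloppy v4->45/v45->4")
print("loop pair instead would leave a flat valley the data cannot resolve.")
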