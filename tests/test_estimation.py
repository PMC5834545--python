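"""GA fitting and Monte-Carlo parameter-space exploration."""

import numpy as np
import pytest

from pipkin.calibration import adjustment_score
from pipkin.estimation import (AdmissibilityRules, GAConfig, fit_ga,
                               monte_carlo_search)
from pipkin.synthetic import generate_scenario

TINY_GA = dict(population_size=16, generations=8, seed=5)


@pytest.fixture(scope="module")
def noiseless_scenario():
    return generate_scenario(seed=7, noise_sigma=0.0, n_free_parameters=2)


class TestFitGA:
    def test_perfect_start_returned_unchanged(self, model, noiseless_scenario):
        sc = noiseless_scenario
        res = fit_ga(model, sc.truth, sc.targets, phenomena=[],
                     config=GAConfig(**TINY_GA), free_parameters=sc.free_parameters)
        assert res.best_score == 0.0
        assert res.trace == [0.0]
        for h in sc.free_parameters:
            from pipkin.sensitivity import get_param
            assert get_param(res.best_params, h) == pytest.approx(
                get_param(sc.truth, h), rel=1e-12)

    def test_best_never_worse_than_start_and_trace_monotone(self, model, reference):
        from pipkin.calibration import load_targets
        targets, _ = load_targets()
        start_score = adjustment_score(model, reference, targets, phenomena=[]).total
        res = fit_ga(model, reference, targets, phenomena=[],
                     config=GAConfig(**TINY_GA),
                     free_parameters=["gamma:v0->45", "gamma:v4->45"])
        assert res.best_score <= start_score
        assert all(a >= b for a, b in zip(res.trace, res.trace[1:]))

    def test_deterministic_under_seed(self, model, noiseless_scenario):
        sc = noiseless_scenario
        def run():
            res = fit_ga(model, sc.truth, sc.targets, phenomena=[],
                         config=GAConfig(population_size=10, generations=3, seed=9),
                         free_parameters=sc.free_parameters)
            return res.best_score, res.trace
        assert run() == run()


class TestMonteCarlo:
    def test_reference_injected_is_admissible(self, model, reference):
        res = monte_carlo_search(model, reference, n=1, seed=3,
                                 include_reference=True)
        assert res.n_admissible == 1
        assert res.admissible_scores[0] == 0.0

    def test_wide_ranges_rarely_admissible(self, model, reference):
        res = monte_carlo_search(model, reference, n=120, seed=3)
        assert res.n_admissible <= res.n_tested
        assert res.fraction < 0.10
        lo, hi = res.fraction_ci
        assert 0.0 <= lo <= res.fraction <= hi <= 1.0

    def test_near_zero_influx_cap_excludes_everything(self, model, reference):
        rules = AdmissibilityRules.default()
        rules.influx_cap = 1e-12
        res = monte_carlo_search(model, reference, n=3, seed=1, rules=rules,
                                 include_reference=True)
        assert res.n_admissible == 0

    def test_invalid_caps_rejected(self):
        with pytest.raises(ValueError):
            rules = AdmissibilityRules.default()
            rules.influx_cap = 0.0
            rules.__post_init__()

    def test_deterministic_under_seed(self, model, reference):
        a = monte_carlo_search(model, reference, n=40, seed=11)
        b = monte_carlo_search(model, reference, n=40, seed=11)
        assert a.n_admissible == b.n_admissible
        assert a.admissible_scores == b.admissible_scores
        c = monte_carlo_search(model, reference, n=40, seed=12)
        # different seed explores different candidates
        assert (a.n_admissible != c.n_admissible) or True  # smoke: no crash

    def test_stored_sets_revalidate(self, model, reference):
        from pipkin.dynamics import find_steady_state
        rules = AdmissibilityRules.default()
        res = monte_carlo_search(model, reference, n=40, seed=11, rules=rules,
                                 include_reference=True)
        for p in res.admissible_params:
            ss = find_steady_state(model, p)
            assert rules.check(p, ss)
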