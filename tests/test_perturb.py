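"""Knockout/knockdown semantics and the preset registry."""

import numpy as np
import pytest

from pipkin import gma_flux
from pipkin.perturb import (PerturbationSpec, apply, identity, knockout_preset,
                            preset_names, spec_from_dict)


class TestApply:
    def test_is_pure(self, model, reference):
        before = reference.enzyme_activity["PIP5KI"]
        apply(reference, knockout_preset("pip5ki_ko"), model)
        assert reference.enzyme_activity["PIP5KI"] == before

    def test_identity_leaves_params_unchanged(self, model, reference):
        p = apply(reference, identity, model)
        assert p.gamma == reference.gamma
        assert p.enzyme_activity == reference.enzyme_activity
        assert p.influx_rate == reference.influx_rate

    def test_pip5ki_knockout_removes_both_fluxes(self, model, reference):
        p = apply(reference, knockout_preset("pip5ki_ko"), model)
        assert p.enzyme_activity["PIP5KI"] == 0.0
        assert p.enzyme_activity["PI4K_PIP5KI_DVL"] == 0.0  # complex goes too
        assert p.enzyme_activity["PI4K"] == reference.enzyme_activity["PI4K"]

    def test_pi4k_knockout_disables_v04_and_v045(self, model, reference):
        p = apply(reference, knockout_preset("pi4k_ko"), model)
        assert p.rate_coefficient("v0->4", model) == 0.0
        assert p.rate_coefficient("v0->45", model) == 0.0
        assert p.rate_coefficient("v4->45", model) > 0.0

    def test_complex_only_knockout_spares_single_enzymes(self, model, reference):
        p = apply(reference, knockout_preset("complex_ko"), model)
        assert p.enzyme_activity["PI4K_PIP5KI_DVL"] == 0.0
        assert p.rate_coefficient("v0->4", model) > 0.0
        assert p.rate_coefficient("v4->45", model) > 0.0

    def test_unknown_ids_raise(self, model, reference):
        with pytest.raises(KeyError):
            apply(reference, PerturbationSpec(enzyme_scales={"NOPE": 0.5}), model)
        with pytest.raises(KeyError):
            apply(reference, PerturbationSpec(gamma_scales={"v9->9": 0.5}), model)

    def test_enzyme_scale_multiplies_every_member_flux(self, model, reference, basal):
        """Fluxes are linear in E: scaling an enzyme by s scales each flux it
        catalyses by exactly s at fixed state."""
        s = 0.37
        p = apply(reference, PerturbationSpec(enzyme_scales={"PTEN": s}), model)
        x = basal.abundances
        for fid in model.member_fluxes("PTEN"):
            fl = model.flux(fid)
            v0 = gma_flux(basal[fl.substrate], reference.gamma[fid],
                          reference.enzyme_activity[fl.enzyme], reference.f[fid])
            v1 = gma_flux(basal[fl.substrate], p.gamma[fid],
                          p.enzyme_activity[fl.enzyme], p.f[fid])
            assert v1 == pytest.approx(s * v0, rel=1e-12)


class TestComposition:
    def test_scales_multiply(self):
        a = PerturbationSpec(enzyme_scales={"PTEN": 0.5})
        b = PerturbationSpec(enzyme_scales={"PTEN": 0.5, "SHIP": 2.0})
        c = a.compose(b)
        assert c.enzyme_scales == {"PTEN": 0.25, "SHIP": 2.0}

    def test_associative(self):
        a = PerturbationSpec(enzyme_scales={"PTEN": 0.5})
        b = PerturbationSpec(gamma_scales={"v0->4": 0.2})
        c = PerturbationSpec(influx_scales={"v->0": 2.0})
        left = a.compose(b).compose(c)
        right = a.compose(b.compose(c))
        assert left.enzyme_scales == right.enzyme_scales
        assert left.gamma_scales == right.gamma_scales
        assert left.influx_scales == right.influx_scales

    def test_negative_scale_rejected(self):
        with pytest.raises(ValueError):
            PerturbationSpec(enzyme_scales={"PTEN": -0.1})


class TestPresets:
    def test_registry_contains_all_experiments(self):
        names = preset_names()
        for required in ("pip5ki_ko", "pi4k_ko", "complex_ko", "sioss_x2",
                         "pip5kii_ko", "mtmr_65", "apical", "basolateral",
                         "ship_fast", "ship_slow",
                         "fig3b_block_all_PI45P2_inputs"):
            assert required in names

    def test_unknown_preset_raises(self):
        with pytest.raises(KeyError):
            knockout_preset("not_a_preset")

    def test_fig3b_block_keeps_20pct_of_v04(self, model, reference):
        p = apply(reference, knockout_preset("fig3b_block_all_PI45P2_inputs"), model)
        assert p.gamma["v0->4"] == pytest.approx(0.2 * reference.gamma["v0->4"])
        for blocked in ("v34->4", "v45->4", "v0->45", "v5->45", "v345->45"):
            assert p.gamma[blocked] == 0.0
        assert p.influx_rate["v->4"] == 0.0
        assert p.gamma["v4->45"] == reference.gamma["v4->45"]  # conduit stays

    def test_membrane_presets_set_absolute_activities(self, model, reference):
        apical = apply(reference, knockout_preset("apical"), model)
        baso = apply(reference, knockout_preset("basolateral"), model)
        assert apical.enzyme_activity["PTEN"] == pytest.approx(2.3e-15)
        assert apical.enzyme_activity["PI3KI"] == pytest.approx(6.1e-16)
        assert baso.enzyme_activity["PTEN"] == pytest.approx(3.9e-17)
        assert baso.enzyme_activity["PI3KI"] == pytest.approx(1.5e-14)

    def test_ship_modes(self, model, reference):
        fast = apply(reference, knockout_preset("ship_fast"), model)
        assert fast.gamma["v345->34"] == pytest.approx(6e13)
        assert fast.f["v345->34"] == pytest.approx(0.9998)
        slow = apply(reference, knockout_preset("ship_slow"), model)
        assert slow.gamma["v345->34"] == pytest.approx(1e11)
        assert slow.f["v345->34"] == pytest.approx(0.9982)

    def test_spec_from_dict_round_trip(self):
        spec = spec_from_dict({"enzyme_scales": {"PTEN": 0.5},
                               "influx_scales": {"v->0": 2}})
        assert spec.enzyme_scales == {"PTEN": 0.5}
        assert spec.influx_scales == {"v->0": 2.0}
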