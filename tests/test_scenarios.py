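"""Perturbation schedules, effective parameters, presets."""

import math

import pytest

from osmotip import (
    Perturbation,
    Scenario,
    effective_params,
    get_preset,
    preset_names,
    standard_lilium,
)


class TestPerturbation:
    def test_unknown_parameter_rejected(self):
        with pytest.raises(ValueError):
            Perturbation("bogus", "step", 0.0, value=1.0)

    def test_step_needs_value(self):
        with pytest.raises(ValueError):
            Perturbation("C_o", "step", 0.0)

    def test_sinusoid_amplitude_bounded(self):
        with pytest.raises(ValueError):
            Perturbation("C_o", "sinusoid", 0.0, amplitude=1.0)

    def test_before_onset_unchanged(self, params):
        p = Perturbation("C_o", "step", 100.0, value=0.4)
        assert p.evaluate(0.3, 50.0, params.perturbation_half_time) == 0.3

    def test_step_converges_to_target(self, params):
        p = Perturbation("C_o", "step", 100.0, value=0.4)
        late = p.evaluate(0.3, 110.0, params.perturbation_half_time)
        assert late == pytest.approx(0.4, abs=1e-9)

    def test_sinusoid_formula(self):
        p = Perturbation("L_perm", "sinusoid", 0.0, amplitude=1 / 3,
                         frequency=1.2)
        # quarter period of a 1.2/min drive: t = 12.5 s, sin = 1
        assert p.evaluate(20.0, 12.5, 0.2) == pytest.approx(20 * (1 + 1 / 3))
        assert p.evaluate(20.0, 25.0, 0.2) == pytest.approx(20.0, abs=1e-9)


class TestEffectiveParams:
    def test_no_scenario_is_identity(self, params):
        assert effective_params(params, None, 10.0) is params

    def test_step_changes_osmolarity(self, params):
        sc = Scenario([Perturbation("C_o", "step", 0.0, value=0.4)])
        p = effective_params(params, sc, 50.0)
        assert p.C_o == pytest.approx(0.4, abs=1e-9)
        assert p.Pi_o == pytest.approx(p.RT * 0.4, rel=1e-9)

    def test_calcium_drives_alpha_proportionally(self, params):
        sc = Scenario([Perturbation("C_Ca", "step", 0.0,
                                    value=params.C_Ca * 20)])
        p = effective_params(params, sc, 50.0)
        assert p.alpha == pytest.approx(20 * params.alpha, rel=1e-6)

    def test_area_follows_zone_length(self, params):
        sc = Scenario([Perturbation("L_perm", "step", 0.0, value=10.0)])
        p = effective_params(params, sc, 50.0)
        assert p.A_mem == pytest.approx(2 * math.pi * p.r * 10.0, rel=1e-6)

    def test_negative_time_rejected(self, params):
        with pytest.raises(ValueError):
            effective_params(params, Scenario(), -1.0)


class TestPresets:
    def test_all_presets_resolve(self, params):
        for name in preset_names():
            p, scenario, preset = get_preset(name, params)
            assert preset.name == name
            assert preset.duration > 0

    def test_expected_preset_names_exist(self):
        names = set(preset_names())
        assert {"baseline", "fig3_alpha_zero", "fig3_alpha_x20",
                "fig3_alpha_half", "fig5_dilute", "fig5_shock",
                "fig5_hyper", "fig6_whole_tube_permeable",
                "fig6_whole_tube_permeable_no_sensor",
                "fig10_pectin_sine", "fig10_alpha_sine",
                "fig11_Lperm_sine",
                "fig11_Lperm_sine_no_sensor"} <= names

    def test_alpha_zero_preset_targets_zero(self, params):
        _, scenario, _ = get_preset("fig3_alpha_zero", params)
        (p,) = scenario.perturbations
        assert p.parameter == "alpha" and p.value == 0.0

    def test_fig6_presets_use_whole_tube_area(self, params):
        p, _, preset = get_preset("fig6_whole_tube_permeable", params)
        assert p.whole_tube_permeable
        assert preset.L0 == 20.0

    def test_unknown_preset_raises_with_choices(self, params):
        with pytest.raises(KeyError, match="baseline"):
            get_preset("not_a_preset", params)
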