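import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isletsim import (
    PHENOTYPES,
    apply_phenotype,
    kcal_to_enteral_rate,
    make_grodsky_protocols,
    make_ivgtt,
    make_pulsed,
    make_sinusoidal,
    mgdl_to_mm,
    rate_to_cc_per_hr,
)
from isletsim.conversions import mg_rate_to_mmol


class TestGrodskyProtocols:
    def test_staircase_third_step(self):
        proto = make_grodsky_protocols()["staircase"]
        assert proto.value(12.0) == pytest.approx(mgdl_to_mm(150.0))

    def test_restimulation_off_interval(self):
        proto = make_grodsky_protocols()["restimulation"]
        assert proto.value(62.0) == 0.0
        assert proto.value(59.0) == pytest.approx(mgdl_to_mm(300.0))
        assert proto.value(66.0) == pytest.approx(mgdl_to_mm(300.0))

    def test_constant_level_family(self):
        levels = make_grodsky_protocols()["constant_levels"]
        assert len(levels) == 6
        assert levels[5].value(30.0) == pytest.approx(mgdl_to_mm(500.0))

    def test_ramp_reaches_peak(self):
        proto = make_grodsky_protocols()["ramp"]
        assert proto.value(0.0) == pytest.approx(0.0, abs=1e-9)
        assert proto.value(59.999) == pytest.approx(mgdl_to_mm(500.0), rel=1e-3)


class TestRateProtocols:
    def test_sinusoid_at_zero_phase_and_extrema(self):
        proto = make_sinusoidal(0.03, 0.33, 120.0, duration=240.0)
        assert proto.value(0.0) == pytest.approx(0.03)
        t = np.linspace(0, 120, 4801)
        vals = proto.values(t)
        assert vals.min() == pytest.approx(0.67 * 0.03, rel=1e-4)
        assert vals.max() == pytest.approx(1.33 * 0.03, rel=1e-4)

    def test_sinusoid_zero_modulation_is_constant(self):
        proto = make_sinusoidal(0.03, 0.0, 120.0, duration=240.0)
        assert np.allclose(proto.values(np.linspace(0, 200, 50)), 0.03)

    def test_pulse_train_duty_cycle(self):
        proto = make_pulsed(0.033, period=10.0, pulse_width=1.0, duration=90.0)
        assert proto.value(0.5) == pytest.approx(0.033)
        assert proto.value(5.0) == 0.0
        t = np.arange(0, 90, 0.01)
        on = proto.values(t) > 0
        assert on.mean() == pytest.approx(0.1, abs=0.01)

    def test_ivgtt_rate_and_schedule(self):
        proto, schedule = make_ivgtt(dose_g_per_kg=0.36, infusion_minutes=3.0)
        assert len(schedule) == 23
        t_bolus = schedule[2]  # the 0' sample coincides with the bolus
        assert proto.value(t_bolus + 0.5) == pytest.approx(0.36 / 3.0 / 0.18016, rel=1e-6)
        assert proto.value(t_bolus + 3.5) == 0.0

    def test_zero_dose_ivgtt_is_null_protocol(self):
        proto, _ = make_ivgtt(dose_g_per_kg=0.0)
        assert proto.value(31.0) == 0.0

    @given(st.floats(min_value=0.0, max_value=300.0))
    @settings(max_examples=50, derandomize=True)
    def test_every_protocol_nonnegative(self, t):
        protos = make_grodsky_protocols()
        for p in [protos["staircase"], protos["restimulation"], protos["ramp_hold"],
                  protos["ramp"], make_sinusoidal(0.03, 0.33, 100.0, 300.0),
                  make_pulsed(0.03, 10.0, 1.0, 300.0)]:
            assert p.value(t) >= 0.0


class TestConversions:
    def test_enteral_feed_reference_value(self):
        assert kcal_to_enteral_rate(90.0, 60.0) == pytest.approx(0.035, rel=0.02)

    def test_enteral_feed_linearity(self):
        assert kcal_to_enteral_rate(180.0, 60.0) == pytest.approx(
            2 * kcal_to_enteral_rate(90.0, 60.0)
        )
        assert kcal_to_enteral_rate(0.0, 60.0) == 0.0

    def test_pump_setting_reference_value(self):
        assert rate_to_cc_per_hr(6.0, 70.0, 0.2) == pytest.approx(126.0)

    def test_pump_setting_linearity(self):
        assert rate_to_cc_per_hr(3.0, 70.0, 0.2) == pytest.approx(63.0)
        assert rate_to_cc_per_hr(0.0, 70.0, 0.2) == 0.0

    def test_mg_rate_conversion_invertible(self):
        assert mg_rate_to_mmol(6.0) * 180.16 == pytest.approx(6.0)


class TestPhenotypes:
    def test_ngt_is_identity(self, human):
        meta, env = human
        m2, e2 = apply_phenotype(meta, env, PHENOTYPES["NGT"])
        assert m2.lognormal == dict(meta.lognormal)
        assert e2 == env

    def test_igt_modifies_sensitivity_and_potentiation_only(self, human):
        meta, env = human
        m2, e2 = apply_phenotype(meta, env, PHENOTYPES["IGT"])
        assert e2.insulin_sensitivity == pytest.approx(1.4e-4 * 0.65)
        assert e2.hepatic_output == env.hepatic_output
        assert m2.lognormal["max_potentiation_rate"][0] == pytest.approx(6.5e-3 * 0.5)
        assert m2.lognormal["basal_packet"] == meta.lognormal["basal_packet"]

    def test_t2dm_scenarios(self, human):
        meta, env = human
        m2, e2 = apply_phenotype(meta, env, PHENOTYPES["T2DM"])
        assert e2.insulin_sensitivity == pytest.approx(1.4e-4 * 0.3)
        assert e2.hepatic_output == pytest.approx(0.016)
        assert m2.lognormal["max_potentiation_rate"][0] == pytest.approx(6.5e-3 * 0.05)
        assert m2.lognormal["basal_packet"][0] == pytest.approx(3e-3 * 0.3)
        assert m2.threshold_dist.half_activation == pytest.approx(9.7697)
        m3, _ = apply_phenotype(meta, env, PHENOTYPES["T2DM-shift"])
        assert m3.threshold_dist.half_activation == pytest.approx(4.0)

    def test_inputs_not_mutated(self, human):
        meta, env = human
        apply_phenotype(meta, env, PHENOTYPES["T2DM-shift"])
        assert meta.threshold_dist.half_activation == pytest.approx(9.7697)
        assert env.insulin_sensitivity == pytest.approx(1.4e-4)
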