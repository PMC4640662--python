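import math
from dataclasses import replace

import numpy as np
import pytest
from scipy.stats import kstest

from isletsim import (
    FiringUnitState,
    asymptotic_packet_size,
    sample_population,
    step_units,
)
from conftest import single_unit_params


def _fresh_state(params):
    return FiringUnitState(
        threshold=params.resting_threshold.copy(),
        packet=params.basal_packet.copy(),
        potentiation=params.basal_packet.copy(),
    )


class TestSampling:
    def test_zero_sd_gives_degenerate_parameter(self, human):
        meta, _ = human
        lognormal = dict(meta.lognormal)
        lognormal["recovery_rate"] = (0.3, 0.0)
        meta = replace(meta, lognormal=lognormal, n_units=500)
        pop = sample_population(meta, seed=0)
        assert np.all(pop.params.recovery_rate == 0.3)

    def test_threshold_samples_match_hill_cdf(self, human):
        meta, _ = human
        pop = sample_population(meta, seed=3)  # N = 1e5
        stat = kstest(pop.params.resting_threshold, meta.threshold_dist.cdf).statistic
        assert stat < 0.01

    def test_recovery_rate_moments(self, human):
        meta, _ = human
        pop = sample_population(meta, seed=4)
        mean, sd = meta.lognormal["recovery_rate"]
        se = sd / math.sqrt(meta.n_units)
        assert abs(pop.params.recovery_rate.mean() - mean) < 3 * se
        assert pop.params.recovery_rate.std() == pytest.approx(sd, rel=0.05)

    def test_packet_means_scale_with_unit_count(self, human):
        meta, _ = human
        small = sample_population(meta.with_units(20_000), seed=0)
        # n_ref stays 1e5: per-unit packets are 5x larger so organ total is fixed
        assert small.params.basal_packet.mean() == pytest.approx(
            5 * meta.lognormal["basal_packet"][0], rel=0.01
        )

    def test_reproducible_for_fixed_seed(self, human):
        meta, _ = human
        a = sample_population(meta.with_units(1000), seed=7)
        b = sample_population(meta.with_units(1000), seed=7)
        assert np.array_equal(a.params.resting_threshold, b.params.resting_threshold)
        assert np.array_equal(a.params.recovery_rate, b.params.recovery_rate)

    def test_negative_sd_rejected(self, human):
        meta, _ = human
        lognormal = dict(meta.lognormal)
        lognormal["recovery_rate"] = (0.3, -0.1)
        with pytest.raises(ValueError):
            replace(meta, lognormal=lognormal)

    def test_csv_roundtrip_columns(self, human):
        meta, _ = human
        pop = sample_population(meta.with_units(50), seed=0)
        df = pop.to_frame()
        assert list(df.columns[:9]) == ["G", "alpha", "R", "k", "Dbar", "rho", "Gamma", "gamma", "zeta"]
        assert len(df) == 50


class TestAsymptoticPacket:
    def test_zero_glucose_gives_basal_packet(self):
        p = single_unit_params()
        assert asymptotic_packet_size(p, 0.0)[0] == pytest.approx(3e-3)

    def test_saturation_limit(self):
        p = single_unit_params()
        expected = 6.5e-3 / 0.1 + 3e-3
        assert asymptotic_packet_size(p, 1e6)[0] == pytest.approx(expected, rel=1e-6)

    def test_reference_value_at_basal_glycemia(self):
        # rho/k * Gb^gamma/(Gb^gamma+Gamma^gamma) + Dbar at the human means
        p = single_unit_params()
        assert asymptotic_packet_size(p, 4.25)[0] == pytest.approx(3.036e-3, rel=1e-3)


class TestStepUnits:
    def test_subthreshold_releases_nothing_and_threshold_decays(self):
        p = single_unit_params()
        s = _fresh_state(p)
        s.threshold[0] = 10.0  # above resting, below glycemia? no: glycemia below it
        before = s.threshold[0]
        s, released, fired = step_units(s, p, g_now=5.0, g_delayed=5.0, dt=0.1)
        assert released == 0.0 and fired == 0
        assert s.threshold[0] < before
        assert s.threshold[0] > p.resting_threshold[0]

    def test_firing_releases_packet_and_resets(self):
        p = single_unit_params()
        s = _fresh_state(p)
        s.packet[0] = 5e-3
        s, released, fired = step_units(s, p, g_now=3.0, g_delayed=3.0, dt=0.1)
        assert fired == 1
        assert released == pytest.approx(5e-3)
        # post-state: threshold jumped to refractory then decayed one step
        assert s.threshold[0] > 900.0
        assert s.packet[0] < 5e-4  # emptied, then one step of refill

    def test_no_refire_while_refractory(self):
        p = single_unit_params()
        s = _fresh_state(p)
        step_units(s, p, 3.0, 3.0, 0.1)
        _, released, fired = step_units(s, p, 20.0, 20.0, 0.1)
        assert fired == 0 and released == 0.0

    def test_released_mass_bookkeeping(self, human):
        """Total released over a run equals the sum of packets at firing instants."""
        meta, _ = human
        pop = sample_population(meta.with_units(2000), seed=2)
        rng = np.random.default_rng(0)
        total = 0.0
        by_hand = 0.0
        for _ in range(300):
            g = rng.uniform(3.0, 12.0)
            eligible = g >= pop.state.threshold
            by_hand += pop.state.packet[eligible].sum()
            _, released, fired = step_units(pop.state, pop.params, g, g, 0.5)
            assert fired == int(eligible.sum())
            total += released
        assert total == pytest.approx(by_hand, rel=1e-12)

    def test_potentiation_stays_above_basal(self, human):
        meta, _ = human
        pop = sample_population(meta.with_units(2000), seed=5)
        for i in range(400):
            g = 6.0 + 4.0 * math.sin(i / 30.0)
            step_units(pop.state, pop.params, g, g, 0.5)
        assert np.all(pop.state.potentiation >= pop.params.basal_packet - 1e-12)

    def test_trajectories_converge_as_dt_shrinks(self):
        """Sub-threshold packet/potentiation trajectories converge ~linearly in dt."""
        p = single_unit_params(resting_threshold=50.0)  # never fires at g<=10

        def run(dt):
            s = _fresh_state(p)
            n = int(round(60.0 / dt))
            for i in range(n):
                g = 5.0 + 4.0 * math.sin(2 * math.pi * i * dt / 17.0)
                step_units(s, p, g, g, dt)
            return np.array([s.threshold[0], s.packet[0], s.potentiation[0]])

    # reference at a very fine step; error should shrink ~linearly
        ref = run(0.0125)
        err_coarse = np.abs(run(0.4) - ref).max()
        err_fine = np.abs(run(0.2) - ref).max()
        assert err_fine < 0.75 * err_coarse

    def test_periodic_firing_matches_closed_form_period(self):
        """Constant supra-basal glycemia: firing period = threshold decay time."""
        p = single_unit_params(resting_threshold=2.0, recovery_rate=0.3)
        g = 7.0
        dt = 0.1
        s = _fresh_state(p)
        fire_steps = []
        for i in range(4000):
            _, _, fired = step_units(s, p, g, g, dt)
            if fired:
                fire_steps.append(i)
        intervals = np.diff(fire_steps) * dt
        closed_form = math.log((1000.0 - 2.0) / (g - 2.0)) / 0.3
        assert np.all(np.abs(intervals - closed_form) <= dt + 1e-9)

    def test_nonfinite_state_rejected(self):
        p = single_unit_params()
        s = _fresh_state(p)
        s.packet[0] = math.nan
        with pytest.raises(FloatingPointError):
            step_units(s, p, 5.0, 5.0, 0.1)
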