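import math

import numpy as np
import pytest

from isletsim import (
    InVivoParams,
    InVivoState,
    insulin_mass_balance,
    make_enteral,
    ou_step,
    sample_population,
    saturate,
    simulate_in_vivo,
    step_environment,
    urinary_drive,
)
from isletsim.runner import RunConfig, run


class TestOuStep:
    def test_deterministic_decay_without_volatility(self):
        xi = 1.0
        dt = 0.01
        for _ in range(1000):
            xi = ou_step(xi, a=0.04, b=0.0, dt=dt, noise=0.0)
        assert xi == pytest.approx(math.exp(-0.04 * 10.0), rel=1e-3)

    def test_zero_is_fixed_point(self):
        assert ou_step(0.0, 0.04, 5.56e-4, 0.1, noise=0.0) == 0.0

    def test_stationary_variance(self):
        a, b, dt = 0.04, 5.56e-4, 0.1
        rng = np.random.default_rng(11)
        xi = 0.0
        xs = np.empty(100_000)
        for i in range(xs.size):
            xi = ou_step(xi, a, b, dt, rng.standard_normal())
            xs[i] = xi
        assert xs[5000:].var() == pytest.approx(b**2 / (2 * a), rel=0.10)


class TestPiecewiseTerms:
    @pytest.mark.parametrize(
        "x,expected", [(-6e-3, -5.56e-3), (0.0, 0.0), (0.05, 0.05), (0.2, 9.44e-2)]
    )
    def test_saturate(self, x, expected):
        assert saturate(x, -5.56e-3, 9.44e-2) == pytest.approx(expected)

    @pytest.mark.parametrize("g,expected", [(4.0, 0.0), (9.0, 0.0), (12.0, 3.0)])
    def test_urinary_drive(self, g, expected):
        assert urinary_drive(g, 9.0) == expected


class TestStepEnvironment:
    def test_hepatic_output_drives_glycemia_slope(self):
        """No insulin, no inputs, sub-renal glycemia: dG/dt = k3/V_G."""
        env = InVivoParams()
        state = InVivoState(glycemia=4.0, liver=np.zeros(1), insulin=0.0)
        step_environment(state, env, released=0.0, k_ex=0.0, v_ent=0.0, dt=0.1, noise=0.0)
        assert (state.glycemia - 4.0) / 0.1 == pytest.approx(0.05)

    def test_liver_steady_state_under_constant_release(self):
        env = InVivoParams()
        state = InVivoState(glycemia=4.25, liver=np.zeros(1), insulin=0.0)
        r = 2.0  # pmol/kgBW per minute
        dt = 0.005  # small enough that the impulse-injection bias O(dt) is negligible
        for _ in range(40000):
            step_environment(state, env, released=r * dt, k_ex=0.0, v_ent=0.0, dt=dt, noise=0.0)
        expected = r / (env.liver_transfer_rate + env.liver_clearance_rate)
        assert state.liver[0] == pytest.approx(expected, rel=0.01)

    def test_hepatic_extraction_fraction(self):
        """Long-run plasma share of released insulin = h_d/(h_d+h_x)."""
        env = InVivoParams()
        state = InVivoState(glycemia=4.25, liver=np.zeros(1), insulin=0.0)
        dt = 0.1
        plasma_in = 0.0
        released_total = 0.0
        for _ in range(40000):
            rel = 0.15
            plasma_in += env.liver_transfer_rate * (state.liver[0] + rel) * dt
            step_environment(state, env, rel, 0.0, 0.0, dt, 0.0)
            released_total += rel
        frac = plasma_in / released_total
        assert frac == pytest.approx(0.9 / 1.4, rel=1e-2)

    def test_glycemia_collapse_raises(self):
        env = InVivoParams()
        state = InVivoState(glycemia=0.01, liver=np.zeros(1), insulin=5e4)
        with pytest.raises(FloatingPointError):
            for _ in range(100):
                step_environment(state, env, 0.0, 0.0, 0.0, 1.0, 0.0)


@pytest.fixture(scope="module")
def basal_run(small_human_meta, human):
    _, env = human
    pop = sample_population(small_human_meta, seed=8)
    return simulate_in_vivo(pop, env, None, duration=240.0, seed=8, freeze_noise=True)


class TestClosedLoop:

    def test_insulin_mass_balance_closes(self, basal_run):
        bal = insulin_mass_balance(basal_run)
        rhs = bal["liver_loss"] + bal["plasma_clearance"] + bal["stored"]
        assert rhs == pytest.approx(bal["released"], rel=1e-10)

    def test_basal_regime_is_stationary_normoglycemic(self, basal_run):
        """After burn-in the noise-free loop sits in the normal fasting band."""
        g = basal_run.glycemia
        first, second = g[: len(g) // 2], g[len(g) // 2 :]
        assert abs(first.mean() - second.mean()) < 0.25
        assert 4.0 < g.mean() < 6.0

    def test_hepatic_production_respects_saturation_bounds(self, small_human_meta, human):
        _, env = human
        pop = sample_population(small_human_meta, seed=9)
        res = simulate_in_vivo(pop, env, None, duration=120.0, seed=9)
        k3_min, k3_max = res.extras["k3_range"]
        assert k3_min >= env.hepatic_output + env.sat_lower - 1e-15
        assert k3_max <= env.hepatic_output + env.sat_upper + 1e-15

    def test_glycemia_stays_positive_across_seeds(self, small_human_meta, human):
        _, env = human
        proto = make_enteral(0.035, 120.0)
        for seed in range(10):
            pop = sample_population(small_human_meta, seed=seed)
            res = simulate_in_vivo(
                pop, env, proto, duration=120.0, seed=seed, burn_in=120.0
            )
            assert np.all(res.glycemia > 0)

    def test_feeding_amplifies_slow_oscillations(self, small_human_meta, human):
        """Constant enteral input amplifies the spontaneous insulin oscillation."""
        _, env = human
        pop = sample_population(small_human_meta, seed=2)
        fed = simulate_in_vivo(pop, env, make_enteral(0.035, 480.0), duration=480.0, seed=2)
        pop = sample_population(small_human_meta, seed=2)
        ctl = simulate_in_vivo(pop, env, None, duration=480.0, seed=2)
        swing = lambda x: np.percentile(x, 95) - np.percentile(x, 5)
        assert swing(fed.insulin) > 2.0 * swing(ctl.insulin)

    def test_protocol_longer_than_run_rejected(self, small_human_meta, human):
        _, env = human
        pop = sample_population(small_human_meta, seed=0)
        with pytest.raises(ValueError):
            simulate_in_vivo(pop, env, make_enteral(0.035, 300.0), duration=100.0, seed=0)


class TestRunner:
    def test_same_config_same_seed_is_bit_identical(self, tmp_path):
        cfg = RunConfig(
            protocol="porksen", seed=5, n_units=5000, duration=30.0, burn_in=60.0,
            output=str(tmp_path / "a"),
        )
        run(cfg)
        cfg2 = RunConfig(
            protocol="porksen", seed=5, n_units=5000, duration=30.0, burn_in=60.0,
            output=str(tmp_path / "b"),
        )
        run(cfg2)
        assert (tmp_path / "a.csv").read_text() == (tmp_path / "b.csv").read_text()

    def test_unknown_protocol_rejected(self):
        with pytest.raises(ValueError):
            run(RunConfig(protocol="nonexistent"))

    def test_ivgtt_emits_23_point_schedule(self):
        cfg = RunConfig(protocol="ivgtt", phenotype="NGT", seed=1, n_units=5000, burn_in=60.0)
        _, metrics = run(cfg)
        assert len(metrics["schedule_samples"]["time_min"]) == 23
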