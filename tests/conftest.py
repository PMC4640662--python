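import numpy as np
import pytest

from isletsim import load_defaults, sample_population


@pytest.fixture(scope="session")
def human():
    return load_defaults("human")


@pytest.fixture(scope="session")
def rat():
    return load_defaults("rat")


@pytest.fixture(scope="session")
def small_human_meta(human):
    """Reduced population for fast closed-loop invariant checks."""
    meta, _ = human
    return meta.with_units(20_000)


@pytest.fixture()
def rat_population(rat):
    meta, _ = rat
    return sample_population(meta, seed=1)


def single_unit_params(**overrides):
    """One hand-built firing unit with round numbers."""
    from isletsim import FiringUnitParams

    defaults = dict(
        resting_threshold=2.0,
        refractory_threshold=1000.0,
        recovery_rate=0.3,
        packet_decay_rate=0.1,
        basal_packet=3e-3,
        max_potentiation_rate=6.5e-3,
        potentiation_half_glycemia=9.0,
        potentiation_steepness=10.0,
        packet_relaxation_rate=0.1,
    )
    defaults.update(overrides)
    return FiringUnitParams(**{k: np.array([v], dtype=float) for k, v in defaults.items()})
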