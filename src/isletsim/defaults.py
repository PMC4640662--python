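"""Reference parameter sets for the two experimental species.

``human`` pairs the population meta-parameters with the closed-loop in
vivo environment; ``rat`` pairs the (smaller, faster-recovering)
population used for perfused-pancreas work with the open-loop in vitro
chain.  The percent-activation table from which the threshold
distribution was identified ships as a small CSV fixture.

Note the published in vitro parameter listing quotes the portal transfer
rate twice (0.85 and 0.8); we adopt 0.85, the primary listing position.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .in_vitro import InVitroParams
from .in_vivo import InVivoParams
from .population import PopulationMeta
from .thresholds import ThresholdDistribution

__all__ = [
    "THRESHOLD_DISTRIBUTION",
    "HUMAN_META",
    "HUMAN_ENV",
    "RAT_META",
    "RAT_ENV",
    "load_defaults",
    "load_activation_table",
]

#: Hill-CDF threshold distribution identified from perfused-pancreas
#: percent-activation data (shared by both species).
THRESHOLD_DISTRIBUTION = ThresholdDistribution(hill_exponent=2.5137, half_activation=9.7697)

HUMAN_META = PopulationMeta(
    n_units=100_000,
    n_ref=100_000,
    glucose_delay=8.0,  # tau, min
    threshold_dist=THRESHOLD_DISTRIBUTION,
    lognormal={
        # (arithmetic mean, arithmetic sd)
        "recovery_rate": (0.3, 0.12),
        "refractory_threshold": (1000.0, 50.0),
        "packet_decay_rate": (0.1, 0.002),
        "basal_packet": (3e-3, 3.6e-5),
        "max_potentiation_rate": (6.5e-3, 2e-6),
        "potentiation_half_glycemia": (9.0, 0.1),
        "potentiation_steepness": (10.0, 0.1),
        "packet_relaxation_rate": (0.1, 0.02),
    },
)

HUMAN_ENV = InVivoParams()  # field defaults are the human values

RAT_META = PopulationMeta(
    n_units=10_000,
    n_ref=10_000,
    glucose_delay=0.0,
    threshold_dist=THRESHOLD_DISTRIBUTION,
    lognormal={
        "recovery_rate": (0.65, 0.4),
        "refractory_threshold": (1000.0, 50.0),
        "packet_decay_rate": (0.1, 0.002),
        "basal_packet": (0.09, 5e-4),
        "max_potentiation_rate": (3.2e-2, 2e-5),
        "potentiation_half_glycemia": (10.0, 0.1),
        "potentiation_steepness": (5.0, 0.05),
        "packet_relaxation_rate": (0.2, 0.02),
    },
)

RAT_ENV = InVitroParams(portal_transfer_rate=0.85, measurement_transfer_rate=4.8)


def load_defaults(species: str):
    """Default (population meta, environment params) for a species.

    ``human`` returns in vivo parameters, ``rat`` in vitro parameters.
    """
    if species == "human":
        return HUMAN_META, HUMAN_ENV
    if species == "rat":
        return RAT_META, RAT_ENV
    raise ValueError(f"unknown species {species!r}; expected 'human' or 'rat'")


def load_activation_table() -> np.ndarray:
    """Percent-activation points, shape (6, 2): (glycemia mg/dl, PA %)."""
    with resources.files("isletsim.data").joinpath("grodsky_activation.csv").open() as fh:
        df = pd.read_csv(fh)
    return df.to_numpy(dtype=float)
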