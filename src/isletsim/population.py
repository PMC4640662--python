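"""Heterogeneous population of insulin-secreting firing units.

Each unit is an independent excitable controller: it releases its whole
insulin packet the moment sensed glycemia reaches its threshold, jumps to
a refractory threshold and relaxes exponentially back to its resting
threshold, while the releasable packet refills toward a potentiation
level that itself grows under sustained (delayed) glucose exposure.

Unit parameters are stored columnwise in numpy arrays.  Resting
thresholds are drawn from the Hill-CDF :class:`~isletsim.thresholds.ThresholdDistribution`;
every other parameter is drawn from an independent log-normal whose
arithmetic mean and standard deviation are population meta-parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from . import _kernels
from .thresholds import ThresholdDistribution

__all__ = [
    "LOGNORMAL_PARAMS",
    "PopulationMeta",
    "FiringUnitParams",
    "FiringUnitState",
    "FiringUnitPopulation",
    "sample_population",
    "asymptotic_packet_size",
    "step_units",
]

#: parameters drawn log-normally, keyed by field name; values give the
#: short column label used in tabular output.
LOGNORMAL_PARAMS: Mapping[str, str] = {
    "recovery_rate": "alpha",
    "refractory_threshold": "R",
    "packet_decay_rate": "k",
    "basal_packet": "Dbar",
    "max_potentiation_rate": "rho",
    "potentiation_half_glycemia": "Gamma",
    "potentiation_steepness": "gamma",
    "packet_relaxation_rate": "zeta",
}

#: packet-size parameters whose population mean scales as n_ref/n_units so
#: the total insulin available from the organ is independent of how finely
#: it is discretized into units.
_PACKET_SIZE_PARAMS = ("basal_packet", "max_potentiation_rate")


@dataclass(frozen=True)
class PopulationMeta:
    """Meta-parameters defining the unit population.

    Attributes
    ----------
    n_units : number of simulated units N.
    n_ref : reference unit count at which the packet-size means
        (``basal_packet``, ``max_potentiation_rate``) are quoted; packet
        means are rescaled by ``n_ref / n_units`` at sampling time.
    glucose_delay : delay tau (min) with which the potentiation drive
        senses glycemia.
    threshold_dist : distribution of resting thresholds G_n.
    lognormal : per-parameter (arithmetic mean, arithmetic sd) pairs for
        the log-normally distributed unit parameters.
    """

    n_units: int
    n_ref: int
    glucose_delay: float
    threshold_dist: ThresholdDistribution
    lognormal: Mapping[str, tuple[float, float]]

    def __post_init__(self) -> None:
        if self.n_units < 1 or self.n_ref < 1:
            raise ValueError("n_units and n_ref must be >= 1")
        if self.glucose_delay < 0:
            raise ValueError("glucose_delay must be >= 0")
        missing = set(LOGNORMAL_PARAMS) - set(self.lognormal)
        if missing:
            raise ValueError(f"missing log-normal meta-parameters: {sorted(missing)}")
        for name, (mean, sd) in self.lognormal.items():
            if mean <= 0:
                raise ValueError(f"{name}: mean must be > 0")
            if sd < 0:
                raise ValueError(f"{name}: sd must be >= 0")

    def with_units(self, n_units: int) -> "PopulationMeta":
        """Same population at a different discretization level."""
        return replace(self, n_units=n_units)


@dataclass
class FiringUnitParams:
    """Per-unit parameter arrays (one entry per unit)."""

    resting_threshold: np.ndarray  # G_n, mM
    refractory_threshold: np.ndarray  # R_n, mM
    recovery_rate: np.ndarray  # alpha_n, 1/min
    packet_decay_rate: np.ndarray  # k_n, 1/min
    basal_packet: np.ndarray  # Dbar_n, pmol/kgBW
    max_potentiation_rate: np.ndarray  # rho_n, pmol/kgBW/min
    potentiation_half_glycemia: np.ndarray  # Gamma_n, mM
    potentiation_steepness: np.ndarray  # gamma_n
    packet_relaxation_rate: np.ndarray  # zeta_n, 1/min

    def __post_init__(self) -> None:
        if np.any(self.refractory_threshold <= self.resting_threshold):
            raise ValueError("refractory threshold must exceed resting threshold")

    @property
    def n_units(self) -> int:
        return self.resting_threshold.shape[0]


@dataclass
class FiringUnitState:
    """Per-unit dynamic state arrays."""

    threshold: np.ndarray  # B_n, mM
    packet: np.ndarray  # J_n, pmol/kgBW
    potentiation: np.ndarray  # D_n, pmol/kgBW

    def copy(self) -> "FiringUnitState":
        return FiringUnitState(
            self.threshold.copy(), self.packet.copy(), self.potentiation.copy()
        )


@dataclass
class FiringUnitPopulation:
    """Parameters, state and meta-parameters of a sampled population."""

    params: FiringUnitParams
    state: FiringUnitState
    meta: PopulationMeta

    @property
    def n_units(self) -> int:
        return self.params.n_units

    def reset_basal(self) -> None:
        """Return every unit to the zero-glucose basal state.

        Thresholds sit at their resting values and both the packet and the
        potentiation level equal the basal packet size (the configuration
        of a perfused pancreas before any stimulus).
        """
        self.state.threshold[:] = self.params.resting_threshold
        self.state.packet[:] = self.params.basal_packet
        self.state.potentiation[:] = self.params.basal_packet

    def to_frame(self) -> pd.DataFrame:
        """One row per unit, short column labels (G, R, alpha, ...)."""
        data = {"G": self.params.resting_threshold}
        for attr, label in LOGNORMAL_PARAMS.items():
            data[label] = getattr(self.params, attr)
        data["B"] = self.state.threshold
        data["J"] = self.state.packet
        data["D"] = self.state.potentiation
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _lognormal_from_moments(
    mean: float, sd: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Sample a log-normal specified by its arithmetic mean and sd.

    sd == 0 degenerates to a point mass at the mean.
    """
    if sd == 0.0:
        return np.full(n, mean)
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - 0.5 * sigma2
    return rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=n)


def sample_population(
    meta: PopulationMeta, seed: int | np.random.Generator | None = None
) -> FiringUnitPopulation:
    """Draw a population of firing units from its meta-parameters.

    Resting thresholds come from the Hill-CDF threshold distribution by
    inverse-CDF sampling; all other parameters are independent
    log-normals matched to the quoted arithmetic moments.  The packet-size
    means are scaled by ``n_ref / n_units`` so total available insulin is
    invariant to the number of units.  The initial state is the
    zero-glucose basal state (see :meth:`FiringUnitPopulation.reset_basal`).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = meta.n_units
    scale = meta.n_ref / meta.n_units

    g_n = meta.threshold_dist.sample(n, rng)

    drawn = {}
    for attr in LOGNORMAL_PARAMS:
        mean, sd = meta.lognormal[attr]
        if attr in _PACKET_SIZE_PARAMS:
            mean = mean * scale
        drawn[attr] = _lognormal_from_moments(mean, sd, n, rng)

    params = FiringUnitParams(resting_threshold=g_n, **drawn)
    pop = FiringUnitPopulation(
        params=params,
        state=FiringUnitState(
            threshold=g_n.copy(),
            packet=params.basal_packet.copy(),
            potentiation=params.basal_packet.copy(),
        ),
        meta=meta,
    )
    return pop


def asymptotic_packet_size(params: FiringUnitParams, basal_glycemia: float) -> np.ndarray:
    """Packet size each unit converges to under constant glycemia.

    At steady glycemia G_b the potentiation level settles at
    rho/k * G_b^gamma / (G_b^gamma + Gamma^gamma) + Dbar, and the packet
    follows it.  At zero glucose this is just the basal packet.
    """
    if basal_glycemia < 0:
        raise ValueError("basal glycemia must be >= 0")
    if basal_glycemia == 0.0:
        return params.basal_packet.copy()
    gam = params.potentiation_steepness
    # Hill term computed in log space: stable for large steepness values
    x = gam * (np.log(params.potentiation_half_glycemia) - np.log(basal_glycemia))
    hill = 1.0 / (1.0 + np.exp(np.clip(x, -50.0, 50.0)))
    return (
        params.max_potentiation_rate / params.packet_decay_rate * hill
        + params.basal_packet
    )


class _StepCache:
    """Per-dt precomputation for repeated stepping of one population."""

    def __init__(self, params: FiringUnitParams, dt: float):
        if dt <= 0:
            raise ValueError("dt must be > 0")
        self.dt = dt
        self.decay_threshold = np.exp(-params.recovery_rate * dt)
        self.decay_packet = np.exp(-params.packet_relaxation_rate * dt)
        self.decay_potentiation = np.exp(-params.packet_decay_rate * dt)
        self.ln_half_glycemia = np.log(params.potentiation_half_glycemia)
        self.loading_over_decay = (
            params.max_potentiation_rate / params.packet_decay_rate
        )

    def step(
        self,
        state: FiringUnitState,
        params: FiringUnitParams,
        g_now: float,
        g_delayed: float,
    ) -> tuple[float, int]:
        return _kernels.step_units_kernel(
            state.threshold,
            state.packet,
            state.potentiation,
            params.resting_threshold,
            params.refractory_threshold,
            self.decay_threshold,
            self.decay_packet,
            self.decay_potentiation,
            params.potentiation_steepness,
            self.ln_half_glycemia,
            self.loading_over_decay,
            params.basal_packet,
            float(g_now),
            float(g_delayed),
        )


def step_units(
    state: FiringUnitState,
    params: FiringUnitParams,
    g_now: float,
    g_delayed: float,
    dt: float,
) -> tuple[FiringUnitState, float, int]:
    """Advance the population one step of length dt (state updated in place).

    The firing set {n : g_now >= B_n} is evaluated on the start-of-step
    state; fired units contribute their packet to the released mass, jump
    to the refractory threshold and empty their packet, after which every
    unit's continuous dynamics advance by one step.  Returns the updated
    state, the total released insulin mass (pmol/kgBW) and the number of
    units that fired.
    """
    if not (
        np.all(np.isfinite(state.threshold))
        and np.all(np.isfinite(state.packet))
        and np.all(np.isfinite(state.potentiation))
    ):
        raise FloatingPointError("non-finite unit state")
    cache = _StepCache(params, dt)
    released, fired = cache.step(state, params, g_now, g_delayed)
    return state, released, fired
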