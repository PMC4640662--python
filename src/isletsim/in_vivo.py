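"""Closed-loop whole-body environment for the secretory-unit population.

Released insulin passes through a linear chain of liver compartments
(losing a fraction to hepatic clearance), enters the plasma insulin
distribution space, and stimulates tissue glucose uptake.  Glycemia is
driven by net hepatic glucose output (a bounded Ornstein-Uhlenbeck
fluctuation around a central value), insulin-dependent uptake,
supra-threshold renal elimination, splanchnic absorption of enteral feeds
and any exogenous IV infusion.  Glycemia in turn is the only signal the
secretory units sense, closing the metabolic loop.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .population import FiringUnitPopulation, _StepCache, asymptotic_packet_size
from .protocols import GlucoseProtocol
from .results import SimulationResult

__all__ = [
    "InVivoParams",
    "InVivoState",
    "ou_step",
    "saturate",
    "urinary_drive",
    "step_environment",
    "simulate_in_vivo",
    "insulin_mass_balance",
]


@dataclass(frozen=True)
class InVivoParams:
    """Whole-body metabolic and kinetic parameters (human scale).

    Units: rates 1/min, volumes l/kgBW, glycemias mM, hepatic output
    mmol/kgBW/min, insulin sensitivity 1/(min*pM).
    """

    liver_compartments: int = 1  # L
    liver_transfer_rate: float = 0.9  # h_d
    liver_clearance_rate: float = 0.5  # h_x
    insulin_clearance_rate: float = 0.08  # k4
    insulin_volume: float = 0.25  # V_I
    renal_elimination_rate: float = 8.57e-3  # k1
    renal_threshold: float = 9.0  # G_u, mM
    insulin_sensitivity: float = 1.4e-4  # k2
    hepatic_output: float = 0.01  # central k3, mmol/kgBW/min
    glucose_volume: float = 0.2  # V_G
    basal_glycemia: float = 4.25  # G_b, mM
    gut_absorption_rate: float = 0.03  # k_ga
    ou_reversion: float = 0.04  # a
    ou_volatility: float = 5.56e-4  # b, mmol/kgBW/min^{3/2}
    sat_lower: float = -5.56e-3  # m
    sat_upper: float = 9.44e-2  # M

    def __post_init__(self) -> None:
        if self.liver_compartments < 1:
            raise ValueError("need at least one liver compartment")
        if self.sat_lower >= self.sat_upper:
            raise ValueError("saturation bounds must satisfy lower < upper")
        for name in (
            "liver_transfer_rate",
            "liver_clearance_rate",
            "insulin_clearance_rate",
            "insulin_volume",
            "renal_elimination_rate",
            "renal_threshold",
            "insulin_sensitivity",
            "hepatic_output",
            "glucose_volume",
            "basal_glycemia",
            "gut_absorption_rate",
            "ou_reversion",
            "ou_volatility",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class InVivoState:
    """Environment compartment state."""

    glycemia: float  # G, mM
    liver: np.ndarray  # Q_1..Q_L, pmol/kgBW
    insulin: float  # I, pM
    gut_glucose: float = 0.0  # A, mmol/kgBW
    hepatic_noise: float = 0.0  # xi, mmol/kgBW/min

    def copy(self) -> "InVivoState":
        return InVivoState(
            self.glycemia, self.liver.copy(), self.insulin, self.gut_glucose, self.hepatic_noise
        )


def ou_step(xi: float, a: float, b: float, dt: float, noise: float) -> float:
    """One Euler-Maruyama step of the mean-reverting hepatic fluctuation.

    dxi = -a*xi*dt + b*dW; `noise` is a standard normal variate.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    return xi - a * xi * dt + b * math.sqrt(dt) * noise


def saturate(x: float, lower: float, upper: float) -> float:
    """Clip the hepatic fluctuation to its physiological range."""
    if lower >= upper:
        raise ValueError("need lower < upper")
    return min(max(x, lower), upper)


def urinary_drive(glycemia: float, renal_threshold: float) -> float:
    """Supra-threshold glycemia driving renal glucose elimination, mM."""
    if glycemia < 0:
        raise ValueError("glycemia must be >= 0")
    return max(0.0, glycemia - renal_threshold)


def step_environment(
    state: InVivoState,
    params: InVivoParams,
    released: float,
    k_ex: float,
    v_ent: float,
    dt: float,
    noise: float,
) -> InVivoState:
    """Advance the environment one explicit-Euler step (in place).

    The insulin mass released by the pancreas this step enters the first
    liver compartment as an impulse; all continuous derivatives are then
    evaluated on start-of-step values (post-impulse for the liver chain).
    ``k_ex`` and ``v_ent`` are the IV and enteral glucose rates
    (mmol/kgBW/min) over the step.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if released < 0:
        raise ValueError("released mass must be >= 0")
    p = params
    q = state.liver
    q[0] += released

    dq = -(p.liver_transfer_rate + p.liver_clearance_rate) * q
    if q.shape[0] > 1:
        dq[1:] += p.liver_transfer_rate * q[:-1]
    plasma_influx = p.liver_transfer_rate * q[-1] / p.insulin_volume

    k3 = p.hepatic_output + saturate(state.hepatic_noise, p.sat_lower, p.sat_upper)
    dg = (
        -p.renal_elimination_rate * urinary_drive(state.glycemia, p.renal_threshold)
        - p.insulin_sensitivity * state.insulin * state.glycemia
        + (k3 + p.gut_absorption_rate * state.gut_glucose + k_ex) / p.glucose_volume
    )
    da = -p.gut_absorption_rate * state.gut_glucose + v_ent
    di = -p.insulin_clearance_rate * state.insulin + plasma_influx

    q += dt * dq
    state.insulin += dt * di
    state.gut_glucose += dt * da
    state.glycemia += dt * dg
    state.hepatic_noise = ou_step(state.hepatic_noise, p.ou_reversion, p.ou_volatility, dt, noise)

    if state.glycemia <= 0 or not math.isfinite(state.glycemia):
        raise FloatingPointError("glycemia left (0, inf); reduce dt")
    return state


def simulate_in_vivo(
    population: FiringUnitPopulation,
    env: InVivoParams,
    protocol: GlucoseProtocol | None = None,
    duration: float = 90.0,
    dt: float = 0.1,
    seed: int | np.random.Generator | None = None,
    burn_in: float = 600.0,
    sample_dt: float = 1.0,
    freeze_noise: bool = False,
) -> SimulationResult:
    """Closed-loop simulation of a glucose administration protocol.

    The run starts from an analytic guess of the basal state (unit
    thresholds at rest, packets at their asymptotic size for basal
    glycemia, empty liver/plasma insulin stores) and first evolves the
    closed loop for ``burn_in`` minutes with no exogenous input, so the
    stochastic stationary regime is reached before protocol time 0.
    Glycemia, insulinemia (both sampled at bin starts), the binned
    insulin secretion rate and firing counts are then recorded every
    ``sample_dt`` minutes for ``duration`` minutes.

    ``freeze_noise=True`` zeroes the hepatic fluctuation (deterministic
    run, used for numerical checks).

    The population state is advanced in place; resample the population
    (or restore its state) before reusing it for another run.
    """
    if duration <= 0 or dt <= 0:
        raise ValueError("duration and dt must be > 0")
    if protocol is not None and protocol.t_end > duration + 1e-9:
        raise ValueError(
            f"protocol extends to t={protocol.t_end} beyond duration {duration}"
        )
    if protocol is not None and protocol.kind == "imposed-concentration":
        raise ValueError("imposed-concentration protocols belong to the in vitro setup")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    n_burn = round(burn_in / dt)
    n_steps = round(duration / dt)
    n_total = n_burn + n_steps
    sample_every = max(1, round(sample_dt / dt))
    n_samples = n_steps // sample_every

    # exogenous inputs, evaluated left-continuously on the step grid
    t_proto = np.arange(n_steps) * dt
    k_ex = np.zeros(n_steps)
    v_ent = np.zeros(n_steps)
    if protocol is not None:
        vals = protocol.values(t_proto)
        if protocol.kind == "iv-rate":
            k_ex = vals
        else:
            v_ent = vals

    if freeze_noise:
        noise = np.zeros(n_total)
        xi0 = 0.0
    else:
        noise = rng.standard_normal(n_total)
        # stationary distribution of the mean-reverting fluctuation
        xi0 = rng.normal(0.0, env.ou_volatility / math.sqrt(2.0 * env.ou_reversion))

    # basal initial conditions; the burn-in dissipates the remaining error
    pop = population
    pop.state.threshold[:] = pop.params.resting_threshold
    basal_packet = asymptotic_packet_size(pop.params, env.basal_glycemia)
    pop.state.packet[:] = basal_packet
    pop.state.potentiation[:] = basal_packet
    state = InVivoState(
        glycemia=env.basal_glycemia,
        liver=np.zeros(env.liver_compartments),
        insulin=0.0,
        gut_glucose=0.0,
        hepatic_noise=xi0,
    )

    stepper = _StepCache(pop.params, dt)
    delay_steps = pop.meta.glucose_delay / dt
    g_trace = np.empty(n_total)

    time = np.arange(n_samples) * sample_dt
    glycemia = np.zeros(n_samples)
    insulin = np.zeros(n_samples)
    isr = np.zeros(n_samples)
    firings = np.zeros(n_samples, dtype=np.int64)

    released_all = 0.0
    released_protocol = 0.0
    liver_loss = 0.0
    plasma_clearance = 0.0
    k3_min, k3_max = math.inf, -math.inf

    for i in range(n_total):
        g_now = state.glycemia
        g_trace[i] = g_now
        # delayed glycemia via the recorded trace (pre-history = basal)
        j = i - delay_steps
        if j < 0:
            g_delayed = env.basal_glycemia
        else:
            j0 = int(j)
            frac = j - j0
            if frac > 0.0 and j0 + 1 <= i:
                g_delayed = (1.0 - frac) * g_trace[j0] + frac * g_trace[j0 + 1]
            else:
                g_delayed = g_trace[j0]

        released, fired = stepper.step(pop.state, pop.params, g_now, g_delayed)
        released_all += released

        in_protocol = i >= n_burn
        ip = i - n_burn
        kex_i = k_ex[ip] if in_protocol else 0.0
        vent_i = v_ent[ip] if in_protocol else 0.0

        if in_protocol and ip % sample_every == 0 and ip // sample_every < n_samples:
            k = ip // sample_every
            glycemia[k] = g_now
            insulin[k] = state.insulin

        # ledger uses the same values as the Euler update (post-impulse
        # liver masses, start-of-step serum insulin), so the insulin mass
        # balance closes exactly
        liver_loss += env.liver_clearance_rate * (state.liver.sum() + released) * dt
        plasma_clearance += (
            env.insulin_clearance_rate * state.insulin * env.insulin_volume * dt
        )
        k3_now = env.hepatic_output + saturate(
            state.hepatic_noise, env.sat_lower, env.sat_upper
        )
        k3_min = min(k3_min, k3_now)
        k3_max = max(k3_max, k3_now)

        step_environment(state, env, released, kex_i, vent_i, dt, noise[i])

        if in_protocol:
            released_protocol += released
            k = ip // sample_every
            if k < n_samples:
                isr[k] += released / sample_dt
                firings[k] += fired

    extras = {
        "kind": "in_vivo",
        "dt": dt,
        "sample_dt": sample_dt,
        "burn_in": burn_in,
        "n_units": pop.n_units,
        "protocol": getattr(protocol, "name", None),
        "released_total": released_protocol,
        "released_all": released_all,
        "liver_loss": liver_loss,
        "plasma_clearance": plasma_clearance,
        "k3_range": (k3_min, k3_max),
        "final_state": state,
        "stored_liver": float(state.liver.sum()),
        "stored_plasma": state.insulin * env.insulin_volume,
    }
    return SimulationResult(time, glycemia, insulin, isr, firings, extras)


def insulin_mass_balance(result: SimulationResult) -> dict:
    """Insulin mass bookkeeping over a whole in vivo run (burn-in included).

    Under the stepping conventions above the identity

        released_all == liver_loss + plasma_clearance + stored

    holds to floating-point round-off (initial stores are empty).
    """
    e = result.extras
    return {
        "released": e["released_all"],
        "liver_loss": e["liver_loss"],
        "plasma_clearance": e["plasma_clearance"],
        "stored": e["stored_liver"] + e["stored_plasma"],
    }
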