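"""Reproducible experiment runner.

A :class:`RunConfig` names a species, a protocol (with overrides), the
population size, step sizes, duration and a single seed; :func:`run`
executes the simulation end to end and optionally writes a tidy
time-series CSV plus a flat JSON metrics report, both stamped with the
seed and a hash of the resolved configuration.

The global seed fans out to named substreams (population sampling,
environment noise, assay noise) so each stochastic component is
independently reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import analysis
from .conversions import mg_rate_to_mmol
from .defaults import load_defaults
from .in_vitro import simulate_in_vitro
from .in_vivo import simulate_in_vivo
from .population import sample_population
from .protocols import (
    PHENOTYPES,
    apply_phenotype,
    make_constant_iv,
    make_enteral,
    make_grodsky_protocols,
    make_ivgtt,
    make_pulsed,
    make_sinusoidal,
)
from .results import SimulationResult

__all__ = ["RunConfig", "run"]

#: protocol name -> (species, builder(args) -> (protocol, duration, schedule))
_GRODSKY_KEYS = {
    "grodsky1": "staircase",
    "grodsky3": "restimulation",
    "grodsky4": "ramp_hold",
    "grodsky5": "ramp",
}


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved description of one simulation run."""

    protocol: str
    species: str = ""  # inferred from the protocol when empty
    protocol_args: dict = field(default_factory=dict)
    phenotype: str | None = None
    n_units: int | None = None
    dt: float | None = None
    duration: float | None = None
    burn_in: float = 600.0
    sample_dt: float | None = None
    seed: int = 0
    output: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def digest(self) -> str:
        """Short hash of the resolved configuration (output path excluded)."""
        payload = {k: v for k, v in asdict(self).items() if k != "output"}
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _build_protocol(cfg: RunConfig):
    """Resolve (species, protocol, duration, sampling schedule)."""
    name, args = cfg.protocol, dict(cfg.protocol_args)
    if name in _GRODSKY_KEYS:
        proto = make_grodsky_protocols()[_GRODSKY_KEYS[name]]
        return "rat", proto, proto.t_end, None
    if name == "grodsky2":
        level = args.pop("level_mgdl", 300.0)
        protos = make_grodsky_protocols(constant_levels_mgdl=(level,))
        proto = protos["constant_levels"][0]
        return "rat", proto, proto.t_end, None
    if name == "simon":
        duration = cfg.duration or 1440.0
        rate = args.pop("rate", 0.035)  # mmol/kgBW/min
        return "human", make_enteral(rate, duration), duration, None
    if name == "sturis":
        duration = cfg.duration or 720.0
        k_bar = mg_rate_to_mmol(args.pop("mg_per_kg_min", 6.0))
        delta_frac = args.pop("delta_frac", 0.0)
        period = args.pop("period", 120.0)
        if delta_frac > 0:
            proto = make_sinusoidal(k_bar, delta_frac, period, duration)
        else:
            proto = make_constant_iv(k_bar, duration)
        return "human", proto, duration, None
    if name == "porksen":
        duration = cfg.duration or 90.0
        g_inf = mg_rate_to_mmol(args.pop("mg_per_kg_min", 6.0))
        proto = make_pulsed(
            g_inf,
            period=args.pop("period", 10.0),
            pulse_width=args.pop("pulse_width", 1.0),
            duration=duration,
        )
        return "human", proto, duration, None
    if name == "ivgtt":
        proto, schedule = make_ivgtt(
            dose_g_per_kg=args.pop("dose_g_per_kg", 0.36),
            infusion_minutes=args.pop("infusion_minutes", 3.0),
        )
        duration = cfg.duration or (float(schedule[-1]) + 1.0)
        return "human", proto, duration, schedule
    raise ValueError(f"unknown protocol {name!r}")


def _metrics(result: SimulationResult) -> dict:
    """Generic flat metrics report for one run."""
    dt = result.sample_dt
    pulses = analysis.detect_pulses(result.insulin, dt)
    out = {
        "glycemia_mean_mM": float(np.mean(result.glycemia)),
        "insulin_mean": float(np.mean(result.insulin)),
        "isr_mean_pmol_kg_min": float(np.mean(result.isr)),
        "firings_total": int(result.firings.sum()),
        "n_pulses": len(pulses),
        "mean_interpulse_min": float(np.mean(pulses.intervals)) if len(pulses) > 1 else None,
    }
    if result.time[-1] >= 360.0:
        period = analysis.estimate_period(result.insulin, dt, detrend_window=240.0)
        out["insulin_period_min"] = period
    return out


def run(cfg: RunConfig) -> tuple[SimulationResult, dict]:
    """Execute a configured run; write CSV/JSON when an output stem is set."""
    species, protocol, duration, schedule = _build_protocol(cfg)
    if cfg.species and cfg.species != species:
        raise ValueError(f"protocol {cfg.protocol} requires species {species!r}")
    meta, env = load_defaults(species)
    if cfg.phenotype is not None:
        if species != "human":
            raise ValueError("phenotype scenarios apply to in vivo (human) runs")
        try:
            scenario = PHENOTYPES[cfg.phenotype]
        except KeyError:
            raise ValueError(f"unknown phenotype {cfg.phenotype!r}") from None
        meta, env = apply_phenotype(meta, env, scenario)
    if cfg.n_units is not None:
        meta = meta.with_units(cfg.n_units)

    ss = np.random.SeedSequence(cfg.seed)
    rng_sample, rng_env, _rng_assay = (np.random.default_rng(s) for s in ss.spawn(3))
    population = sample_population(meta, rng_sample)

    if species == "rat":
        dt = cfg.dt or 0.5
        result = simulate_in_vitro(population, env, protocol, duration, dt=dt)
    else:
        dt = cfg.dt or 0.1
        result = simulate_in_vivo(
            population,
            env,
            protocol,
            duration,
            dt=dt,
            seed=rng_env,
            burn_in=cfg.burn_in,
            sample_dt=cfg.sample_dt or 1.0,
        )

    config_echo = {
        "config_hash": cfg.digest(),
        "seed": cfg.seed,
        "protocol": cfg.protocol,
        "species": species,
        "phenotype": cfg.phenotype,
        "n_units": population.n_units,
        "dt": dt,
    }
    result.extras["config"] = config_echo
    metrics = _metrics(result)
    metrics.update(config_echo)

    if schedule is not None:
        sampled = result.at_times(schedule)
        metrics["schedule_samples"] = sampled.to_dict(orient="list")

    if cfg.output:
        stem = Path(cfg.output)
        stem.parent.mkdir(parents=True, exist_ok=True)
        result.to_csv(stem.with_suffix(".csv"))
        with open(stem.with_suffix(".json"), "w") as fh:
            json.dump(metrics, fh, indent=2, default=float)
    return result, metrics
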