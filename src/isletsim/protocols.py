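"""Glucose administration protocols and phenotype scenarios.

A :class:`GlucoseProtocol` is a piecewise description of the exogenous
glucose input of an experiment.  Three kinds exist:

``imposed-concentration``
    perfusate glucose concentration (mM) imposed directly on an explanted
    pancreas (open loop);
``iv-rate``
    intravenous glucose infusion rate (mmol/kgBW/min) entering plasma;
``enteral-rate``
    enteral feeding rate (mmol/kgBW/min) entering the splanchnic
    absorption compartment.

Builders construct the classic experimental designs: staircase and
constant perfusions, stimulus removal/restimulation, ramps, constant and
sinusoidal IV infusions, brief periodic glucose pulses, the IVGTT bolus
and constant enteral feeding.  Protocols evaluate to 0 outside their
segments and are left-continuous (the value over [t, t+dt) is the value
at t).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .conversions import (
    GLUCOSE_MOLAR_MASS,
    kcal_to_enteral_rate,
    mg_rate_to_mmol,
    mgdl_to_mm,
    rate_to_cc_per_hr,
)

__all__ = [
    "Segment",
    "GlucoseProtocol",
    "PhenotypeScenario",
    "PHENOTYPES",
    "IVGTT_SAMPLING_MINUTES",
    "make_grodsky_protocols",
    "make_sinusoidal",
    "make_pulsed",
    "make_constant_iv",
    "make_enteral",
    "make_ivgtt",
    "apply_phenotype",
    "kcal_to_enteral_rate",
    "rate_to_cc_per_hr",
]

_SHAPES = ("constant", "ramp", "sinusoid", "pulse-train")
_KINDS = ("imposed-concentration", "iv-rate", "enteral-rate")


@dataclass(frozen=True)
class Segment:
    """One piece of a protocol: a shape active on [t_start, t_end)."""

    t_start: float
    t_end: float
    shape: str
    params: dict

    def __post_init__(self) -> None:
        if self.shape not in _SHAPES:
            raise ValueError(f"unknown shape {self.shape!r}")
        if self.t_start < 0 or self.t_end <= self.t_start:
            raise ValueError("need 0 <= t_start < t_end")

    def values(self, t: np.ndarray) -> np.ndarray:
        """Evaluate the shape at times t (no support masking)."""
        rel = t - self.t_start
        p = self.params
        if self.shape == "constant":
            return np.full_like(t, p["value"], dtype=float)
        if self.shape == "ramp":
            width = self.t_end - self.t_start
            frac = np.clip(rel / width, 0.0, 1.0)
            return p["start"] + (p["stop"] - p["start"]) * frac
        if self.shape == "sinusoid":
            return p["mean"] + p["amplitude"] * np.sin(2.0 * math.pi * rel / p["period"])
        # pulse-train: on for the first `width` minutes of every period
        phase = np.mod(rel, p["period"])
        return np.where(phase < p["width"], p["rate"], 0.0)


@dataclass(frozen=True)
class GlucoseProtocol:
    """Piecewise exogenous glucose input with explicit units."""

    kind: str
    segments: tuple[Segment, ...]
    name: str = ""

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown protocol kind {self.kind!r}")
        segs = tuple(sorted(self.segments, key=lambda s: s.t_start))
        object.__setattr__(self, "segments", segs)
        for a, b in zip(segs, segs[1:]):
            if b.t_start < a.t_end - 1e-12:
                raise ValueError("protocol segments overlap")

    @property
    def t_end(self) -> float:
        return self.segments[-1].t_end if self.segments else 0.0

    def values(self, t) -> np.ndarray:
        """Evaluate the input at times t (0 outside all segments).

        Negative values are rejected: every protocol is a nonnegative
        concentration or rate.
        """
        t = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.zeros_like(t)
        for seg in self.segments:
            mask = (t >= seg.t_start) & (t < seg.t_end)
            if mask.any():
                out[mask] = seg.values(t[mask])
        if np.any(out < 0):
            raise ValueError("protocol evaluates to a negative value")
        return out

    def value(self, t: float) -> float:
        return float(self.values(np.array([t]))[0])


# ---------------------------------------------------------------------------
# perfused-pancreas (imposed concentration) protocols


def _imposed(segments, name):
    return GlucoseProtocol("imposed-concentration", tuple(segments), name=name)


def make_grodsky_protocols(
    *,
    staircase_levels_mgdl: Sequence[float] = (50.0, 100.0, 150.0, 200.0),
    staircase_step_min: float = 5.0,
    constant_levels_mgdl: Sequence[float] = (50.0, 100.0, 150.0, 200.0, 300.0, 500.0),
    constant_duration: float = 60.0,
    restim_level_mgdl: float = 300.0,
    restim_on: float = 60.0,
    restim_off: float = 5.0,
    restim_second: float = 30.0,
    ramp_hold_peak_mgdl: float = 150.0,
    ramp_hold_rise: float = 40.0,
    ramp_hold_plateau: float = 30.0,
    ramp_peak_mgdl: float = 500.0,
    ramp_duration: float = 60.0,
) -> dict:
    """The five classic perfused-pancreas designs.

    Returns a dict with keys ``staircase``, ``constant_levels`` (a list,
    one protocol per level), ``restimulation``, ``ramp_hold`` and
    ``ramp``.  Glucose levels are given in mg/dl and converted to mM
    internally.  The ramp slopes/durations are configurable because the
    original reports give only the qualitative design.
    """
    stairs = [
        Segment(
            i * staircase_step_min,
            (i + 1) * staircase_step_min,
            "constant",
            {"value": mgdl_to_mm(level)},
        )
        for i, level in enumerate(staircase_levels_mgdl)
    ]
    constants = [
        _imposed(
            [Segment(0.0, constant_duration, "constant", {"value": mgdl_to_mm(lvl)})],
            name=f"constant_{lvl:g}mgdl",
        )
        for lvl in constant_levels_mgdl
    ]
    restim = [
        Segment(0.0, restim_on, "constant", {"value": mgdl_to_mm(restim_level_mgdl)}),
        # stimulus removed: concentration 0 on [restim_on, restim_on+restim_off)
        Segment(
            restim_on + restim_off,
            restim_on + restim_off + restim_second,
            "constant",
            {"value": mgdl_to_mm(restim_level_mgdl)},
        ),
    ]
    ramp_hold = [
        Segment(
            0.0,
            ramp_hold_rise,
            "ramp",
            {"start": 0.0, "stop": mgdl_to_mm(ramp_hold_peak_mgdl)},
        ),
        Segment(
            ramp_hold_rise,
            ramp_hold_rise + ramp_hold_plateau,
            "constant",
            {"value": mgdl_to_mm(ramp_hold_peak_mgdl)},
        ),
    ]
    ramp = [
        Segment(0.0, ramp_duration, "ramp", {"start": 0.0, "stop": mgdl_to_mm(ramp_peak_mgdl)})
    ]
    return {
        "staircase": _imposed(stairs, "staircase"),
        "constant_levels": constants,
        "restimulation": _imposed(restim, "restimulation"),
        "ramp_hold": _imposed(ramp_hold, "ramp_hold"),
        "ramp": _imposed(ramp, "ramp"),
    }


# ---------------------------------------------------------------------------
# in vivo (rate) protocols


def make_constant_iv(rate: float, duration: float, name: str = "constant_iv") -> GlucoseProtocol:
    """Constant IV glucose infusion at `rate` mmol/kgBW/min."""
    return GlucoseProtocol(
        "iv-rate", (Segment(0.0, duration, "constant", {"value": rate}),), name=name
    )


def make_sinusoidal(
    k_ex_bar: float, delta_frac: float, period: float, duration: float | None = None
) -> GlucoseProtocol:
    """Sinusoidally modulated IV infusion.

    rate(t) = k_ex_bar * (1 + delta_frac * sin(2*pi*t/period)), in
    mmol/kgBW/min.  ``delta_frac`` in [0, 1) keeps the rate nonnegative.
    """
    if not 0.0 <= delta_frac < 1.0:
        raise ValueError("delta_frac must lie in [0, 1)")
    if duration is None:
        duration = 10.0 * period
    seg = Segment(
        0.0,
        duration,
        "sinusoid",
        {"mean": k_ex_bar, "amplitude": delta_frac * k_ex_bar, "period": period},
    )
    return GlucoseProtocol("iv-rate", (seg,), name="sinusoidal_iv")


def make_pulsed(
    g_inf: float, period: float = 10.0, pulse_width: float = 1.0, duration: float = 90.0
) -> GlucoseProtocol:
    """Brief periodic IV glucose pulses.

    Infusion at ``g_inf`` mmol/kgBW/min during the first ``pulse_width``
    minutes of every ``period``-minute cycle, 0 otherwise.
    """
    if not 0.0 < pulse_width < period:
        raise ValueError("need 0 < pulse_width < period")
    if g_inf == 0.0:
        return GlucoseProtocol("iv-rate", (), name="pulsed_iv")
    seg = Segment(
        0.0, duration, "pulse-train", {"rate": g_inf, "period": period, "width": pulse_width}
    )
    return GlucoseProtocol("iv-rate", (seg,), name="pulsed_iv")


def make_enteral(rate: float, duration: float) -> GlucoseProtocol:
    """Constant enteral feeding at `rate` mmol/kgBW/min."""
    return GlucoseProtocol(
        "enteral-rate", (Segment(0.0, duration, "constant", {"value": rate}),), name="enteral"
    )


#: standard IVGTT sampling schedule (minutes relative to the bolus)
IVGTT_SAMPLING_MINUTES: tuple[float, ...] = (
    -30, -15, 0, 2, 4, 6, 8, 10, 12, 15, 20, 25, 30, 35, 40, 50, 60, 80, 100, 120, 140, 160, 180,
)


def make_ivgtt(
    dose_g_per_kg: float = 0.36,
    infusion_minutes: float = 3.0,
    lead_in: float = 30.0,
) -> tuple[GlucoseProtocol, np.ndarray]:
    """IVGTT bolus protocol plus its sampling schedule.

    The bolus (g glucose / kg body weight) is delivered as a constant IV
    rate over ``infusion_minutes`` (rapid injection, 1-4 min) starting at
    ``lead_in`` minutes, so the standard -30' and -15' pre-bolus samples
    fall inside the simulated window.  Returns the protocol and the
    23-point sampling grid in absolute simulation minutes.
    """
    if not 1.0 <= infusion_minutes <= 4.0:
        raise ValueError("infusion must last between 1 and 4 minutes")
    if lead_in < 30.0:
        raise ValueError("lead-in must cover the -30' pre-bolus sample")
    schedule = lead_in + np.asarray(IVGTT_SAMPLING_MINUTES, dtype=float)
    if dose_g_per_kg == 0.0:
        return GlucoseProtocol("iv-rate", (), name="ivgtt"), schedule
    rate = dose_g_per_kg * 1000.0 / GLUCOSE_MOLAR_MASS / infusion_minutes
    seg = Segment(lead_in, lead_in + infusion_minutes, "constant", {"value": rate})
    return GlucoseProtocol("iv-rate", (seg,), name="ivgtt"), schedule


# ---------------------------------------------------------------------------
# phenotype scenarios


@dataclass(frozen=True)
class PhenotypeScenario:
    """Multiplicative parameter modifications defining a glucose-tolerance state.

    Factors multiply the normal-subject values of peripheral insulin
    sensitivity (k2), central hepatic glucose output, and the population
    means of the maximal potentiation rate and basal packet size.  An
    optional override moves the half-activation glycemia of the threshold
    distribution (a left shift recruits units at lower glycemias).
    """

    name: str
    insulin_sensitivity_factor: float = 1.0
    hepatic_output_factor: float = 1.0
    potentiation_rate_factor: float = 1.0
    basal_packet_factor: float = 1.0
    half_activation_override: float | None = None

    def __post_init__(self) -> None:
        for f in (
            self.insulin_sensitivity_factor,
            self.hepatic_output_factor,
            self.potentiation_rate_factor,
            self.basal_packet_factor,
        ):
            if f <= 0:
                raise ValueError("phenotype factors must be > 0")


PHENOTYPES: dict[str, PhenotypeScenario] = {
    "NGT": PhenotypeScenario("NGT"),
    "IFG": PhenotypeScenario(
        "IFG", hepatic_output_factor=1.6, potentiation_rate_factor=0.5
    ),
    "IGT": PhenotypeScenario(
        "IGT", insulin_sensitivity_factor=0.65, potentiation_rate_factor=0.5
    ),
    "IFG+IGT": PhenotypeScenario(
        "IFG+IGT",
        insulin_sensitivity_factor=0.65,
        hepatic_output_factor=1.6,
        potentiation_rate_factor=0.25,
    ),
    "T2DM": PhenotypeScenario(
        "T2DM",
        insulin_sensitivity_factor=0.3,
        hepatic_output_factor=1.6,
        potentiation_rate_factor=0.05,
        basal_packet_factor=0.3,
    ),
    # same secretory/metabolic defects plus a left shift of the threshold
    # distribution (faster, more complete recruitment at lower glycemia,
    # suppressing the first-phase response)
    "T2DM-shift": PhenotypeScenario(
        "T2DM-shift",
        insulin_sensitivity_factor=0.3,
        hepatic_output_factor=1.6,
        potentiation_rate_factor=0.05,
        basal_packet_factor=0.3,
        half_activation_override=4.0,
    ),
}


def apply_phenotype(meta, env_params, scenario: PhenotypeScenario):
    """Return (population meta, in vivo params) modified per the scenario.

    Population means of the packet-size parameters are scaled (standard
    deviations are left untouched), the environment's insulin sensitivity
    and central hepatic output are scaled, and the threshold
    distribution's half-activation glycemia is replaced if the scenario
    overrides it.  Inputs are not mutated.
    """
    lognormal = dict(meta.lognormal)
    mean, sd = lognormal["max_potentiation_rate"]
    lognormal["max_potentiation_rate"] = (mean * scenario.potentiation_rate_factor, sd)
    mean, sd = lognormal["basal_packet"]
    lognormal["basal_packet"] = (mean * scenario.basal_packet_factor, sd)

    dist = meta.threshold_dist
    if scenario.half_activation_override is not None:
        dist = replace(dist, half_activation=scenario.half_activation_override)

    new_meta = replace(meta, lognormal=lognormal, threshold_dist=dist)
    new_env = replace(
        env_params,
        insulin_sensitivity=env_params.insulin_sensitivity
        * scenario.insulin_sensitivity_factor,
        hepatic_output=env_params.hepatic_output * scenario.hepatic_output_factor,
    )
    return new_meta, new_env
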