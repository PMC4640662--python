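"""Unit conversions used throughout the simulator.

Glycemia is carried internally in mM, insulin rates in pmol/kgBW/min and
glucose rates in mmol/kgBW/min.  Experimental protocols from the clinical
literature are usually quoted in mg/dl (concentrations), mg/kgBW/min
(infusion rates), kcal/h (enteral feeding) or cc/hr (pump settings); the
helpers below own those conversions so no magic factor appears anywhere
else in the package.
"""

from __future__ import annotations

#: mg/dl of glucose per mM (molar mass 180.16 g/mol / 10)
MGDL_PER_MM = 18.016

#: molar mass of glucose, g/mol
GLUCOSE_MOLAR_MASS = 180.16

#: metabolizable energy of glucose, kcal/g
KCAL_PER_G_GLUCOSE = 4.0


def mgdl_to_mm(mg_dl: float) -> float:
    """Convert a glucose concentration from mg/dl to mM."""
    return mg_dl / MGDL_PER_MM


def mm_to_mgdl(mm: float) -> float:
    """Convert a glucose concentration from mM to mg/dl."""
    return mm * MGDL_PER_MM


def mg_rate_to_mmol(mg_per_kg_min: float) -> float:
    """Convert a glucose infusion rate from mg/kgBW/min to mmol/kgBW/min."""
    return mg_per_kg_min / GLUCOSE_MOLAR_MASS


def kcal_to_enteral_rate(kcal_per_h: float, body_weight_kg: float) -> float:
    """Glucose-equivalent enteral infusion rate, mmol/kgBW/min.

    All administered calories are treated as (possibly delayed) glucose at
    4 kcal/g: nutrients that are not carbohydrate either provide glucose
    via gluconeogenesis or spare glucose oxidation.

    Parameters
    ----------
    kcal_per_h : caloric administration rate of the enteral feed.
    body_weight_kg : subject body weight.
    """
    if kcal_per_h < 0 or body_weight_kg <= 0:
        raise ValueError("kcal rate must be >= 0 and body weight > 0")
    g_per_min = kcal_per_h / KCAL_PER_G_GLUCOSE / 60.0
    mg_per_kg_min = g_per_min * 1000.0 / body_weight_kg
    return mg_rate_to_mmol(mg_per_kg_min)


def rate_to_cc_per_hr(
    mg_per_kg_min: float, body_weight_kg: float, solution_g_per_cc: float = 0.2
) -> float:
    """Pump setting (cc/hr) equivalent to a mass infusion rate.

    With the default 20% glucose solution, 6 mg/kgBW/min for a 70 kg
    subject corresponds to 126 cc/hr.
    """
    if body_weight_kg <= 0 or solution_g_per_cc <= 0:
        raise ValueError("body weight and solution strength must be positive")
    g_per_hr = mg_per_kg_min * body_weight_kg * 60.0 / 1000.0
    return g_per_hr / solution_g_per_cc
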