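"""Resting-threshold distribution of the secretory units.

The fraction of secretory units recruited at a given glycemia follows a
Hill-shaped cumulative distribution

    F(g) = g**nu / (g_half**nu + g**nu),

so ``g_half`` is the glycemia at which half of the units have fired at
least once and ``nu`` controls how sharply recruitment progresses.  The
two parameters are identified by ordinary least squares from
percent-activation data measured at the onset of constant glucose steps
in the perfused pancreas (the initial spike at each glucose level is
attributed to every unit whose resting threshold lies below that level).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .conversions import mgdl_to_mm

__all__ = ["ThresholdDistribution", "fit_threshold_cdf"]


@dataclass(frozen=True)
class ThresholdDistribution:
    """Hill-CDF distribution of resting firing thresholds.

    Parameters
    ----------
    hill_exponent : dimensionless steepness (nu > 0).
    half_activation : glycemia at 50% recruitment, mM (> 0).
    """

    hill_exponent: float
    half_activation: float

    def __post_init__(self) -> None:
        if not (self.hill_exponent > 0 and self.half_activation > 0):
            raise ValueError("hill_exponent and half_activation must be > 0")

    def cdf(self, g):
        """Fraction of units with resting threshold <= g (g in mM, >= 0)."""
        g = np.asarray(g, dtype=float)
        if np.any(g < 0):
            raise ValueError("glycemia must be non-negative")
        nu, gh = self.hill_exponent, self.half_activation
        with np.errstate(divide="ignore", over="ignore"):
            # 1 / (1 + (gh/g)**nu) is stable for large g; handles g=0 -> 0
            out = np.where(g > 0, 1.0 / (1.0 + (gh / np.where(g > 0, g, 1.0)) ** nu), 0.0)
        return out if out.ndim else float(out)

    def pdf(self, g):
        """Probability density of resting thresholds, 1/mM."""
        g = np.asarray(g, dtype=float)
        if np.any(g < 0):
            raise ValueError("glycemia must be non-negative")
        nu, gh = self.hill_exponent, self.half_activation
        num = nu * gh**nu * np.power(g, nu - 1.0, where=g > 0, out=np.zeros_like(g))
        out = np.where(g > 0, num / (g**nu + gh**nu) ** 2, 0.0)
        return out if out.ndim else float(out)

    def ppf(self, q):
        """Inverse CDF: threshold below which a fraction q of units lies."""
        q = np.asarray(q, dtype=float)
        if np.any((q < 0) | (q >= 1)):
            raise ValueError("quantile must lie in [0, 1)")
        nu, gh = self.hill_exponent, self.half_activation
        out = gh * (q / (1.0 - q)) ** (1.0 / nu)
        return out if out.ndim else float(out)

    def sample(
        self,
        n: int,
        rng: np.random.Generator,
        lower: float = 0.1,
        upper: float = 100.0,
    ) -> np.ndarray:
        """Draw n thresholds by inverse-CDF sampling, truncated to (lower, upper).

        Truncation discards the pathological tails of the heavy-tailed Hill
        distribution (sub-0.1 mM and supra-100 mM thresholds are
        physiologically meaningless).
        """
        qlo = self.cdf(lower)
        qhi = self.cdf(upper)
        u = rng.uniform(qlo, qhi, size=n)
        return self.ppf(u)


def fit_threshold_cdf(
    points: Iterable[Sequence[float]] | np.ndarray,
) -> ThresholdDistribution:
    """Fit the Hill CDF to (glycemia mg/dl, percent activation) pairs.

    Minimizes the unweighted sum of squared residuals between F(g) and
    PA/100, with glycemias converted to mM.  At least three points with
    distinct glycemias and non-constant activation are required for the
    two-parameter fit to be identifiable.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (glycemia mg/dl, percent activation) pairs")
    g_mgdl, pa = pts[:, 0], pts[:, 1]
    if np.any((pa < 0) | (pa > 100)):
        raise ValueError("percent activation must lie in [0, 100]")
    if len(np.unique(g_mgdl)) < 3:
        raise ValueError("need at least 3 distinct glycemias to identify the fit")
    if np.allclose(pa, pa[0]):
        raise ValueError("constant activation: fit is unidentifiable")

    g = mgdl_to_mm(g_mgdl)
    frac = pa / 100.0

    def hill(g, nu, gh):
        return g**nu / (gh**nu + g**nu)

    # start near the middle of the plausible range; the surface is smooth
    (nu, gh), _ = curve_fit(
        hill, g, frac, p0=(2.0, np.median(g)), bounds=([0.1, 0.1], [50.0, 100.0])
    )
    return ThresholdDistribution(hill_exponent=float(nu), half_activation=float(gh))
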