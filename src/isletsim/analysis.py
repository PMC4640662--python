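"""Post-processing of simulated hormone time series.

Assay-noise injection and the three-point moving-average filter mirror
how clinical studies preprocess sampled glycemia/insulinemia; pulse
detection, period estimation and the entrainment ratio quantify the
oscillation and entrainment phenomena; phase metrics summarize the
biphasic secretory response to a glucose step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "PulseSet",
    "PhaseMetrics",
    "add_assay_noise",
    "moving_average_3",
    "detect_pulses",
    "estimate_period",
    "entrainment_ratio",
    "phase_metrics",
]


@dataclass(frozen=True)
class PulseSet:
    """Detected pulses of a uniformly sampled series."""

    times: np.ndarray  # peak times, min (strictly increasing)
    heights: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("pulse times must be strictly increasing")

    @property
    def intervals(self) -> np.ndarray:
        """Inter-peak intervals, min."""
        return np.diff(self.times)

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class PhaseMetrics:
    """First/second-phase summary of a secretory response to a step."""

    first_phase_peak: float
    peak_time: float
    nadir: float
    nadir_time: float
    second_phase_slope: float
    degenerate: bool = False


def add_assay_noise(
    series: np.ndarray, cv: float, seed: int | np.random.Generator | None = None
) -> np.ndarray:
    """Multiplicative Gaussian assay noise: value * (1 + cv*z), floored at 0.

    ``cv`` is the intra-assay coefficient of variation (e.g. 0.01 for
    glycemia, 0.058 for insulinemia assays).
    """
    if cv < 0:
        raise ValueError("cv must be >= 0")
    series = np.asarray(series, dtype=float)
    if cv == 0.0:
        return series.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    noisy = series * (1.0 + cv * rng.standard_normal(series.shape))
    return np.maximum(noisy, 0.0)


def moving_average_3(series: np.ndarray) -> np.ndarray:
    """Centered three-point moving average; endpoints copied unchanged."""
    series = np.asarray(series, dtype=float)
    if series.size < 3:
        raise ValueError("need at least 3 samples")
    out = series.copy()
    out[1:-1] = (series[:-2] + series[1:-1] + series[2:]) / 3.0
    return out


def _moving_mean(series: np.ndarray, window: int) -> np.ndarray:
    """Centered moving mean with edge correction (shrinking window)."""
    kernel = np.ones(window)
    summed = np.convolve(series, kernel, mode="same")
    counts = np.convolve(np.ones(series.size), kernel, mode="same")
    return summed / counts


def detect_pulses(
    series: np.ndarray,
    dt: float,
    min_prominence_frac: float = 0.5,
    detrend_window: float | None = None,
) -> PulseSet:
    """Local maxima with prominence >= frac * series standard deviation.

    When pulses of interest ride a slower trend (e.g. fast insulin pulses
    on top of an ultradian swing), pass ``detrend_window`` (minutes,
    several pulse periods wide): peaks are then located on the series
    minus its centered moving mean, so pulses on the falling flank of the
    slow component are not masked.  The prominence scale always refers to
    the standard deviation of the series as given — a pulse counts only
    if it stands out against the overall signal variability, not merely
    against the detrended residual.  Deterministic given the input; a
    constant series yields no pulses.
    """
    series = np.asarray(series, dtype=float)
    if dt <= 0:
        raise ValueError("dt must be > 0")
    sd = float(np.std(series))
    if sd == 0.0:
        return PulseSet(np.array([]), np.array([]))
    search = series
    if detrend_window is not None:
        win = max(3, int(round(detrend_window / dt)) | 1)
        search = series - _moving_mean(series, win)
    idx, _ = find_peaks(search, prominence=min_prominence_frac * sd)
    return PulseSet(times=idx * dt, heights=series[idx])


def estimate_period(
    series: np.ndarray,
    dt: float,
    detrend_window: float = 60.0,
    min_prominence: float = 0.2,
) -> float | None:
    """Dominant period as the lag of the strongest prominent autocorrelation peak.

    The series is detrended by subtracting a centered moving mean of
    ``detrend_window`` minutes (choose a window comfortably longer than
    the period of interest), the autocorrelation is normalized to 1 at
    lag 0, and the first local maximum with prominence >=
    ``min_prominence`` is reported.  Give the estimator several cycles
    (ten or more) of data: with few cycles the prominence of a noisy
    oscillation's one-cycle peak sits near the white-noise floor.
    Returns None when no significant period exists (e.g. white noise).
    Invariant to affine transforms of the series.
    """
    series = np.asarray(series, dtype=float)
    if dt <= 0:
        raise ValueError("dt must be > 0")
    n = series.size
    win = max(3, int(round(detrend_window / dt)) | 1)  # odd window
    if n < 2 * win:
        raise ValueError("series too short for the detrending window")
    x = series - _moving_mean(series, win)
    x = x - x.mean()
    if np.allclose(x, 0.0):
        return None
    acf = np.correlate(x, x, mode="full")[n - 1 :]
    acf /= acf[0]
    max_lag = n // 2
    peaks, _ = find_peaks(acf[:max_lag], prominence=min_prominence)
    if peaks.size == 0:
        return None
    return float(peaks[0] * dt)


def entrainment_ratio(
    pulses: PulseSet, forcing_period: float, duration: float | None = None, t0: float = 0.0
) -> float:
    """Fraction of forcing periods containing exactly one pulse.

    Windows are [t0 + k*T, t0 + (k+1)*T) for k = 0.. covering
    ``duration`` (default: up to the last pulse).  1 means perfect 1:1
    entrainment; uncorrelated pulsing scores well below 1.
    """
    if forcing_period <= 0:
        raise ValueError("forcing period must be > 0")
    if len(pulses) == 0:
        return 0.0
    if duration is None:
        duration = float(pulses.times[-1]) - t0 + forcing_period
    n_windows = int(duration // forcing_period)
    if n_windows == 0:
        return 0.0
    window_idx = ((pulses.times - t0) // forcing_period).astype(int)
    window_idx = window_idx[(window_idx >= 0) & (window_idx < n_windows)]
    counts = np.bincount(window_idx, minlength=n_windows)
    return float(np.mean(counts == 1))


def phase_metrics(
    isr: np.ndarray,
    dt: float,
    onset_time: float = 0.0,
    peak_window: float = 5.0,
    nadir_window: float = 15.0,
    slope_window: float = 30.0,
) -> PhaseMetrics:
    """Biphasic-response summary of an ISR series under a step stimulus.

    The first-phase peak is the maximum within ``peak_window`` minutes of
    the step onset, the nadir the minimum within ``nadir_window`` minutes
    after the peak, and the second-phase slope a least-squares trend of
    the ``slope_window`` minutes following the nadir.  A flat series is
    flagged degenerate.
    """
    isr = np.asarray(isr, dtype=float)
    t = np.arange(isr.size) * dt
    if np.std(isr) == 0.0:
        return PhaseMetrics(float(isr[0]) if isr.size else 0.0, onset_time, 0.0, onset_time, 0.0, True)

    sel = (t >= onset_time) & (t <= onset_time + peak_window)
    if not sel.any():
        raise ValueError("step onset outside the series")
    i_peak = np.argmax(np.where(sel, isr, -np.inf))
    peak_time = float(t[i_peak])
    peak = float(isr[i_peak])

    sel = (t > peak_time) & (t <= peak_time + nadir_window)
    if sel.any():
        i_nadir = np.argmin(np.where(sel, isr, np.inf))
        nadir_time = float(t[i_nadir])
        nadir = float(isr[i_nadir])
    else:
        nadir_time, nadir = peak_time, peak

    sel = (t >= nadir_time) & (t <= nadir_time + slope_window)
    if sel.sum() >= 2:
        slope = float(np.polyfit(t[sel], isr[sel], 1)[0])
    else:
        slope = 0.0
    return PhaseMetrics(peak, peak_time, nadir, nadir_time, slope, False)
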