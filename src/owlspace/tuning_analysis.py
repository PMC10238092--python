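"""Tuning-curve metrics for single units.

Best ITD comes from a Gaussian fit restricted to the main (largest) peak of
the ITD curve; frequency tuning is summarized by the outermost half-height
crossings of the frequency curve, with best frequency the midpoint of those
bounds. Frontal units are those with |best ITD| <= 30 us, and ITD converts
to azimuth at ~3 us/degree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .synthetic_data import TrialTable

__all__ = [
    "TuningCurve",
    "NeuronTuningSummary",
    "GaussianFit",
    "FitError",
    "fit_itd_main_peak",
    "frequency_metrics",
    "classify_frontal",
    "itd_to_azimuth",
    "summarize_neuron",
    "summaries_to_frame",
]

FRONTAL_ITD_LIMIT_US = 30.0
ITD_US_PER_DEG = 3.0


class FitError(RuntimeError):
    """Raised when a tuning-curve fit cannot be performed."""


@dataclass
class TuningCurve:
    """Trial-averaged response curve along one stimulus axis."""

    axis: str
    values: np.ndarray
    rates: np.ndarray  # mean spikes/s per value
    n_trials: int = 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if self.values.size != self.rates.size:
            raise ValueError("values and rates must align")
        if (np.diff(self.values) <= 0).any():
            raise ValueError("stimulus values must be strictly increasing")
        if (self.rates < 0).any():
            raise ValueError("rates must be non-negative")

    @classmethod
    def from_trials(cls, table: TrialTable) -> "TuningCurve":
        return cls(
            axis=table.axis,
            values=table.values,
            rates=table.mean_rates(),
            n_trials=table.n_trials,
        )


@dataclass
class GaussianFit:
    center: float
    sd: float
    amplitude: float
    baseline: float
    r_squared: float
    region: tuple[int, int]  # [lo, hi] index bounds of the fitted main peak

    @property
    def fwhm(self) -> float:
        return 2.0 * np.sqrt(2.0 * np.log(2.0)) * self.sd


@dataclass
class NeuronTuningSummary:
    neuron_id: str
    group: str
    best_itd_us: float
    itd_halfwidth_us: float
    freq_lo_hz: float
    freq_hi_hz: float
    best_freq_hz: float
    freq_range_hz: float
    best_ild_db: float | None = None
    is_frontal: bool = field(init=False)

    def __post_init__(self) -> None:
        if not self.freq_lo_hz <= self.best_freq_hz <= self.freq_hi_hz:
            raise ValueError("require freq_lo <= best_freq <= freq_hi")
        self.is_frontal = classify_frontal(self.best_itd_us)


def _smooth3(y: np.ndarray) -> np.ndarray:
    """3-point moving average with edge replication."""
    padded = np.concatenate([y[:1], y, y[-1:]])
    return (padded[:-2] + padded[1:-1] + padded[2:]) / 3.0


def _main_peak_region(rates: np.ndarray) -> tuple[int, int, int]:
    """(lo, peak, hi) index bounds of the largest peak, delimited by the
    nearest flanking local minima of the smoothed curve."""
    s = _smooth3(rates)
    peak = int(np.argmax(s))
    if peak == 0 or peak == s.size - 1:
        # global max of the smoothed curve at an edge: monotone curve
        raise FitError("no interior peak in ITD curve")
    lo = peak
    while lo > 0 and s[lo - 1] < s[lo]:
        lo -= 1
    hi = peak
    while hi < s.size - 1 and s[hi + 1] < s[hi]:
        hi += 1
    return lo, peak, hi


def _gauss(x: np.ndarray, amp: float, mu: float, sd: float, base: float) -> np.ndarray:
    return base + amp * np.exp(-((x - mu) ** 2) / (2.0 * sd**2))


def fit_itd_main_peak(curve: TuningCurve) -> tuple[float, float, GaussianFit]:
    """Gaussian fit to the main ITD peak.

    Returns (best ITD in us, tuning half-width = FWHM in us, diagnostics).
    Side peaks are excluded by restricting the fit to the region between the
    local minima flanking the global maximum.
    """
    if curve.values.size < 5:
        raise FitError("need at least 5 points for a main-peak fit")
    lo, peak, hi = _main_peak_region(curve.rates)
    x = curve.values[lo : hi + 1]
    y = curve.rates[lo : hi + 1]
    if x.size < 4:
        # widen symmetrically so the 4-parameter fit is determined
        lo = max(0, lo - 1)
        hi = min(curve.values.size - 1, hi + 1)
        x = curve.values[lo : hi + 1]
        y = curve.rates[lo : hi + 1]
    span = x[-1] - x[0]
    p0 = (max(y.max() - y.min(), 1e-6), curve.values[peak], max(span / 4.0, 1e-3), y.min())
    try:
        import warnings

        from scipy.optimize import OptimizeWarning

        with warnings.catch_warnings():
            # the covariance is unused; its conditioning is irrelevant here
            warnings.simplefilter("ignore", OptimizeWarning)
            popt, _ = curve_fit(
                _gauss,
                x,
                y,
                p0=p0,
                bounds=(
                    [0.0, x[0] - span, 1e-6, 0.0],
                    [np.inf, x[-1] + span, 10.0 * max(span, 1.0), np.inf],
                ),
                maxfev=20_000,
            )
    except RuntimeError as exc:  # pragma: no cover - rare non-convergence
        raise FitError(f"Gaussian fit did not converge: {exc}") from exc
    amp, mu, sd, base = popt
    resid = y - _gauss(x, *popt)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    fit = GaussianFit(
        center=float(mu),
        sd=float(sd),
        amplitude=float(amp),
        baseline=float(base),
        r_squared=r2,
        region=(lo, hi),
    )
    return fit.center, fit.fwhm, fit


def frequency_metrics(
    curve: TuningCurve, subtract_baseline: bool = False
) -> tuple[float, float, float, float]:
    """(freq_lo, freq_hi, best_freq, freq_range) from half-height crossings.

    The bounds are the outermost crossings of half the maximum rate, linearly
    interpolated between samples; dips below half-height between them are
    ignored. ``subtract_baseline`` removes the minimum rate before applying
    the 50% criterion.
    """
    y = curve.rates.astype(float)
    if subtract_baseline:
        y = y - y.min()
    if np.ptp(y) == 0:
        raise FitError("degenerate frequency curve: all rates equal")
    half = 0.5 * y.max()
    x = curve.values
    above = y >= half

    def interp(i: int, j: int) -> float:
        # half-height crossing between samples i and j
        return float(x[i] + (half - y[i]) * (x[j] - x[i]) / (y[j] - y[i]))

    first = int(np.argmax(above))
    last = int(len(above) - 1 - np.argmax(above[::-1]))
    freq_lo = float(x[first]) if first == 0 else interp(first - 1, first)
    freq_hi = float(x[last]) if last == len(x) - 1 else interp(last + 1, last)
    best = 0.5 * (freq_lo + freq_hi)
    return freq_lo, freq_hi, best, freq_hi - freq_lo


def classify_frontal(best_itd_us: float, limit_us: float = FRONTAL_ITD_LIMIT_US) -> bool:
    """Frontally tuned iff |best ITD| <= 30 us (boundary inclusive)."""
    return bool(abs(best_itd_us) <= limit_us)


def itd_to_azimuth(itd_us: float, slope_us_per_deg: float = ITD_US_PER_DEG) -> float:
    """Convert ITD (us) to azimuthal eccentricity (degrees)."""
    if slope_us_per_deg <= 0:
        raise ValueError("slope must be positive")
    return itd_us / slope_us_per_deg


def summarize_neuron(
    neuron_id: str,
    group: str,
    itd_curve: TuningCurve,
    freq_curve: TuningCurve,
    ild_curve: TuningCurve | None = None,
) -> NeuronTuningSummary:
    """Combine per-axis curves into one summary row."""
    best_itd, halfwidth, _ = fit_itd_main_peak(itd_curve)
    f_lo, f_hi, f_best, f_range = frequency_metrics(freq_curve)
    best_ild = None
    if ild_curve is not None:
        best_ild = float(ild_curve.values[int(np.argmax(ild_curve.rates))])
    return NeuronTuningSummary(
        neuron_id=neuron_id,
        group=group,
        best_itd_us=best_itd,
        itd_halfwidth_us=halfwidth,
        freq_lo_hz=f_lo,
        freq_hi_hz=f_hi,
        best_freq_hz=f_best,
        freq_range_hz=f_range,
        best_ild_db=best_ild,
    )


def summaries_to_frame(summaries: Sequence[NeuronTuningSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "neuron_id": s.neuron_id,
                "group": s.group,
                "best_itd_us": s.best_itd_us,
                "itd_halfwidth_us": s.itd_halfwidth_us,
                "freq_lo_hz": s.freq_lo_hz,
                "freq_hi_hz": s.freq_hi_hz,
                "best_freq_hz": s.best_freq_hz,
                "freq_range_hz": s.freq_range_hz,
                "best_ild_db": s.best_ild_db,
                "is_frontal": s.is_frontal,
            }
            for s in summaries
        ]
    )
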