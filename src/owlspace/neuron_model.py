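"""Model midbrain-map neuron and HRTF-derived spatial tuning maps.

Per tone frequency, ITD and ILD cue fields are extracted from a head-filter
set; a model neuron's response to each direction is the product of a
periodic (cosine-exponential) ITD tuning curve and a Gaussian ILD tuning
curve, normalized to a map maximum of 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.fft import next_fast_len, rfft, irfft

from .hrtf_io import Direction, HRIRSet
from .ipd_reliability import FilterbankSpec, gammatone_kernels

__all__ = [
    "ModelNeuronParams",
    "CueField",
    "SpatialTuningMap",
    "cue_field",
    "itd_response",
    "ild_response",
    "spatial_tuning_map",
    "map_to_frame",
    "DEFAULT_MAP_FREQS_HZ",
]

#: tone frequencies of the standard map construction (3-7 kHz, 1 kHz steps)
DEFAULT_MAP_FREQS_HZ = (3000.0, 4000.0, 5000.0, 6000.0, 7000.0)


@dataclass(frozen=True)
class ModelNeuronParams:
    """Model neuron tuned to frequency ``f`` with best ITD ``mu_n`` (s) and
    best ILD ``delta_n`` (dB); ``sigma`` is the ILD width parameter (dB^2)
    and ``a_max`` the peak rate of both curves (spikes/s)."""

    f: float
    mu_n: float = 0.0
    delta_n: float = 0.0
    sigma: float = 50.0
    a_max: float = 10.0

    def __post_init__(self) -> None:
        if self.f <= 0:
            raise ValueError("f must be positive")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.a_max <= 0:
            raise ValueError("a_max must be positive")


@dataclass
class CueField:
    """Per-direction ITD (us) and ILD (dB, right minus left) at one frequency."""

    frequency_hz: float
    directions: list[Direction]
    itd_us: np.ndarray
    ild_db: np.ndarray
    provenance: dict = field(default_factory=dict)


@dataclass
class SpatialTuningMap:
    """Normalized model-neuron response per direction at one frequency."""

    frequency_hz: float
    directions: list[Direction]
    response: np.ndarray  # in [0, 1], max 1
    provenance: dict = field(default_factory=dict)


def cue_field(
    hrir_set: HRIRSet,
    frequency_hz: float,
    max_lag_s: float = 1e-3,
    fb_order: int = 4,
    erb_scale: float = 1.019,
) -> CueField:
    """Extract the (ITD, ILD) cue pair at every direction for one frequency.

    ITD is the lag of the maximum cross-correlation of the two ears'
    gammatone-filtered (at ``frequency_hz``) impulse responses, searched over
    |lag| <= ``max_lag_s``; ILD is the right-minus-left DFT magnitude
    difference in dB at that frequency.
    """
    fs = hrir_set.sample_rate_hz
    if frequency_hz >= fs / 2.0:
        raise ValueError("frequency at or above Nyquist")
    spec = FilterbankSpec(
        center_freqs_hz=(frequency_hz,), order=fb_order, erb_scale=erb_scale
    )
    kernel = gammatone_kernels(spec, fs)[0]

    n_taps = hrir_set.n_taps
    n_fft = next_fast_len(2 * (n_taps + kernel.size))
    gk2 = np.abs(rfft(kernel, n_fft)) ** 2
    fl = rfft(hrir_set.left, n=n_fft, axis=1)
    fr = rfft(hrir_set.right, n=n_fft, axis=1)
    # cross-correlation of band-filtered ears via the band power spectrum
    c = irfft(gk2[None, :] * fl * np.conj(fr), n_fft, axis=1)
    k = int(round(max_lag_s * fs))
    lags = np.concatenate([c[:, -k:], c[:, : k + 1]], axis=1)
    peak = np.max(np.abs(lags), axis=1)
    tau_s = (np.argmax(lags, axis=1) - k) / fs
    itd_us = tau_s * 1e6
    itd_us = np.where(peak > 1e-14 * max(peak.max(), 1e-300), itd_us, np.nan)

    grid = np.fft.rfftfreq(n_fft, d=1.0 / fs)
    b = int(np.argmin(np.abs(grid - frequency_hz)))
    ild_db = 20.0 * np.log10(np.maximum(np.abs(fr[:, b]), 1e-12)) - 20.0 * np.log10(
        np.maximum(np.abs(fl[:, b]), 1e-12)
    )
    return CueField(
        frequency_hz=float(frequency_hz),
        directions=list(hrir_set.directions),
        itd_us=itd_us,
        ild_db=ild_db,
        provenance={"owl_id": hrir_set.owl_id, "condition": hrir_set.condition.value},
    )


_E = math.e


def itd_response(itd_s: np.ndarray | float, p: ModelNeuronParams) -> np.ndarray | float:
    """Periodic ITD tuning: a_max * (exp(cos(2 pi f (ITD - mu_n))) - 1/e) / (e - 1/e).

    Peaks at a_max for ITD = mu_n (mod 1/f) and reaches 0 at anti-phase.
    """
    itd = np.asarray(itd_s, dtype=float)
    val = p.a_max * (np.exp(np.cos(2 * np.pi * p.f * (itd - p.mu_n))) - 1.0 / _E) / (
        _E - 1.0 / _E
    )
    return float(val) if np.isscalar(itd_s) else val


def ild_response(ild_db: np.ndarray | float, p: ModelNeuronParams) -> np.ndarray | float:
    """Gaussian ILD tuning: a_max * exp(-(ILD - delta_n)^2 / sigma)."""
    ild = np.asarray(ild_db, dtype=float)
    val = p.a_max * np.exp(-((ild - p.delta_n) ** 2) / p.sigma)
    return float(val) if np.isscalar(ild_db) else val


def spatial_tuning_map(cues: CueField, p: ModelNeuronParams) -> SpatialTuningMap:
    """Multiply the ITD and ILD responses per direction, then normalize."""
    if not np.isclose(cues.frequency_hz, p.f):
        raise ValueError(
            f"cue field frequency {cues.frequency_hz} != neuron frequency {p.f}"
        )
    resp = (
        itd_response(cues.itd_us * 1e-6, p) * ild_response(cues.ild_db, p) / p.a_max**2
    )
    finite = np.isfinite(resp)
    if not finite.any():
        raise ValueError("all cue-field cells are flagged; empty map")
    peak = np.nanmax(resp)
    if peak > 0:
        resp = resp / peak
    return SpatialTuningMap(
        frequency_hz=cues.frequency_hz,
        directions=list(cues.directions),
        response=resp,
        provenance={**dict(cues.provenance), "mu_n_s": p.mu_n, "delta_n_db": p.delta_n},
    )


def map_to_frame(m: SpatialTuningMap) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "freq_hz": np.repeat(m.frequency_hz, len(m.directions)),
            "az_deg": [d.azimuth_deg for d in m.directions],
            "el_deg": [d.elevation_deg for d in m.directions],
            "response_norm": m.response,
        }
    )
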