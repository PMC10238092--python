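"""Directional gain across frequency and source location.

Gain is the magnitude of the head filter in dB relative to the free field
(no head = 0 dB), read off the zero-padded DFT of each impulse response at
the requested frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.fft import next_fast_len, rfft

from .hrtf_io import Direction, HRIRSet

__all__ = ["GainMap", "gain_map", "gain_to_frame"]

MIN_FFT = 4096


@dataclass
class GainMap:
    """Gain in dB per (frequency x direction)."""

    frequencies_hz: np.ndarray
    directions: list[Direction]
    gain_db: np.ndarray  # (n_freq, n_directions)
    provenance: dict = field(default_factory=dict)


def gain_map(
    hrir_set: HRIRSet,
    frequencies_hz: Sequence[float],
    ear: str = "mean",
) -> GainMap:
    """Directional gain of ``hrir_set`` at the given frequencies.

    ``ear`` selects "left", "right", or the two-ear "mean" (in dB, the
    default reported value).
    """
    freqs = np.asarray(frequencies_hz, dtype=float)
    fs = hrir_set.sample_rate_hz
    if (freqs >= fs / 2.0).any():
        raise ValueError("requested frequency at or above Nyquist")
    if ear not in ("left", "right", "mean"):
        raise ValueError(f"unknown ear selector {ear!r}")

    n_fft = next_fast_len(max(MIN_FFT, 4 * hrir_set.n_taps))
    grid = np.fft.rfftfreq(n_fft, d=1.0 / fs)
    bins = np.argmin(np.abs(grid[None, :] - freqs[:, None]), axis=1)

    def ear_db(ir: np.ndarray) -> np.ndarray:
        mag = np.abs(rfft(ir, n=n_fft, axis=1))[:, bins]  # (n_dir, n_freq)
        return 20.0 * np.log10(np.maximum(mag, 1e-12)).T  # (n_freq, n_dir)

    if ear == "left":
        g = ear_db(hrir_set.left)
    elif ear == "right":
        g = ear_db(hrir_set.right)
    else:
        g = 0.5 * (ear_db(hrir_set.left) + ear_db(hrir_set.right))
    return GainMap(
        frequencies_hz=freqs,
        directions=list(hrir_set.directions),
        gain_db=g,
        provenance={
            "owl_id": hrir_set.owl_id,
            "condition": hrir_set.condition.value,
            "ear": ear,
        },
    )


def gain_to_frame(m: GainMap) -> pd.DataFrame:
    nf, nd = m.gain_db.shape
    return pd.DataFrame(
        {
            "owl_id": np.repeat(m.provenance.get("owl_id", ""), nf * nd),
            "condition": np.repeat(m.provenance.get("condition", ""), nf * nd),
            "az_deg": np.tile([d.azimuth_deg for d in m.directions], nf),
            "el_deg": np.tile([d.elevation_deg for d in m.directions], nf),
            "freq_hz": np.repeat(m.frequencies_hz, nd),
            "gain_db": m.gain_db.ravel(),
        }
    )
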