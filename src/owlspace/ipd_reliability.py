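"""Interaural-phase-difference (IPD) reliability under concurrent-sound corruption.

Pipeline: render a target and a masker through the measured (or synthetic)
head filters, sum them, decompose into narrow gammatone bands, take the IPD
of each band from the lag of the maximum interaural cross-correlation, and
summarize the spread of IPD across masker locations with the circular
standard deviation. Reliability is the inverse of that spread, averaged over
stimulus repetitions; per-location normalization and cross-owl averaging
yield population maps, and the signed difference between two condition maps
localizes reliability changes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.fft import next_fast_len, rfft, irfft
from scipy.signal import fftconvolve

from .hrtf_io import HRIRSet, ValidationError, elevation_zero_azimuth_order
from .synthetic_data import make_broadband_stimulus, make_vocalization_surrogate

__all__ = [
    "FilterbankSpec",
    "ReliabilityConfig",
    "ReliabilityMap",
    "binaural_render",
    "gammatone_kernels",
    "gammatone_filterbank",
    "band_ipd",
    "circular_sd",
    "reliability_map",
    "normalize_map",
    "normalize_and_average",
    "difference_map",
    "reliability_to_frame",
]


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------


def _default_centers() -> np.ndarray:
    return np.arange(1000.0, 8001.0, 200.0)


@dataclass(frozen=True)
class FilterbankSpec:
    """Gammatone filterbank layout (1-8 kHz in 200 Hz steps by default)."""

    center_freqs_hz: tuple[float, ...] = tuple(_default_centers())
    order: int = 4
    erb_scale: float = 1.019

    def __post_init__(self) -> None:
        c = np.asarray(self.center_freqs_hz)
        if c.size == 0 or (np.diff(c) <= 0).any():
            raise ValueError("center frequencies must be strictly increasing")
        if self.order < 1:
            raise ValueError("gammatone order must be >= 1")

    def validate_rate(self, sample_rate_hz: float) -> None:
        if max(self.center_freqs_hz) >= sample_rate_hz / 2.0:
            raise ValueError(
                f"center frequency {max(self.center_freqs_hz)} Hz >= Nyquist "
                f"({sample_rate_hz / 2.0} Hz)"
            )


@dataclass(frozen=True)
class ReliabilityConfig:
    """Target/masker protocol for one reliability run."""

    masker_amplitude: float = 1.0
    n_repetitions: int = 10
    stimulus_kind: Literal["broadband", "vocalization_surrogate"] = "broadband"
    duration_s: float = 0.1
    band_lo_hz: float = 500.0
    band_hi_hz: float = 10_000.0
    include_coincident_masker: bool = True
    max_lag_s: float = 1e-3
    subsample_peak: bool = True
    epsilon_sd_rad: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.masker_amplitude < 0:
            raise ValueError("masker_amplitude must be >= 0")
        if self.n_repetitions < 1:
            raise ValueError("n_repetitions must be >= 1")


@dataclass
class ReliabilityMap:
    """IPD reliability over (frequency x target azimuth).

    ``raw_sd_rad`` and ``reliability_raw`` are per-owl quantities;
    ``reliability_norm`` is present after per-location normalization (each
    azimuth column scaled to a maximum of 1 across frequencies).
    """

    frequencies_hz: np.ndarray
    target_azimuths_deg: np.ndarray
    raw_sd_rad: np.ndarray | None  # (n_freq, n_az)
    reliability_raw: np.ndarray | None
    reliability_norm: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frequencies_hz = np.asarray(self.frequencies_hz, dtype=float)
        self.target_azimuths_deg = np.asarray(self.target_azimuths_deg, dtype=float)

    def grid_matches(self, other: "ReliabilityMap") -> bool:
        return (
            self.frequencies_hz.shape == other.frequencies_hz.shape
            and self.target_azimuths_deg.shape == other.target_azimuths_deg.shape
            and np.allclose(self.frequencies_hz, other.frequencies_hz)
            and np.allclose(self.target_azimuths_deg, other.target_azimuths_deg)
        )


# ---------------------------------------------------------------------------
# signal primitives
# ---------------------------------------------------------------------------


def binaural_render(
    signal: np.ndarray, hrir_pair: tuple[np.ndarray, np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """Convolve a monaural signal with one direction's (left, right) HRIRs.

    Returns the full linear convolutions, length ``len(signal) + taps - 1``.
    """
    left_ir, right_ir = hrir_pair
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 1:
        raise ValueError("signal must be 1-D")
    return (
        fftconvolve(signal, np.asarray(left_ir, dtype=float)),
        fftconvolve(signal, np.asarray(right_ir, dtype=float)),
    )


def _erb_hz(fc: np.ndarray) -> np.ndarray:
    # Glasberg & Moore equivalent rectangular bandwidth
    return 24.7 + fc / 9.265


def gammatone_kernels(spec: FilterbankSpec, sample_rate_hz: float) -> np.ndarray:
    """FIR gammatone impulse responses, one row per band, peak response 0 dB.

    g(t) = t^(n-1) exp(-2 pi b t) cos(2 pi fc t), b = erb_scale * ERB(fc).
    """
    spec.validate_rate(sample_rate_hz)
    fc = np.asarray(spec.center_freqs_hz, dtype=float)
    b = spec.erb_scale * _erb_hz(fc)
    # long enough for the slowest envelope to decay to ~1e-5 of its peak
    t_max = (spec.order - 1 + 14.0) / (2 * np.pi * b.min())
    n_taps = int(np.ceil(t_max * sample_rate_hz))
    t = np.arange(n_taps) / sample_rate_hz
    env = t[None, :] ** (spec.order - 1) * np.exp(-2 * np.pi * b[:, None] * t[None, :])
    kernels = env * np.cos(2 * np.pi * fc[:, None] * t[None, :])
    # normalize to unit magnitude response at each center frequency
    n_fft = next_fast_len(4 * n_taps)
    spectra = rfft(kernels, n=n_fft, axis=1)
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / sample_rate_hz)
    peak = np.abs(spectra[np.arange(fc.size), np.argmin(np.abs(freqs[None] - fc[:, None]), axis=1)])
    return kernels / peak[:, None]


def gammatone_filterbank(
    signal: np.ndarray, spec: FilterbankSpec, sample_rate_hz: float
) -> np.ndarray:
    """Decompose ``signal`` into bands; output shape (n_bands, len(signal))."""
    signal = np.asarray(signal, dtype=float)
    kernels = gammatone_kernels(spec, sample_rate_hz)
    out = fftconvolve(kernels, signal[None, :], axes=1)
    return out[:, : signal.size]


def wrap_phase(phi: np.ndarray | float) -> np.ndarray | float:
    """Wrap angle(s) to (-pi, pi]."""
    return -((-np.asarray(phi) + np.pi) % (2 * np.pi) - np.pi)


def _peak_lag_samples(lags: np.ndarray, k_lag: int, subsample: bool) -> np.ndarray:
    """Peak location (in samples, relative to zero lag) along the last axis.

    ``lags`` covers lags -(k_lag+1)..(k_lag+1); the search is restricted to
    -k_lag..k_lag and the flanking samples only refine the peak position by
    parabolic interpolation when ``subsample`` is set.
    """
    inner = lags[..., 1:-1]
    k = np.argmax(inner, axis=-1)
    if not subsample:
        return (k - k_lag).astype(float)
    idx = np.indices(k.shape, sparse=True)
    ym1 = lags[(*idx, k)]
    y0 = lags[(*idx, k + 1)]
    yp1 = lags[(*idx, k + 2)]
    denom = ym1 - 2.0 * y0 + yp1
    frac = np.where(
        np.abs(denom) > 0, 0.5 * (ym1 - yp1) / np.where(denom == 0, 1.0, denom), 0.0
    )
    return k - k_lag + np.clip(frac, -0.5, 0.5)


def band_ipd(
    left_band: np.ndarray,
    right_band: np.ndarray,
    center_freq_hz: float,
    sample_rate_hz: float,
    max_lag_s: float = 1e-3,
    subsample_peak: bool = True,
) -> float:
    """IPD of one narrowband pair from the maximum-cross-correlation lag.

    Positive IPD means the right ear leads. The peak lag is refined to
    sub-sample resolution by parabolic interpolation unless
    ``subsample_peak`` is disabled. Returns NaN for zero-energy input.
    """
    left_band = np.asarray(left_band, dtype=float)
    right_band = np.asarray(right_band, dtype=float)
    if left_band.shape != right_band.shape:
        raise ValueError("band signals must share length")
    if not (left_band.any() and right_band.any()):
        return float("nan")
    k = int(round(max_lag_s * sample_rate_hz))
    n = left_band.size
    n_fft = next_fast_len(2 * n + 2)
    c = irfft(rfft(left_band, n_fft) * np.conj(rfft(right_band, n_fft)), n_fft)
    # c[k] = sum_t L[t] R[t-k]; assemble lags -(k+1)..(k+1)
    lags = np.concatenate([c[-(k + 1) :], c[: k + 2]])
    tau = _peak_lag_samples(lags, k, subsample_peak) / sample_rate_hz
    return float(wrap_phase(2 * np.pi * center_freq_hz * tau))


def circular_sd(angles: Sequence[float]) -> float:
    """Circular standard deviation sqrt(-2 ln Rbar) of a set of angles.

    NaN entries are ignored; a zero mean resultant yields +inf.
    """
    a = np.asarray(angles, dtype=float)
    a = a[np.isfinite(a)]
    if a.size < 2:
        raise ValueError("need at least two finite angles")
    rbar = float(np.abs(np.mean(np.exp(1j * a))))
    if rbar < 1e-12:  # vanishing resultant: spread is undefined/unbounded
        return float("inf")
    if rbar >= 1.0 - 1e-14:  # numerically identical angles
        return 0.0
    return float(np.sqrt(-2.0 * np.log(rbar)))


# ---------------------------------------------------------------------------
# the reliability pipeline
# ---------------------------------------------------------------------------


def _stimulus(cfg: ReliabilityConfig, sample_rate_hz: float, seed: int) -> np.ndarray:
    if cfg.stimulus_kind == "vocalization_surrogate":
        return make_vocalization_surrogate(cfg.duration_s, sample_rate_hz, seed)
    hi = min(cfg.band_hi_hz, 0.98 * sample_rate_hz / 2.0)
    return make_broadband_stimulus(cfg.band_lo_hz, hi, cfg.duration_s, sample_rate_hz, seed)


def _token_seed(seed: int, repetition: int, role: int) -> int:
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(repetition, role))
    return int(ss.generate_state(1)[0])


def reliability_map(
    hrir_set: HRIRSet,
    fb: FilterbankSpec | None = None,
    cfg: ReliabilityConfig | None = None,
) -> ReliabilityMap:
    """Raw single-owl IPD reliability over (band center x target azimuth).

    For every repetition fresh target and masker tokens are drawn; for every
    (target azimuth, masker azimuth) pair the two renders are summed (masker
    scaled by ``cfg.masker_amplitude``), band-passed, and each band's IPD is
    taken from its maximum-cross-correlation lag. The circular SD of IPD
    across masker azimuths is averaged over repetitions and inverted (with an
    epsilon floor) to give raw reliability.
    """
    fb = fb or FilterbankSpec()
    cfg = cfg or ReliabilityConfig()
    fs = hrir_set.sample_rate_hz
    fb.validate_rate(fs)

    az_idx = elevation_zero_azimuth_order(hrir_set)
    azimuths = np.array([hrir_set.directions[i].azimuth_deg for i in az_idx])
    n_az = azimuths.size
    if n_az < 2:
        raise ValidationError("need at least two elevation-0 azimuths")
    hl = hrir_set.left[az_idx]
    hr = hrir_set.right[az_idx]

    fc = np.asarray(fb.center_freqs_hz)
    n_bands = fc.size
    kernels = gammatone_kernels(fb, fs)
    k_lag = int(round(cfg.max_lag_s * fs))

    n_sig = int(round(cfg.duration_s * fs))
    m = n_sig + hrir_set.n_taps - 1
    n_fft = next_fast_len(2 * m + 2 * kernels.shape[1])
    # |G|^2 per band: filtering both ears by g multiplies the cross-spectrum
    band_power = np.abs(rfft(kernels, n=n_fft, axis=1)) ** 2  # (n_bands, F)

    sd_accum = np.zeros((n_bands, n_az))
    for rep in range(cfg.n_repetitions):
        target = _stimulus(cfg, fs, _token_seed(cfg.seed, rep, 0))
        masker = _stimulus(cfg, fs, _token_seed(cfg.seed, rep, 1))
        ft = rfft(target, n_fft)
        fm = rfft(masker, n_fft)
        # per-azimuth rendered spectra (renders are convolutions -> products)
        fhl = rfft(hl, n=n_fft, axis=1)
        fhr = rfft(hr, n=n_fft, axis=1)
        lt, rt = ft * fhl, ft * fhr  # target renders, (n_az, F)
        lm, rm = fm * fhl, fm * fhr  # masker renders

        for ti in range(n_az):
            fl = lt[ti] + cfg.masker_amplitude * lm  # (n_az maskers, F)
            fr = rt[ti] + cfg.masker_amplitude * rm
            cross = fl * np.conj(fr)  # (n_az, F)
            # band-filtered cross-correlations for all bands at once
            c = irfft(band_power[:, None, :] * cross[None, :, :], n_fft, axis=2)
            lags = np.concatenate([c[..., -k_lag - 1 :], c[..., : k_lag + 2]], axis=2)
            tau = _peak_lag_samples(lags, k_lag, cfg.subsample_peak) / fs
            ipd = wrap_phase(2 * np.pi * fc[:, None] * tau)  # (n_bands, n_az)
            # zero-energy guard: flag cells whose correlation is ~ zero
            peak = np.max(np.abs(lags), axis=2)
            ipd = np.where(peak > 1e-12 * peak.max(), ipd, np.nan)
            if not cfg.include_coincident_masker:
                ipd[:, ti] = np.nan
            z = np.exp(1j * np.where(np.isfinite(ipd), ipd, 0.0))
            w = np.isfinite(ipd).astype(float)
            nw = w.sum(axis=1)
            if (nw < 2).any():
                raise ValidationError("all-undefined IPD cell encountered")
            rbar = np.abs((z * w).sum(axis=1)) / nw
            sd = np.sqrt(-2.0 * np.log(np.clip(rbar, 1e-300, 1.0)))
            sd_accum[:, ti] += sd

    mean_sd = sd_accum / cfg.n_repetitions
    raw = 1.0 / np.maximum(mean_sd, cfg.epsilon_sd_rad)
    provenance = {
        "owl_ids": [hrir_set.owl_id],
        "condition": hrir_set.condition.value,
        "config": asdict(cfg),
        "filterbank": asdict(fb),
        "config_hash": hashlib.sha256(
            json.dumps(asdict(cfg), sort_keys=True).encode()
        ).hexdigest()[:12],
    }
    return ReliabilityMap(
        frequencies_hz=fc,
        target_azimuths_deg=azimuths,
        raw_sd_rad=mean_sd,
        reliability_raw=raw,
        provenance=provenance,
    )


def normalize_map(m: ReliabilityMap) -> ReliabilityMap:
    """Scale each target-azimuth column to a maximum of 1 across frequencies."""
    if m.reliability_raw is None:
        raise ValueError("map has no raw reliability to normalize")
    col_max = m.reliability_raw.max(axis=0, keepdims=True)
    norm = m.reliability_raw / np.where(col_max > 0, col_max, 1.0)
    return ReliabilityMap(
        frequencies_hz=m.frequencies_hz,
        target_azimuths_deg=m.target_azimuths_deg,
        raw_sd_rad=m.raw_sd_rad,
        reliability_raw=m.reliability_raw,
        reliability_norm=norm,
        provenance=dict(m.provenance),
    )


def normalize_and_average(maps: Sequence[ReliabilityMap]) -> ReliabilityMap:
    """Per-owl, per-location normalization followed by cross-owl averaging."""
    if not maps:
        raise ValueError("no maps given")
    first = maps[0]
    for m in maps[1:]:
        if not first.grid_matches(m):
            raise ValidationError("reliability maps are on different grids")
    normed = [normalize_map(m).reliability_norm for m in maps]
    mean = np.mean(normed, axis=0)
    owl_ids = [oid for m in maps for oid in m.provenance.get("owl_ids", [])]
    return ReliabilityMap(
        frequencies_hz=first.frequencies_hz,
        target_azimuths_deg=first.target_azimuths_deg,
        raw_sd_rad=None,
        reliability_raw=None,
        reliability_norm=mean,
        provenance={**dict(first.provenance), "owl_ids": owl_ids, "n_owls": len(maps)},
    )


def difference_map(a: ReliabilityMap, b: ReliabilityMap) -> ReliabilityMap:
    """Signed cell-wise difference ``a - b`` of two normalized maps."""
    if a.reliability_norm is None or b.reliability_norm is None:
        raise ValueError("difference requires normalized maps")
    if not a.grid_matches(b):
        raise ValidationError("reliability maps are on different grids")
    return ReliabilityMap(
        frequencies_hz=a.frequencies_hz,
        target_azimuths_deg=a.target_azimuths_deg,
        raw_sd_rad=None,
        reliability_raw=None,
        reliability_norm=a.reliability_norm - b.reliability_norm,
        provenance={
            "difference_of": [
                a.provenance.get("condition"),
                b.provenance.get("condition"),
            ]
        },
    )


def reliability_to_frame(m: ReliabilityMap, owl_id: str = "", condition: str = "") -> pd.DataFrame:
    """Long-format table (owl_id, condition, target_az_deg, freq_hz, ...)."""
    nf, na = m.frequencies_hz.size, m.target_azimuths_deg.size
    cols = {
        "owl_id": np.repeat(owl_id or ";".join(m.provenance.get("owl_ids", [])), nf * na),
        "condition": np.repeat(condition or m.provenance.get("condition", ""), nf * na),
        "target_az_deg": np.tile(m.target_azimuths_deg, nf),
        "freq_hz": np.repeat(m.frequencies_hz, na),
    }
    for name, arr in (
        ("raw_sd_rad", m.raw_sd_rad),
        ("reliability_raw", m.reliability_raw),
        ("reliability_norm", m.reliability_norm),
    ):
        cols[name] = arr.ravel() if arr is not None else np.full(nf * na, np.nan)
    return pd.DataFrame(cols)
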