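"""Synthetic inputs with known ground truth.

Two generator families:

* a parametric "owl head" that emits :class:`~owlspace.hrtf_io.HRIRSet`
  objects whose ITD grows linearly with azimuth and whose magnitude model
  differs between the ``normal`` (facial-ruff) and ``ruff_removed``
  conditions, and
* Poisson spike-count tuning curves over ITD, ILD and tone frequency for
  model single units with known tuning parameters.

The head model composes, per ear, a pure fractional delay (+-ITD/2) with a
minimum-phase filter realizing a closed-form magnitude. Keeping delay and
magnitude separable makes both cues exactly controllable, so downstream
extractors can be tested against the generating parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .hrtf_io import Condition, Direction, GridSpec, HRIRSet

__all__ = [
    "HeadModelParams",
    "NeuronGroundTruth",
    "TrialTable",
    "make_head_model_hrirs",
    "head_magnitude_db",
    "head_itd_us",
    "ruff_ramp",
    "make_broadband_stimulus",
    "make_vocalization_surrogate",
    "simulate_tuning_curves",
    "ground_truth_rates",
    "make_population_roster",
    "write_trial_table",
    "read_trial_table",
]

StimulusAxis = Literal["itd_us", "ild_db", "freq_hz"]


# ---------------------------------------------------------------------------
# head model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HeadModelParams:
    """Parameters of the synthetic owl head.

    ITD is linear in azimuth (``itd_slope_us_per_deg``). The ``normal``
    condition adds a frontal high-frequency gain lobe of amplitude
    ``ruff_gain_db`` ramping on above ``ruff_freq_lo_hz``, an elevational ILD
    component and a low-frequency attenuation; ``ruff_removed`` removes all
    three and doubles the azimuthal head-shadow ILD.
    """

    itd_slope_us_per_deg: float = 3.0
    ruff_gain_db: float = 10.0
    ruff_az_sigma_deg: float = 30.0
    ruff_freq_lo_hz: float = 4000.0
    ruff_ramp_hz: float = 1000.0
    shadow_gain_db: float = 6.0  # azimuthal ILD scale at 8 kHz
    elev_ild_gain_db: float = 12.0  # elevational ILD scale at 8 kHz (ruff only)
    periph_gain_db: float = 9.0  # ruffless lateral high-frequency gain
    periph_az_sigma_deg: float = 50.0
    low_freq_atten_db: float = 3.0
    low_freq_cutoff_hz: float = 3000.0
    gain_ripple_db: float = 0.5  # per-owl smooth spectral ripple (seeded)
    hrir_len: int = 256
    sample_rate_hz: float = 48_000.0

    def __post_init__(self) -> None:
        if self.itd_slope_us_per_deg < 0:
            raise ValueError("itd_slope_us_per_deg must be >= 0")
        if self.hrir_len < 64:
            raise ValueError("hrir_len must be >= 64")
        for name in (
            "ruff_gain_db",
            "shadow_gain_db",
            "elev_ild_gain_db",
            "low_freq_atten_db",
            "gain_ripple_db",
        ):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


def ruff_ramp(freq_hz: np.ndarray, params: HeadModelParams) -> np.ndarray:
    """Raised-cosine on-ramp w(f) of the frontal ruff lobe: 0 below
    ``ruff_freq_lo_hz``, 1 above ``ruff_freq_lo_hz + ruff_ramp_hz``."""
    f = np.asarray(freq_hz, dtype=float)
    x = np.clip((f - params.ruff_freq_lo_hz) / params.ruff_ramp_hz, 0.0, 1.0)
    return 0.5 - 0.5 * np.cos(np.pi * x)


def _low_freq_ramp(freq_hz: np.ndarray, params: HeadModelParams) -> np.ndarray:
    # 1 below the cutoff, raised-cosine down to 0 one ramp width above it
    f = np.asarray(freq_hz, dtype=float)
    x = np.clip((f - params.low_freq_cutoff_hz) / params.ruff_ramp_hz, 0.0, 1.0)
    return 0.5 + 0.5 * np.cos(np.pi * x)


def _freq_scale(freq_hz: np.ndarray) -> np.ndarray:
    # frequency weighting of head-shadow / elevational ILD, 0..1 up to 8 kHz
    return np.clip(np.asarray(freq_hz, dtype=float) / 8000.0, 0.0, 1.0)


def head_itd_us(azimuth_deg: float | np.ndarray, params: HeadModelParams) -> np.ndarray:
    """Model ITD: linear (itd_slope) within +-90 degrees, folding back toward
    the rear as on a real head (a source behind mirrors its frontal ITD)."""
    az = np.asarray(azimuth_deg, dtype=float)
    folded = np.where(np.abs(az) <= 90.0, az, np.sign(az) * (180.0 - np.abs(az)))
    out = params.itd_slope_us_per_deg * folded
    return float(out) if np.isscalar(azimuth_deg) else out


def _owl_ripple_db(freq_hz: np.ndarray, params: HeadModelParams, seed: int) -> np.ndarray:
    """Smooth per-owl spectral ripple, identical across ears and conditions."""
    rng = np.random.default_rng(seed)
    amps = rng.normal(0.0, params.gain_ripple_db, size=4) / np.arange(1, 5)
    phases = rng.uniform(0, 2 * np.pi, size=4)
    f = np.asarray(freq_hz, dtype=float)
    out = np.zeros_like(f)
    for k in range(4):
        out += amps[k] * np.cos(2 * np.pi * (k + 1) * f / 10_000.0 + phases[k])
    return out


def head_magnitude_db(
    freq_hz: np.ndarray,
    azimuth_deg: float,
    elevation_deg: float,
    params: HeadModelParams,
    condition: Condition | str,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form (left_db, right_db) magnitude model at one direction.

    This is the oracle the generated HRIRs are tested against.
    """
    condition = Condition(condition)
    f = np.asarray(freq_hz, dtype=float)
    az = np.deg2rad(azimuth_deg)
    el = np.deg2rad(elevation_deg)

    base = _owl_ripple_db(f, params, seed)
    if condition is Condition.NORMAL:
        lobe = (
            params.ruff_gain_db
            * ruff_ramp(f, params)
            * np.exp(-(azimuth_deg**2) / (2.0 * params.ruff_az_sigma_deg**2))
        )
        atten = params.low_freq_atten_db * _low_freq_ramp(f, params)
        ild = params.shadow_gain_db * _freq_scale(f) * np.sin(az)
        ild = ild + params.elev_ild_gain_db * _freq_scale(f) * np.sin(el)
    else:
        # bare ear canals point laterally: high-frequency gain moves off-axis
        lobe = (
            params.periph_gain_db
            * _freq_scale(f)
            * (1.0 - np.exp(-(azimuth_deg**2) / (2.0 * params.periph_az_sigma_deg**2)))
        )
        atten = 0.0
        # head shadow is the dominant (and doubled) ILD source without the ruff
        ild = 2.0 * params.shadow_gain_db * _freq_scale(f) * np.sin(az)

    common = base + lobe - atten
    return common - ild / 2.0, common + ild / 2.0


def _minimum_phase_spectrum(amplitude: np.ndarray, n_fft: int) -> np.ndarray:
    """Minimum-phase complex spectrum (rfft grid) with the given magnitude."""
    log_mag = np.log(np.maximum(amplitude, 1e-12))
    cep = np.fft.irfft(log_mag, n=n_fft)
    fold = np.zeros_like(cep)
    fold[0] = cep[0]
    fold[1 : n_fft // 2] = 2.0 * cep[1 : n_fft // 2]
    fold[n_fft // 2] = cep[n_fft // 2]
    return np.exp(np.fft.rfft(fold))


def make_head_model_hrirs(
    params: HeadModelParams,
    condition: Condition | str,
    grid: GridSpec,
    seed: int = 0,
    owl_id: str | None = None,
) -> HRIRSet:
    """Synthesize an HRIR set for one owl (seed) and condition on ``grid``."""
    condition = Condition(condition)
    directions = grid.directions()
    if not directions:
        raise ValueError("grid must contain at least one direction")
    fs = params.sample_rate_hz
    if fs < 20_000.0:
        raise ValueError("sample_rate_hz too low for the 10 kHz analysis band")

    n = params.hrir_len
    n_fft = 8 * n
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / fs)
    base_delay_s = n / (4.0 * fs)
    taper = np.ones(n)
    taper[-16:] = 0.5 + 0.5 * np.cos(np.linspace(0, np.pi, 16))

    left = np.empty((len(directions), n))
    right = np.empty((len(directions), n))
    for i, d in enumerate(directions):
        l_db, r_db = head_magnitude_db(
            freqs, d.azimuth_deg, d.elevation_deg, params, condition, seed
        )
        itd_s = head_itd_us(d.azimuth_deg, params) * 1e-6
        # positive ITD = right ear first: delay the left ear, advance the right
        for ear_db, delay_s, out in (
            (l_db, base_delay_s + itd_s / 2.0, left),
            (r_db, base_delay_s - itd_s / 2.0, right),
        ):
            spec = _minimum_phase_spectrum(10.0 ** (ear_db / 20.0), n_fft)
            spec = spec * np.exp(-2j * np.pi * freqs * delay_s)
            h = np.fft.irfft(spec, n=n_fft)[:n]
            out[i] = h * taper

    return HRIRSet(
        owl_id=owl_id or f"synthetic_{seed}",
        condition=condition,
        sample_rate_hz=fs,
        directions=directions,
        left=left,
        right=right,
        meta={"head_model": asdict(params), "seed": seed},
    )


# ---------------------------------------------------------------------------
# stimuli
# ---------------------------------------------------------------------------


def make_broadband_stimulus(
    band_lo_hz: float,
    band_hi_hz: float,
    duration_s: float,
    sample_rate_hz: float,
    seed: int,
) -> np.ndarray:
    """Random-phase, flat-magnitude noise within [band_lo, band_hi], unit RMS."""
    if not (0.0 < band_lo_hz < band_hi_hz < sample_rate_hz / 2.0):
        raise ValueError(
            f"invalid band [{band_lo_hz}, {band_hi_hz}] at fs={sample_rate_hz}"
        )
    n = int(round(duration_s * sample_rate_hz))
    if n < 2:
        raise ValueError("duration too short")
    rng = np.random.default_rng(seed)
    freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate_hz)
    mag = ((freqs >= band_lo_hz) & (freqs <= band_hi_hz)).astype(float)
    phase = rng.uniform(0, 2 * np.pi, size=mag.shape)
    phase[0] = 0.0
    if n % 2 == 0:
        phase[-1] = 0.0
    x = np.fft.irfft(mag * np.exp(1j * phase), n=n)
    return x / np.sqrt(np.mean(x**2))


def make_vocalization_surrogate(
    duration_s: float,
    sample_rate_hz: float,
    seed: int,
) -> np.ndarray:
    """Spectro-temporally rich surrogate call: a harmonic-stack chirp over a
    noise floor, with energy across 0.5-10 kHz; unit RMS."""
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    n = int(round(duration_s * sample_rate_hz))
    rng = np.random.default_rng(seed)
    t = np.arange(n) / sample_rate_hz
    # fundamental sweeps 550 -> 1300 Hz (log chirp)
    f0 = 550.0 * (1300.0 / 550.0) ** (t / max(t[-1], 1e-9))
    phase0 = 2 * np.pi * np.cumsum(f0) / sample_rate_hz
    x = np.zeros(n)
    nyq = sample_rate_hz / 2.0
    for k in range(1, 17):
        if k * f0.max() >= min(10_500.0, nyq):
            break
        amp = k**-0.5
        x += amp * np.sin(k * phase0 + rng.uniform(0, 2 * np.pi))
    # broadband floor ~ -20 dB re the stack
    floor = make_broadband_stimulus(
        400.0, min(10_500.0, 0.98 * nyq), duration_s, sample_rate_hz, seed + 1
    )
    x = x / np.sqrt(np.mean(x**2)) + 0.1 * floor
    return x / np.sqrt(np.mean(x**2))


# ---------------------------------------------------------------------------
# model single units
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NeuronGroundTruth:
    """Generating parameters of one synthetic single unit."""

    best_itd_us: float
    best_freq_hz: float
    freq_lo_hz: float
    freq_hi_hz: float
    ild_best_db: float = 0.0
    ild_sigma: float = 50.0  # dB^2, Gaussian denominator exp(-(x)^2 / sigma)
    itd_env_sigma_us: float = 40.0
    side_peak_ratio: float = 0.5
    base_rate: float = 1.0
    max_rate: float = 60.0
    n_trials: int = 20
    trial_dur_s: float = 0.1
    freq_ramp_hz: float = 800.0

    def __post_init__(self) -> None:
        if not (self.freq_lo_hz < self.best_freq_hz < self.freq_hi_hz):
            raise ValueError("require freq_lo < best_freq < freq_hi")
        if not (0.0 <= self.side_peak_ratio < 1.0):
            raise ValueError("side_peak_ratio must be in [0, 1)")
        if not (self.max_rate > self.base_rate >= 0.0):
            raise ValueError("require max_rate > base_rate >= 0")


@dataclass
class TrialTable:
    """Per-trial spike counts along one stimulus axis."""

    axis: StimulusAxis
    values: np.ndarray  # (n_values,)
    counts: np.ndarray  # (n_values, n_trials) non-negative ints
    trial_dur_s: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.values.size:
            raise ValueError("counts must be (n_values, n_trials)")
        if (self.counts < 0).any():
            raise ValueError("spike counts must be non-negative")

    @property
    def n_trials(self) -> int:
        return self.counts.shape[1]

    def mean_rates(self) -> np.ndarray:
        """Mean firing rate (spikes/s) per stimulus value."""
        return self.counts.mean(axis=1) / self.trial_dur_s


def _trapezoid(f: np.ndarray, lo: float, hi: float, ramp: float) -> np.ndarray:
    """Piecewise-linear profile with value 0.5 at ``lo`` and ``hi``."""
    w = min(ramp, (hi - lo) / 2.0)
    up = np.clip((f - (lo - w)) / (2.0 * w), 0.0, 1.0)
    down = np.clip(((hi + w) - f) / (2.0 * w), 0.0, 1.0)
    return np.minimum(up, down)


def ground_truth_rates(
    gt: NeuronGroundTruth, axis: StimulusAxis, values: Sequence[float]
) -> np.ndarray:
    """Noiseless firing rate (spikes/s) of the generator at each stimulus value."""
    v = np.asarray(values, dtype=float)
    drive = gt.max_rate - gt.base_rate
    if axis == "itd_us":
        period_us = 1e6 / gt.best_freq_hz
        g = np.exp(-((v - gt.best_itd_us) ** 2) / (2 * gt.itd_env_sigma_us**2))
        for sign in (-1.0, 1.0):
            g = g + gt.side_peak_ratio * np.exp(
                -((v - gt.best_itd_us - sign * period_us) ** 2)
                / (2 * gt.itd_env_sigma_us**2)
            )
        return gt.base_rate + drive * np.minimum(g, 1.0)
    if axis == "ild_db":
        return gt.base_rate + drive * np.exp(-((v - gt.ild_best_db) ** 2) / gt.ild_sigma)
    if axis == "freq_hz":
        return gt.base_rate + drive * _trapezoid(
            v, gt.freq_lo_hz, gt.freq_hi_hz, gt.freq_ramp_hz
        )
    raise ValueError(f"unknown stimulus axis {axis!r}")


def simulate_tuning_curves(
    gt: NeuronGroundTruth,
    axis: StimulusAxis,
    values: Sequence[float],
    seed: int,
    n_trials: int | None = None,
) -> TrialTable:
    """Draw Poisson spike counts for each stimulus value of one protocol."""
    v = np.asarray(values, dtype=float)
    rng = np.random.default_rng(seed)
    rates = ground_truth_rates(gt, axis, v)
    n_tr = gt.n_trials if n_trials is None else n_trials
    counts = rng.poisson(rates[:, None] * gt.trial_dur_s, size=(v.size, n_tr))
    return TrialTable(
        axis=axis,
        values=v,
        counts=counts,
        trial_dur_s=gt.trial_dur_s,
        meta={"ground_truth": asdict(gt), "seed": seed},
    )


# standard tonal protocol: 0.5-10 kHz in 200 Hz steps
TONE_FREQS_HZ = np.arange(500.0, 10_001.0, 200.0)


def make_population_roster(
    group: str,
    n_neurons: int,
    seed: int,
    frontal_best_freq_hz: float | None = None,
) -> list[NeuronGroundTruth]:
    """Synthetic neuron populations mimicking the three experimental groups.

    Frontal neurons (|best ITD| <= 30 us) have group-dependent mean best
    frequency (normal 6.0 kHz > juvenile 4.9 kHz > ruff_removed 4.5 kHz) and
    best frequency declines with |best ITD| with a group-dependent slope.
    """
    presets = {
        # (frontal best freq Hz, slope Hz per us of |ITD|, dispersion Hz, itd span)
        "normal": (6000.0, -10.0, 700.0, 250.0),
        "ruff_removed": (4500.0, -3.0, 700.0, 250.0),
        "juvenile": (4900.0, -3.0, 900.0, 120.0),
    }
    if group not in presets:
        raise ValueError(f"unknown group {group!r}")
    mean_f, slope, disp, itd_span = presets[group]
    if frontal_best_freq_hz is not None:
        mean_f = frontal_best_freq_hz
    rng = np.random.default_rng(seed)
    roster = []
    for _ in range(n_neurons):
        # quadratic warp oversamples frontal space, as the midbrain map does
        itd = itd_span * rng.uniform() ** 2 * rng.choice([-1.0, 1.0])
        bf = mean_f + slope * abs(itd) + rng.normal(0.0, disp)
        bf = float(np.clip(bf, 1500.0, 9000.0))
        half_range = rng.uniform(1100.0, 1700.0)
        roster.append(
            NeuronGroundTruth(
                best_itd_us=float(itd),
                best_freq_hz=bf,
                freq_lo_hz=bf - half_range,
                freq_hi_hz=bf + half_range,
                ild_best_db=float(rng.normal(0.0, 4.0)),
                itd_env_sigma_us=float(np.clip(4e4 / bf, 25.0, 90.0)),
                side_peak_ratio=float(rng.uniform(0.3, 0.7)),
                base_rate=float(rng.uniform(0.5, 3.0)),
                max_rate=float(rng.uniform(40.0, 80.0)),
            )
        )
    return roster


# ---------------------------------------------------------------------------
# trial-table IO: TSV + JSON ground-truth sidecar
# ---------------------------------------------------------------------------


def write_trial_table(table: TrialTable, path: str | Path) -> None:
    """Write as long-format TSV (value, trial, count) with a JSON sidecar."""
    path = Path(path)
    n_val, n_tr = table.counts.shape
    df = pd.DataFrame(
        {
            "value": np.repeat(table.values, n_tr),
            "trial": np.tile(np.arange(n_tr), n_val),
            "count": table.counts.ravel(),
        }
    )
    df.insert(0, "axis", table.axis)
    df.to_csv(path, sep="\t", index=False)
    sidecar = {"axis": table.axis, "trial_dur_s": table.trial_dur_s, **table.meta}
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(sidecar, fh, indent=1, default=float)


def read_trial_table(path: str | Path) -> TrialTable:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    sidecar_path = path.with_suffix(path.suffix + ".json")
    meta: dict = {}
    trial_dur = 0.1
    if sidecar_path.exists():
        with open(sidecar_path) as fh:
            meta = json.load(fh)
        trial_dur = float(meta.pop("trial_dur_s", trial_dur))
    axis = str(df["axis"].iloc[0])
    values = np.sort(df["value"].unique())
    n_tr = int(df["trial"].max()) + 1
    counts = np.zeros((values.size, n_tr), dtype=int)
    lookup = {v: i for i, v in enumerate(values)}
    for _, row in df.iterrows():
        counts[lookup[row["value"]], int(row["trial"])] = int(row["count"])
    meta.pop("axis", None)
    return TrialTable(axis=axis, values=values, counts=counts, trial_dur_s=trial_dur, meta=meta)
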