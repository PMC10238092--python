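"""Read, write and validate binaural head-related impulse-response (HRIR) sets.

The canonical on-disk dialect is a JSON manifest plus one stereo 32-bit-float
WAV file per direction (channel 0 = left ear).  A read-only loader for the
SOFA ``SimpleFreeFieldHRIR`` convention (an HDF5 container) is also provided.

Sign conventions used package-wide:

* positive azimuth = source to the *right* of the midline,
* positive ITD = sound arrives at the *right* ear first
  (``t_left - t_right > 0``).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.io import wavfile

__all__ = [
    "Condition",
    "Direction",
    "HRIRSet",
    "GridSpec",
    "GridValidationReport",
    "read_hrir_set",
    "write_hrir_set",
    "read_sofa",
    "validate_grid",
    "FormatError",
    "ValidationError",
]

#: tolerance (degrees) for treating two directions as identical
DIRECTION_TOL_DEG = 1e-6

#: minimum sample rate accepted for any HRIR set (2x the 10 kHz analysis top)
MIN_SAMPLE_RATE_HZ = 20_000.0


class FormatError(ValueError):
    """Raised when an on-disk artifact does not match the expected layout."""


class ValidationError(ValueError):
    """Raised when data violates an HRIRSet invariant."""


class Condition(str, Enum):
    """Head condition of an HRIR set."""

    NORMAL = "normal"
    RUFF_REMOVED = "ruff_removed"
    SYNTHETIC_CUSTOM = "synthetic_custom"


@dataclass(frozen=True, order=True)
class Direction:
    """A source direction in degrees.

    Positive azimuth is to the right of the midline; positive elevation is up.
    """

    azimuth_deg: float
    elevation_deg: float = 0.0

    def __post_init__(self) -> None:
        if not (-180.0 <= self.azimuth_deg <= 180.0):
            raise ValidationError(
                f"azimuth {self.azimuth_deg} outside [-180, 180] degrees"
            )
        if not (-90.0 <= self.elevation_deg <= 90.0):
            raise ValidationError(
                f"elevation {self.elevation_deg} outside [-90, 90] degrees"
            )

    def isclose(self, other: "Direction", tol: float = DIRECTION_TOL_DEG) -> bool:
        return (
            abs(self.azimuth_deg - other.azimuth_deg) <= tol
            and abs(self.elevation_deg - other.elevation_deg) <= tol
        )

    def mirrored(self) -> "Direction":
        """Same direction reflected through the median plane."""
        return Direction(-self.azimuth_deg, self.elevation_deg)


@dataclass
class HRIRSet:
    """One owl/condition's binaural impulse responses on a direction grid.

    ``left`` and ``right`` have shape ``(n_directions, n_taps)`` and share the
    ordering of ``directions``.
    """

    owl_id: str
    condition: Condition
    sample_rate_hz: float
    directions: list[Direction]
    left: np.ndarray
    right: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.condition = Condition(self.condition)
        self.left = np.asarray(self.left, dtype=np.float64)
        self.right = np.asarray(self.right, dtype=np.float64)
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        n = len(self.directions)
        if n < 1:
            raise ValidationError("HRIRSet requires at least one direction")
        if self.left.ndim != 2 or self.right.ndim != 2:
            raise ValidationError("impulse responses must be 2-D (direction, tap)")
        if self.left.shape != self.right.shape or self.left.shape[0] != n:
            raise ValidationError(
                f"impulse-response shapes {self.left.shape}/{self.right.shape} "
                f"inconsistent with {n} directions"
            )
        if not (np.isfinite(self.left).all() and np.isfinite(self.right).all()):
            raise ValidationError("impulse responses contain non-finite samples")
        if self.sample_rate_hz < MIN_SAMPLE_RATE_HZ:
            raise ValidationError(
                f"sample rate {self.sample_rate_hz} Hz below the "
                f"{MIN_SAMPLE_RATE_HZ:.0f} Hz minimum"
            )
        for i, a in enumerate(self.directions):
            for b in self.directions[i + 1 :]:
                if a.isclose(b):
                    raise ValidationError(f"duplicate direction {a}")

    # -- convenience --------------------------------------------------------
    @property
    def n_taps(self) -> int:
        return self.left.shape[1]

    @property
    def azimuths_deg(self) -> np.ndarray:
        return np.array([d.azimuth_deg for d in self.directions])

    @property
    def elevations_deg(self) -> np.ndarray:
        return np.array([d.elevation_deg for d in self.directions])

    def index_of(self, direction: Direction) -> int:
        for i, d in enumerate(self.directions):
            if d.isclose(direction):
                return i
        raise KeyError(f"direction {direction} not in set")

    def pair(self, direction: Direction) -> tuple[np.ndarray, np.ndarray]:
        """(left, right) impulse responses for one direction."""
        i = self.index_of(direction)
        return self.left[i], self.right[i]

    def subset(self, keep: Iterable[int]) -> "HRIRSet":
        idx = list(keep)
        return HRIRSet(
            owl_id=self.owl_id,
            condition=self.condition,
            sample_rate_hz=self.sample_rate_hz,
            directions=[self.directions[i] for i in idx],
            left=self.left[idx].copy(),
            right=self.right[idx].copy(),
            meta=dict(self.meta),
        )

    def mirrored(self) -> "HRIRSet":
        """Left/right-mirrored head: ears swapped, azimuths negated."""
        return HRIRSet(
            owl_id=self.owl_id + "_mirror",
            condition=self.condition,
            sample_rate_hz=self.sample_rate_hz,
            directions=[d.mirrored() for d in self.directions],
            left=self.right.copy(),
            right=self.left.copy(),
            meta=dict(self.meta),
        )


# ---------------------------------------------------------------------------
# canonical manifest dialect
# ---------------------------------------------------------------------------

MANIFEST_NAME = "hrir_manifest.json"


def write_hrir_set(hrir_set: HRIRSet, path: str | Path) -> None:
    """Write ``hrir_set`` as a JSON manifest plus one stereo WAV per direction.

    Amplitudes are stored as 32-bit floats, so the round trip is lossless for
    float32-representable data.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, d in enumerate(hrir_set.directions):
        fname = f"dir_{i:03d}_az{d.azimuth_deg:+08.2f}_el{d.elevation_deg:+07.2f}.wav"
        stereo = np.stack(
            [hrir_set.left[i], hrir_set.right[i]], axis=1
        ).astype(np.float32)
        wavfile.write(path / fname, int(round(hrir_set.sample_rate_hz)), stereo)
        entries.append(
            {
                "azimuth_deg": d.azimuth_deg,
                "elevation_deg": d.elevation_deg,
                "file": fname,
            }
        )
    manifest = {
        "owl_id": hrir_set.owl_id,
        "condition": hrir_set.condition.value,
        "sample_rate_hz": hrir_set.sample_rate_hz,
        "directions": entries,
    }
    with open(path / MANIFEST_NAME, "w") as fh:
        json.dump(manifest, fh, indent=1)


def read_hrir_set(path: str | Path) -> HRIRSet:
    """Read an HRIR set from a manifest directory or a SOFA file."""
    path = Path(path)
    if path.is_file() and path.suffix.lower() == ".sofa":
        return read_sofa(path)
    manifest_path = path / MANIFEST_NAME if path.is_dir() else path
    if not manifest_path.exists():
        raise FileNotFoundError(f"manifest not found: {manifest_path}")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    root = manifest_path.parent
    rate = float(manifest["sample_rate_hz"])
    directions: list[Direction] = []
    left, right = [], []
    for entry in manifest["directions"]:
        wav_path = root / entry["file"]
        if not wav_path.exists():
            raise FileNotFoundError(f"audio file missing: {wav_path}")
        wav_rate, data = wavfile.read(wav_path)
        if abs(wav_rate - rate) > 0.5:
            raise FormatError(
                f"{wav_path}: sample rate {wav_rate} != manifest rate {rate}"
            )
        if data.ndim != 2 or data.shape[1] != 2:
            raise FormatError(f"{wav_path}: expected 2-channel audio")
        directions.append(
            Direction(float(entry["azimuth_deg"]), float(entry["elevation_deg"]))
        )
        left.append(np.asarray(data[:, 0], dtype=np.float64))
        right.append(np.asarray(data[:, 1], dtype=np.float64))
    lengths = {len(x) for x in left}
    if len(lengths) != 1:
        raise FormatError(f"impulse responses have mixed lengths {sorted(lengths)}")
    return HRIRSet(
        owl_id=str(manifest["owl_id"]),
        condition=Condition(manifest["condition"]),
        sample_rate_hz=rate,
        directions=directions,
        left=np.array(left),
        right=np.array(right),
    )


# ---------------------------------------------------------------------------
# SOFA (AES69) reader, SimpleFreeFieldHRIR convention, read-only
# ---------------------------------------------------------------------------


def read_sofa(
    path: str | Path,
    owl_id: str | None = None,
    condition: Condition | str = Condition.SYNTHETIC_CUSTOM,
) -> HRIRSet:
    """Read a SOFA ``SimpleFreeFieldHRIR`` file via HDF5.

    SOFA azimuth is measured counter-clockwise (left positive); it is negated
    here to match the package convention (right positive) and wrapped to
    [-180, 180].
    """
    import h5py  # optional dependency, imported lazily

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"SOFA file not found: {path}")
    with h5py.File(path, "r") as fh:
        conv = fh.attrs.get("SOFAConventions", b"")
        if isinstance(conv, bytes):
            conv = conv.decode()
        if conv and conv != "SimpleFreeFieldHRIR":
            raise FormatError(f"unsupported SOFA convention {conv!r}")
        ir = np.asarray(fh["Data.IR"])  # (M, R, N)
        rate = float(np.asarray(fh["Data.SamplingRate"]).ravel()[0])
        pos = np.asarray(fh["SourcePosition"])  # (M, 3): az, el, dist
    if ir.ndim != 3 or ir.shape[1] != 2:
        raise FormatError(f"Data.IR has shape {ir.shape}; expected (M, 2, N)")
    directions = []
    for az_ccw, el, _ in pos:
        az = -float(az_ccw)  # CCW-positive -> right-positive
        az = (az + 180.0) % 360.0 - 180.0
        directions.append(Direction(az, float(el)))
    return HRIRSet(
        owl_id=owl_id or path.stem,
        condition=Condition(condition),
        sample_rate_hz=rate,
        directions=directions,
        left=ir[:, 0, :].astype(np.float64),
        right=ir[:, 1, :].astype(np.float64),
    )


# ---------------------------------------------------------------------------
# grid validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GridSpec:
    """Required measurement grid for an HRIR set."""

    azimuths_deg: tuple[float, ...]
    elevations_deg: tuple[float, ...] = (0.0,)

    @classmethod
    def standard_azimuth(cls) -> "GridSpec":
        """+-160 degrees at 20-degree steps, elevation 0."""
        return cls(tuple(float(a) for a in range(-160, 161, 20)))

    def directions(self) -> list[Direction]:
        return [
            Direction(az, el)
            for el in self.elevations_deg
            for az in self.azimuths_deg
        ]


@dataclass
class GridValidationReport:
    complete: bool
    missing: list[Direction]
    extra: list[Direction]


def validate_grid(hrir_set: HRIRSet, required: GridSpec) -> GridValidationReport:
    """Report missing/extra directions relative to ``required``.

    Extra directions do not make the set incomplete.
    """
    have = list(hrir_set.directions)
    missing = []
    for want in required.directions():
        if not any(want.isclose(d) for d in have):
            missing.append(want)
    wanted = required.directions()
    extra = [d for d in have if not any(d.isclose(w) for w in wanted)]
    return GridValidationReport(complete=not missing, missing=missing, extra=extra)


def elevation_zero_azimuth_order(hrir_set: HRIRSet) -> list[int]:
    """Indices of elevation-0 directions sorted by azimuth."""
    idx = [
        i
        for i, d in enumerate(hrir_set.directions)
        if abs(d.elevation_deg) <= DIRECTION_TOL_DEG
    ]
    idx.sort(key=lambda i: hrir_set.directions[i].azimuth_deg)
    if not idx:
        raise ValidationError("set has no elevation-0 directions")
    return idx
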