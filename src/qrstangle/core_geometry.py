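"""Conventional vectorcardiographic computation of the spatial QRS-T angle.

The VCG represents each heartbeat as a 3-D trajectory ``v(t) = (x(t), y(t),
z(t))`` over the orthogonal leads X, Y, Z.  The depolarization (QRS) and
repolarization (T) phases form two loops; each loop's dominant orientation is
summarized by a single vector, and the spatial QRS-T angle is the 3-D angle
between the dominant QRS and T vectors.  Wide angles (>= ~110 degrees) are
associated with elevated sudden-cardiac-death risk.

Conventions used throughout:

* vectors are ``numpy`` arrays of shape ``(3,)`` in mV;
* sample indices are 0-based and all windows include both endpoints;
* angles are reported in degrees in ``[0, 180]``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Literal

import numpy as np

__all__ = [
    "DegenerateVectorError",
    "Fiducials",
    "Loop",
    "VcgBeat",
    "dominant_vector_max",
    "dominant_vector_mean",
    "extract_loop",
    "loop_origin",
    "qrst_angle_conventional",
    "spatial_angle",
    "unit",
]

#: Length of the pre-QRS baseline window used for the loop origin, in seconds.
ORIGIN_WINDOW_S = 0.025


class DegenerateVectorError(ValueError):
    """A zero-magnitude vector (or all-zero loop) where a direction is needed."""


@dataclass(frozen=True)
class VcgBeat:
    """One signal-averaged heartbeat on the orthogonal leads X, Y, Z.

    Parameters
    ----------
    samples
        Array of shape ``(n, 3)``; column order X, Y, Z, in mV.
    sampling_rate
        Sampling frequency in Hz, constant and positive.
    """

    samples: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 2 or samples.shape[1] != 3:
            raise ValueError("VcgBeat samples must have shape (n, 3)")
        if samples.shape[0] < 2:
            raise ValueError("VcgBeat needs at least 2 samples")
        if not np.all(np.isfinite(samples)):
            raise ValueError("VcgBeat samples must be finite")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")
        object.__setattr__(self, "samples", samples)

    def __len__(self) -> int:
        return self.samples.shape[0]


@dataclass(frozen=True)
class Fiducials:
    """QRS/T boundary and R-peak sample indices on a beat (0-based, inclusive)."""

    qrs_onset: int
    qrs_offset: int
    t_onset: int
    t_offset: int
    r_peak: int

    def __post_init__(self) -> None:
        ok = (
            0 <= self.qrs_onset <= self.r_peak <= self.qrs_offset
            and self.qrs_offset < self.t_onset <= self.t_offset
        )
        if not ok:
            raise ValueError(f"inconsistent fiducials: {self}")

    def validate_against(self, n_samples: int) -> None:
        if self.t_offset >= n_samples:
            raise ValueError(
                f"fiducials extend to sample {self.t_offset} "
                f"but the beat has only {n_samples} samples"
            )


@dataclass(frozen=True)
class Loop:
    """A QRS or T loop: origin-subtracted trajectory samples of one phase."""

    samples: np.ndarray
    phase: Literal["QRS", "T"]

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 2 or samples.shape[1] != 3 or samples.shape[0] < 1:
            raise ValueError("Loop samples must have shape (n >= 1, 3)")
        object.__setattr__(self, "samples", samples)

    def __len__(self) -> int:
        return self.samples.shape[0]


def unit(v: np.ndarray) -> np.ndarray:
    """Return ``v`` rescaled to unit magnitude.

    Raises
    ------
    DegenerateVectorError
        If ``v`` has zero magnitude.
    """
    v = np.asarray(v, dtype=float)
    norm = np.linalg.norm(v)
    if norm == 0.0:
        raise DegenerateVectorError("cannot normalize a zero-magnitude vector")
    return v / norm


def spatial_angle(u1: np.ndarray, u2: np.ndarray) -> float:
    """Angle between two 3-D vectors in degrees, in ``[0, 180]``.

    Computed as ``atan2(||u1 x u2||, u1 . u2)``, which covers obtuse angles
    and is numerically stable near 0 and 180 degrees; the result is invariant
    to positive rescaling of either argument.
    """
    u1 = np.asarray(u1, dtype=float)
    u2 = np.asarray(u2, dtype=float)
    if np.linalg.norm(u1) == 0.0 or np.linalg.norm(u2) == 0.0:
        raise DegenerateVectorError("spatial angle undefined for zero vectors")
    cross = np.cross(u1, u2)
    return float(np.degrees(np.arctan2(np.linalg.norm(cross), np.dot(u1, u2))))


def loop_origin(beat: VcgBeat, qrs_onset: int) -> np.ndarray:
    """Loop origin: componentwise median over the 25 ms window ending at QRS onset.

    The window is ``[qrs_onset - round(0.025 * fs), qrs_onset]`` inclusive
    (13 samples at 500 Hz).  A window reaching before the first sample is
    clipped to sample 0 with a warning.
    """
    if not 0 <= qrs_onset < len(beat):
        raise ValueError("qrs_onset outside the beat")
    half = int(round(ORIGIN_WINDOW_S * beat.sampling_rate))
    start = qrs_onset - half
    if start < 0:
        warnings.warn(
            "origin window extends before the beat start; clipping to sample 0",
            stacklevel=2,
        )
        start = 0
    window = beat.samples[start : qrs_onset + 1]
    return np.median(window, axis=0)


def extract_loop(
    beat: VcgBeat, onset: int, offset: int, origin: np.ndarray, phase: str = "QRS"
) -> Loop:
    """Slice ``[onset, offset]`` (inclusive) out of the beat and subtract the origin."""
    if not (0 <= onset <= offset < len(beat)):
        raise ValueError(f"invalid loop bounds [{onset}, {offset}] for beat of length {len(beat)}")
    origin = np.asarray(origin, dtype=float)
    return Loop(beat.samples[onset : offset + 1] - origin, phase=phase)  # type: ignore[arg-type]


def dominant_vector_max(loop: Loop) -> np.ndarray:
    """The loop sample of maximal magnitude (earliest index wins ties)."""
    mags = np.linalg.norm(loop.samples, axis=1)
    return loop.samples[int(np.argmax(mags))].copy()


def dominant_vector_mean(loop: Loop) -> np.ndarray:
    """Mean of all loop samples whose magnitude is >= 70 % of the maximum.

    The threshold comparison is inclusive.  This average direction is more
    robust than the single maximal-magnitude sample when the loop morphology
    is complex, which is why it is the default labeling method.
    """
    mags = np.linalg.norm(loop.samples, axis=1)
    mmax = mags.max()
    if mmax == 0.0:
        raise DegenerateVectorError(f"all-zero {loop.phase} loop has no dominant direction")
    return loop.samples[mags >= 0.7 * mmax].mean(axis=0)


# Hook refining loop onsets/offsets before extraction.  The delineation
# refinement rules used with clinical delineators are not part of this
# package; the default leaves the fiducials untouched.
FiducialAdjuster = Callable[[VcgBeat, Fiducials], Fiducials]


def identity_adjuster(beat: VcgBeat, fid: Fiducials) -> Fiducials:
    return fid


def qrst_angle_conventional(
    beat: VcgBeat,
    fid: Fiducials,
    method: Literal["mean", "max"] = "mean",
    adjuster: FiducialAdjuster = identity_adjuster,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Dominant QRS/T vectors and the spatial QRS-T angle of one averaged beat.

    The loop origin (pre-QRS baseline median) is subtracted from both loops,
    each loop is summarized by its dominant vector (``"mean"``: mean of
    samples above 70 % of peak magnitude, the default; ``"max"``: the single
    peak-magnitude sample), and the angle between the two dominant vectors is
    returned in degrees.

    Returns
    -------
    (u_qrs, u_t, alpha)
        Dominant vectors in mV and the angle in degrees.

    Raises
    ------
    DegenerateVectorError
        If either loop is all-zero (e.g., a flat T wave); never silently 0.
    """
    fid = adjuster(beat, fid)
    fid.validate_against(len(beat))
    origin = loop_origin(beat, fid.qrs_onset)
    qrs_loop = extract_loop(beat, fid.qrs_onset, fid.qrs_offset, origin, phase="QRS")
    t_loop = extract_loop(beat, fid.t_onset, fid.t_offset, origin, phase="T")
    if method == "mean":
        u_qrs = dominant_vector_mean(qrs_loop)
        u_t = dominant_vector_mean(t_loop)
    elif method == "max":
        u_qrs = dominant_vector_max(qrs_loop)
        u_t = dominant_vector_max(t_loop)
    else:
        raise ValueError(f"unknown dominant-vector method {method!r}")
    alpha = spatial_angle(u_qrs, u_t)
    return u_qrs, u_t, alpha
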