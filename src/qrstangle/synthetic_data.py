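"""Synthetic 12-lead ECG records with known ground-truth QRS/T vectors.

Each synthetic heartbeat is a two-dipole model: the QRS and T phases are
Gaussian envelopes along fixed 3-D directions separated by a controllable
angle, with an optional derivative-of-Gaussian component orthogonal to the
QRS direction (``loop_spread``) that turns the QRS phase into a genuine loop
rather than a line segment.  The VCG is projected to the 8 independent
standard leads through the fixed right pseudo-inverse of the Kors matrix, so
the labeling pipeline's Kors step recovers the generating VCG exactly, and
the derived limb leads follow the standard linear relations.  This makes
every pipeline stage testable against closed-form ground truth; waveform
realism beyond two dipole phases (Q waves, ST deviation, arrhythmia) is
deliberately out of scope because the pipeline consumes signal-averaged
beats.

Records default to the PTB-XL geometry: 10 s at 500 Hz with 10 beats
(60 bpm).  Dataset metadata follows the cohort structure the pipeline
assumes: 48 % female, ages uniform on 18-90, six morphological classes whose
angle distributions are concentrated low for NORM and heavier above 90
degrees for the disease classes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .core_geometry import Fiducials, VcgBeat, spatial_angle
from .kors_vcg import Ecg12Record, derive_limb_leads, kors_matrix
from .labeling_split import MORPH_CLASSES
from . import wfdb_io

__all__ = [
    "SyntheticBeatSpec",
    "SyntheticRecord",
    "default_angle_sampler",
    "generate_beat",
    "generate_dataset",
    "generate_record",
    "kors_pseudo_inverse",
    "project_to_12lead",
    "sample_vector_pair",
    "write_dataset",
]

FS = 500.0  # Hz, PTB-XL record rate
RECORD_SECONDS = 10.0
BEATS_PER_RECORD = 10  # 60 bpm over 10 s
FIRST_R_S = 0.4  # leaves full averaging windows at both record edges
ENVELOPE_CUTOFF = 0.01  # fiducials at 1 % of each phase's peak envelope


@dataclass(frozen=True)
class SyntheticBeatSpec:
    """Ground-truth description of one synthetic beat.

    Widths are Gaussian standard deviations in ms; centers are relative to
    the R peak.  ``loop_spread`` adds a derivative-of-Gaussian component of
    that relative magnitude orthogonal to the QRS direction.
    """

    alpha_true: float = 60.0  # degrees
    qrs_direction: tuple[float, float, float] | None = None  # unit; random if None
    qrs_magnitude: float = 1.5  # mV
    t_magnitude: float = 0.5  # mV
    qrs_width: float = 12.0  # ms (Gaussian sigma)
    t_width: float = 50.0  # ms
    qrs_center: float = 0.0  # ms relative to R peak
    t_center: float = 300.0  # ms
    loop_spread: float = 0.15  # fraction of QRS magnitude
    noise_sd: float = 0.02  # mV, white noise on the independent leads
    sex_code: int = 0
    age_years: float = 55.0
    morph_class: str = "NORM"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha_true <= 180.0:
            raise ValueError("alpha_true must lie in [0, 180] degrees")
        if self.qrs_width <= 0 or self.t_width <= 0:
            raise ValueError("widths must be positive")
        if self.t_center <= self.qrs_center:
            raise ValueError("T center must follow the QRS center")
        if self.morph_class not in MORPH_CLASSES:
            raise ValueError(f"unknown morphological class {self.morph_class!r}")


@dataclass
class SyntheticRecord:
    """A generated 12-lead record together with its ground truth."""

    record: Ecg12Record
    u_qrs_true: np.ndarray  # mV
    u_t_true: np.ndarray  # mV
    alpha_true: float  # degrees
    fiducials: Fiducials  # on the beat/averaging window (R at pre-window index)
    r_peaks: np.ndarray  # absolute sample indices in the record
    spec: SyntheticBeatSpec


def sample_vector_pair(
    alpha_true: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Unit vectors at exactly ``alpha_true`` degrees apart.

    The first is uniform on the sphere; the second sits at the requested
    angle with uniformly random azimuth about the first, so repeated draws at
    a fixed angle cover all octants.
    """
    if not 0.0 <= alpha_true <= 180.0:
        raise ValueError("alpha_true must lie in [0, 180]")
    u1 = rng.normal(size=3)
    u1 /= np.linalg.norm(u1)
    helper = np.array([1.0, 0.0, 0.0]) if abs(u1[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(u1, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u1, e1)
    phi = rng.uniform(0.0, 2.0 * np.pi)
    a = np.radians(alpha_true)
    u2 = np.cos(a) * u1 + np.sin(a) * (np.cos(phi) * e1 + np.sin(phi) * e2)
    return u1, u2


def _orthogonal_unit(u: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    helper = rng.normal(size=3)
    v = np.cross(u, helper)
    n = np.linalg.norm(v)
    while n < 1e-8:  # pragma: no cover - vanishing probability
        helper = rng.normal(size=3)
        v = np.cross(u, helper)
        n = np.linalg.norm(v)
    return v / n


def _envelope(t: np.ndarray, center: float, sigma: float) -> np.ndarray:
    """Compactly supported Gaussian envelope with unit peak.

    The raw Gaussian is shifted and rescaled so it reaches exactly zero at
    the 1 % cutoff that defines the phase window, making the beat strictly
    isoelectric outside its QRS/T windows -- as the loop-origin model
    assumes of the pre-QRS baseline.
    """
    g = np.exp(-((t - center) ** 2) / (2.0 * sigma**2))
    return np.maximum(0.0, g - ENVELOPE_CUTOFF) / (1.0 - ENVELOPE_CUTOFF)


def generate_beat(
    spec: SyntheticBeatSpec,
    pre_s: float = 0.300,
    post_s: float = 0.500,
    fs: float = FS,
) -> tuple[VcgBeat, Fiducials, dict]:
    """One synthetic VCG beat over the averaging window (R at ``pre_s``).

    The trajectory is ``m_QRS u_QRS g(t) + loop_spread m_QRS u_perp g'(t) +
    m_T u_T g_T(t) + noise`` with Gaussian envelopes.  Fiducials are placed
    where each phase's envelope crosses 1 % of its peak; overlapping QRS/T
    windows are rejected.  With ``loop_spread = 0`` and ``noise_sd = 0`` the
    dominant mean vector of each phase lies exactly along its generating
    direction.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.qrs_direction is not None:
        u_qrs = np.asarray(spec.qrs_direction, dtype=float)
        u_qrs = u_qrs / np.linalg.norm(u_qrs)
        e1 = _orthogonal_unit(u_qrs, rng)
        e2 = np.cross(u_qrs, e1)
        phi = rng.uniform(0.0, 2.0 * np.pi)
        a = np.radians(spec.alpha_true)
        u_t = np.cos(a) * u_qrs + np.sin(a) * (np.cos(phi) * e1 + np.sin(phi) * e2)
    else:
        u_qrs, u_t = sample_vector_pair(spec.alpha_true, rng)

    half_width_ms = np.sqrt(2.0 * np.log(1.0 / ENVELOPE_CUTOFF))
    qrs_half = half_width_ms * spec.qrs_width
    t_half = half_width_ms * spec.t_width
    if spec.qrs_center + qrs_half >= spec.t_center - t_half:
        raise ValueError("QRS and T windows overlap; widen the centers or narrow the widths")

    n = int(round((pre_s + post_s) * fs)) + 1
    r_index = int(round(pre_s * fs))
    t_ms = (np.arange(n) - r_index) / fs * 1000.0

    g_qrs = _envelope(t_ms, spec.qrs_center, spec.qrs_width)
    g_t = _envelope(t_ms, spec.t_center, spec.t_width)
    samples = (
        spec.qrs_magnitude * g_qrs[:, None] * u_qrs
        + spec.t_magnitude * g_t[:, None] * u_t
    )
    if spec.loop_spread > 0.0:
        u_perp = _orthogonal_unit(u_qrs, rng)
        dgauss = -(t_ms - spec.qrs_center) / spec.qrs_width * g_qrs
        dgauss /= np.exp(-0.5)  # unit peak
        samples += spec.loop_spread * spec.qrs_magnitude * dgauss[:, None] * u_perp
    if spec.noise_sd > 0.0:
        samples = samples + rng.normal(0.0, spec.noise_sd, size=samples.shape)

    def clip(x: float) -> int:
        return int(np.clip(round(x), 0, n - 1))

    fid = Fiducials(
        qrs_onset=clip(r_index + (spec.qrs_center - qrs_half) / 1000.0 * fs),
        qrs_offset=clip(r_index + (spec.qrs_center + qrs_half) / 1000.0 * fs),
        t_onset=clip(r_index + (spec.t_center - t_half) / 1000.0 * fs),
        t_offset=clip(r_index + (spec.t_center + t_half) / 1000.0 * fs),
        r_peak=clip(r_index + spec.qrs_center / 1000.0 * fs),
    )
    truth = {
        "u_qrs": spec.qrs_magnitude * u_qrs,
        "u_t": spec.t_magnitude * u_t,
        "alpha": float(spatial_angle(u_qrs, u_t)),
    }
    return VcgBeat(samples, fs), fid, truth


@lru_cache(maxsize=1)
def kors_pseudo_inverse() -> np.ndarray:
    """Fixed 8x3 right pseudo-inverse P of the Kors matrix M (M @ P = I)."""
    return np.linalg.pinv(kors_matrix())


def project_to_12lead(xyz: np.ndarray) -> dict[str, np.ndarray]:
    """Project a VCG trajectory ``(n, 3)`` to all 12 standard leads.

    The 8 independent leads are ``P @ [X;Y;Z]`` with P the Kors
    pseudo-inverse, so the Kors reconstruction recovers the VCG exactly; the
    derived limb leads are computed from I and II.
    """
    xyz = np.asarray(xyz, dtype=float)
    eight = xyz @ kors_pseudo_inverse().T  # (n, 8) in I, II, V1..V6 order
    leads = {name: eight[:, i] for i, name in enumerate(
        ("I", "II", "V1", "V2", "V3", "V4", "V5", "V6"))}
    leads.update(derive_limb_leads(leads["I"], leads["II"]))
    return leads


def generate_record(spec: SyntheticBeatSpec, record_id: str = "synth") -> SyntheticRecord:
    """A 10 s, 500 Hz, 12-lead record of repeated copies of one beat.

    The clean beat repeats at 60 bpm; white noise of ``spec.noise_sd`` is
    added independently per independent lead (derived limb leads keep their
    exact linear relations to I and II).
    """
    clean_spec = replace(spec, noise_sd=0.0)
    beat, fid, truth = generate_beat(clean_spec)
    n_total = int(round(RECORD_SECONDS * FS))
    r_peaks = (FIRST_R_S + np.arange(BEATS_PER_RECORD)) * FS
    r_peaks = r_peaks.round().astype(int)

    xyz = np.zeros((n_total, 3))
    r_index = int(round(0.300 * FS))
    beat_len = len(beat)
    for r in r_peaks:
        start = r - r_index
        xyz[start : start + beat_len] += beat.samples

    leads = project_to_12lead(xyz)
    if spec.noise_sd > 0.0:
        rng = np.random.default_rng(spec.seed + 1)
        for name in ("I", "II", "V1", "V2", "V3", "V4", "V5", "V6"):
            leads[name] = leads[name] + rng.normal(0.0, spec.noise_sd, size=n_total)
        derived = derive_limb_leads(leads["I"], leads["II"])
        leads.update(derived)

    record = Ecg12Record(
        signals=leads,
        sampling_rate=FS,
        record_id=record_id,
        metadata={
            "sex": "F" if spec.sex_code else "M",
            "age": spec.age_years,
            "diagnostic_class": spec.morph_class if spec.morph_class != "LOWM" else "NORM",
            "afib_aflutter": False,
            "brady_tachy_sinus_arrhythmia": False,
        },
    )
    return SyntheticRecord(
        record=record,
        u_qrs_true=truth["u_qrs"],
        u_t_true=truth["u_t"],
        alpha_true=truth["alpha"],
        fiducials=fid,
        r_peaks=r_peaks,
        spec=spec,
    )


# -- dataset-level sampling -------------------------------------------------

#: Default class mix, NORM-dominated with a small LOWM fraction.
DEFAULT_CLASS_MIX = {
    "NORM": 0.44,
    "MI": 0.13,
    "CD": 0.13,
    "STTC": 0.12,
    "HYP": 0.08,
    "LOWM": 0.10,
}

FEMALE_FRACTION = 0.48


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, low: float = 0.0, high: float = 180.0
) -> float:
    while True:
        x = rng.normal(mean, sd)
        if low <= x <= high:
            return x


def default_angle_sampler(morph_class: str, rng: np.random.Generator) -> float:
    """Class-dependent angle draw: NORM concentrated low, disease classes
    with substantial mass above 90 degrees, LOWM broad."""
    if morph_class == "NORM":
        return _truncated_normal(rng, 40.0, 22.0)
    if morph_class == "LOWM":
        return _truncated_normal(rng, 75.0, 45.0)
    if rng.random() < 0.55:
        return _truncated_normal(rng, 60.0, 30.0)
    return _truncated_normal(rng, 115.0, 30.0)


AngleSampler = Callable[[str, np.random.Generator], float]


def uniform_angle_sampler(morph_class: str, rng: np.random.Generator) -> float:
    return rng.uniform(0.0, 180.0)


def generate_dataset(
    n: int,
    angle_distribution: AngleSampler | str = "default",
    class_mix: dict[str, float] | None = None,
    noise_sd: float = 0.02,
    loop_spread: float = 0.15,
    seed: int = 0,
) -> tuple[list[SyntheticRecord], pd.DataFrame]:
    """Generate ``n`` records plus their ground-truth label table.

    ``angle_distribution`` may be "default" (class-dependent), "uniform", or
    any callable ``(morph_class, rng) -> degrees``.  Reproducible under
    ``seed``: identical seeds give identical records and tables.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    sampler: AngleSampler
    if angle_distribution == "default":
        sampler = default_angle_sampler
    elif angle_distribution == "uniform":
        sampler = uniform_angle_sampler
    else:
        sampler = angle_distribution  # type: ignore[assignment]
    mix = class_mix or DEFAULT_CLASS_MIX
    classes = list(mix)
    probs = np.array([mix[c] for c in classes], dtype=float)
    probs /= probs.sum()

    rng = np.random.default_rng(seed)
    records = []
    rows = []
    for i in range(n):
        morph = classes[rng.choice(len(classes), p=probs)]
        alpha = sampler(morph, rng)
        qrs_mag = rng.uniform(0.8, 2.2)
        ratio = rng.uniform(0.02, 0.095) if morph == "LOWM" else rng.uniform(0.15, 0.5)
        spec = SyntheticBeatSpec(
            alpha_true=alpha,
            qrs_magnitude=qrs_mag,
            t_magnitude=ratio * qrs_mag,
            loop_spread=loop_spread,
            noise_sd=noise_sd,
            sex_code=int(rng.random() < FEMALE_FRACTION),
            age_years=float(rng.uniform(18.0, 90.0)),
            morph_class=morph,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        rec = generate_record(spec, record_id=f"synth{i:05d}")
        records.append(rec)
        rows.append(
            {
                "record_id": rec.record.record_id,
                "alpha_true": rec.alpha_true,
                "xQRS_true": rec.u_qrs_true[0],
                "yQRS_true": rec.u_qrs_true[1],
                "zQRS_true": rec.u_qrs_true[2],
                "xT_true": rec.u_t_true[0],
                "yT_true": rec.u_t_true[1],
                "zT_true": rec.u_t_true[2],
                "sex_code": spec.sex_code,
                "age_years": spec.age_years,
                "morph_class": morph,
                "r_peaks": ";".join(str(int(r)) for r in rec.r_peaks),
            }
        )
    return records, pd.DataFrame(rows)


def write_dataset(
    records: list[SyntheticRecord], truth: pd.DataFrame, directory: str | Path
) -> Path:
    """Write records as WFDB files plus ``truth.csv``; returns the directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for rec in records:
        wfdb_io.write_record(rec.record, directory)
    truth.to_csv(directory / "truth.csv", index=False)
    return directory
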