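"""Target labeling and stratified train/validation splitting.

Each eligible 12-lead record is labeled with the dominant VCG vectors
``u_QRS`` and ``u_T`` (computed from the signal-averaged X, Y, Z beats by the
conventional approach), the spatial angle between them, scaled patient
metadata, and a morphological class.  The six classes are the five diagnostic
superclasses NORM, MI, CD, STTC, HYP plus LOWM (low-magnitude T wave:
``|u_T| / |u_QRS| < 0.1``), which overrides the diagnostic class.

The train/validation split is stratified by morphological class, sex, and 5
degree bins of the angle, assigning ``round(0.8 * n)`` of each stratum to
training (``round(0.5 * n)`` for LOWM, which is more error-prone) so both
sets preserve the angle distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_geometry import DegenerateVectorError, VcgBeat, qrst_angle_conventional
from .kors_vcg import Ecg12Record
from .preprocessing import (
    ModelInput,
    PreprocessingConfig,
    prepare_model_input,
    process_record,
)

__all__ = [
    "AngleLabel",
    "LABEL_COLUMNS",
    "MORPH_CLASSES",
    "classify_lowm",
    "label_record",
    "labels_to_frame",
    "stratified_split",
]

MORPH_CLASSES = ("NORM", "MI", "CD", "STTC", "HYP", "LOWM")

LOWM_RATIO = 0.1

LABEL_COLUMNS = [
    "record_id",
    "xQRS",
    "yQRS",
    "zQRS",
    "xT",
    "yT",
    "zT",
    "alpha_deg",
    "sex_code",
    "age_scaled",
    "morph_class",
]


@dataclass(frozen=True)
class AngleLabel:
    """Training target for one record."""

    record_id: str
    u_qrs: np.ndarray  # mV
    u_t: np.ndarray  # mV
    alpha: float  # degrees in [0, 180]
    sex_code: int
    age_scaled: float
    morph_class: str

    def __post_init__(self) -> None:
        if self.morph_class not in MORPH_CLASSES:
            raise ValueError(f"unknown morphological class {self.morph_class!r}")
        if not 0.0 <= self.alpha <= 180.0:
            raise ValueError("alpha must lie in [0, 180] degrees")


def classify_lowm(u_qrs: np.ndarray, u_t: np.ndarray) -> bool:
    """LOWM rule: T-vector magnitude strictly below one tenth of the QRS magnitude."""
    qrs_mag = float(np.linalg.norm(u_qrs))
    if qrs_mag == 0.0:
        raise DegenerateVectorError("zero QRS magnitude: LOWM rule undefined")
    return float(np.linalg.norm(u_t)) / qrs_mag < LOWM_RATIO


def label_record(
    record: Ecg12Record,
    r_peaks: np.ndarray | None = None,
    config: PreprocessingConfig = PreprocessingConfig(),
    model_leads: tuple[str, ...] | None = None,
) -> AngleLabel | tuple[AngleLabel, ModelInput]:
    """Label one record: preprocess, compute dominant vectors, classify.

    Runs the full pipeline (Kors transform, filtering, quality gating, beat
    averaging, conventional angle computation with the mean-based dominant
    vectors) and attaches scaled metadata and the morphological class.  When
    ``model_leads`` is given the matching :class:`ModelInput` is returned as
    well, guaranteeing labels and network inputs come from one preprocessing
    pass.

    Raises
    ------
    IneligibleRecordError / UnusableRecordError
        If the record fails the eligibility or quality rules.
    DegenerateVectorError
        If a loop is degenerate (e.g., flat T wave); such records are
        excluded from labeling rather than silently labeled 0.
    """
    avg = process_record(record, r_peaks=r_peaks, config=config)
    assert avg.fiducials is not None
    xyz = np.stack([avg.beats["X"], avg.beats["Y"], avg.beats["Z"]], axis=1)
    beat = VcgBeat(xyz, avg.sampling_rate)
    u_qrs, u_t, alpha = qrst_angle_conventional(beat, avg.fiducials, method="mean")

    sex = record.metadata.get("sex", 0)
    sex_code = {"M": 0, "m": 0, "F": 1, "f": 1}.get(sex, sex) if isinstance(sex, str) else int(sex)
    age = float(record.metadata.get("age", 0.0))
    age_scaled = float(np.clip(age / 100.0, 0.0, 1.0))
    diag = record.metadata.get("diagnostic_class", "NORM")
    if isinstance(diag, (list, tuple)):  # multi-label records: first listed class
        diag = diag[0] if diag else "NORM"
    morph = "LOWM" if classify_lowm(u_qrs, u_t) else str(diag)

    label = AngleLabel(
        record_id=record.record_id,
        u_qrs=u_qrs,
        u_t=u_t,
        alpha=alpha,
        sex_code=sex_code,
        age_scaled=age_scaled,
        morph_class=morph,
    )
    if model_leads is None:
        return label
    model_input = prepare_model_input(avg, model_leads, sex_code, age, config)
    return label, model_input


def labels_to_frame(labels: list[AngleLabel]) -> pd.DataFrame:
    """Assemble labels into the CSV-ready table."""
    rows = [
        {
            "record_id": lb.record_id,
            "xQRS": lb.u_qrs[0],
            "yQRS": lb.u_qrs[1],
            "zQRS": lb.u_qrs[2],
            "xT": lb.u_t[0],
            "yT": lb.u_t[1],
            "zT": lb.u_t[2],
            "alpha_deg": lb.alpha,
            "sex_code": lb.sex_code,
            "age_scaled": lb.age_scaled,
            "morph_class": lb.morph_class,
        }
        for lb in labels
    ]
    return pd.DataFrame(rows, columns=LABEL_COLUMNS)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def angle_bin(alpha: float, width: float = 5.0) -> int:
    """5-degree bin index of an angle; bins are [i, i+5) with [175, 180] closed."""
    return min(int(alpha // width), int(180.0 // width) - 1)


def stratified_split(
    labels: pd.DataFrame,
    seed: int,
    train_fraction: float = 0.8,
    lowm_fraction: float = 0.5,
    bin_width: float = 5.0,
    min_class_count: int = 100,
) -> pd.Series:
    """Stratified train/validation assignment preserving the angle distribution.

    Within every (morphological class x sex x 5 degree angle bin) stratum,
    ``round(f * n)`` records are drawn uniformly at random into the training
    set, where ``f`` is 0.8 except for the LOWM class (0.5); the remainder go
    to validation.  Classes rarer than ``min_class_count`` are dropped before
    splitting.  Identical seeds yield identical assignments.

    Returns a Series indexed like ``labels`` with values "train"/"validation";
    dropped records receive "excluded".
    """
    if labels.empty:
        raise ValueError("labels table is empty")
    rng = np.random.default_rng(seed)
    split = pd.Series("excluded", index=labels.index, dtype=object)

    class_counts = labels["morph_class"].value_counts()
    keep = labels["morph_class"].map(class_counts) >= min_class_count
    eligible = labels[keep]

    bins = eligible["alpha_deg"].map(lambda a: angle_bin(a, bin_width))
    groups = eligible.groupby(
        [eligible["morph_class"], eligible["sex_code"], bins], sort=True
    )
    for (morph, _sex, _bin), idx in sorted(groups.groups.items()):
        idx = np.array(sorted(idx))
        fraction = lowm_fraction if morph == "LOWM" else train_fraction
        n_train = _round_half_up(fraction * len(idx))
        chosen = rng.choice(idx, size=n_train, replace=False) if n_train else []
        split.loc[idx] = "validation"
        split.loc[list(chosen)] = "train"
    return split
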