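"""Kors regression reconstruction of the VCG (leads X, Y, Z) from 12-lead ECG.

Of the 12 standard leads only 8 are linearly independent: the limb leads III,
aVR, aVL, aVF are fixed combinations of I and II.  The Kors regression matrix
maps the 8 independent leads {I, II, V1..V6} to the orthogonal leads X, Y, Z
and is the transform that most accurately reconstructs Frank's VCG from a
standard 12-lead ECG.  The 3x8 coefficients are shipped as a version-
controlled plain-text table (``data/kors_matrix.tsv``, transcribed from the
published regression matrix of Kors et al. 1990) so they can be audited.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Any

import numpy as np

__all__ = [
    "ALL_12_LEADS",
    "INDEPENDENT_LEADS",
    "Ecg12Record",
    "derive_limb_leads",
    "ecg12_to_vcg",
    "kors_matrix",
]

#: The eight linearly independent standard leads, in Kors-matrix column order.
INDEPENDENT_LEADS = ("I", "II", "V1", "V2", "V3", "V4", "V5", "V6")

#: Standard 12-lead order used by PTB-XL records.
ALL_12_LEADS = ("I", "II", "III", "aVR", "aVL", "aVF", "V1", "V2", "V3", "V4", "V5", "V6")


@lru_cache(maxsize=1)
def kors_matrix() -> np.ndarray:
    """The 3x8 Kors coefficient matrix (rows X, Y, Z; columns I, II, V1..V6)."""
    text = resources.files("qrstangle").joinpath("data/kors_matrix.tsv").read_text()
    lines = [ln.split("\t") for ln in text.strip().splitlines()]
    header = tuple(lines[0][1:])
    if header != INDEPENDENT_LEADS:
        raise RuntimeError(f"unexpected lead order in kors_matrix.tsv: {header}")
    rows = {parts[0]: [float(x) for x in parts[1:]] for parts in lines[1:]}
    return np.array([rows["X"], rows["Y"], rows["Z"]], dtype=float)


class IncompleteRecordError(ValueError):
    """A required independent lead is missing and cannot be derived."""


@dataclass
class Ecg12Record:
    """A 12-lead ECG record with metadata, in the PTB-XL layout.

    Parameters
    ----------
    signals
        Mapping ``lead name -> 1-D array`` in mV; all leads equal length.
    sampling_rate
        Hz.
    record_id
        Identifier used in file names and label tables.
    metadata
        Free-form mapping; recognized keys are ``sex`` ("M"/"F"), ``age``
        (years), ``diagnostic_class`` (NORM/MI/CD/STTC/HYP), and boolean
        rhythm flags ``afib_aflutter`` and ``brady_tachy_sinus_arrhythmia``.
    """

    signals: dict[str, np.ndarray]
    sampling_rate: float
    record_id: str = "record"
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signals = {k: np.asarray(v, dtype=float) for k, v in self.signals.items()}
        lengths = {v.shape[0] for v in self.signals.values()}
        if len(lengths) > 1:
            raise ValueError("all leads must have equal length")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_samples(self) -> int:
        return next(iter(self.signals.values())).shape[0]

    def lead(self, name: str) -> np.ndarray:
        """Return a lead, deriving augmented/limb leads from I and II if absent."""
        if name in self.signals:
            return self.signals[name]
        if name in ("III", "aVR", "aVL", "aVF"):
            try:
                i, ii = self.signals["I"], self.signals["II"]
            except KeyError as exc:
                raise IncompleteRecordError(
                    f"cannot derive lead {name}: leads I and II required"
                ) from exc
            return derive_limb_leads(i, ii)[name]
        raise IncompleteRecordError(f"lead {name} missing from record {self.record_id}")


def derive_limb_leads(i: np.ndarray, ii: np.ndarray) -> dict[str, np.ndarray]:
    """Derived limb leads from I and II via Einthoven/Goldberger relations."""
    return {
        "III": ii - i,
        "aVR": -(i + ii) / 2.0,
        "aVL": i - ii / 2.0,
        "aVF": ii - i / 2.0,
    }


def ecg12_to_vcg(record: Ecg12Record) -> np.ndarray:
    """Reconstruct leads X, Y, Z from the 8 independent leads via the Kors matrix.

    Augmented/derived limb leads are never fed to the matrix.  Returns an
    array of shape ``(n_samples, 3)`` at the record's sampling rate.
    """
    missing = [name for name in INDEPENDENT_LEADS if name not in record.signals]
    if missing:
        raise IncompleteRecordError(
            f"record {record.record_id} lacks independent leads: {missing}"
        )
    stacked = np.stack([record.signals[name] for name in INDEPENDENT_LEADS], axis=0)
    return (kors_matrix() @ stacked).T
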