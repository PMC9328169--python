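"""Minimal WFDB record I/O for 12-lead ECGs (PTB-XL layout subset).

Supports the subset of the WFDB standard that PTB-XL-style records use: a
plain-text ``.hea`` header plus a single ``.dat`` file in format 16 (16-bit
little-endian two's-complement integers, samples interleaved across signals).
Record metadata (sex, age, diagnostic class, rhythm flags) travels in header
comment lines.  The same reader serves both real and synthetic records so the
downstream pipeline has exactly one input path.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any

import numpy as np

from .kors_vcg import Ecg12Record

__all__ = ["read_record", "write_record"]

_DEFAULT_GAIN = 1000.0  # ADC units per mV; PTB-XL uses 1 uV resolution

_META_KEYS = (
    "sex",
    "age",
    "diagnostic_class",
    "afib_aflutter",
    "brady_tachy_sinus_arrhythmia",
)
_BOOL_KEYS = ("afib_aflutter", "brady_tachy_sinus_arrhythmia")


def write_record(record: Ecg12Record, directory: str | Path, gain: float = _DEFAULT_GAIN) -> Path:
    """Write an ``Ecg12Record`` as ``<record_id>.hea`` + ``<record_id>.dat``.

    Returns the path of the header file.  Samples are quantized to int16 at
    ``gain`` ADC units per mV and clipped to the int16 range.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    leads = list(record.signals)
    data = np.stack([record.signals[name] for name in leads], axis=1)
    digital = np.clip(np.rint(data * gain), -32768, 32767).astype("<i2")

    name = record.record_id
    lines = [f"{name} {len(leads)} {record.sampling_rate:g} {record.n_samples}"]
    checksums = digital.astype(np.int64).sum(axis=0) % 65536
    for j, lead in enumerate(leads):
        cksum = int(checksums[j]) - 65536 if checksums[j] > 32767 else int(checksums[j])
        lines.append(
            f"{name}.dat 16 {gain:g}/mV 16 0 {int(digital[0, j])} {cksum} 0 {lead}"
        )
    for key in _META_KEYS:
        if key in record.metadata:
            value = record.metadata[key]
            if key in _BOOL_KEYS:
                value = int(bool(value))
            lines.append(f"# {key}: {value}")

    header = directory / f"{name}.hea"
    header.write_text("\n".join(lines) + "\n")
    digital.tofile(directory / f"{name}.dat")
    return header


def read_record(header_path: str | Path) -> Ecg12Record:
    """Read a format-16 WFDB record written by :func:`write_record` or PTB-XL-like."""
    header_path = Path(header_path)
    lines = [ln.strip() for ln in header_path.read_text().splitlines() if ln.strip()]
    signal_lines = [ln for ln in lines if not ln.startswith("#")]
    comments = [ln for ln in lines if ln.startswith("#")]

    rec_fields = signal_lines[0].split()
    name, n_sig = rec_fields[0], int(rec_fields[1])
    fs = float(rec_fields[2]) if len(rec_fields) > 2 else 250.0
    n_samp = int(rec_fields[3]) if len(rec_fields) > 3 else 0

    leads: list[str] = []
    gains: list[float] = []
    baselines: list[float] = []
    dat_file = None
    for ln in signal_lines[1 : 1 + n_sig]:
        parts = ln.split()
        dat_file = parts[0]
        fmt = parts[1]
        if fmt != "16":
            raise ValueError(f"unsupported WFDB signal format {fmt!r}")
        gain_spec = parts[2]
        gain_num = gain_spec.split("/")[0]
        if "(" in gain_num:
            gain_str, base_str = gain_num.rstrip(")").split("(")
            baselines.append(float(base_str))
        else:
            gain_str = gain_num
            baselines.append(0.0)
        gains.append(float(gain_str) if float(gain_str) != 0 else 200.0)
        leads.append(parts[-1])

    assert dat_file is not None
    digital = np.fromfile(header_path.parent / dat_file, dtype="<i2")
    digital = digital.reshape(-1, n_sig)
    if n_samp and digital.shape[0] != n_samp:
        raise ValueError(
            f"{dat_file}: expected {n_samp} samples per signal, found {digital.shape[0]}"
        )
    physical = (digital - np.array(baselines)) / np.array(gains)

    metadata: dict[str, Any] = {}
    for ln in comments:
        body = ln.lstrip("#").strip()
        if ":" not in body:
            continue
        key, _, value = body.partition(":")
        key, value = key.strip(), value.strip()
        if key == "age":
            metadata[key] = float(value)
        elif key in _BOOL_KEYS:
            metadata[key] = bool(int(value))
        elif key in _META_KEYS:
            metadata[key] = value
    return Ecg12Record(
        signals={lead: physical[:, j] for j, lead in enumerate(leads)},
        sampling_rate=fs,
        record_id=name,
        metadata=metadata,
    )
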