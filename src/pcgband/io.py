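"""Readers and writers for the formats the pipeline touches.

WAV audio (RIFF PCM16 mono), CSV cohort manifests, PhysioNet/CinC-2016 style
reference label files, and the metrics comparison table. Readers reject
malformed input rather than guessing; every writer produces files its paired
reader accepts.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .types import ABNORMAL, LABELS, NORMAL, Recording

__all__ = [
    "read_wav",
    "write_wav",
    "read_manifest",
    "write_manifest",
    "read_reference_csv",
    "write_metrics_csv",
    "read_metrics_csv",
]

_PCM16_FULL_SCALE = 32768.0


def read_wav(path: str | Path) -> Recording:
    """Read a mono PCM WAV file into an unlabeled Recording.

    Samples are scaled to [-1, 1]; absolute pressure calibration is never
    needed downstream. Multi-channel or non-integer codecs are rejected.
    """
    path = Path(path)
    if path.stat().st_size == 0:
        raise ValueError(f"{path}: empty file is not a WAV recording")
    try:
        fs, data = wavfile.read(path)
    except Exception as exc:  # wavfile raises bare ValueError on bad RIFF
        raise ValueError(f"{path}: not a readable RIFF/WAVE file ({exc})") from exc
    if data.ndim != 1:
        raise ValueError(f"{path}: only mono WAV is supported, got {data.ndim} channels")
    if data.dtype == np.int16:
        samples = data.astype(np.float64) / _PCM16_FULL_SCALE
    elif data.dtype == np.int32:
        samples = data.astype(np.float64) / 2147483648.0
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    else:
        raise ValueError(f"{path}: unsupported WAV sample format {data.dtype}")
    return Recording(samples, float(fs), None, record_id=path.stem)


def write_wav(path: str | Path, samples: np.ndarray, fs: float, peak: float = 0.95) -> None:
    """Write a waveform as 16-bit PCM mono, peak-normalized to ``peak``."""
    x = np.asarray(samples, dtype=np.float64)
    m = np.max(np.abs(x)) if x.size else 0.0
    if m > 0:
        x = x * (peak / m)
    q = np.clip(np.round(x * _PCM16_FULL_SCALE), -32768, 32767)
    wavfile.write(Path(path), int(round(fs)), q.astype(np.int16))


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a cohort manifest CSV and validate its contract."""
    df = pd.read_csv(path, dtype=str)
    required = ["record_id", "subject_id", "label", "wav_path"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: manifest missing columns {missing}")
    if df["record_id"].duplicated().any():
        dupes = df.loc[df["record_id"].duplicated(), "record_id"].tolist()
        raise ValueError(f"{path}: duplicate record ids {dupes}")
    bad = sorted(set(df["label"]) - set(LABELS))
    if bad:
        raise ValueError(f"{path}: unknown labels {bad}")
    per_subject = df.groupby("subject_id")["label"].nunique()
    mixed = per_subject[per_subject > 1].index.tolist()
    if mixed:
        raise ValueError(f"{path}: subjects with conflicting labels {mixed}")
    return df


def write_manifest(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_reference_csv(path: str | Path, dialect: str = "cohort") -> dict[str, str]:
    """Read a label reference file into a record -> {normal, abnormal} map.

    ``cohort``: our manifest format (header row).
    ``physionet2016``: headerless two-column ``record,label`` with label in
    {-1, 1}; -1 maps to normal, 1 to abnormal.
    """
    path = Path(path)
    if dialect == "cohort":
        df = read_manifest(path)
        return dict(zip(df["record_id"], df["label"]))
    if dialect != "physionet2016":
        raise ValueError(f"unknown dialect {dialect!r}")

    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = [p.strip() for p in line.split(",")]
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'record,label', got {line!r}")
            rec, tok = parts
            if tok == "-1":
                label = NORMAL
            elif tok == "1":
                label = ABNORMAL
            else:
                raise ValueError(f"{path}:{lineno}: unknown label token {tok!r} in {line!r}")
            if rec in mapping and mapping[rec] != label:
                raise ValueError(f"{path}:{lineno}: conflicting labels for record {rec!r}")
            mapping[rec] = label
    return mapping


_METRIC_COLUMNS = [
    "model",
    "band",
    "accuracy_mean",
    "accuracy_std",
    "sensitivity_mean",
    "sensitivity_std",
    "specificity_mean",
    "specificity_std",
]


def write_metrics_csv(table, path: str | Path) -> None:
    """Write a ComparisonTable (or its DataFrame) as CSV.

    One row per (model, band) plus one difference row per model; accepts the
    table object duck-typed via ``to_frame`` so this module needs no import
    from the experiment layer.
    """
    frame = table.to_frame() if hasattr(table, "to_frame") else pd.DataFrame(table)
    if frame.empty:
        frame = pd.DataFrame(columns=_METRIC_COLUMNS)
    frame.to_csv(path, index=False, float_format="%.12g")


def read_metrics_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
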