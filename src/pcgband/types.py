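"""Core value types shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

NORMAL = "normal"
ABNORMAL = "abnormal"
LABELS = (NORMAL, ABNORMAL)


@dataclass
class Recording:
    """A sampled heart-sound pressure waveform.

    Amplitude units are arbitrary: the measurement chain's absolute gain is
    never used downstream (clips are re-normalized before the transform).
    ``label`` may be ``None`` for recordings read from disk before a label
    manifest is joined.
    """

    samples: np.ndarray
    fs: float
    label: str | None = None
    subject_id: str = ""
    record_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("Recording.samples must be one-dimensional (mono)")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("Recording.samples must be finite")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.label is not None and self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs


@dataclass
class LabeledDataset:
    """A list of labeled recordings with a provenance tag.

    All recordings must share one sampling rate; resampling is an explicit
    user step, never silent.
    """

    recordings: list[Recording] = field(default_factory=list)
    provenance: str = "user"  # {synthetic, physionet, user}

    def __post_init__(self) -> None:
        fss = {r.fs for r in self.recordings}
        if len(fss) > 1:
            raise ValueError(f"recordings mix sampling rates {sorted(fss)}")

    @property
    def fs(self) -> float:
        if not self.recordings:
            raise ValueError("empty dataset has no sampling rate")
        return self.recordings[0].fs

    def __len__(self) -> int:
        return len(self.recordings)
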