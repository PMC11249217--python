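"""Band manipulation and spectral diagnostics.

The audible-only dataset variant is created by a 20 Hz Butterworth high-pass
applied forward-backward (zero phase, so timing of S1/S2 is untouched and the
effective order doubles). Also: one-sided FFT amplitude spectra, SNR
estimation, and fixed-length clip extraction with per-clip normalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

__all__ = [
    "FilterSpec",
    "design_highpass",
    "apply_zero_phase",
    "compute_spectrum",
    "estimate_snr",
    "segment_and_normalize",
]


@dataclass(frozen=True)
class FilterSpec:
    """A realizable high-pass filter for zero-phase application."""

    kind: str
    cutoff: float  # Hz
    fs: float  # Hz
    order: int  # single-pass order; forward-backward doubles it
    sos: np.ndarray  # second-order sections

    def gain_db(self, freqs) -> np.ndarray:
        """Single-pass magnitude response in dB at the given frequencies."""
        _, h = sps.sosfreqz(self.sos, worN=np.atleast_1d(freqs), fs=self.fs)
        mag = np.abs(h)
        with np.errstate(divide="ignore"):
            return 20.0 * np.log10(mag)


def design_highpass(fs: float, cutoff: float = 20.0, order: int = 4) -> FilterSpec:
    """Butterworth high-pass: maximally flat passband, -3 dB at the cutoff
    (single pass). Raises if the cutoff is not below Nyquist."""
    if not 0 < cutoff < fs / 2:
        raise ValueError(f"cutoff must satisfy 0 < {cutoff} < fs/2 = {fs / 2}")
    if order < 1:
        raise ValueError("order must be >= 1")
    sos = sps.butter(order, cutoff, btype="highpass", fs=fs, output="sos")
    _, poles, _ = sps.sos2zpk(sos)
    if np.any(np.abs(poles) >= 1.0):
        raise ValueError("designed filter is unstable")  # pragma: no cover
    return FilterSpec("high-pass", cutoff, fs, order, sos)


def apply_zero_phase(spec: FilterSpec, x: np.ndarray) -> np.ndarray:
    """Forward-backward filtering: no group delay, output length preserved."""
    x = np.asarray(x, dtype=np.float64)
    min_len = 3 * (2 * spec.order + 1)
    if len(x) <= min_len:
        raise ValueError(f"input of {len(x)} samples is too short for zero-phase "
                         f"filtering (need > {min_len})")
    return sps.sosfiltfilt(spec.sos, x)


def compute_spectrum(x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided amplitude spectrum ``(freqs, magnitude)``.

    Interior bins are doubled so a unit-amplitude tone reads ~1 at its bin;
    Parseval consistency (sum |X_k|^2 over the two-sided spectrum equals
    N * sum x^2) is preserved up to that known one-sided bookkeeping.
    """
    x = np.asarray(x, dtype=np.float64)
    if len(x) < 2:
        raise ValueError("need at least two samples")
    n = len(x)
    spec = np.abs(np.fft.rfft(x)) / n
    mag = spec.copy()
    mag[1:] *= 2.0
    if n % 2 == 0:
        mag[-1] /= 2.0  # Nyquist bin is not mirrored
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    return freqs, mag


def estimate_snr(signal_segment: np.ndarray, noise_segment: np.ndarray) -> float:
    """10*log10(P_signal / P_noise) with P the mean squared amplitude."""
    s = np.asarray(signal_segment, dtype=np.float64)
    w = np.asarray(noise_segment, dtype=np.float64)
    if s.size == 0 or w.size == 0:
        raise ValueError("segments must be non-empty")
    p_n = float(np.mean(w**2))
    if p_n == 0.0:
        raise ValueError("noise segment has zero power; SNR undefined")
    p_s = float(np.mean(s**2))
    return 10.0 * np.log10(p_s / p_n)


def segment_and_normalize(
    x: np.ndarray, fs: float, clip_len: float = 5.0, hop: float | None = None
) -> list[np.ndarray]:
    """Cut fixed-length clips and scale each to zero mean / max-abs 1.

    Trailing samples that do not fill a clip are dropped. An all-zero clip
    stays all-zero. ``hop`` defaults to ``clip_len`` (non-overlapping).
    """
    x = np.asarray(x, dtype=np.float64)
    if hop is None:
        hop = clip_len
    n_clip = int(round(clip_len * fs))
    n_hop = int(round(hop * fs))
    if n_clip > len(x):
        raise ValueError(f"clip_len {clip_len:g}s exceeds signal duration {len(x) / fs:g}s")
    if n_hop < 1:
        raise ValueError("hop must be positive")
    clips = []
    for start in range(0, len(x) - n_clip + 1, n_hop):
        clip = x[start:start + n_clip].copy()
        clip -= clip.mean()
        m = np.max(np.abs(clip))
        if m > 0:
            clip /= m
        clips.append(clip)
    return clips
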