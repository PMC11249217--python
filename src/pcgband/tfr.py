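"""Time-frequency representations: STFT, Morlet CWT, scalogram rendering.

The classification path uses the continuous wavelet transform with the
analytic Morlet mother wavelet

    psi(t) = pi^(-1/4) * exp(i*w0*t) * exp(-t^2/2),      w0 = 6,

evaluated over a log-spaced 2-300 Hz grid. A child wavelet at scale ``a`` and
translation ``b`` is ``psi_{b,a}(t) = a^(-1/2) * psi((t-b)/a)`` and the
coefficient is the inner product ``W(b,a) = integral f(t) conj(psi_{b,a}(t)) dt``
discretized as a Riemann sum on the sampling grid. The fast path evaluates
that sum for every ``b`` at once by FFT cross-correlation; tests compare it
against direct summation.

The fixed window of the STFT gives it a fixed frequency resolution, so
closely spaced low-frequency tones that the constant-Q CWT separates merge
into a single STFT ridge — the motivation for feeding scalograms, not
spectrograms, to the classifiers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.fft import fft, ifft, next_fast_len
from scipy.signal import ShortTimeFFT, get_window

__all__ = [
    "WindowSpec",
    "WaveletSpec",
    "TFImage",
    "morlet_wavelet",
    "stft",
    "cwt_morlet",
    "cwt_morlet_coeffs",
    "render_scalogram",
    "save_scalogram_png",
    "save_scalogram_array",
]

MORLET_W0 = 6.0  # standard analytic Morlet center frequency (rad per unit time)


@dataclass(frozen=True)
class WindowSpec:
    """STFT analysis window: named taper, length and hop in samples."""

    window: str = "hann"
    length: int = 200  # 100 ms at 2 kHz
    hop: int = 100

    def __post_init__(self) -> None:
        if self.length < 2:
            raise ValueError("window length must be >= 2 samples")
        if self.hop < 1:
            raise ValueError("hop must be >= 1 sample")


def _log_freq_grid(fmin: float, fmax: float, n: int) -> np.ndarray:
    return np.geomspace(fmin, fmax, n)


@dataclass(frozen=True)
class WaveletSpec:
    """Morlet CWT configuration.

    Scales follow from the frequency grid via ``a = w0 / (2*pi*f)`` (seconds),
    so the wavelet's oscillation at scale ``a`` sits at frequency ``f``.
    """

    w0: float = MORLET_W0
    freqs: np.ndarray = field(default_factory=lambda: _log_freq_grid(2.0, 300.0, 96))
    support: float = 5.0  # kernel half-width in units of the scale

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=np.float64)
        object.__setattr__(self, "freqs", f)
        if f.size == 0:
            raise ValueError("frequency grid is empty")
        if np.any(np.diff(f) <= 0) or f[0] <= 0:
            raise ValueError("frequency grid must be positive and strictly increasing")

    def scales(self) -> np.ndarray:
        return self.w0 / (2 * np.pi * self.freqs)


@dataclass
class TFImage:
    """Time x frequency magnitude matrix with explicit axes."""

    values: np.ndarray  # shape (n_times, n_freqs), non-negative magnitudes
    times: np.ndarray  # s
    freqs: np.ndarray  # Hz

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.shape != (len(self.times), len(self.freqs)):
            raise ValueError("axis lengths do not match the value matrix")
        if not np.all(np.isfinite(v)):
            raise ValueError("TFImage values must be finite")

    @property
    def energy(self) -> float:
        return float(np.sum(np.asarray(self.values, dtype=np.float64) ** 2))


def morlet_wavelet(t: np.ndarray, w0: float = MORLET_W0) -> np.ndarray:
    """The analytic Morlet mother wavelet evaluated at times ``t``."""
    t = np.asarray(t, dtype=np.float64)
    return np.pi**-0.25 * np.exp(1j * w0 * t) * np.exp(-(t**2) / 2)


def stft(x: np.ndarray, fs: float, spec: WindowSpec | None = None) -> TFImage:
    """Magnitude short-time Fourier transform, frequency rows 0..fs/2."""
    if spec is None:
        spec = WindowSpec()
    x = np.asarray(x, dtype=np.float64)
    if len(x) < spec.length:
        raise ValueError(f"signal ({len(x)} samples) shorter than the window ({spec.length})")
    win = get_window(spec.window, spec.length)
    sft = ShortTimeFFT(win, hop=spec.hop, fs=fs, fft_mode="onesided")
    S = sft.stft(x)  # (n_freqs, n_times)
    times = sft.t(len(x))
    return TFImage(np.abs(S).T, np.asarray(times), sft.f.copy())


# Cached kernel spectra keyed by (scale in ns, fs in mHz, support, w0, nfft,
# dtype): within one cohort every clip shares length and grid, so kernels are
# built once.
_KERNEL_CACHE: dict[tuple, np.ndarray] = {}
_KERNEL_CACHE_MAX = 4096


def _kernel_fft(a: float, fs: float, support: float, w0: float, nfft: int,
                dtype) -> tuple[np.ndarray, int]:
    m = int(np.ceil(support * a * fs))
    key = (int(round(a * 1e9)), int(round(fs * 1e3)), support, w0, nfft, np.dtype(dtype).str)
    if key not in _KERNEL_CACHE:
        if len(_KERNEL_CACHE) >= _KERNEL_CACHE_MAX:
            _KERNEL_CACHE.clear()
        dt = 1.0 / fs
        u = np.arange(-m, m + 1) * dt
        # g[j] = conj(psi(u/a)) / sqrt(a) * dt ; reversed so full convolution
        # computes the cross-correlation sum_n x[n] g[n-b].
        g = np.conj(morlet_wavelet(u / a, w0)) / np.sqrt(a) * dt
        _KERNEL_CACHE[key] = fft(g[::-1].astype(dtype), nfft)
    return _KERNEL_CACHE[key], m


def cwt_morlet_coeffs(
    x: np.ndarray, fs: float, spec: WaveletSpec | None = None, *,
    dtype=np.complex128,
) -> tuple[np.ndarray, np.ndarray]:
    """Complex CWT coefficients, shape (n_times, n_freqs), plus the frequency grid.

    ``dtype=np.complex64`` halves memory traffic for bulk dataset conversion;
    the default keeps full double precision.
    """
    if spec is None:
        spec = WaveletSpec()
    x = np.asarray(x, dtype=np.float64)
    if x.size == 0:
        raise ValueError("empty signal")
    if spec.freqs[-1] >= fs / 2:
        raise ValueError("frequency grid must stay below Nyquist")
    n = len(x)
    scales = spec.scales()
    # FFT-length ladder: short kernels (high frequencies) get away with much
    # less zero padding than the longest wavelet; the signal spectrum is
    # cached once per ladder rung. nfft >= n + 2m keeps circular wraparound
    # out of the retained samples.
    m_all = np.ceil(spec.support * scales * fs).astype(int)
    ladder = sorted({next_fast_len(n + 2 * int(m)) for m in
                     {m_all.max(), m_all.max() // 2, m_all.max() // 4,
                      m_all.max() // 8, m_all.min()}})
    x_cast = x.astype(np.complex64 if np.dtype(dtype) == np.complex64 else np.complex128)
    X_cache: dict[int, np.ndarray] = {}
    out = np.empty((n, len(scales)), dtype=dtype)
    for k, a in enumerate(scales):
        need = n + 2 * int(m_all[k])
        nfft = next(L for L in ladder if L >= need)
        if nfft not in X_cache:
            X_cache[nfft] = fft(x_cast, nfft)
        K, m = _kernel_fft(a, fs, spec.support, spec.w0, nfft, dtype)
        y = ifft(X_cache[nfft] * K)
        # Full convolution with the reversed kernel computes the correlation:
        # y[l] = sum_n x[n] g[n - (l - m)], so W(b) = y[b + m].
        out[:, k] = y[m:m + n]
    return out, spec.freqs.copy()


def cwt_morlet(x: np.ndarray, fs: float, spec: WaveletSpec | None = None, *,
               dtype=np.complex128) -> TFImage:
    """Morlet scalogram: |W(b, a)| mapped to (time, frequency)."""
    coeffs, freqs = cwt_morlet_coeffs(x, fs, spec, dtype=dtype)
    times = np.arange(len(x)) / fs
    return TFImage(np.abs(coeffs), times, freqs)


def ridge_frequencies(img: TFImage) -> np.ndarray:
    """Per-time-column frequency of maximum magnitude."""
    return img.freqs[np.argmax(img.values, axis=1)]


def render_scalogram(img: TFImage, out_h: int = 64, out_w: int = 64) -> np.ndarray:
    """Render a TFImage to an ``out_h x out_w`` matrix in [0, 1].

    Log-magnitude (log1p), per-image min-max scaling, bilinear resampling.
    Row 0 is the lowest frequency; with the CWT's geometric grid the row axis
    is log-frequency. A degenerate all-equal image renders as all zeros.
    """
    v = np.asarray(img.values, dtype=np.float64)
    if v.size == 0:
        raise ValueError("empty TFImage")
    n_t = v.shape[0]
    if n_t > 8 * out_w:
        # Block-average the (dense, sample-rate) time axis down to a few
        # columns per output pixel before the log/interp stages.
        step = n_t // (4 * out_w)
        keep = (n_t // step) * step
        v = v[:keep].reshape(-1, step, v.shape[1]).mean(axis=1)
    v = np.log1p(np.abs(v)).T  # (freq, time), row 0 = lowest frequency
    lo, hi = v.min(), v.max()
    if hi > lo:
        v = (v - lo) / (hi - lo)
    else:
        v = np.zeros_like(v)
    h, w = v.shape
    rows = np.linspace(0, h - 1, out_h)
    cols = np.linspace(0, w - 1, out_w)
    grid = np.meshgrid(rows, cols, indexing="ij")
    out = ndimage.map_coordinates(v, grid, order=1, mode="nearest")
    return np.clip(out, 0.0, 1.0)


def save_scalogram_png(image01: np.ndarray, path: str | Path) -> None:
    """Export a rendered [0,1] scalogram as an 8-bit grayscale PNG
    (low frequencies at the bottom of the picture)."""
    import imageio.v3 as iio

    img = np.clip(np.asarray(image01), 0, 1)
    iio.imwrite(Path(path), (img[::-1] * 255).round().astype(np.uint8))


def save_scalogram_array(img: TFImage, path_base: str | Path) -> None:
    """Dump a TFImage as ``<base>.npy`` plus a JSON axis sidecar."""
    base = Path(path_base)
    np.save(base.with_suffix(".npy"), np.asarray(img.values, dtype=np.float32))
    sidecar = {
        "times_s": [float(t) for t in (img.times[0], img.times[-1])],
        "n_times": int(len(img.times)),
        "freqs_hz": [float(f) for f in img.freqs],
    }
    base.with_suffix(".json").write_text(json.dumps(sidecar))
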