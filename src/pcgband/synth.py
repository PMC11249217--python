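"""Synthetic phonocardiogram cohorts.

The generator emulates the statistical structure of a clinically collected
heart-sound dataset: S1/S2 valve-closure bursts, an optional systolic murmur
(abnormal class only), a sub-20 Hz infrasound wave whose amplitude may differ
between classes, subject-level physiology offsets, heart-rate variability and
additive measurement noise calibrated to a target SNR.

Two dials separate where the class information lives in frequency:

* ``infra_effect`` multiplies the infrasound component's amplitude for the
  abnormal class (1.0 = no class information below 20 Hz);
* ``murmur_effect`` multiplies the murmur amplitude for the abnormal class
  (the murmur is absent from the normal class altogether).

With ``infra_effect = 1`` and no murmur the two classes are distributionally
identical, which makes chance-level downstream accuracy a testable property.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import signal as sps

from .io import write_manifest, write_wav
from .types import ABNORMAL, LABELS, NORMAL, Recording

__all__ = [
    "SoundComponent",
    "PcgSimConfig",
    "default_sim_config",
    "gen_cycle",
    "simulate_recording",
    "simulate_cohort",
    "table1_cohort",
    "load_sim_config",
    "TABLE1_SUBJECTS",
    "TABLE1_RECS_PER_SUBJECT",
]

# Collected-dataset shape being emulated: 85 normal / 62 pre-operative
# subjects contributing 276 / 195 recordings (plus 51 post-operative
# subjects with 177 recordings, outside the binary task).
TABLE1_SUBJECTS = (85, 62)
TABLE1_RECS_PER_SUBJECT = (276 / 85, 195 / 62)
TABLE1_POSTOP = (51, 177 / 51)


@dataclass(frozen=True)
class SoundComponent:
    """One damped acoustic burst within the cardiac cycle.

    When ``bandwidth`` is None the burst is a damped sinusoid
    ``amplitude * exp(-damping*(t-onset)) * sin(2*pi*center_freq*(t-onset))``;
    when set, the carrier is unit-RMS band-limited Gaussian noise spanning
    ``center_freq +/- bandwidth/2`` (used for murmurs).
    """

    center_freq: float  # Hz
    damping: float  # 1/s, exponential decay rate of the envelope
    amplitude: float  # relative pressure units
    onset: float  # s offset within the cardiac cycle
    onset_jitter_sd: float = 0.0  # s
    bandwidth: float | None = None  # Hz, noise-burst half-spread if set

    def __post_init__(self) -> None:
        if self.center_freq <= 0:
            raise ValueError("center_freq must be > 0")
        if self.damping <= 0:
            raise ValueError("damping must be > 0")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.onset < 0:
            raise ValueError("onset must be >= 0")
        if self.onset_jitter_sd < 0:
            raise ValueError("onset_jitter_sd must be >= 0")


def _default_s1() -> list[SoundComponent]:
    return [
        SoundComponent(30.0, 40.0, 1.00, 0.00, 0.005),
        SoundComponent(60.0, 40.0, 0.70, 0.00, 0.005),
        SoundComponent(100.0, 40.0, 0.40, 0.00, 0.005),
    ]


def _default_s2() -> list[SoundComponent]:
    return [
        SoundComponent(50.0, 50.0, 0.80, 0.35, 0.005),
        SoundComponent(90.0, 50.0, 0.60, 0.35, 0.005),
        SoundComponent(140.0, 50.0, 0.35, 0.35, 0.005),
    ]


def _default_infra() -> SoundComponent:
    # Slow hemodynamic wave well below the 20 Hz audibility split.
    return SoundComponent(8.0, 8.0, 1.2, 0.0, 0.010)


def _default_murmur() -> SoundComponent:
    # Systolic band-limited noise burst between S1 and S2 (100-250 Hz).
    return SoundComponent(175.0, 15.0, 0.25, 0.10, 0.010, bandwidth=150.0)


@dataclass
class PcgSimConfig:
    """Simulation parameters for one cohort."""

    fs: float = 2000.0  # Hz
    duration: float = 10.0  # s per recording
    hr_mean: float = 70.0  # bpm
    hr_sd: float = 3.0  # bpm
    s1_components: list[SoundComponent] = field(default_factory=_default_s1)
    s2_components: list[SoundComponent] = field(default_factory=_default_s2)
    murmur: SoundComponent | None = field(default_factory=_default_murmur)
    infra: SoundComponent = field(default_factory=_default_infra)
    infra_effect: float = 1.0
    murmur_effect: float = 1.0
    snr_db: float = 33.05  # additive-noise level; +inf disables noise
    subject_amp_sd: float = 0.10  # log-normal sd of per-subject amplitudes
    subject_freq_jitter: float = 0.05  # +/- fraction of component frequencies
    seed: int | None = None

    def components(self, label: str) -> list[SoundComponent]:
        """Effective component list for a class, effect dials applied."""
        if label not in LABELS:
            raise ValueError(f"unknown label {label!r}")
        comps = [replace(self.infra)]
        comps.extend(self.s1_components)
        comps.extend(self.s2_components)
        if label == ABNORMAL:
            comps[0] = replace(comps[0], amplitude=comps[0].amplitude * self.infra_effect)
            if self.murmur is not None:
                comps.append(
                    replace(self.murmur, amplitude=self.murmur.amplitude * self.murmur_effect)
                )
        return comps

    def validate(self) -> None:
        freqs = [c.center_freq for c in self.s1_components + self.s2_components]
        freqs.append(self.infra.center_freq)
        if self.murmur is not None:
            freqs.append(self.murmur.center_freq + (self.murmur.bandwidth or 0) / 2)
        fmax = max(freqs) if freqs else 0.0
        if fmax >= self.fs / 2:
            raise ValueError(
                f"component frequency {fmax:g} Hz is not below Nyquist ({self.fs / 2:g} Hz)"
            )
        if self.infra.center_freq >= 20.0:
            raise ValueError("infra component must lie strictly below 20 Hz")
        if self.duration <= 60.0 / self.hr_mean:
            raise ValueError("duration must cover at least one full cardiac cycle")
        if not (np.isfinite(self.snr_db) or self.snr_db == math.inf):
            raise ValueError("snr_db must be finite (or +inf to disable noise)")


def default_sim_config(**overrides) -> PcgSimConfig:
    cfg = PcgSimConfig(**overrides)
    cfg.validate()
    return cfg


def _render_component(comp: SoundComponent, n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """One burst on an ``n``-sample cycle grid. Consumes rng identically
    regardless of amplitude so that classes sharing a component list stay
    sample-for-sample comparable."""
    onset = comp.onset + rng.normal(0.0, comp.onset_jitter_sd)
    onset = max(onset, 0.0)
    t = np.arange(n) / fs
    rel = t - onset
    env = np.where(rel >= 0, np.exp(-comp.damping * np.clip(rel, 0, None)), 0.0)
    if comp.bandwidth is None:
        carrier = np.sin(2 * np.pi * comp.center_freq * rel)
        return comp.amplitude * env * np.where(rel >= 0, carrier, 0.0)
    lo = comp.center_freq - comp.bandwidth / 2
    hi = comp.center_freq + comp.bandwidth / 2
    noise = rng.standard_normal(n)
    sos = sps.butter(2, [lo, hi], btype="bandpass", fs=fs, output="sos")
    band = sps.sosfiltfilt(sos, noise)
    rms = np.sqrt(np.mean(band**2))
    if rms > 0:
        band = band / rms
    return comp.amplitude * env * band


def gen_cycle(
    config: PcgSimConfig, label: str, cycle_len: float, rng: np.random.Generator
) -> np.ndarray:
    """Synthesize one cardiac cycle of ``cycle_len`` seconds."""
    config.validate()
    comps = config.components(label)
    onmax = max((c.onset for c in comps), default=0.0)
    if cycle_len <= onmax:
        raise ValueError(f"cycle_len {cycle_len:g}s does not cover latest onset {onmax:g}s")
    n = int(round(cycle_len * config.fs))
    out = np.zeros(n)
    for comp in comps:
        if comp.center_freq >= config.fs / 2:
            raise ValueError(
                f"component at {comp.center_freq:g} Hz is not below Nyquist"
            )
        out += _render_component(comp, n, config.fs, rng)
    return out


def _draw_cycle_len(config: PcgSimConfig, rng: np.random.Generator) -> float:
    # 60 / Normal(hr_mean, hr_sd), truncated to a physiologic positive range.
    for _ in range(1000):
        hr = rng.normal(config.hr_mean, config.hr_sd)
        if np.isfinite(hr) and 20.0 < hr < 240.0:
            return 60.0 / hr
    raise RuntimeError("could not draw a positive heart rate")


def simulate_recording(
    config: PcgSimConfig,
    label: str,
    subject_id: str = "S000",
    record_id: str = "S000_r0",
    rng: np.random.Generator | None = None,
    return_parts: bool = False,
):
    """Simulate one recording: concatenated cycles plus calibrated noise.

    With ``return_parts=True`` also returns ``(clean, noise)`` so the realized
    SNR can be measured directly from the known decomposition.
    """
    config.validate()
    if rng is None:
        if config.seed is None:
            raise ValueError("simulate_recording needs an rng or a config seed")
        rng = np.random.default_rng(config.seed)
    n_total = int(round(config.fs * config.duration))
    pieces: list[np.ndarray] = []
    onsets: list[int] = []
    n_done = 0
    while n_done < n_total:
        clen = _draw_cycle_len(config, rng)
        cyc = gen_cycle(config, label, clen, rng)
        onsets.append(n_done)
        pieces.append(cyc)
        n_done += len(cyc)
    clean = np.concatenate(pieces)[:n_total]

    if np.isposinf(config.snr_db):
        noise = np.zeros_like(clean)
    else:
        p_sig = float(np.mean(clean**2))
        w = rng.standard_normal(n_total)
        if p_sig == 0.0:
            noise = np.zeros_like(clean)
        else:
            p_noise = p_sig / 10.0 ** (config.snr_db / 10.0)
            noise = w * np.sqrt(p_noise / np.mean(w**2))
    rec = Recording(clean + noise, config.fs, label, subject_id, record_id)
    rec.cycle_onsets = np.asarray(onsets)  # sample indices laid down by the generator
    if return_parts:
        return rec, clean, noise
    return rec


def _perturb_subject(config: PcgSimConfig, rng: np.random.Generator) -> PcgSimConfig:
    """Per-subject physiology offsets: log-normal amplitude factors and
    uniform frequency jitter applied component-wise."""

    def tweak(comp: SoundComponent) -> SoundComponent:
        amp = comp.amplitude * float(np.exp(rng.normal(0.0, config.subject_amp_sd)))
        freq = comp.center_freq * float(rng.uniform(1 - config.subject_freq_jitter,
                                                    1 + config.subject_freq_jitter))
        return replace(comp, amplitude=amp, center_freq=freq)

    return replace(
        config,
        infra=tweak(config.infra),
        s1_components=[tweak(c) for c in config.s1_components],
        s2_components=[tweak(c) for c in config.s2_components],
        murmur=None if config.murmur is None else tweak(config.murmur),
        hr_mean=float(np.clip(config.hr_mean + rng.normal(0.0, 4.0), 45.0, 120.0)),
    )


def _spread_counts(n_subjects: int, mean: float, rng: np.random.Generator) -> np.ndarray:
    """Deterministic total = round(n*mean), spread as evenly as possible with
    the remainder assigned to a seeded random subset of subjects."""
    total = max(n_subjects, int(round(n_subjects * mean)))
    base, rem = divmod(total, n_subjects)
    counts = np.full(n_subjects, base, dtype=int)
    extra = rng.choice(n_subjects, size=rem, replace=False)
    counts[extra] += 1
    return counts


def simulate_cohort(
    config: PcgSimConfig,
    n_normal_subjects: int,
    n_abnormal_subjects: int,
    recs_per_subject_mean: float | tuple[float, float] = 1.0,
    *,
    seed: int | None = None,
    out_dir: str | Path,
) -> pd.DataFrame:
    """Generate a labeled cohort of WAV files plus a CSV manifest.

    Subject-level labels (all of a subject's recordings share one label),
    per-subject physiology offsets, and a deterministic recording budget per
    class. Returns the manifest DataFrame; also writes ``manifest.csv`` and
    one 16-bit PCM WAV per recording under ``out_dir``.
    """
    if seed is None:
        raise ValueError("simulate_cohort requires an explicit seed: runs must be reproducible")
    if n_normal_subjects < 0 or n_abnormal_subjects < 0:
        raise ValueError("subject counts must be >= 0")
    if n_normal_subjects + n_abnormal_subjects < 1:
        raise ValueError("need at least one subject")
    config.validate()
    if isinstance(recs_per_subject_mean, (int, float)):
        recs_means = (float(recs_per_subject_mean), float(recs_per_subject_mean))
    else:
        recs_means = (float(recs_per_subject_mean[0]), float(recs_per_subject_mean[1]))

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(int(seed))
    count_rng = np.random.default_rng(root.spawn(1)[0])

    rows = []
    class_plan = [
        (NORMAL, "N", n_normal_subjects, recs_means[0]),
        (ABNORMAL, "A", n_abnormal_subjects, recs_means[1]),
    ]
    for label, prefix, n_subj, recs_mean in class_plan:
        if n_subj == 0:
            continue
        counts = _spread_counts(n_subj, recs_mean, count_rng)
        subject_seqs = root.spawn(n_subj)
        for i, seq in enumerate(subject_seqs):
            rng = np.random.default_rng(seq)
            subject_id = f"{prefix}{i + 1:03d}"
            sub_cfg = _perturb_subject(config, rng)
            for r in range(counts[i]):
                record_id = f"{subject_id}_r{r + 1}"
                rec = simulate_recording(sub_cfg, label, subject_id, record_id, rng)
                wav_path = out_dir / f"{record_id}.wav"
                write_wav(wav_path, rec.samples, rec.fs)
                rows.append(
                    {
                        "record_id": record_id,
                        "subject_id": subject_id,
                        "label": label,
                        "wav_path": wav_path.name,
                    }
                )
    manifest = pd.DataFrame(rows, columns=["record_id", "subject_id", "label", "wav_path"])
    write_manifest(manifest, out_dir / "manifest.csv")
    return manifest


def table1_cohort(
    out_dir: str | Path,
    *,
    seed: int,
    scale: float = 1.0,
    config: PcgSimConfig | None = None,
    include_postop: bool = False,
) -> pd.DataFrame:
    """The default cohort preset: collected-dataset proportions (85 normal /
    62 abnormal subjects; 276 / 195 recordings), scalable by one factor.

    ``include_postop`` adds a third, post-operative group (51 subjects, 177
    recordings at scale 1) for data-shape realism: acoustically normal-like
    (no murmur, baseline infrasound) but tagged ``group='postop'`` in the
    manifest so the binary comparison can exclude it, which the experiment
    stage does by default.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    if config is None:
        config = default_sim_config()
    n_norm = max(1, int(round(TABLE1_SUBJECTS[0] * scale)))
    n_abn = max(1, int(round(TABLE1_SUBJECTS[1] * scale)))
    manifest = simulate_cohort(
        config,
        n_norm,
        n_abn,
        TABLE1_RECS_PER_SUBJECT,
        seed=seed,
        out_dir=out_dir,
    )
    manifest["group"] = manifest["label"].map({NORMAL: "normal", ABNORMAL: "preop"})
    if include_postop:
        post_cfg = replace(config, murmur=None, infra_effect=1.0)
        n_post = max(1, int(round(TABLE1_POSTOP[0] * scale)))
        post = simulate_cohort(
            post_cfg, n_post, 0, TABLE1_POSTOP[1],
            seed=int(np.random.SeedSequence([int(seed), 997]).generate_state(1)[0] % 2**31),
            out_dir=Path(out_dir) / "postop",
        )
        post["subject_id"] = "P" + post["subject_id"].str[1:]
        post["record_id"] = "P" + post["record_id"].str[1:]
        post["wav_path"] = "postop/" + post["wav_path"]
        post["group"] = "postop"
        manifest = pd.concat([manifest, post], ignore_index=True)
    write_manifest(manifest, Path(out_dir) / "manifest.csv")
    return manifest


def load_sim_config(path: str | Path) -> PcgSimConfig:
    """Read a PcgSimConfig from a nested-key YAML file mirroring field names."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}

    def comp(d: dict) -> SoundComponent:
        return SoundComponent(**d)

    for key in ("s1_components", "s2_components"):
        if key in raw:
            raw[key] = [comp(d) for d in raw[key]]
    for key in ("murmur", "infra"):
        if key in raw and raw[key] is not None:
            raw[key] = comp(raw[key])
    cfg = PcgSimConfig(**raw)
    cfg.validate()
    return cfg
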