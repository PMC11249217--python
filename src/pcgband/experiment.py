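"""The headline computation: band-ablation comparison under subject-disjoint
k-fold cross-validation.

Every recording is turned into two paired scalogram datasets from identical
raw samples: the *infrasound* variant (full band) and the *audible* variant
(20 Hz zero-phase high-pass applied before the transform). Each model is
trained and evaluated per fold on both variants and the per-fold accuracy,
sensitivity and specificity (Positive = abnormal) are summarized as
mean +/- std over folds plus an (infrasound - audible) difference row.

Folding is at the subject level, stratified by class: all recordings of a
subject share the subject's fold, so no individual contributes data to both
the training and the test side of any split.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import models as mdl
from .io import read_manifest, read_wav
from .preprocess import apply_zero_phase, design_highpass
from .tfr import WaveletSpec, cwt_morlet, render_scalogram
from .types import ABNORMAL, NORMAL

__all__ = [
    "BandDataset",
    "FoldResult",
    "ComparisonTable",
    "make_band_variants",
    "subject_kfold",
    "confusion_metrics",
    "run_comparison",
    "INFRASOUND",
    "AUDIBLE",
]

INFRASOUND = "infrasound"  # full band, nothing removed
AUDIBLE = "audible"  # sub-20 Hz content removed
HIGHPASS_CUTOFF = 20.0  # Hz


@dataclass
class BandDataset:
    """Scalogram images for one band variant, aligned across variants."""

    band: str
    images: np.ndarray  # (N, H, W) in [0, 1]
    labels: np.ndarray  # strings from types.LABELS
    subject_ids: np.ndarray
    record_ids: np.ndarray

    def __len__(self) -> int:
        return len(self.images)

    @property
    def y(self) -> np.ndarray:
        return (self.labels == ABNORMAL).astype(np.float64)


def _clip_pairs(samples: np.ndarray, fs: float, clip_len: float):
    """Paired (full-band, audible) clips cut at identical boundaries.

    The audible clip reuses the full-band clip's normalization scale:
    per-clip max-abs renormalization would otherwise cancel the stop-band
    attenuation and re-inflate what the filter removed.
    """
    spec = design_highpass(fs, HIGHPASS_CUTOFF)
    filtered = apply_zero_phase(spec, samples)
    n_clip = int(round(clip_len * fs))
    pairs = []
    for start in range(0, len(samples) - n_clip + 1, n_clip):
        full = samples[start:start + n_clip].copy()
        full -= full.mean()
        scale = np.max(np.abs(full))
        aud = filtered[start:start + n_clip].copy()
        aud -= aud.mean()
        if scale > 0:
            full /= scale
            aud /= scale
        pairs.append((full, aud))
    return pairs


def make_band_variants(
    manifest: pd.DataFrame | str | Path,
    wav_dir: str | Path | None = None,
    *,
    clip_len: float = 5.0,
    image_hw: tuple[int, int] = (64, 64),
    wavelet: WaveletSpec | None = None,
) -> tuple[BandDataset, BandDataset]:
    """Build the paired (infrasound, audible) scalogram datasets for a cohort.

    Both variants pass through identical segmentation, Morlet CWT (2-300 Hz)
    and rendering; the audible variant is 20 Hz zero-phase high-passed first.
    Record ordering and labels are identical across the two variants.
    """
    if not isinstance(manifest, pd.DataFrame):
        manifest_path = Path(manifest)
        if wav_dir is None:
            wav_dir = manifest_path.parent
        manifest = read_manifest(manifest_path)
    if wav_dir is None:
        raise ValueError("wav_dir is required when passing a manifest DataFrame")
    wav_dir = Path(wav_dir)
    manifest = _binary_task_rows(manifest)

    imgs = {INFRASOUND: [], AUDIBLE: []}
    labels, subjects, records = [], [], []
    fs_seen: set[float] = set()
    for row in manifest.itertuples(index=False):
        rec = read_wav(wav_dir / row.wav_path)
        fs_seen.add(rec.fs)
        if len(fs_seen) > 1:
            raise ValueError(f"cohort mixes sampling rates {sorted(fs_seen)}")
        if wavelet is None:
            # default 2-300 Hz analysis grid, capped below Nyquist for
            # low-rate cohorts
            wavelet = WaveletSpec(freqs=np.geomspace(2.0, min(300.0, 0.45 * rec.fs), 96))
        for k, (full, aud) in enumerate(_clip_pairs(rec.samples, rec.fs, clip_len)):
            for band, clip in ((INFRASOUND, full), (AUDIBLE, aud)):
                img = cwt_morlet(clip, rec.fs, wavelet, dtype=np.complex64)
                imgs[band].append(render_scalogram(img, *image_hw))
            labels.append(row.label)
            subjects.append(row.subject_id)
            records.append(f"{row.record_id}_c{k}")

    labels = np.asarray(labels)
    subjects = np.asarray(subjects)
    records = np.asarray(records)
    out = tuple(
        BandDataset(band, np.asarray(imgs[band], dtype=np.float32), labels, subjects, records)
        for band in (INFRASOUND, AUDIBLE)
    )
    return out


def _binary_task_rows(manifest: pd.DataFrame) -> pd.DataFrame:
    """Positive = abnormal (pre-op), Negative = normal; a post-operative
    third group, when present, is excluded from the binary task."""
    if "group" in manifest.columns:
        return manifest[manifest["group"] != "postop"].reset_index(drop=True)
    return manifest


def subject_kfold(manifest: pd.DataFrame, k: int = 5, *, seed: int) -> dict[str, int]:
    """Stratified subject-level fold assignment: subject_id -> fold index.

    Subjects, not recordings, are partitioned; within each class subjects are
    shuffled and dealt round-robin so per-fold class counts differ by at most
    one subject from the global ratio.
    """
    subj = manifest[["subject_id", "label"]].drop_duplicates()
    if subj["subject_id"].duplicated().any():
        raise ValueError("a subject carries more than one label")
    rng = np.random.default_rng(seed)
    assignment: dict[str, int] = {}
    for label in (NORMAL, ABNORMAL):
        ids = subj.loc[subj["label"] == label, "subject_id"].to_numpy()
        if len(ids) < k:
            raise ValueError(
                f"class {label!r} has {len(ids)} subjects, fewer than k={k} folds"
            )
        rng.shuffle(ids)
        for i, sid in enumerate(ids):
            assignment[sid] = i % k
    return assignment


@dataclass
class FoldResult:
    fold: int
    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def accuracy(self) -> float:
        return 100.0 * (self.tp + self.tn) / (self.tp + self.fn + self.tn + self.fp)

    @property
    def sensitivity(self) -> float | None:
        pos = self.tp + self.fn
        return None if pos == 0 else 100.0 * self.tp / pos

    @property
    def specificity(self) -> float | None:
        neg = self.tn + self.fp
        return None if neg == 0 else 100.0 * self.tn / neg


def confusion_metrics(y_true: np.ndarray, y_prob: np.ndarray,
                      threshold: float = 0.5, fold: int = 0) -> FoldResult:
    """Confusion counts and percent metrics; Positive = abnormal.

    A metric whose denominator is empty is reported as None (missing), not 0.
    """
    y = np.asarray(y_true, dtype=np.float64).reshape(-1)
    p = np.asarray(y_prob, dtype=np.float64).reshape(-1)
    if y.shape != p.shape:
        raise ValueError("y_true and y_prob differ in length")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    pred = p >= threshold
    pos = y > 0.5
    return FoldResult(
        fold=fold,
        tp=int(np.sum(pred & pos)),
        fn=int(np.sum(~pred & pos)),
        tn=int(np.sum(~pred & ~pos)),
        fp=int(np.sum(pred & ~pos)),
    )


_METRICS = ("accuracy", "sensitivity", "specificity")


@dataclass
class ComparisonTable:
    """Per (model, band) mean +/- std of each metric over folds, plus
    (infrasound - audible) difference rows. Std is the population std over
    the k fold values."""

    fold_results: list[dict] = field(default_factory=list)

    def add(self, model: str, band: str, result: FoldResult) -> None:
        self.fold_results.append(
            {
                "model": model,
                "band": band,
                "fold": result.fold,
                "tp": result.tp,
                "fn": result.fn,
                "tn": result.tn,
                "fp": result.fp,
                "accuracy": result.accuracy,
                "sensitivity": result.sensitivity,
                "specificity": result.specificity,
            }
        )

    def summary(self, model: str, band: str) -> dict[str, float]:
        rows = [r for r in self.fold_results if r["model"] == model and r["band"] == band]
        if not rows:
            raise KeyError(f"no folds recorded for ({model}, {band})")
        out = {}
        for metric in _METRICS:
            vals = [r[metric] for r in rows if r[metric] is not None]
            out[f"{metric}_mean"] = float(np.mean(vals)) if vals else float("nan")
            out[f"{metric}_std"] = float(np.std(vals)) if vals else float("nan")
        return out

    def models(self) -> list[str]:
        seen = dict.fromkeys(r["model"] for r in self.fold_results)
        return list(seen)

    def bands(self, model: str) -> list[str]:
        seen = dict.fromkeys(r["band"] for r in self.fold_results if r["model"] == model)
        return list(seen)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for model in self.models():
            bands = self.bands(model)
            for band in bands:
                rows.append({"model": model, "band": band, **self.summary(model, band)})
            if INFRASOUND in bands and AUDIBLE in bands:
                si = self.summary(model, INFRASOUND)
                sa = self.summary(model, AUDIBLE)
                diff = {"model": model, "band": "difference"}
                for metric in _METRICS:
                    diff[f"{metric}_mean"] = si[f"{metric}_mean"] - sa[f"{metric}_mean"]
                    diff[f"{metric}_std"] = float("nan")
                rows.append(diff)
        columns = ["model", "band"] + [f"{m}_{s}" for m in _METRICS for s in ("mean", "std")]
        return pd.DataFrame(rows, columns=columns)

    def save_folds_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.fold_results, indent=1))


def _fold_seed(seed: int, *indices: int) -> int:
    ss = np.random.SeedSequence([int(seed), *[int(i) for i in indices]])
    return int(ss.generate_state(1)[0] % 2**31)


def run_comparison(
    manifest: pd.DataFrame | str | Path,
    wav_dir: str | Path | None = None,
    *,
    model_tags: tuple[str, ...] = ("cnn-dense",),
    cnn_cfg: mdl.CnnConfig | None = None,
    train_cfg: mdl.TrainConfig = mdl.REDUCED_TRAIN,
    k: int = 5,
    seed: int,
    clip_len: float = 5.0,
    datasets: tuple[BandDataset, BandDataset] | None = None,
) -> ComparisonTable:
    """Train/evaluate every (model, band) pair under one shared subject-level
    fold split and return the comparison table.

    ``datasets`` short-circuits scalogram construction when the paired band
    variants were already computed for this manifest.
    """
    if not isinstance(manifest, pd.DataFrame):
        manifest_path = Path(manifest)
        if wav_dir is None:
            wav_dir = manifest_path.parent
        manifest = read_manifest(manifest_path)
    manifest = _binary_task_rows(manifest)
    if cnn_cfg is None:
        cnn_cfg = mdl.CnnConfig()
    if datasets is None:
        datasets = make_band_variants(
            manifest, wav_dir, clip_len=clip_len, image_hw=cnn_cfg.input_hw
        )
    folds = subject_kfold(manifest, k, seed=_fold_seed(seed, 0))
    table = ComparisonTable()
    for mi, tag in enumerate(model_tags):
        for bi, ds in enumerate(datasets):
            fold_of = np.array([folds[s] for s in ds.subject_ids])
            y = ds.y
            for fold in range(k):
                test = fold_of == fold
                train_idx = ~test
                for side, mask in (("train", train_idx), ("test", test)):
                    if len(np.unique(y[mask])) < 2:
                        raise ValueError(
                            f"fold {fold} degenerates to one class on the {side} side"
                        )
                child = _fold_seed(seed, mi + 1, bi, fold)
                model = mdl.build_model(tag, cnn_cfg, seed=child)
                mdl.train(model, ds.images[train_idx], y[train_idx],
                          mdl.TrainConfig(
                              learning_rate=train_cfg.learning_rate,
                              batch_size=train_cfg.batch_size,
                              epochs=train_cfg.epochs,
                              seed=child,
                          ))
                probs = mdl.predict(model, ds.images[test])
                table.add(tag, ds.band, confusion_metrics(y[test], probs, fold=fold))
    return table
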