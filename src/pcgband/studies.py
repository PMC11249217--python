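"""Pre-registered study configurations for the band-ablation experiments.

These are the *study conditions*, fixed once: a compute-scaled cohort with
the collected dataset's class proportions (~120 subjects at scale 0.82), one
5-second recording per subject, 64x64 scalograms, 3-fold subject-disjoint CV
and the reduced 15-epoch training profile. The effect-size dials are the
only thing that varies between arms:

* signal arm — ``infra_effect = 1.6`` with a weak murmur (amplitude 0.12),
  so the infrasound band carries strong class information and the audible
  band a weak cue; the accuracy difference (infrasound - audible) should be
  positive.
* null arm — ``infra_effect = 1.0`` and no murmur: the two classes are
  distributionally identical and any accuracy difference is sampling noise.
"""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path


from . import models as mdl
from . import synth
from .experiment import ComparisonTable, run_comparison

__all__ = [
    "study_sim_config",
    "run_band_study",
    "accuracy_difference",
    "mean_band_accuracy",
]

STUDY_SCALE = 0.82  # 70 normal + 51 abnormal subjects
STUDY_DURATION_S = 5.0  # one clip per recording
STUDY_K = 3
WEAK_MURMUR_AMP = 0.12


def study_sim_config(infra_effect: float = 1.6,
                     murmur: bool = True) -> synth.PcgSimConfig:
    """Simulation config for one study arm."""
    cfg = synth.default_sim_config(duration=STUDY_DURATION_S, infra_effect=infra_effect)
    if murmur:
        cfg = replace(cfg, murmur=replace(cfg.murmur, amplitude=WEAK_MURMUR_AMP))
    else:
        cfg = replace(cfg, murmur=None)
    return cfg


def run_band_study(
    work_dir: str | Path,
    seed: int,
    *,
    infra_effect: float = 1.6,
    murmur: bool = True,
    scale: float = STUDY_SCALE,
    model_tags: tuple[str, ...] = ("cnn-dense",),
    k: int = STUDY_K,
    train_cfg: mdl.TrainConfig = mdl.REDUCED_TRAIN,
) -> ComparisonTable:
    """One full study run: simulate cohort, build band variants, CV-train."""
    cfg = study_sim_config(infra_effect=infra_effect, murmur=murmur)
    cohort_dir = Path(work_dir) / f"cohort_s{seed}"
    n_norm = max(1, round(synth.TABLE1_SUBJECTS[0] * scale))
    n_abn = max(1, round(synth.TABLE1_SUBJECTS[1] * scale))
    manifest = synth.simulate_cohort(cfg, n_norm, n_abn, 1.0, seed=seed,
                                     out_dir=cohort_dir)
    return run_comparison(
        manifest, cohort_dir, model_tags=model_tags, train_cfg=train_cfg,
        k=k, seed=seed, clip_len=STUDY_DURATION_S,
    )


def accuracy_difference(table: ComparisonTable, model: str = "cnn-dense") -> float:
    """The headline number: accuracy(infrasound band) - accuracy(audible band),
    in percentage points, mean over folds."""
    frame = table.to_frame()
    row = frame[(frame["model"] == model) & (frame["band"] == "difference")]
    return float(row["accuracy_mean"].iloc[0])


def mean_band_accuracy(table: ComparisonTable, band: str,
                       model: str = "cnn-dense") -> float:
    return table.summary(model, band)["accuracy_mean"]
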