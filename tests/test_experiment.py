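"""Band-variant pairing, subject-disjoint folding, confusion metrics and the
end-to-end comparison table."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pcgband import experiment as ex
from pcgband import io
from pcgband import models as m
from pcgband import tfr


TINY_CNN = m.CnnConfig(input_hw=(16, 16), base_features=4, depth=2,
                       dense_hidden=(8,), lstm_units=4)
TINY_TRAIN = m.TrainConfig(learning_rate=1e-3, batch_size=8, epochs=2)


def manifest_of(rows):
    return pd.DataFrame(rows, columns=["record_id", "subject_id", "label", "wav_path"])


def random_manifest(rng, n_normal, n_abnormal, max_recs=3):
    rows = []
    for label, prefix, count in (("normal", "n", n_normal), ("abnormal", "a", n_abnormal)):
        for s in range(count):
            sid = f"{prefix}{s}"
            for r in range(rng.integers(1, max_recs + 1)):
                rows.append((f"{sid}_r{r}", sid, label, f"{sid}_r{r}.wav"))
    return manifest_of(rows)


class TestSubjectKfold:
    def test_even_split_of_ten_subjects(self, rng):
        manifest = random_manifest(rng, 5, 5)
        folds = ex.subject_kfold(manifest, k=5, seed=0)
        counts = np.bincount(list(folds.values()), minlength=5)
        assert list(counts) == [2] * 5

    def test_partition_and_stratification_over_random_manifests(self):
        rng = np.random.default_rng(99)
        for trial in range(100):
            n_n = int(rng.integers(3, 12))
            n_a = int(rng.integers(3, 12))
            k = int(rng.integers(2, min(n_n, n_a) + 1))
            manifest = random_manifest(rng, n_n, n_a)
            folds = ex.subject_kfold(manifest, k=k, seed=trial)
            subj = manifest.drop_duplicates("subject_id")
            assert set(folds) == set(subj["subject_id"])  # total partition
            recs_fold = manifest["subject_id"].map(folds)
            assert recs_fold.notna().all()  # every recording inherits a fold
            for label, group in subj.groupby("label"):
                per_fold = np.bincount([folds[s] for s in group["subject_id"]], minlength=k)
                assert per_fold.max() - per_fold.min() <= 1  # stratified +/-1

    def test_fewer_subjects_than_folds_rejected(self, rng):
        manifest = random_manifest(rng, 3, 2)
        with pytest.raises(ValueError, match="fewer than k"):
            ex.subject_kfold(manifest, k=3, seed=0)


class TestConfusionMetrics:
    def test_perfect_predictions(self):
        r = ex.confusion_metrics(np.array([1, 0, 1]), np.array([0.9, 0.1, 0.8]))
        assert (r.accuracy, r.sensitivity, r.specificity) == (100.0, 100.0, 100.0)

    def test_hand_counted_case(self):
        y = np.array([1] * 4 + [0] * 6)
        p = np.array([0.9, 0.8, 0.7, 0.2] + [0.1, 0.2, 0.3, 0.4, 0.9, 0.8])
        r = ex.confusion_metrics(y, p)
        assert (r.tp, r.fn, r.tn, r.fp) == (3, 1, 4, 2)
        assert r.sensitivity == pytest.approx(75.0)
        assert r.specificity == pytest.approx(200 / 3)
        assert r.accuracy == pytest.approx(70.0)

    def test_all_negative_predictions(self):
        r = ex.confusion_metrics(np.array([1, 1, 0]), np.array([0.1, 0.2, 0.3]))
        assert r.sensitivity == 0.0
        assert r.specificity == 100.0

    def test_empty_positive_set_reports_missing(self):
        r = ex.confusion_metrics(np.array([0, 0]), np.array([0.1, 0.9]))
        assert r.sensitivity is None
        assert r.specificity == 50.0

    def test_metric_identities_on_random_counts(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            y = (rng.uniform(size=40) > 0.4).astype(float)
            if y.min() == y.max():
                continue
            p = rng.uniform(size=40)
            r = ex.confusion_metrics(y, p)
            n = r.tp + r.fn + r.tn + r.fp
            assert n == 40
            assert r.accuracy * n == pytest.approx(100 * (r.tp + r.tn))
            assert r.sensitivity == pytest.approx(100 * r.tp / (r.tp + r.fn))
            assert r.specificity == pytest.approx(100 * r.tn / (r.tn + r.fp))


class TestBandVariants:
    FS = 2000.0

    def write_tone_cohort(self, tmp_path):
        from scipy.signal import windows

        # short fade-in/out: a hard cut would add broadband edge splatter
        # that has nothing to do with either band
        t = np.arange(int(2 * self.FS)) / self.FS
        taper = windows.tukey(len(t), 0.1)
        io.write_wav(tmp_path / "hund.wav", taper * np.sin(2 * np.pi * 100 * t), self.FS)
        io.write_wav(tmp_path / "infra.wav", taper * np.sin(2 * np.pi * 8 * t), self.FS)
        manifest = manifest_of([
            ("hund", "s1", "normal", "hund.wav"),
            ("infra", "s2", "abnormal", "infra.wav"),
        ])
        return manifest

    def test_passband_tone_variants_nearly_identical(self, tmp_path):
        manifest = self.write_tone_cohort(tmp_path)
        infra, audible = ex.make_band_variants(manifest, tmp_path, clip_len=2.0)
        diff = np.max(np.abs(infra.images[0] - audible.images[0]))
        assert diff <= 0.02

    def test_infrasound_tone_loses_scalogram_energy(self, tmp_path):
        # paired clips share the full-band normalization scale, so the
        # stop-band attenuation shows up as a >=100x energy drop
        self.write_tone_cohort(tmp_path)
        rec = io.read_wav(tmp_path / "infra.wav")
        pairs = ex._clip_pairs(rec.samples, self.FS, 2.0)
        full, aud = pairs[0]
        e_full = tfr.cwt_morlet(full, self.FS).energy
        e_aud = tfr.cwt_morlet(aud, self.FS).energy
        assert e_aud <= 0.01 * e_full

    def test_variants_share_ordering_and_labels(self, tiny_cohort):
        manifest, cohort_dir, _ = tiny_cohort
        infra, audible = ex.make_band_variants(manifest, cohort_dir, clip_len=2.0,
                                               image_hw=(16, 16))
        np.testing.assert_array_equal(infra.record_ids, audible.record_ids)
        np.testing.assert_array_equal(infra.labels, audible.labels)
        assert infra.images.shape == audible.images.shape


class TestRunComparison:
    def run(self, tiny_cohort, seed=11):
        manifest, cohort_dir, _ = tiny_cohort
        return ex.run_comparison(
            manifest, cohort_dir, model_tags=("cnn-dense",), cnn_cfg=TINY_CNN,
            train_cfg=TINY_TRAIN, k=2, seed=seed, clip_len=2.0,
        )

    def test_same_seed_gives_identical_tables(self, tiny_cohort):
        f1 = self.run(tiny_cohort).to_frame()
        f2 = self.run(tiny_cohort).to_frame()
        pd.testing.assert_frame_equal(f1, f2)

    def test_difference_row_is_exact_band_subtraction(self, tiny_cohort):
        table = self.run(tiny_cohort)
        frame = table.to_frame().set_index("band")
        for metric in ("accuracy", "sensitivity", "specificity"):
            expected = (frame.loc[ex.INFRASOUND, f"{metric}_mean"]
                        - frame.loc[ex.AUDIBLE, f"{metric}_mean"])
            assert frame.loc["difference", f"{metric}_mean"] == pytest.approx(
                expected, abs=1e-9
            )

    def test_folds_are_subject_disjoint_in_the_log(self, tiny_cohort):
        manifest, _, _ = tiny_cohort
        table = self.run(tiny_cohort)
        # every (model, band) records k folds with full confusion counts
        n_clips = manifest.shape[0]  # one clip per 2 s recording
        for row in table.fold_results:
            assert row["tp"] + row["fn"] + row["tn"] + row["fp"] < n_clips


    def test_degenerate_fold_is_rejected_by_name(self, rng):
        # one abnormal subject contributes no clips, so some fold's test side
        # holds a single class and the run must stop, naming the fold
        rows = [("n0_r0", "n0", "normal", "x.wav"), ("n1_r0", "n1", "normal", "x.wav"),
                ("a0_r0", "a0", "abnormal", "x.wav"), ("a1_r0", "a1", "abnormal", "x.wav")]
        manifest = manifest_of(rows)
        imgs = rng.uniform(size=(3, 16, 16)).astype(np.float32)
        labels = np.array(["normal", "normal", "abnormal"])
        subjects = np.array(["n0", "n1", "a0"])
        records = np.array(["n0_r0_c0", "n1_r0_c0", "a0_r0_c0"])
        ds = tuple(
            ex.BandDataset(band, imgs, labels, subjects, records)
            for band in (ex.INFRASOUND, ex.AUDIBLE)
        )
        with pytest.raises((ValueError, KeyError), match="fold|a1"):
            ex.run_comparison(manifest, ".", model_tags=("cnn-dense",),
                              cnn_cfg=TINY_CNN, train_cfg=TINY_TRAIN, k=2,
                              seed=0, datasets=ds)
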