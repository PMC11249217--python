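"""Generator contracts: spectral placement, SNR calibration, cohort shape,
class-information dials and byte-level determinism."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.signal import find_peaks

from pcgband import preprocess as pp
from pcgband import synth
from tests.conftest import make_light_config


def silent_config(**overrides):
    """No acoustic sources at all: infra amplitude zero, no S1/S2/murmur."""
    defaults = dict(
        fs=500.0,
        duration=2.0,
        s1_components=[],
        s2_components=[],
        murmur=None,
        infra=synth.SoundComponent(8.0, 8.0, 0.0, 0.0, 0.0),
        snr_db=np.inf,
    )
    defaults.update(overrides)
    return synth.default_sim_config(**defaults)


class TestGenCycle:
    def test_no_sources_yield_silence(self, rng):
        cyc = synth.gen_cycle(silent_config(), "normal", 0.8, rng)
        assert cyc.shape == (400,)
        assert np.all(cyc == 0)

    def test_single_component_peaks_at_its_frequency(self, rng):
        cfg = silent_config(
            fs=2000.0,
            s1_components=[synth.SoundComponent(50.0, 20.0, 1.0, 0.0, 0.0)],
        )
        cyc = synth.gen_cycle(cfg, "normal", 1.0, rng)
        freqs, mag = pp.compute_spectrum(cyc, cfg.fs)
        assert abs(freqs[np.argmax(mag)] - 50.0) <= 2.0

    def test_unit_effects_make_classes_identical(self):
        cfg = make_light_config(murmur=None, infra_effect=1.0, snr_db=np.inf)
        a = synth.gen_cycle(cfg, "normal", 0.9, np.random.default_rng(3))
        b = synth.gen_cycle(cfg, "abnormal", 0.9, np.random.default_rng(3))
        np.testing.assert_array_equal(a, b)

    def test_rejects_component_above_nyquist(self, rng):
        with pytest.raises(ValueError, match="Nyquist"):
            synth.gen_cycle(
                silent_config(s1_components=[synth.SoundComponent(400.0, 10.0, 1.0, 0.0)]),
                "normal",
                0.8,
                rng,
            )

    def test_rejects_cycle_shorter_than_latest_onset(self, rng):
        cfg = make_light_config()
        with pytest.raises(ValueError, match="onset"):
            synth.gen_cycle(cfg, "normal", 0.2, rng)


class TestSimulateRecording:
    def test_realized_snr_matches_configured(self):
        cfg = make_light_config(snr_db=33.05, duration=5.0)
        _, clean, noise = synth.simulate_recording(
            cfg, "normal", rng=np.random.default_rng(0), return_parts=True
        )
        assert pp.estimate_snr(clean, noise) == pytest.approx(33.05, abs=0.5)

    def test_infinite_snr_disables_noise(self):
        cfg = make_light_config(snr_db=np.inf)
        rec, clean, noise = synth.simulate_recording(
            cfg, "normal", rng=np.random.default_rng(1), return_parts=True
        )
        assert np.all(noise == 0)
        np.testing.assert_array_equal(rec.samples, clean)

    def test_s1_onset_count_at_fixed_heart_rate(self):
        # 70 bpm, zero variability, 10 s: cycle starts at k*(60/70) s -> 11 or 12
        cfg = silent_config(
            fs=500.0,
            duration=10.0,
            hr_mean=70.0,
            hr_sd=0.0,
            s1_components=[synth.SoundComponent(40.0, 40.0, 1.0, 0.0, 0.0)],
        )
        rec = synth.simulate_recording(cfg, "normal", rng=np.random.default_rng(2))
        env = np.convolve(np.abs(rec.samples), np.ones(25) / 25, mode="same")
        peaks, _ = find_peaks(env, height=0.3 * env.max(), distance=int(0.6 * 500 * 60 / 70))
        assert len(peaks) in (11, 12)

    def test_duration_must_cover_one_cycle(self):
        with pytest.raises(ValueError, match="cycle"):
            make_light_config(duration=0.5)


class TestSimulateCohort:
    def test_table1_preset_recording_ratio(self, tmp_path):
        manifest = synth.table1_cohort(tmp_path, seed=0, scale=1.0, config=make_light_config())
        counts = manifest["label"].value_counts()
        ratio = counts["normal"] / counts["abnormal"]
        assert 1.3 <= ratio <= 1.5
        subjects = manifest.drop_duplicates("subject_id")["label"].value_counts()
        assert subjects["normal"] == 85 and subjects["abnormal"] == 62

    def test_single_subject_cohort(self, tmp_path, light_config):
        manifest = synth.simulate_cohort(light_config, 1, 0, 1.0, seed=3, out_dir=tmp_path)
        assert len(manifest) == 1
        assert manifest["label"].iloc[0] == "normal"
        assert (tmp_path / manifest["wav_path"].iloc[0]).exists()

    def test_same_seed_gives_byte_identical_wavs(self, tmp_path, light_config):
        m1 = synth.simulate_cohort(light_config, 2, 2, 1.0, seed=5, out_dir=tmp_path / "a")
        m2 = synth.simulate_cohort(light_config, 2, 2, 1.0, seed=5, out_dir=tmp_path / "b")
        assert m1.drop(columns="wav_path").equals(m2.drop(columns="wav_path"))
        for name in m1["wav_path"]:
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_seed_is_mandatory(self, tmp_path, light_config):
        with pytest.raises(ValueError, match="seed"):
            synth.simulate_cohort(light_config, 1, 1, 1.0, out_dir=tmp_path)

    def test_subjects_keep_one_label(self, tmp_path, light_config):
        manifest = synth.simulate_cohort(light_config, 3, 2, 2.0, seed=9, out_dir=tmp_path)
        assert (manifest.groupby("subject_id")["label"].nunique() == 1).all()

    def test_default_preset_has_energy_in_both_bands(self, tmp_path):
        # emulates the observed spectrum: content below 20 Hz and in 20-300 Hz
        cfg = synth.default_sim_config(duration=5.0)
        total_low = total_mid = total = 0.0
        for seed in range(3):
            rec = synth.simulate_recording(cfg, "normal", rng=np.random.default_rng(seed))
            freqs, mag = pp.compute_spectrum(rec.samples, cfg.fs)
            e = mag**2
            total += e.sum()
            total_low += e[freqs < 20].sum()
            total_mid += e[(freqs >= 20) & (freqs <= 300)].sum()
        assert total_low >= 0.01 * total
        assert total_mid >= 0.01 * total


class TestPostopGroup:
    def test_postop_group_is_generated_but_excluded_from_the_task(self, tmp_path):
        from pcgband.experiment import _binary_task_rows
        from tests.conftest import make_light_config

        manifest = synth.table1_cohort(
            tmp_path, seed=4, scale=0.05, config=make_light_config(),
            include_postop=True,
        )
        groups = manifest.groupby("group")["subject_id"].nunique()
        assert groups["postop"] >= 1
        task = _binary_task_rows(manifest)
        assert set(task["group"]) == {"normal", "preop"}
        # post-op WAVs exist on disk alongside the main cohort
        post_paths = manifest.loc[manifest["group"] == "postop", "wav_path"]
        assert all((tmp_path / p).exists() for p in post_paths)
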