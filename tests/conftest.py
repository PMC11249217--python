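"""Shared fixtures: light simulation configs and tiny cohorts.

The "light" config keeps every synthesis feature (S1/S2/infra components,
heart-rate variability, SNR calibration) but at a low sampling rate and short
duration so unit tests stay fast; full-scale conditions live in the
acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from pcgband import synth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_light_config(**overrides) -> synth.PcgSimConfig:
    defaults = dict(
        fs=500.0,
        duration=2.0,
        hr_mean=70.0,
        hr_sd=2.0,
        s1_components=[synth.SoundComponent(30.0, 40.0, 1.0, 0.0, 0.002)],
        s2_components=[synth.SoundComponent(50.0, 50.0, 0.8, 0.35, 0.002)],
        murmur=synth.SoundComponent(120.0, 15.0, 0.3, 0.10, 0.002, bandwidth=80.0),
        infra=synth.SoundComponent(8.0, 8.0, 1.2, 0.0, 0.002),
    )
    defaults.update(overrides)
    return synth.default_sim_config(**defaults)


@pytest.fixture
def light_config():
    return make_light_config()


@pytest.fixture
def tiny_cohort(tmp_path):
    """4 normal + 4 abnormal subjects, one 2 s recording each, fs 500."""
    cfg = make_light_config(infra_effect=1.5)
    manifest = synth.simulate_cohort(cfg, 4, 4, 1.0, seed=7, out_dir=tmp_path / "cohort")
    return manifest, tmp_path / "cohort", cfg
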