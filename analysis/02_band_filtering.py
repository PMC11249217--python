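"""Spectral diagnostics: where the energy lives and what the 20 Hz cut removes.

Measures, on freshly simulated recordings: the average FFT energy split
around 20 Hz (the synthetic cohorts, like the real measurements, carry
substantial infrasound energy), the realized SNR against the configured
33.05 dB, and the zero-phase high-pass response at key frequencies.

Run:  python analysis/02_band_filtering.py --seed 1
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from pcgband import preprocess as pp
from pcgband import synth

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, required=True)
parser.add_argument("--n", type=int, default=10, help="recordings to average")
args = parser.parse_args()

cfg = synth.default_sim_config(duration=5.0)
low = mid = total = 0.0
snrs = []
for i in range(args.n):
    rng = np.random.default_rng(args.seed + i)
    rec, clean, noise = synth.simulate_recording(cfg, "normal", rng=rng, return_parts=True)
    snrs.append(pp.estimate_snr(clean, noise))
    freqs, mag = pp.compute_spectrum(rec.samples, cfg.fs)
    e = mag**2
    total += e.sum()
    low += e[freqs < 20].sum()
    mid += e[(freqs >= 20) & (freqs <= 300)].sum()

spec = pp.design_highpass(cfg.fs, 20.0)
probe = np.array([5.0, 10.0, 20.0, 50.0, 100.0, 300.0])
gains = spec.gain_db(probe)

rows = [{"quantity": "energy_fraction_below_20hz", "value": low / total},
        {"quantity": "energy_fraction_20_300hz", "value": mid / total},
        {"quantity": "mean_realized_snr_db", "value": float(np.mean(snrs))},
        {"quantity": "configured_snr_db", "value": cfg.snr_db}]
rows += [{"quantity": f"hp_gain_db_at_{f:g}hz", "value": g} for f, g in zip(probe, gains)]
frame = pd.DataFrame(rows)

Path("results").mkdir(exist_ok=True)
frame.to_csv("results/02_band_filtering.csv", index=False)
print(frame.to_string(index=False))
print("\nThe high-pass is -3 dB at its 20 Hz cutoff (single pass; the "
      "forward-backward application squares the response) and flat in the "
      "audible band, so the audible-only variant differs from the original "
      "only below ~20 Hz.")
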