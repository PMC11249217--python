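# pcgband

**Does discarding the infrasound band change heart-sound diagnosis?**

Heart sounds carry energy well below the ~20 Hz audibility threshold —
hemodynamic waves that a conventional stethoscope (and any pipeline that
high-passes its input) simply never sees. `pcgband` is a tested pipeline for
quantifying what that sub-20 Hz band is worth to a deep-learning classifier:
it synthesizes phonocardiogram (PCG) cohorts whose class information can be
placed *below* or *above* 20 Hz at will, converts recordings to Morlet-CWT
scalograms, trains CNN classifiers, and compares accuracy, sensitivity and
specificity between the full-band and audible-only variants of the same
recordings.

## The analysis in one paragraph

Every recording is turned into two paired datasets from identical raw
samples: an **infrasound** variant (untouched) and an **audible** variant,
produced by a 4th-order Butterworth high-pass at 20 Hz applied
forward-backward (zero phase, so S1/S2 timing is untouched). Both go through
identical segmentation into 5 s clips, a continuous wavelet transform with
the analytic Morlet wavelet (ω₀ = 6) on a 96-point log grid over 2–300 Hz,

    W(b, a) = ∫ f(t) · a^(-1/2) ψ*((t − b)/a) dt,   a = ω₀ / 2πf,

and rendering to 64×64 log-magnitude images. Two classifiers are trained on
each variant under subject-disjoint stratified k-fold cross-validation
(Positive = abnormal): a VGG-style **CNN-dense** (base width 16, four
blocks of two 3×3 same-padded convolutions with feature doubling and 2×2
max-pooling, one 848-unit hidden dense layer; 2.03×10⁶ trainable
parameters) and a **CNN-LSTM** that re-reads the final feature map as a
time sequence into two 85-unit LSTM layers (5.55×10⁵ parameters). The
headline number is the per-model difference row: metric(infrasound) −
metric(audible).

The synthetic cohorts mirror a clinically collected dataset's structure:
85 normal / 62 abnormal subjects (scalable), ~3.2 recordings per subject
(≈1.41:1 recording imbalance), subject-level physiology offsets, heart-rate
variability, components down to a few Hz, and additive noise calibrated to
33.05 dB SNR. Two dials — `infra_effect` (abnormal-class amplitude
multiplier on the sub-20 Hz component) and the murmur amplitude — control
where the class information lives, so the band comparison has a known
ground truth.

## Worked example

```bash
python analysis/05_band_comparison.py --seed 0
```

simulates a 121-subject cohort with class information mostly below 20 Hz
(`infra_effect = 1.6`, weak murmur), builds both band variants and runs the
3-fold subject-disjoint comparison of the CNN-dense model (~2 minutes on one
core). Output from that exact command:

```
    model       band  accuracy_mean  accuracy_std  sensitivity_mean  sensitivity_std  specificity_mean  specificity_std
cnn-dense infrasound      96.707317      1.121023         98.039216         2.772968         95.772947         3.403141
cnn-dense    audible      56.951220      7.502891         25.490196        21.657571         80.072464        14.645930
cnn-dense difference      39.756098           NaN         72.549020              NaN         15.700483              NaN

cnn-dense: accuracy(infrasound) - accuracy(audible) = +39.76 points
```

Reading it: with the infrasound band intact the classifier recovers the
abnormal class almost perfectly (96.7% accuracy); after the 20 Hz high-pass
only the weak audible murmur remains and accuracy collapses toward the
majority class (57.0%). The +39.8-point difference row is the cost of
discarding the infrasound band *for this synthetic effect size* — the sign,
not the magnitude, is the transferable conclusion. Running with `--null`
(no class information anywhere) gives a difference of 0.0 and chance-level
accuracy in both bands.

The other drivers: `01_simulate_cohort.py` (cohort shape),
`02_band_filtering.py` (spectrum, SNR calibration, filter response),
`03_scalograms.py` (STFT-vs-CWT low-frequency resolution),
`04_architecture_audit.py` (layer-by-layer parameter counts). Each writes
its table under `results/`. The same stages are available as a CLI:
`pcgband simulate|bandsplit|scalogram|train|compare` (every subcommand
requires `--seed` and freezes its effective config next to its outputs).

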