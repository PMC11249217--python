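# Methods

## Problem and design

The pipeline asks a band-ablation question: given heart-sound recordings
whose diagnostic information may extend into the infrasound range (below
~20 Hz), how much classification performance is lost when that band is
removed before feature extraction? Because the real clinical recordings the
question comes from cannot be redistributed, the package pairs the analysis
with a synthetic-cohort generator whose ground truth is controlled: the
experimenter decides how much class information lives below 20 Hz and how
much in the audible band, and the analysis must recover the consequences.

## Synthetic phonocardiograms

A cardiac cycle is a sum of damped bursts

    s(t) = Σ_k A_k · exp(−d_k (t − τ_k)) · sin(2π f_k (t − τ_k)),  t ≥ τ_k,

with per-cycle Gaussian jitter on each onset τ_k. Defaults (chosen inside
the 2–300 Hz analysis range, with the infrasound component strictly below
the 20 Hz split):

| component | frequencies (Hz) | onset (s) | damping (1/s) | amplitudes |
|---|---|---|---|---|
| S1 | 30, 60, 100 | 0.00 | 40 | 1.0, 0.7, 0.4 |
| S2 | 50, 90, 140 | 0.35 | 50 | 0.8, 0.6, 0.35 |
| infrasound wave | 8 | 0.00 | 8 | 1.2 |
| murmur (abnormal only) | 100–250 band-noise | 0.10 | 15 | configurable |

The murmur carrier is unit-RMS band-limited Gaussian noise rather than a
sinusoid, reflecting its broadband character. Two dimensionless dials carry
the class signal: `infra_effect` multiplies the infrasound amplitude for the
abnormal class (1.0 ⇒ nothing to learn below 20 Hz), and the murmur — absent
from the normal class — supplies the audible cue. With `infra_effect = 1`
and no murmur the two class distributions are *identical*, which the tests
exploit as a null model.

Recordings concatenate cycles whose lengths are 60/HR with HR ~
Normal(70, 3) bpm truncated to a physiologic range; white Gaussian noise is
added with its power scaled so the realized signal-to-noise ratio equals the
configured value exactly (default 33.05 dB, the measured level of the
emulated dataset). Cohorts follow the emulated dataset's proportions — 85
normal / 62 abnormal subjects contributing 276 / 195 recordings (≈1.41:1) —
scalable by a single factor, with deterministic recording budgets so the
imbalance survives small scales. Per-subject physiology offsets (log-normal
amplitude factors, sd 10%; ±5% frequency jitter; HR offset) make recordings
within a subject correlated, which is what gives subject-disjoint
cross-validation its meaning here.

What the generator does **not** emulate: real valve mechanics and
hemodynamics, sensor/adapter transfer functions, pathology heterogeneity,
colored noise, artifacts (friction, speech, motion). Passing tests therefore
demonstrate that the *pipeline* recovers a known band-localized effect under
realistic dataset structure — not that any particular clinical effect size
is reproduced.

## Preprocessing and transforms

- **Band split.** Butterworth high-pass, order 4, cutoff 20 Hz, applied
  forward-backward (`sosfiltfilt`): zero phase, effective order 8, −3 dB at
  the cutoff per pass. Butterworth was chosen for its maximally flat
  passband — the audible band being compared must not be colored. The
  filter family, order and clip length are declared choices; the emulated
  protocol specifies only "high-pass at 20 Hz with phase correction".
- **Segmentation.** 5 s non-overlapping clips (several cardiac cycles at
  70 bpm), each scaled to zero mean and max-abs 1. In the band pipeline the
  audible clip reuses its full-band twin's scale: per-clip renormalization
  would otherwise re-inflate exactly the energy the filter removed.
- **CWT.** Analytic Morlet, ω₀ = 6, scales a = ω₀/(2πf) on a 96-point
  log-spaced grid over 2–300 Hz (capped below Nyquist for low-rate test
  cohorts). Coefficients are the Riemann sum of the wavelet inner product on
  the sampling grid, evaluated for all translations at once by FFT
  cross-correlation with kernels truncated at |t| ≤ 5a (Gaussian tail
  < 4·10⁻⁶). An FFT-length ladder reuses the signal spectrum across scales;
  kernels are cached per (scale, length). The test suite checks the fast
  path against brute-force direct summation at random (b, a) within 1%
  (observed agreement ~10⁻⁶ relative), and checks linearity at 10⁻⁹ on the
  complex coefficients.
- **STFT.** Hann window, 100 ms, 50% hop — kept only for the resolution
  comparison (10 Hz bins merge a 5 Hz + 8 Hz pair that the constant-Q CWT
  separates); the classification path is CWT-only.
- **Rendering.** log(1 + |W|), per-image min–max to [0, 1], bilinear
  resampling to 64×64 with frequency rows low→high; dense time axes are
  block-averaged to ~4 columns per output pixel first. A degenerate
  all-equal image renders as zeros. Grayscale log-magnitude is a declared
  choice; the emulated study does not state its colormap or resolution.

## Classifiers

Both models share a VGG-style trunk on 64×64×1 inputs: four blocks of two
3×3 same-padded convolutions (ReLU) and 2×2 max-pooling, feature widths
16/32/64/128 (293,232 trunk parameters). Heads:

- **CNN-dense**: flatten (4·4·128 = 2048) → dense 848 (ReLU) → sigmoid
  logit. Total 2,031,633 ⇒ 2.03×10⁶ at three significant figures.
- **CNN-LSTM**: the final 4×4×128 map is re-read as a 4-step sequence along
  the time axis (512 features per step) → two stacked 85-unit LSTM layers →
  sigmoid logit from the last step. Total 554,778 ⇒ 5.55×10⁵.

The reference totals fix the otherwise-unstated head widths: 848 and 85 are
the unique-in-spirit free knobs making the counts round correctly, and they
are constants in code, asserted by tests, not user parameters. LSTM
parameters use the single-bias convention, 4(d·u + u² + u) per layer, with
the forget-gate bias initialized to 1. Initialization is Glorot-uniform
throughout; no dropout or batch-norm (none are part of the emulated
design). The layer stack, reverse-mode gradients, binary cross-entropy on
logits and Adam are implemented in NumPy (channels-last, float32, im2col
expressed as per-offset GEMMs on shifted views to keep single-core memory
traffic low); gradients are verified against central differences in float64.

**Training profiles.** The full profile is Adam, lr 10⁻⁴, batch 12,
100 epochs, binary cross-entropy. The *reduced* profile used by the tests
and the study drivers keeps batch 12 but runs 15 epochs at lr 10⁻³ — a
short schedule needs larger steps; the choice was made from
training-loss-descent behavior on the separable sanity fixture, and all
study conclusions are sign-level, not tuned to it.

## The comparison experiment

Folding is at the **subject** level, stratified by class (round-robin after
a seeded shuffle within class, so per-fold class counts differ by ≤1
subject). Record-level folding would leak subject identity between train
and test; the emulated study does not say which it used, and the subject
level is the defensible choice. Each (model, band, fold) trains from a
fresh seeded initialization; fold seeds derive from the run seed through
`SeedSequence` so any sub-run is independently reproducible. Metrics are
computed from confusion counts with Positive = abnormal, reported in
percent as mean ± std over folds (population std, matching the ± convention
of the emulated tables); a metric with an empty denominator is reported as
missing, never as zero. The decision threshold is fixed at 0.5. Difference
rows are exact subtractions of the band means.

## Study conditions (fixed once)

The pre-registered band studies in `pcgband.studies` and the acceptance
tests use: Table-1 proportions scaled 0.82 (70 + 51 = 121 subjects), one
5 s recording per subject (one clip each), 64×64 scalograms, 3-fold CV,
CNN-dense, reduced profile; signal arm `infra_effect = 1.6` with murmur
amplitude 0.12, null arm `infra_effect = 1.0` with no murmur; five seeds
for the signal arm, three for the null arm, and a separate balanced
24 + 24-subject cohort (two seeds) for the chance-level check, where
stratified folds center chance exactly at 50%. One recording per subject
and these seed counts are compute-scale choices for a single-core run; the
subject count, image size, fold count and epoch budget are the stated study
conditions. Observed behavior at these conditions: the signal arm gives a
large positive accuracy difference (tens of points — the synthetic effect
is deliberately strong; only its sign is the finding), and in the null arm
both band models collapse to the majority class, making the difference
exactly zero in most replicates.

## Numerical notes and limitations

- Everything is deterministic given seeds: cohorts are byte-identical WAVs,
  training histories repeat to machine precision on the same BLAS.
- WAV I/O is 16-bit PCM mono; read normalizes to [−1, 1] (write uses
  full-scale 32768 with clipping at +1, so round-trips stay within half a
  quantization step). Absolute pressure calibration is deliberately
  dropped — all downstream normalization is per-clip/per-image.
- `estimate_snr` needs the clean/noise decomposition, which only the
  generator can supply; on real data it would have to be replaced by a
  noise-floor estimate.
- The zero-phase filter's "energy partition" property (high-passed +
  residual ≈ original energy) holds away from the transition band; a signal
  concentrated near 20 Hz violates it by construction.
- The PhysioNet/CinC-2016 reference-label dialect is supported for loading
  real cohorts (WAV + `record,−1/1` CSV), but no external dataset is
  fetched, and numerical reproduction of results on external data is out of
  scope here.
- Paired band variants share one fold split and one model initialization
  per (fold, seed), which makes the null difference tightly coupled — a
  variance-reduction choice, not an accident.
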