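# Methods

`ecgbeats` implements a five-class heartbeat classification pipeline for
single-lead ECG sampled at 360 Hz: wavelet denoising, Pan-Tompkins R-peak
detection, R-centred beat segmentation with z-scoring, class balancing, a
12-layer 1-D convolutional network, and ten-fold cross-validation reported
through one integrated confusion matrix. The five classes are normal (NOR),
left and right bundle branch block (LBBB, RBBB), atrial premature (AP) and
premature ventricular (PVC) beats — MIT-BIH annotation codes N, L, R, A, V;
all other codes are excluded.

## Synthetic data generator

Because the package must be testable without the external arrhythmia
database, it ships a generator that emulates the statistical structure the
pipeline relies on, not the full physiology of real ECG.

Each beat is a sum of Gaussian bumps (amplitude mV, centre s relative to R,
sigma s) — a McSharry-style PQRST amplitude profile without the phase ODE.
The five templates encode textbook lead-II morphology: NOR has an upright P,
a narrow tall R and an upright T; LBBB a broad, notched, dominantly negative
QRS with discordant upright T; RBBB a broad rSR' with inverted T; AP a
narrow QRS with an ectopic (inverted) P and a short preceding RR interval
(0.60 s mean vs 0.80 s for NOR); PVC a very wide QRS with no P and a deep
discordant T. The Q-to-S span (outer ±2-sigma edges of the QRS components)
is ≥ 0.12 s for LBBB/RBBB/PVC and < 0.12 s for NOR/AP, so the clinical
wide/narrow distinction guarantees class separability: a nearest-centroid
classifier reaches 100 % on noiseless beats, which is the oracle the
learning tests compare against.

Two choices matter for realism of the *detector's* input: the PVC's QRS is
wide in *duration* but keeps steep edges (narrow-sigma R bump plus a
separated S), because real ventricular beats retain substantial 5–15 Hz
energy; a single very smooth Gaussian of the same duration would be nearly
invisible to a band-pass QRS detector. And each beat's annotation is
snapped (±3 samples) to the sampled waveform's extremum, since the
continuous R centre generally falls between samples — this mirrors expert
annotations, which mark the discrete peak.

RR intervals are drawn per beat from the incoming beat's template
(mean ± SD, clipped to [0.25 s, 2 s]); noise is additive baseline wander
(default 0.1 mV at 0.3 Hz), power-line hum (0.05 mV at 60 Hz) and white
noise (SD 0.05 mV) — the package's "mild" condition. All randomness flows
from one `numpy.random.Generator`; the same seed gives bit-identical
records. `generate_balanced_dataset` emits one record per class with an
unannotated lead-in beat so every returned beat window contains a preceding
beat (without it, the first beat of each record is a contextual outlier).

What the generator does **not** model: multi-beat rhythm disturbances,
EMG noise, electrode artefacts, inter-patient morphology variation, and the
long-tailed class imbalance of real recordings. Passing tests therefore
demonstrate that the pipeline's machinery is correct and that the network
can learn morphologically distinct classes — not that the reported
real-data accuracy transfers.

## Wavelet denoising

`wavelet_denoise` decomposes with `sym4` (symmetric signal extension,
default level `min(8, dwt_max_level)`), shrinks every detail band and
reconstructs; output length equals input length. The noise scale
sigma = median(|d₁|)/0.6745 is estimated from the finest band only, where
broadband noise dominates; per-band estimates would read coarse-band QRS
energy as noise and destroy the signal (measured: ~58 % RMS distortion on a
clean record, vs ~0.003 % with the single-band estimate). Thresholds are
per band: universal sigma·√(2 ln N_b) by default, or a SURE-minimising
threshold with the usual hybrid fallback in sparse bands; soft shrinkage by
default, hard available. With `remove_baseline_level` (default on) the
deepest approximation (< ~0.7 Hz at level 8) is zeroed to suppress baseline
wander — note this also removes the signal's own DC/slow trend, which is
harmless in the pipeline (segments are z-scored) but matters when comparing
against a clean reference, so the denoising benchmarks run with it off.

Boundary behaviour: symmetric padding affects roughly (filter_len − 1)·2^level
samples at each end. Interior samples are shift-consistent — cropping by a
multiple of 2^level and denoising commutes to < 1e-6 relative RMS on the
deep interior — when the threshold is held fixed; the data-driven threshold
itself is slightly shift-sensitive (~1e-3 relative), which bounds
shift-consistency of the default configuration.

## R-peak detection

`pan_tompkins` follows the classic stages: band-pass, five-point
derivative, squaring, 150 ms moving-window integration, adaptive dual
thresholds (SPKI/NPKI with 0.125 updates, gate = NPKI + 0.25·(SPKI−NPKI)),
a 200 ms refractory period, and search-back at half threshold whenever an
RR interval exceeds 1.66× the running average of the last eight. The
original integer band-pass is tied to 200 Hz sampling, so a zero-phase
(filtfilt) order-2 Butterworth 5–15 Hz band-pass is used instead,
preserving peak timing. Search-back is evaluated both when a candidate is
rejected and before committing the next accepted beat, so a missed
low-amplitude beat inside a long gap is recovered either way.

Each accepted trigger is relocated to the extremum of the raw signal within
±75 ms, measured as deviation from a ~1 s local median baseline — a
window-local median would be corrupted by wide QRS complexes that fill the
relocation window. Ties go to the earliest sample. Detection is
amplitude-scale invariant and polarity-blind (squaring), verified on the
negative-dominant LBBB template.

The pipeline can bypass detection and use annotation-supplied R indices
(`rpeaks: annotations`, the default), mirroring the fact that benchmark
beats are expert-annotated; `rpeaks: detect` labels each detected peak by
the nearest annotation within 75 ms.

## Segmentation, balancing, folds

Windows are 360 samples, half-open `[r − 180, r + 180)`, R at 0-based
offset 180; windows crossing a record boundary are dropped and counted;
each segment is z-scored with the population (divide-by-n) SD, the same
convention the metric summaries use. Balancing hits exact per-class
targets: uniform duplication with replacement below target (originals all
kept), uniform subsampling without replacement above, byte-identical
pass-through at target. By default balancing is applied to the whole pool
before fold assignment, reproducing the study protocol; this lets duplicated
minority beats straddle train/test folds (an optimistic-bias caveat), so a
strict `balance_train_only` mode balances inside each training split
instead. Folds are stratified (per-class counts per fold differ by ≤ 1,
fold sizes by ≤ 1) via `StratifiedKFold`, with an equivalent interleaved
fallback when a class has fewer members than k.

## The network

Declared architecture (fixed, asserted at build time):

| layer | kind | output | kernel | stride |
|---|---|---|---|---|
| 1 | conv (16 filters) | 360×16 | 13 | 1 |
| 2 | avg-pool | 179×16 | 3 | 2 |
| 3 | conv (32) | 179×32 | 15 | 1 |
| 4 | avg-pool | 89×32 | 3 | 2 |
| 5 | conv (64) | 89×64 | 17 | 1 |
| 6 | avg-pool | 44×64 | 3 | 2 |
| 7 | conv (128) | 44×128 | 19 | 1 |
| 8 | avg-pool | 21×128 | 3 | 2 |
| 9 | dropout 0.5 | 21×128 | – | – |
| 10 | dense | 35 | – | – |
| 11 | dense | 5 | – | – |
| 12 | softmax | 5 | – | – |

Stride-1 convolutions preserve length, which forces "same" zero padding;
pooling is plain 1/k averaging (no learnable pooling weights — the
"average-pooling" naming is taken at face value); ReLU follows every
convolution, i.e. precedes every pooling layer; there is no activation
between the two dense layers other than the final softmax. The dense
layers carry an L2 factor of 5, interpreted as a per-layer multiplier on a
global base weight decay of 1e-4 (the convention of the toolbox the
architecture originates from), giving an effective 5e-4 — both knobs are
exposed (`l2_factor`, `base_l2`).

The implementation is pure NumPy: convolutions run as contiguous im2col +
GEMM in float32 with channels-last activations, gradients are analytic
(conv input gradients are computed as a flipped-kernel correlation, one
GEMM per tap), and training uses Adam (β₁ 0.9, β₂ 0.999, ε 1e-8), batch
size 36, 60 epochs by default with the step schedule
lr(e) = 1e-3 · 0.1^⌊(e−1)/20⌋, per-epoch reshuffling from the run seed,
inverted-scaling dropout active only during training, and Glorot-uniform
seeded initialisation. Backprop is verified against central-difference
numerical gradients (float64, 1e-4 relative) in the test suite; a non-finite
loss aborts with the epoch/batch position.

## Metrics

Confusion matrices are 5×5 with **rows = predicted, columns = actual** (so
column sums are true class counts). Per class: Sen = TP/(TP+FN),
Spe = TN/(TN+FP), Ppr = TP/(TP+FP), each ×100; overall accuracy is
100·trace/total (the multi-class reading of the accuracy formula). Ten-fold
results are integrated by cell-wise summation before metrics are computed.
Macro summaries are the mean and *population* SD over the five per-class
values; `round_first` reproduces summaries derived from printed two-decimal
columns. Zero-denominator metrics are reported as undefined (`None`), never
coerced to 0 or 100.

The package embeds the published benchmark confusion matrices of four
classifiers on the balanced 32,422-beat dataset as metric oracles
(`reference_tables`). Their display conventions are mixed — some cells are
rounded, others truncated, macro rows derive from the matrices while SD rows
derive from the printed columns — and the `tables` consistency check accepts
any of these derivations. Three cells are inconsistent under every
convention and are recorded as known discrepancies rather than corrected.

## Default study configuration and problem sizes

The default synthetic study (`PipelineConfig()`) uses 300 beats per class
(1,500 total), mild noise, annotation-supplied R peaks, denoising on,
whole-pool balancing to equal counts (a no-op on the balanced generator
output), ten folds, and 20 training epochs per fold — sizes chosen so the
full cross-validated run completes in minutes on one CPU while leaving the
learning problem non-trivial under noise. The acceptance script
(`scripts/acceptance.py`) reruns this configuration from scratch, plus the
table recomputation, detector scoring (30-beat trains, ±5 samples noiseless
/ ±10 noisy), and the denoising RMSE benchmark (white noise, SD 0.1 mV).

## Known limitations

* The synthetic task is far easier than real MIT-BIH classification;
  cross-validated accuracy near 100 % on it validates machinery, not
  clinical performance.
* Whole-pool balancing before fold assignment leaks duplicated minority
  beats across folds by design (matching the study protocol); use
  `balance_train_only` for honest minority-class estimates.
* The beat-wise (intra-patient) split protocol is implemented; record-wise
  (inter-patient) protocols are out of scope.
* WFDB-format I/O activates only when the optional `wfdb` package is
  installed; the plain-CSV dialect is the tested path.
* Training determinism holds per BLAS build; different BLAS backends may
  differ in the last float32 bits.
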