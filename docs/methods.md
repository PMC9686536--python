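# Methods

This note records the signal model, the parameter choices and their
rationale, what the synthetic data does and does not emulate, and the
numerical decisions a maintainer should know about. It states no empirical
result beyond what the test suite and `scripts/acceptance.py` compute.

## Signal front end

**Amplitude convention.** Integer PCM is divided by 2^(bits−1), so all
samples and thresholds live on [−1, 1]. 16-bit/48 kHz WAV is the reference
recording format; other rates are accepted, with the analysis window
re-derived as 21.3 ms rounded to a multiple of 8 samples (so the hop stays
an integer 1/8 window; at 48 kHz this is exactly 1024/128).

**Denoising filter.** A Butterworth high-pass IIR, designed with
`scipy.signal.butter` and applied as a single causal pass (`lfilter`).
Order is configurable (default 4): the Butterworth design puts the −3 dB
point at the requested cutoff for *every* order, and 1500 Hz is the only
constraint the recording protocol fixes. Forward–backward filtering is
deliberately not used — it would square the magnitude response and move the
−3 dB point off 1500 Hz. `minus3db_frequency` measures the realized
half-power frequency from the coefficients (dense `freqz` grid + Brent root
find) rather than trusting the design request.

**Windows.** Hamming and Hann are evaluated at n = 0…M−1 with divisor M
(the periodic form), giving the edge values 0.08 and 0 respectively. Hann
is the default for spectral work. Framing drops a trailing remainder
shorter than one window, so the frame count is exactly
⌊(L−M)/hop⌋+1.

## Endpoint detection

The zero-crossing count per frame is offset-gated: samples with |s| ≤ 0.01
(full scale) are treated as idle-channel noise and skipped, and a crossing
is counted when the sign of the last *significant* sample flips. A strict
"both neighbours above offset" rule would randomly miss the ~5 % of
crossings whose neighbouring sample lands inside the dead zone; the
sign-tracking rule counts each physical crossing exactly once (a clean
5 kHz frame yields 213 ± 1).

ZCR is computed on untapered frames (a window taper rescales amplitudes and
would interact with the offset gate; it cannot change sign structure, but
the gate makes amplitude matter).

Runs of frames with ZCR strictly above 10 become candidates; runs shorter
than 30 or longer than 110 frames are discarded. There is no hysteresis or
gap merging. Frame-to-sample conversion is half-open and 0-based:
`start_sample = start_frame·hop`, `end_sample = (end_frame−1)·hop + M`.

**Run-length accounting.** A frame overlapping a call by only ~1 ms already
exceeds 10 crossings, so a detected run is ≈ (d + M − 2o)/hop frames for a
call of d samples (o ≈ samples needed for 11 crossings at the call's
fundamental) — about 7 frames more than the ⌊(d−M)/hop⌋+1 frames the call
itself yields. The 30–110-frame gate therefore corresponds to call
durations of roughly 0.06–0.27 s, not the nominal 0.1–0.35 s; this is why
the synthetic generator's default duration range tops out at 0.27 s (see
below).

## Features

All three features share the front end: Hann-windowed 1024-sample frames,
one-sided 513-bin DFT **modulus** (not power), dB scale EdB = 10·log₁₀E
with energies floored at 1e−10 (so silence maps to −100 dB and no feature
is ever non-finite). A consequence of the modulus-plus-10·log convention is
that scaling the waveform by c shifts the spectrogram by 10·log₁₀c dB (not
20·log₁₀c); the tests pin this down.

* **Cepstrogram.** Per frame, the DCT-II of the 513-bin dB spectrum with
  normalization 2/N, N = 513 (the spectrum length, since the transform is
  applied to the dB spectrum). Coefficient indices [5, 165) are kept —
  half-open and 0-based, forced by the 160-coefficient output width. The
  excluded low coefficients carry the spectral mean/tilt.
* **MFCC+Logfbank.** The 26-filter Mel bank spans 0 Hz–Nyquist (band edges
  configurable). Filter edge/center frequencies are 28 points equally
  spaced on the Mel scale; the triangles are laid out on the nearest FFT
  bins (unit peak at the center bin), while the exact Mel-spaced center
  frequencies are stored for inspection. Mel energies pass through the same
  10·log₁₀ scaling as the spectrogram (one dB convention throughout), and
  the MFCC is the same 2/N DCT-II with N = 26. All 26 DCT coefficients are
  kept, including the 0th — forced by 26+26 = 52 — with no liftering and no
  delta features.
* **Padding.** Variable-length calls (30–110 frames) are padded row-wise to
  110 frames with the feature of an all-zero frame (−100 dB rows for the
  spectrogram; the corresponding transforms of the constant floor spectrum
  for the other two). All pad rows are identical, so the padded region is
  constant across the dataset and carries no label information.
  Interpolation/resampling to a fixed length was rejected because it would
  distort the time axis that the recurrent models consume.

## Classifiers

All five networks are implemented on a small reverse-mode autograd engine
(`chickcall.nn`, float64, numerically gradient-checked in the tests) with
Adam and early stopping. Shared choices:

* **Head**: dense 64 (ReLU) → dropout 0.2 → dense 32 (ReLU) → dense 1 →
  sigmoid. The hidden activations are a design choice (unconstrained
  elsewhere); the sigmoid output with binary cross-entropy is forced by the
  binary label and accuracy monitoring. Training computes the loss in logit
  form (log-sum-exp), which is exactly sigmoid+BCE but stable.
* **Conv blocks** (CNN, CRNN, TwoStream): 3×3 convolutions with same
  padding, 64 filters, each followed by 3×3 max pooling with stride 3
  (stride = pool size; "3×3 maxpooling" is read as non-overlapping).
  Same padding keeps three pool stages viable on the 52-wide feature.
* **GRU stack**: two 64-unit layers; the head consumes the final layer's
  last time step (chosen over sequence pooling; the call's informative
  content has been integrated by the last step, and the fixed-length
  padding makes "last step" well defined).
* **CRNN time-flatten**: the conv output (N, C, T′, D′) is re-arranged to
  (N, T′, C·D′), preserving temporal order while folding channels and
  frequency — the natural reading of arranging tensors "in time order".
* **TwoStream**: conv branch (flattened) and GRU branch (last step) run
  independently on the same input and concatenate before the head.
* **ResNet-50**: the standard 4-stage bottleneck design — 7×7/2 stem with
  batch norm, 3×3/2 max pool, bottleneck blocks (1×1 reduce, 3×3, 1×1
  expand, 4× expansion, projection shortcuts) in counts 3/4/6/3, global
  average pooling, then the shared head. The single-channel feature matrix
  is replicated to 3 channels at the input. The 3×3 layer of stage 4 uses
  512 channels (the bottleneck invariant). A `width_multiplier` scales all
  channel counts (minimum 1 per layer) so the topology runs at desk scale;
  1.0 reproduces the full network. Pretrained initialization is an optional
  externally supplied weight file, never required.
* **Training**: Adam with library-default hyper-parameters (lr 1e−3,
  β₁ 0.9, β₂ 0.999), batch size 32, max 2000 epochs by default (the
  GRU is the slowest architecture to converge). Early stopping monitors
  validation accuracy with patience 100 by default: if accuracy has not
  increased for `patience` epochs the run stops and the best epoch's
  parameters are restored. All randomness (init, shuffling, dropout) is
  seeded, so runs are exactly reproducible.

## Splits and voting

Test birds are drawn per breed and per sex (default 20 % of birds), and
only then are calls sampled: training and validation calls come exclusively
from training birds. This bird-disjoint split is the pipeline's central
methodological safeguard — calls of one bird are so self-similar that a
call-level split leaks identity into the test set. Partition call counts
follow the study's 5 : 1 : 2.5 (train : validation : test) proportions per
sex, scaled to what the smaller sex provides, keeping sexes balanced.

A bird's sex is the strict majority over an odd number of its calls
(41 by default; even counts are rejected rather than tie-broken). The 41
calls are the earliest detected ones — the selection order is otherwise
unspecified, and earliest-first is deterministic and matches how a
conveyor-style deployment would operate. With independent per-call accuracy
p > ½ the vote's accuracy is the binomial tail P(Bin(n, p) ≥ ⌈n/2⌉),
which the Monte-Carlo test reproduces; in practice per-bird correlation
makes the amplification weaker than the independent-calls bound.

## Synthetic data

`generate_call` synthesizes a harmonic chirp: fundamental ≈ 5 kHz plus a
per-bird identity offset (uniform ±150 Hz, fixed per bird), plus an optional
per-sex offset (default +400 Hz on cocks); two harmonics (relative
amplitudes 0.3 and 0.1); a sinusoidal component near 16 kHz standing in for
formant energy (level 0.35); a slow within-call drift of ±15 Hz; Hann-shaped
attack (8 ms) and decay (15 ms); peak amplitude ≈ 0.7 full scale.
`generate_recording` places calls with silent gaps and can add low-pass
(<1 kHz, 10th-order Butterworth-shaped) noise at a chosen RMS — the shape
of handling/movement noise. `generate_study` builds one recording per bird,
with "breeds" that differ only in their per-sex offset (defaults 400, 250,
100 Hz, ordered from easily to barely separable).

Call durations are drawn uniform [0.10, 0.27] s by default: inside the
species' 0.1–0.35 s range, with the upper end set so every planted call
maps inside the detector's 30–110-frame run-length gate (see run-length
accounting above). Ground truth records each call's sample extent *and* the
frame run the detector is expected to report, computed analytically from
the overlap needed for 11 crossings at the call's fundamental.

Encoding sex as a fundamental-frequency offset is a *test device*, not a
biological claim: the real acoustic sex cue is unknown (it is not visible
by inspection), and published work implicates formant structure as much as
pitch. What the generator provides is a controllable separability dial with
exact ground truth. Passing the end-to-end benchmark therefore shows the
*pipeline* is sound — detection, features, training, split hygiene and
voting — not that real chicks of any breed are separable; conversely the
zero-offset control shows the bird-disjoint split prevents identity
leakage from masquerading as sex signal. Real recordings differ in ways the
generator does not model: broadband and impulsive noise, overlapping or
truncated calls, within-bird drift over minutes, and breed differences that
are not a single scalar.

## Problem sizes

The bundled benchmark (`run_benchmark`) defaults to 20 birds per sex,
45 calls per bird, a CNN at width 0.125 (8 filters) on the 110×52 feature,
40 epochs with patience 10 — a deliberately scaled-down study that a single
CPU handles comfortably while preserving the full protocol (bird-disjoint
split, 41-call vote). Width 1.0 and the 2000-epoch/patience-100 protocol
reproduce the full-scale configuration unchanged.

## Known limitations

* The numpy backend is single-threaded apart from BLAS matmuls; full-width
  ResNet-50 on 110×513 spectrograms is functional but slow, and no GPU path
  exists.
* Threshold semantics ("ZCR > 10 per frame") make detected runs ~7 frames
  longer than the call's own frame count; boundaries are accurate to ±2
  frames on clean signals but systematically generous.
* The detector assumes clean, low-noise recordings (its design premise);
  broadband noise above the high-pass cutoff will defeat it.
* `evaluate` assumes complete prediction coverage of the test partition and
  fails loudly otherwise; there is no partial-coverage mode.
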