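# Methods

This note records the modelling and implementation decisions behind
`painspeech`: what the pipeline computes, what the synthetic corpus does and
does not emulate, and where genuinely open choices were settled.

## Preprocessing

Clips are standardized to mono, 8 kHz, 3 s (24,000 samples).  Resampling is
band-limited polyphase (`scipy.signal.resample_poly`); a nearest-sample
index remapping would alias and corrupt the Mel features, so it is not
used.  Multichannel audio is averaged to mono.  No amplitude normalization
is applied at this stage — clip level is a class cue in the synthetic
corpus, and the feature floor makes silence well-defined.  Length fixing
pads zeros strictly at the tail or keeps the first 24,000 samples; the
operation is idempotent.

## Log-Mel features

- Framing: Hann window (periodic form), 1024 samples, hop 256, **no
  centering** — every frame lies wholly inside the signal, so a standard
  clip yields T = floor((24000 − 1024)/256) + 1 = 90 frames.  Library
  conventions that center-pad (yielding 94 frames) are intentionally not
  followed; a `center` flag exists for sensitivity checks.
- Spectrum: one-sided power spectrum, 513 bins for n_fft = 1024.
- Mel filterbank: 64 triangular filters, HTK scale
  `Mel(f) = 2595 log10(1 + f/700)` (no Slaney break-point variant),
  centers equally spaced in mel between f_min = 0 and f_max = Nyquist
  (4 kHz), peak-normalized to 1 (no area normalization).  A filter narrower
  than one FFT bin is a configuration error, not a silent zero row.
- Compression: natural logarithm of (energy + 1e-9).  The log base is a
  uniform rescaling of the features; natural log is frozen for
  reproducibility.
- Reference path: `naive_logmel` evaluates the defining DFT sum directly
  (O(n²) matrix form) and is the oracle the fast rFFT path is tested
  against (worst-case relative error ~1e-12 on random clips).

## The classifier

Three stacked bidirectional GRU layers, hidden size 64.  The cell uses
three distinct biases (b_z, b_r, b_h); initial hidden states are zero in
both directions; weights initialize uniformly in ±1/√H from a seeded
generator.  Inverted dropout (p = 0.5) is applied between recurrent layers
and on the pooled embedding, training mode only; evaluation is fully
deterministic.  The utterance embedding is the arithmetic mean of the
top-layer bidirectional outputs over time — with an output size of one,
adaptive average pooling and the plain time mean coincide, and the head
sees only the pooled vector (no final-time-step concatenation).  Argmax
ties break toward the lowest class index.

The forward pass, backward pass, and Adam are NumPy implementations.  The
backward pass is analytic (derived from the gating equations) and is tested
against central finite differences on every parameter group; the cell
forward is tested against a scalar triple-loop evaluation.

## Training protocol

Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8) with **coupled** L2 weight decay
(decay added to the gradient, the classic formulation), learning rate 1e-4,
weight decay 1e-5, batches of 8 drawn in a seeded shuffle, at most 20
epochs.  Early stopping halts after 3 consecutive epochs without a new best
of the monitored accuracy, and the parameters from the best monitored epoch
are restored.  The protocol monitors the *held-out test set* — an
optimistic-bias choice reproduced deliberately; passing a separate
validation set to `eval_set` gives the hygienic variant.

Class-balanced loss uses inverse-frequency weights w_c = N/(K·N_c), which
reduce to 1 on balanced data.  The loss is computed from logits via
log-sum-exp; the probability-form `weighted_cross_entropy` states the
semantic contract and is used in tests.

Two split modes exist because the protocol description is ambiguous between
stratified holdout and speaker-independent splitting: `speaker_grouped`
(default) assigns whole speakers greedily after a seeded shuffle so the
clip count approaches the 80/20 target as closely as speaker granularity
allows; `clip_stratified` splits clips per class.  The ablation runner uses
the stratified mode, matching its stated setup, and reports both macro and
pain-class precision/recall/F1 since the aggregation of its published
counterpart is unstated.

## The synthetic corpus

The generator emulates the *statistical shape* of a cold-pressor pain
speech corpus — 51 speakers × 138 clips at full scale, mean duration 2.6 s
(SD 0.6, truncated to [0.5, 6] s), four-way aligned labels — with a
harmonic source model per clip:

- a pulse train at the clip's fundamental with cycle-level jitter,
  ≥ 8 harmonics (up to 12, capped at 95% of Nyquist) rolled off by a
  per-speaker spectral tilt;
- pain intensity raises F0 (×1.10/1.20/1.35 for mild/moderate/severe),
  raises energy (+2/+4/+7 dB) and raises jitter (0.8/1.3/2.0% vs 0.3%),
  the direction reported for vocal pain responses;
- the thermal condition is marked by sinusoidal amplitude modulation at
  6 Hz (cold) vs 3 Hz (warm), depth 0.9 — an arbitrary synthetic marker
  whose only purpose is to make the cold/warm task discoverable;
- white noise at 25 dB SNR relative to the signal.

Speaker profiles draw base F0 uniformly from 110–220 Hz, spectral tilt from
−12 to −9 dB/octave, and a level scale spanning about ±0.3 dB — an
idealized, gain-calibrated close-talk recording chain.  Each clip is
phonated at a pitch wobbled around the speaker's base F0 (log-normal,
σ = 0.08): utterance-level prosodic variation is a basic property of real
speech, and without it a per-speaker fixed F0 would act as a speaker
fingerprint that rewards memorization over the class cues.

Determinism: the corpus is a pure function of `SynthConfig`; per-clip seeds
derive from a hash of (corpus seed, speaker, clip index), so regeneration
is byte-identical.  WAVs are 16-bit PCM mono; amplitudes are chosen so the
severe gain stays far below full scale, and a 0.9-full-scale normalization
acts only as a clipping guard (per-clip peak normalization would cancel the
class energy gain the corpus is required to carry).

What the generator does **not** emulate: phonetic content, formant
structure, real prosody, breaths/noise annotations, per-speaker level and
tilt diversity at realistic magnitudes, or any calibrated correspondence
between the configured effect sizes and real pain speech (no per-class
acoustic statistics are published for the reference corpus).  Consequently,
passing the desk-scale learnability checks shows that the pipeline can
extract speaker-invariant class cues under controlled conditions — it says
nothing about accuracy on real recordings, where level variability,
channel effects and linguistic content dominate.

## Desk-scale study conditions

The end-to-end checks run on 6 speakers × 40 clips (240 clips; a
speaker-grouped 80/20 split holds out one full speaker of 40 clips) —
large enough for the protocol to fit within a few hundred optimizer steps,
small enough to run in about a minute per task on one CPU.  Under these
conditions with the default effect sizes and seed 0, the pain task reaches
0.92–0.98 held-out-speaker accuracy; the thermal task learns more slowly
(its modulation-rate cue must be read from envelope dynamics) and typically
sits well above chance but below the pain task at this scale; a zero-effect
corpus (all class gains zeroed, jitter equalized) stays within binomial
noise of the majority rate, confirming the pipeline cannot hallucinate
signal.

## Numerical details and edge cases

- Softmax and the loss are computed with max-shift / log-sum-exp; a zero
  probability at the true class in the probability-form loss is floored at
  1e-12.
- A never-predicted class has precision 0 and triggers a warning; weighted
  (support-weighted) recall equals accuracy for single-label data and is
  asserted as a property.
- Metric values are kept at double precision internally and rounded to
  four decimals only at rendering, half-even.
- Checkpoints are a versioned `.npz` (all parameter tensors plus model
  config and metadata) and round-trip bit-exactly.
- Empty sequences, empty classes, rate mismatches, duplicate clip ids,
  misaligned pain/intensity labels, and unknown label vocabularies all
  raise descriptive errors rather than propagating silently.

## Known limitations

- The learnability margin on the pain task depends on the held-out speaker:
  a speaker at the edge of the F0 range is genuinely harder, and corpus
  seeds other than the default can land at ~0.80 held-out accuracy.
- The thermal marker is weaker than the pain cues at desk scale; the task
  is learnable but not saturated within the 20-epoch budget.
- The external-corpus adapter validates one documented layout and fails
  loudly otherwise; it does not guess alternative schemas, and the quality
  filter is opt-in because no exclusion rule is documented for the
  reference protocol.
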