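# painspeech

Speech-based pain classification with Log-Mel spectrogram features and a
stacked bidirectional GRU classifier ("GRU-Mixer"), plus a synthetic
vocalization corpus generator so the whole pipeline can be exercised and
validated at desk scale without any external dataset.

The package targets researchers in speech-based health assessment who want
a small, fully inspectable, end-to-end reference implementation of this
family of models: audio standardization, feature extraction, the recurrent
classifier, the training protocol, and the evaluation reports, each testable
against independent oracles.

## The method

A mono clip `x[n]` is resampled to `f_s = 8 kHz` and forced to a 3-second
window (`N = 3 f_s = 24,000` samples) by tail zero-padding or truncation.
Hann-windowed frames (`N_FFT = 1024`, hop `H = 256`) are transformed to
one-sided power spectra, projected onto `M = 64` triangular Mel filters
(`Mel(f) = 2595 log10(1 + f/700)`), and log-compressed with floor
`ε = 1e-9`, giving a `T × 64` Log-Mel matrix (`T = 90` for a standard clip).

The classifier runs `L = 3` bidirectional GRU layers (hidden size `H = 64`)
over the frame sequence,

    z_t = σ(W_z x_t + U_z h_{t-1} + b_z)
    r_t = σ(W_r x_t + U_r h_{t-1} + b_r)
    h̃_t = tanh(W_h x_t + U_h (r_t ⊙ h_{t-1}) + b_h)
    h_t = (1 - z_t) ⊙ h_{t-1} + z_t ⊙ h̃_t

concatenating forward and backward states per step, then averages the
top-layer outputs over time ("temporal mixing", `h̄ = (1/T) Σ_t h_t`) and
maps the pooled embedding through dropout (p = 0.5) and a linear softmax
head.  Training uses class-balanced cross-entropy, Adam (lr 1e-4, coupled
L2 weight decay 1e-5), mini-batches of 8, at most 20 epochs with early
stopping after 3 epochs without improvement of the monitored accuracy, and
a speaker-independent 80/20 split.  Three tasks share the backbone:
pain vs. non-pain, cold vs. warm, and mild/moderate/severe intensity.

Everything numerical — the GRU forward pass, analytic backpropagation, and
Adam — is implemented in NumPy inside the package and verified against
scalar-loop equation oracles and finite-difference gradients.

## Worked example

```python
from painspeech import SynthConfig, synth_corpus, TrainConfig, train_task
from painspeech.metrics import render_report

table = synth_corpus(SynthConfig(n_speakers=6, clips_per_speaker=40, seed=0), "demo_corpus")
clf, report, history, split = train_task(table, "pain_binary",
                                         TrainConfig(seed=0), root="demo_corpus")
print(render_report(report))
```

prints

```
Classes         Precision    Recall  F1-Score
non-pain           0.9048    0.9500    0.9268
pain               0.9474    0.9000    0.9231
Macro Avg.         0.9261    0.9250    0.9250
Weighted Avg.      0.9261    0.9250    0.9250
Accuracy           0.9250
```

Training held out one full speaker (40 clips), monitored its accuracy per
epoch, and stopped after 15 epochs with the best checkpoint from epoch 12:
the classifier recognises pain vocalizations of a voice it never saw at
92.5% accuracy, because the synthetic pain effects (raised fundamental
frequency, raised energy, raised jitter) are speaker-independent cues.

The same flow is available from the shell:

```
painspeech synth --speakers 6 --clips 40 --seed 0 --out demo_corpus
painspeech train --corpus demo_corpus/metadata.csv --task pain_binary --seed 0 --out run
painspeech evaluate --corpus demo_corpus/metadata.csv --checkpoint run/checkpoint.npz \
    --task pain_binary --out eval
painspeech ablate --corpus demo_corpus/metadata.csv --seed 0 --out ablation
```

`ablate` trains the six regularization variants (full model; no dropout; no
weight decay; no early stopping; no dropout + no weight decay; bare GRU)
with a shared seed and split and writes a CSV of accuracy / precision /
recall / F1 per variant.

## Layout

- `src/painspeech/synth.py` — synthetic vocalization corpus generator
- `src/painspeech/preprocess.py` — resample / mono / fixed-length
- `src/painspeech/melspec.py` — Log-Mel features + naive-DFT reference
- `src/painspeech/gru.py`, `network.py` — GRU primitives and the full model
  (NumPy forward + analytic backward)
- `src/painspeech/train.py` — splits, class weights, Adam, early stopping,
  ablation grid
- `src/painspeech/model.py` — scikit-learn style `GRUMixerClassifier` and
  corpus-level orchestration
- `src/painspeech/metrics.py` — confusion matrices and report tables
- `src/painspeech/corpus.py`, `tame.py`, `tasks.py`, `cli.py` — I/O, the
  optional external-corpus adapter, task definitions, command line

See `docs/methods.md` for modelling choices, generator assumptions, and
limitations.
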