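# Methods

## Problem and model

The package detects holosystolic murmurs — band-limited noise filling
the interval between the first (S1) and second (S2) heart sounds, the
auscultatory signature of a ventricular septal defect (VSD) — in
10-second phonocardiogram (PCG) clips, and explains *where* in the clip
the decision evidence lies.

A clip is converted to a sequence of log-power spectral frames
X = [x(1), …, x(N)]: frames of `frame_length` samples taken every
`frame_shift` samples (tail samples that do not fill a frame are
dropped, so N = ⌊(num_samples − frame_length)/frame_shift⌋ + 1), Hann
windowed, real-FFT transformed, squared, floored at 1e−10, and
log-compressed. With the canonical 512/256 framing each frame is a
257-dimensional vector. Three classifiers share this input:

* **CNN** — three tanh convolutional layers (32 filters each; kernels
  1×4, 1×4, 4×4 in time × frequency, same padding, stride 1, no
  pooling), global average over frames, then two 512-unit tanh dense
  layers and a softmax output.
* **CRNN** — two 16-filter 1×4 conv layers, the frequency×channel axes
  flattened per frame into y(n), two stacked 256-unit LSTM layers, and
  the last recurrent output h(N) fed to two 256-unit dense layers and a
  softmax output.
* **TAP-CRNN** — the CRNN encoder plus a temporal attentive pooling
  (TAP) block between the encoder and the dense head:

  - global attentive vector  c(n) = [W_c y(n); W_r h(N)],
  - global weights           α(n) = softmax_n(uᵀ tanh(c(n) + b_global)),
  - scaled features          z(n) = α(n) y(n),
  - local weights            β(n) = softmax_n(vᵀ tanh(W_l z(n) + b_l)),
  - attentive context        f̂ = (1/N) Σ_n α(n) β(n) y(n),
  - head input               s = [f̂; W_g h(N)].

  Both softmaxes run across the N frames of one clip, so α and β are
  distributions over time; a per-frame softmax of a scalar would be
  identically 1 and make the pooled average degenerate. W_g is a
  learned rnn_dim × rnn_dim matrix. The per-frame product
  EPL(n) = α(n)·β(n) is reported as the event presence likelihood.

Training minimizes softmax cross-entropy with Adam (default learning
rate 1e−3, β₁ = 0.9, β₂ = 0.999). All layers use tanh activations;
only the output is a softmax. Everything — convolution, LSTM, TAP,
dense head, reverse-mode gradients, Adam — is implemented in numpy
inside the package; a central-finite-difference check of every
parameter tensor is part of the test suite (relative error < 1e−4 on a
small instance, typically ~1e−6).

Clips are processed at natural length; minibatches (default size 8) are
formed by accumulating gradients across clips, so the attention
normalizations always run over real frames and no padding or masking is
ever introduced.

### Numerical and design choices

* **Attention score initialization.** The score vectors u and v start
  at zero, so both attentions open exactly uniform. With random-signed
  score vectors the trained attention polarity is a coin flip between
  "attend the event" and "attend the background": both configurations
  can reach zero training loss, the classification objective cannot
  tell them apart, and the anti-localized half renders the EPL useless
  as an explanation. Starting uniform lets the first data-driven
  updates break the symmetry toward frames that carry class evidence.
* **Feature standardization.** Per recording, one scalar mean and one
  scalar standard deviation computed over the whole log-power matrix
  are removed (toggleable). This cancels the recording gain — a
  waveform scale factor is an additive constant in log power, so the
  EPL is invariant to amplitude scaling — without imprinting the
  recording's average spectral signature onto every frame. Per-bin
  standardization would do the latter, letting a model read the
  clip-level class from any single frame; frame-level attention then
  has no reason to prefer murmur frames.
* **Kernel orientation.** "1×4" kernels are 1 frame × 4 frequency
  bins: convolutions scan frequency within a frame, matching the
  intent of frequency-shift-invariant features. Same padding keeps the
  frame count; the per-frame conv feature is the flattened
  frequency × channel block (cnn_dim = n_bins × last filter count).
* **CNN temporal pooling.** The CNN baseline summarizes time by a
  global average of the per-frame conv features before its dense head.
* **Decision rule.** Predicted class is the posterior argmax; the
  murmur-class posterior is the score swept for the ROC (trapezoid
  AUC). Murmur is the positive class in all metrics.
* **Degenerate inputs.** A single-frame clip yields α = β = EPL = [1].
  Sites with no positives (or no negatives) report the affected
  metrics as absent, never as zero. LSTM forget-gate biases start
  at 1; softmaxes subtract the row maximum before exponentiation.

## Synthetic cohort generator

No public recordings accompany the original clinical dataset, so the
package ships a seeded simulator that reproduces the acoustic structure
the classifiers rely on:

* S1 and S2 are ~50 ms exponentially decaying multi-tone bursts
  (40–140 Hz) placed periodically at the configured heart rate
  (default 80 bpm, S1→S2 gap 35 % of the cycle), with ±10 % amplitude
  variation per beat.
* A murmur-class clip adds Gaussian noise band-passed to 100–600 Hz,
  gated onto every S1→S2 interval with 10 ms raised-cosine flanks. Its
  level is `murmur_snr_db` over the white background floor
  (`background_noise_db`, default −20 dB re the unit S1 peak).
* Every clip carries a continuous colored ambient component
  (80–700 Hz, default −24 dB) emulating room rumble and airflow, plus
  the white floor. Because the ambient band overlaps the murmur band
  and its level varies between subjects, no recording-level statistic
  such as average band energy separates the classes; the murmur is
  identified by its timing within the cardiac cycle, as in real
  auscultation.
* Per subject, heart rate (±10 bpm), murmur SNR (±3 dB), noise floor
  (±6 dB), and ambient level (±6 dB) are jittered once, so
  subject-exclusive splitting is meaningful.
* The five auscultation sites differ by a murmur gain profile
  (tricuspid and Erb's point 1.0, pulmonic/mitral 0.7, aortic 0.6),
  reflecting where a VSD murmur is loudest.
* Waveforms are peak-normalized to 0.9 and written as mono 16-bit WAV;
  systolic intervals are stored in a TSV sidecar next to each clip.

What the generator does **not** emulate: hemodynamics, diastolic or
crescendo–decrescendo murmurs, innocent murmurs, speech or friction
artifacts, sensor variation, and pathological rhythm. Passing the
synthetic benchmarks therefore demonstrates that the implementation
learns and localizes a gated band-limited event under confounded noise
— not clinical-grade murmur detection.

## Evaluation protocols

Splitting is always at the subject level. The train/test split draws
`round(fraction × n_subjects)` subjects per class (default 70 %); the
K-fold splitter shuffles each class and deals subjects into K folds
whose per-class counts differ by at most one. Metrics are computed from
the confusion counts (murmur positive): accuracy, sensitivity,
specificity, PPV, NPV as percentages to one decimal, ROC by threshold
sweep of the murmur posterior, AUC by the trapezoid rule. K-fold
reports add an arithmetic-mean row over folds. Per-site reports filter
the test set by site label.

## EPL explanation and its score

For one clip the TAP-CRNN's EPL trace (per-frame α·β, aligned to frame
center times) is exported as TSV and optionally plotted under the
spectrogram. On annotated synthetic clips it is scored by a pairwise
ranking statistic: the probability that a uniformly chosen murmur frame
receives a higher EPL than a uniformly chosen non-murmur frame, ties
counting one half, averaged over clips. 0.5 is chance, 1.0 perfect.
This is an artifact-level surrogate for the qualitative claim that
murmur regions should receive high EPL; it is not a clinically
validated localization metric.

## Desk-scale experiment sizes

The published architecture (257 bins × 16 filters ⇒ 4112-dimensional
per-frame features and two 4112×4112 attention matrices) is far larger
than needed to study the mechanism on synthetic data, so the canned
experiments in `tapcrnn.experiments` run a reduced instance chosen to
keep a full benchmark in minutes on one CPU: 2000 Hz clips, 128/128
framing (65 bins, 156 frames per 10-s clip), 4-filter conv layers in
each architecture's published layer structure (two 1×4 layers for the
recurrent models; 1×4, 1×4, 4×4 for the CNN), two 32-unit LSTM layers,
a 2×32 dense head, learning rate 3e−4, batch 8, 25 epochs (20 for the
three-architecture comparison). The benchmark cohort is 24 + 24
subjects × 5 sites × 1 clip (240 clips); a 2/3 subject-exclusive split
gives 160 training and 80 held-out clips. The three-architecture
comparison runs at murmur SNR 0 dB (murmur at the in-band background
level) over four seeds and 12 + 12 subjects. Layer counts, kernel
shapes, activations, optimizer, loss, and the TAP equations are
identical to the full-scale models; only widths and the sample rate
shrink.

## Known limitations

* Attention polarity is only nudged — not guaranteed — by the uniform
  start: the classification loss cannot distinguish "attend the
  murmur" from "attend the background", and on some initializations
  the trained EPL still anti-localizes (ranking score well below 0.5)
  even though classification accuracy is unaffected. Inspect the EPL
  against annotations before trusting it on a new task.
* The relative ranking of the three architectures on the synthetic
  cohort does not mirror reported clinical experience. A simulated
  holosystolic murmur is stationary gated band noise, for which the
  CNN's average-over-frames pooling is a near-matched duty-cycle
  detector that generalizes from few subjects, whereas the desk-scale
  recurrent models can memorize a small training set before they
  robustly extract the systole-timing cue; at easy SNR all three
  saturate. Differences that favor recurrent attention on real
  recordings (nonstationary murmurs, artifacts, richer inter-patient
  variability) are exactly what the simulator leaves out.
* The LSTM is unidirectional, as in the reference architecture;
  evidence near the clip start must survive the whole recurrence to
  reach h(N).
* The ROC threshold sweep assumes the murmur posterior is a monotone
  score; no probability calibration is attempted.
* Training is single-threaded deterministic for a fixed seed; BLAS
  thread counts may perturb results at the last bit across machines.
* The simulator's murmur is stationary within systole (holosystolic,
  uniform intensity). Ejection-shaped murmurs would need a different
  gate envelope.
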