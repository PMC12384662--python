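# Methods

## Problem and model

`microcaps` detects epileptic seizure states in short windows of
single-channel EEG. A 1-D window of amplitudes is expanded into a small 2-D
matrix and classified by a compact capsule network:

1. **Dimensionality expansion.** A window of `L` points is written row-major
   into an `h x w` matrix with `h >= w`, `h/w <= 2` and `h*w >= L`, zero-padding
   the tail when `L` has no balanced factorisation. The expansion is invertible
   on the unpadded prefix, so no information is lost; it only gives the
   convolutions a 2-D neighbourhood to operate over.
2. **Feature extraction.** Conv-1: 8 filters, 4x4 kernel, same padding, ReLU.
   Conv-2 stage: two stacked 4x4 valid convolutions with 8 filters each
   (spatial size shrinks by 3 per convolution; for a (19, 18) input the
   feature map is (13, 12, 8)).
3. **Primary capsules.** The feature map is reshaped (row-major over rows,
   columns, channels) into vectors of dimension 4 and squashed:
   `v = (|s|^2 / (1 + |s|^2)) s / |s|`, which maps every vector to length < 1
   while preserving direction. The (13, 12, 8) map yields 312 capsules.
4. **Routing-by-agreement.** Each primary capsule `i` predicts each label
   capsule `j` through its own weight matrix, `u_hat[i,j] = u[i] W[i,j]`
   (`W[i,j]` is 4x16). Routing logits `b` start at zero; for `r` rounds
   (default 3) the coupling coefficients are `c[i,:] = softmax(b[i,:])` over
   the label capsules, label capsules are `v[j] = squash(sum_i c[i,j]
   u_hat[i,j])`, and `b[i,j]` grows by the agreement `u_hat[i,j] . v[j]`.
   No `b` update is performed after the final round (it would be unused).
5. **Classification and loss.** The length of label capsule `k` is the
   probability class `k` is present; prediction is the argmax (ties break to
   the lowest index). Training minimises the margin loss
   `L_k = p_k max(0, m+ - |v_k|)^2 + lambda (1 - p_k) max(0, |v_k| - m-)^2`
   with `m+ = 0.9`, `m- = 0.1`, `lambda = 0.5`; the sample loss sums over
   classes and the batch loss is the mean over samples (a mean rather than a
   sum so the loss scale is independent of batch size). There is no
   reconstruction decoder.

Optimisation is Adam at learning rate 5e-4, batch size 32. The default
epoch budget is 400 (most runs stabilise well before that; a hard cap of
1000 is configurable), with an optional early stop when the epoch loss
falls below a configurable threshold (disabled by default — no principled
value exists for it).

## Numerical engine

The network, including backpropagation, is implemented on a small
reverse-mode autodiff core over numpy (`microcaps.autograd`): broadcasting
arithmetic, reductions, ReLU, softmax, two-operand einsum and NHWC 2-D
convolution, with Adam on top. Gradients flow through the unrolled routing
iterations. All arithmetic is float64. Analytic gradients are verified
against central finite differences in the test suite (relative error
~1e-8), and routing is verified against an independent straight-loop
transcription of the update rules to 1e-6.

Numerical guards: the squash norm uses an epsilon of 1e-8 inside the square
root so the zero vector maps to itself with a finite gradient; softmax
subtracts the row maximum; capsule lengths passed to the loss are computed
with the same epsilon guard.

Weight initialisation (the reference protocol is silent): fan-in-scaled
normal for convolution kernels, truncated normal (sd 0.05, clipped at two
sd) for the routing weight array, biases zero. All randomness — weight
init, batch order, shuffling, splits, the generator — derives from a single
seed, and runs are bit-reproducible.

## Window length and architecture presets

Two window lengths are printed in the source protocol: 178 points per 1 s
window, and a 342-point network input. At 173.61 Hz a 1 s window is 174
points, so neither follows from the sampling rate; the package therefore
exposes both as named presets — `table1` (342 points -> (19, 18), exactly
the reference layout) and `ucistyle` (178 points, padded to 180 ->
(15, 12)) — and the default configuration derives the window from
`window_s * fs` (1 s -> 174 points -> padded to 176 -> (16, 11)). The
printed Conv-2 output (13, 12, 8) from a (19, 18, 8) input is unreachable
with a single 4x4 valid convolution; the Conv-2 stage is therefore two
stacked 4x4 valid convolutions, which reproduces the printed shapes
exactly. The printed primary-capsule kernel entry "(2, 4, 16)" admits no
convolutional reading; primary capsules are formed by reshape + squash
only (the arithmetic 13*12*8 = 312*4 forces this).

## Evaluation protocol

Segments from all files of a dataset case are pooled, shuffled, and split
70/30 stratified by class; three stratified folds are formed over the
training portion; one model is trained per fold (fitting on two thirds,
monitoring the remaining third) and each fold-model is evaluated once on
the shared 30% test set. Metrics are reported as mean ± sd over the three
fold-models, in percent. Note the folds share the test set — the sd
reflects training stochasticity, not test-set resampling.

Inputs are z-scored with a global mean/sd computed from the training
segments only (raw Bonn amplitudes are large ADC integers; the global —
not per-segment — transform preserves the between-class amplitude contrast
that carries diagnostic signal).

Sensitivity/specificity conventions: for binary cases the positive class
is the ictal one (class index 1 — set E in the Bonn pairings). For the
ternary case both metrics are macro-averages of one-vs-rest values;
classes with no actual samples (or no negatives) are excluded from the
average with a warning. Class imbalance (e.g. AB vs E is 2:1) is left as
is by default; per-class loss weights are available in the configuration.

## Synthetic data generator

The generator emulates the three clinical states at the Bonn dimensions
(100 files per class, 4096 points, 173.61 Hz, integer ADC-like units):

* background — `1/f` noise plus an 8–12 Hz alpha sinusoid with random
  frequency and phase, unit sd before scaling;
* interictal — background plus Poisson-timed (1.5 events/s) biphasic
  triangular sharp transients, 70 ms wide, 3x background amplitude,
  random polarity;
* ictal — a rhythmic spike-and-wave train at 3–5 Hz (a slow sinusoid
  mixed with a sharpened odd-harmonic component) at 6x background
  amplitude over attenuated background.

Defaults were chosen once as a plausible caricature of the corresponding
Bonn sets: an amplitude contrast of roughly an order of magnitude between
ictal and normal scalp EEG, interictal spikes at around 1–2/s, and
spike-wave rhythms in the classic 3–5 Hz band. Every file is a pure
function of (config, per-file subseed), with subseeds spawned from the
master seed.

What the generator does **not** model: inter-subject variability,
non-stationarity within a file, artifacts, realistic spectra beyond
`1/f` + alpha, or the intracranial/scalp distinction. Synthetic classes
are substantially easier to separate than real interictal/ictal EEG from
the epileptogenic zone. Passing the synthetic end-to-end tests therefore
demonstrates that the pipeline, optimisation and protocol work — near-ceiling
synthetic accuracy does not predict accuracy on clinical recordings, which
must be measured on the real corpus.

## Problem sizes in tests and the acceptance script

The synthetic end-to-end checks use the full Bonn-scale corpus (100 files
per class) with 30 training epochs per fold — the easy synthetic regime
converges well before that, so the short schedule measures the pipeline,
not the epoch budget. Unit and protocol tests use reduced corpora
(6–12 files per class, shorter files) chosen to exercise every code path
quickly. The acceptance script reports, for each quantity, the problem
size it was computed at.

## Known limitations

* Replicating the reference accuracies requires the public Bonn corpus,
  which the package never downloads; the corresponding tests run only when
  a local copy is present under `data/bonn/<SET>/`.
* Several protocol details of the source are under-specified (shuffle
  order relative to the split, the batch aggregation of the loss, Conv-1's
  nonlinearity, input scaling); the choices above are recorded here and
  the replication bound in the tests is set below the printed accuracies
  accordingly.
* Training is CPU-bound pure numpy; a full Bonn case at the default epoch
  budget takes tens of minutes, so the sweep and replication runs use
  reduced epoch budgets by default.
* No multi-channel EEG, EDF/BDF input, artifact rejection, EM routing or
  reconstruction branch.
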