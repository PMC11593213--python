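# Methods

## Scope and model family

`apnealite` implements a family of small 1-D convolutional classifiers
for per-window sleep-apnea detection, in two convolution flavors:
standard ("spatial", SC) convolutions, and depthwise-separable (DSC)
convolutions in which each input channel is first convolved with its own
kernel (depthwise, no bias) and the channel mix is then done by a 1×1
pointwise convolution (with bias). Three architectures exist per flavor:

* **ECG model** — input 1200 samples × 1 channel (12 s at 100 Hz):
  input batch normalization; conv(k=100, c′=3, stride 2, same padding);
  maxpool 2; conv(k=10, c′=50); maxpool 2; conv(k=30, c′=30); maxpool 2;
  flatten (2250 features); dropout 0.25; dense(2, softmax). Hidden
  activations are ReLU.
* **SpO₂ model** — input 128 × 1: convs (k=25, c′=6), (k=10, c′=50),
  (k=15, c′=30), all stride 1, each followed by maxpool 2; flatten
  (480 features); same head.
* **Fusion model** — both single-signal models truncated after their
  flatten layers, features concatenated (2730), dropout 0.25, fresh
  dense(2, softmax) head. Branch weights come from pretrained
  single-signal models (transfer learning); by default the trunks are
  frozen and only the head trains.

### The SpO₂ input-length choice

The segmentation stage can downsample a 12-s SpO₂ window to any target
length, and 96 samples (8 Hz) is a natural choice for oximetry. We
nevertheless default the SpO₂ classifier input to **128 samples**: with
the three pool-2 stages of the architecture, 96-sample inputs give a
flatten width of 360, which is inconsistent with the published
parameter totals of every SpO₂-containing model in the reference
complexity table, while 128 (flatten width 480) reproduces all of them
exactly. Both lengths are supported
(`make_paper_spec(..., spo2_input_length=96)`); only the default
changes.

### Padding and shape conventions

All convolutions use *same* padding — output length ⌈L/stride⌉ — which
is both what the reference parameter totals imply and the common
default in deep-learning frameworks. Pooling is valid with
size = stride = p: output ⌊(L−p)/p⌋+1. Valid-padded convolutions are
supported for custom specs and raise an explicit error when the kernel
exceeds the current length.

## Parameter counting

`complexity.count_params` uses the standard framework conventions,
which reproduce all six reference totals exactly:

| layer | parameters | of which non-trainable |
|---|---|---|
| batchnorm | 4·C (γ, β, running mean, running var) | 2·C |
| conv (SC) | k·c·c′ + c′ | 0 |
| conv (DSC) | k·c + c·c′ + c′ (bias on pointwise only) | 0 |
| dense | n·u + u | 0 |

Fusion models count both truncated trunks plus the new head; the
discarded branch heads are not counted.

## Closed-form costs and the reduction factor

`sc_cost` / `dsc_cost` give the bias-free weight and operation counts
for a single convolution at stride 1 with output size equal to input
size, in 1-D or 2-D. The reduction factor is returned as an exact
`Fraction`, `1/c′ + 1/k^d`. Note the denominator carries the *output*
channel count c′ and the kernel extent; the identity
R = W_DSC/W_SC = O_DSC/O_SC follows from the algebra of the four cost
formulas and is enforced by an exact-rational property test. Separable
convolution is strictly cheaper whenever (k−1)(c′−1) > 1; at k = c′ = 2
the two flavors cost the same, and a 1×1 kernel with one output channel
makes DSC twice as expensive — degenerate cases the tests pin down.

## Operation counting

Published operation totals for convolutional networks depend on
unstated conventions (whether biases, pooling and normalization are
counted, how padding edges are treated). The reference table's
multiplication/addition counts for these six models could not be
reproduced under any natural convention we tried (for the SC-ECG model
the closest natural per-layer sum is 7,385,700 multiplications against
a printed 6,534,116). `count_ops` therefore defines its **own**
documented convention — per conv output element k·c multiplications
(SC) or the depthwise/pointwise split (DSC), one accumulating addition
per multiplication, n·u each for dense, one multiply + add per element
for batchnorm, (p−1) additions per pooled output (max-selection
approximated as addition), nothing for flatten/dropout — and the
energy-model evaluation of the published figures takes the published
counts as *inputs* (`REFERENCE_OP_COUNTS`) rather than pretending our
counter reproduces them.

## Energy model

Per-inference energy pairs every multiplication with one addition into
a 16-bit MAC at 0.39 pJ; additions in excess of the multiplication
count (pool selections and the like) cost 20 fJ each. Values are kept
unrounded internally and rounded to 2 decimals only for display.
Published energy-efficiency factors are quoted as ratios of the
2-decimal tabulated energies, so `efficiency_ratio` rounds *before*
dividing; the unrounded ratios differ slightly (e.g. 9.56 vs 9.4 for
the SC-ECG / DSC-fusion comparison).

## Executable networks

`netbuild` is a self-contained numpy implementation of the layer stack
(im2col convolutions, batchnorm with exponential running statistics —
momentum 0.99, ε = 1e-3 — max-pooling with argmax bookkeeping, inverted
dropout, Glorot-uniform initialization) with full backpropagation, Adam
(β₁ = 0.9, β₂ = 0.999), minibatch shuffling, early stopping on
validation loss, and best-weight restoration. Everything is float32 and
driven by explicit seeds; two runs with identical inputs and seeds are
bit-identical. Gradients were validated against central finite
differences on mixed-layer models. When a fusion model's branches are
all frozen, branch features are precomputed once and only the head is
iterated — a pure optimization with unchanged results, since frozen
batchnorm uses running statistics either way.

Training hyperparameters (learning rate 1e-3, batch 128, up to 20
epochs, patience 5) are conventional defaults, fully configurable;
nothing in the analytic accounting depends on them.

## Segmentation and labeling

Windows are 12 s, half-open [t, t+12), 0-based seconds. Minute-scheme
recordings contribute the first 12 s of each annotated minute with that
minute's label. Event-scheme recordings are cut into consecutive
windows from sleep onset (0 when absent); a window is apneic iff its
apneic overlap is ≥ 10.0 s — computed on the **union** of event
intervals by default, so several short activities can jointly reach the
threshold; a `single` mode considering only the longest event is
available since annotations rarely disambiguate the aggregate reading.
Events running past the recording end are clipped with a warning.
Resampling to classifier input lengths uses polyphase filtering with
line-extrapolated padding (linear interpolation available), which
preserves constants to within FIR passband ripple (< 0.01 in SpO₂
percentage units).

## Splitting, balancing, augmentation

Split first (8:1:1, stratified, largest-remainder per class — each part
within one segment of the target class mix), then SMOTE the *training*
apnea class to parity with normal (k = 5 Euclidean neighbors on the raw
segment vectors, convex combinations with u ~ U(0,1)), then double by
flipping. Flipping defaults to time reversal; amplitude inversion is
available as it is an equally defensible reading of "flipping" for
1-D traces. Validation and test parts are never touched — enforced by
construction and verified bytewise in the tests; provenance ids
(`smote:`, `flip:`) make leakage checkable. For fusion training,
SMOTE interpolates the concatenated [ECG | SpO₂] row so each synthetic
pair is internally consistent.

## Synthetic data generator

The generator emulates exactly the structure the labeling rule and the
classifiers rely on:

* **Events**: counts from per-hour rates (default 30 full events/h,
  plus 4 sub-10-s activities/h so the "< 10 s ⇒ normal" branch is
  exercised), durations uniform (10–60 s full, 3–9 s short),
  non-overlapping with ≥ 12 s gaps allotted by a Dirichlet draw over
  the free time; infeasible schedules raise.
* **ECG** (100 Hz): a fixed Gaussian-bump P-QRS-T template placed at RR
  intervals; RR = 60/75 bpm baseline, lengthened 20 % during events
  with a 5-s post-event shortening rebound; additive Gaussian noise
  (σ = 0.05 of R amplitude).
* **SpO₂** (8 Hz): 97 % baseline; each event starts a desaturation 6 s
  after onset (a circulation-delay figure within the physiological
  5–15 s range), ramping to a nadir ≥ 4 % below baseline at event end
  (attenuated proportionally for sub-10-s activities), recovering
  exponentially with τ = 10 s; Gaussian noise σ = 0.15 %, optional 1 %
  quantization, clipped to [0, 100].

These values were fixed once as physiologically plausible study
conditions; they are configuration, not tuning knobs. What the
generator does *not* model: ECG morphology pathology, movement and
contact artifacts, oximeter averaging, patient heterogeneity, and the
label noise of human scoring. Passing pipeline tests on this data
therefore demonstrate that the implementation is correct and that the
architectures can extract a clean desaturation/bradycardia signature —
not that the printed clinical accuracies transfer to real recordings,
which would require the original clinical corpora and training details
not available here.

At the default desk scale (six 1-h paired recordings, ~1,800 windows,
~25 % apneic), the separable fusion pipeline trains in a few minutes on
one CPU and reaches held-out accuracy ≈ 0.99 — comfortably above the
0.85 floor the end-to-end test asserts, reflecting that the synthetic
task is by design easier than the clinical one.

## Numerical and degenerate-input choices

* Undefined metric ratios (zero denominators) are NaN with a warning,
  never silent zeros.
* Exact rational arithmetic (`fractions.Fraction`) for reduction
  factors; integer arithmetic throughout the analytic counters.
* Recordings shorter than one annotated minute yield an empty segment
  set with a warning (not an error), matching how corpus readers treat
  truncated records.
* SMOTE with fewer than k+1 minority rows raises; identical minority
  points legitimately produce duplicate synthetics.
* Empty layer lists are valid specs with zero parameters and
  operations.

## Known limitations

* The published multiplication/addition totals are not reproduced by
  `count_ops` (convention unrecoverable, see above); parameter totals
  and energies are.
* The pure-numpy trainer is single-threaded-CPU class; it is meant for
  desk-scale experiments and correctness cross-checks, not large-scale
  training.
* Real-data ingestion is limited to this package's plain-text record
  store; clinical-format readers (binary waveform/EDF) are out of
  scope.
* The 2-D cost formulas are exposed for completeness (`dims=2`), but
  only the 1-D instantiation has executable models.
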