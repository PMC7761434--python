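# Methods

## The problem and the model

Motor-imagery EEG (MI-EEG) over the sensorimotor cortex shows event-related
desynchronisation/synchronisation (ERD/ERS): imagining a hand movement
attenuates the mu rhythm (8–12 Hz) over the contralateral hemisphere and can
enhance it ipsilaterally. Entropy statistics pick this up because a stronger
narrowband oscillation makes the signal more regular (lower entropy), so the
channel-wise entropy trajectories of C3 and C4 drift in opposite directions
for left- versus right-hand imagery.

The feature used here is **weighted composite multiscale fuzzy entropy
(WCMFE)**. For a cropped single-channel signal `X` of length `H` and a scale
factor `τ`, the k-th weighted coarse-grained sequence (k = 1..τ) is

    y_k(j) = Σ_{p=1..τ} A_{τ,h}(p) · X((j−1)τ + k + p − 1)

i.e. a weighted mean over consecutive windows of τ samples, at each of the τ
possible window offsets. The weights `A_{τ,h}` are symmetric, positive and sum
to 1, so each coarse-grained series is the signal filtered by a linear-phase
FIR low-pass and decimated by τ. The weight rule, indexed by a mode
h ∈ {1,2,3,4}, is

    A_{τ,h} = [h/10, (5−h)/(5(τ−2)), …, (5−h)/(5(τ−2)), h/10]   (τ > 2)

with uniform fallbacks `[1]` at τ = 1 and `[0.5, 0.5]` at τ = 2 (the rule is
undefined there but those scales are still used). Uniform weights `1/τ`
recover plain composite multiscale fuzzy entropy (CMFE) exactly — same code
path, so the equivalence is bit-for-bit.

Each coarse-grained sequence is scored by **fuzzy entropy**: templates of
length m are centered on their window mean, pairwise similarity is
`exp(−d^n / r_abs)` of the Chebyshev distance `d`, and

    FE = −ln( φ(m+1) / φ(m) ),

where φ(m) is the mean similarity over ordered template pairs i ≠ j. WCMFE at
scale τ is the average FE of the τ offset sequences. The per-trial feature
vector concatenates the WCMFE of every channel at every scale 1..τ_max
(scale-major), giving `n_channels × τ_max` values — 14 for C3/C4 with
τ_max = 7 — which feed a small feed-forward network.

## Parameters

| parameter | default | meaning |
|---|---|---|
| τ_max | 7 | largest coarse-graining scale; beyond it the filtered curves barely change |
| m | 2 | embedding (template) length of the FE kernel |
| n | 2 | boundary gradient of the fuzzy membership |
| r | 0.15 | tolerance as a multiple of the cropped channel's SD |
| h | 3 | weight mode; A_{τ,3} gives the best class separation of the four modes |
| interval | [450, 900] | 1-based inclusive crop (3.5–7.0 s at 128 Hz), the period of clearest class divergence |

Conventions that needed fixing:

* **Template count.** φ(m) and φ(m+1) both use exactly `N′ − m` templates
  (the last window at dimension m is dropped), the standard sample-entropy
  convention that keeps pair counts comparable.
* **Tolerance resolution.** `r_abs = r × SD(cropped channel)` with the
  *population* SD, resolved once per channel per trial and shared by all
  scales and offsets (`r_mode="global"`); per-coarse-grained-sequence
  resolution is selectable (`r_mode="per_sequence"`). The sliding-window
  entropy curves resolve r per window, since there the window is the signal.
* **Scale dependence.** With the literal kernel `exp(−d^n / r_abs)` and
  n ≠ 1, fuzzy entropy is *not* invariant to amplitude scaling even with
  relative r (the exponent scales as `s^{n−1}`). Exact invariance holds at
  n = 1, or for any n after z-scoring the sequence. The tests assert exactly
  those properties.
* **Tail handling.** Offset k keeps its `floor((H − k + 1)/τ)` complete
  windows; windows that would overrun the signal are dropped, so offsets can
  differ in length by one sample unless τ divides H.
* **Degenerate inputs.** A constant sequence has FE = 0 exactly (returned
  before tolerance resolution); resolving r against a constant reference for
  a non-constant computation raises `DegenerateToleranceError`; if φ(m+1)
  underflows to zero, FE returns +inf with a warning rather than raising.
* **Double normalisation.** The coarse-graining definition can be read with
  both a 1/τ prefactor and weights summing to 1; that would shrink weighted
  sequences by τ relative to the plain mean. The weighted mean alone is used,
  which makes uniform weights reproduce CMFE exactly and keeps the two
  methods on one amplitude scale.

## Interval selection

The analysis interval is chosen from class-mean entropy curves: CMFE (τ = 2)
of a 1 s sliding window, averaged over trials per class, per channel.
`select_interval` formalises "where the curves differ most" as the contiguous
window of requested length maximising the mean absolute difference between the
two class curves, ties broken to the earliest start — an explicit stand-in for
what is, in the source protocol, a visual choice. The shipped default
[450, 900] is that protocol's published pick for 128 Hz / 9 s layouts.

## Classifier and evaluation

The classifier is a single-hidden-layer feed-forward network: 14 inputs
(z-scored with training-fold statistics), 6 sigmoid hidden units, 2 linear
outputs, trained by full-batch gradient descent on the MSE against one-hot
targets. The protocol fixes the architecture and loss but not the training
regime; the package's own choices are learning rate 0.05, at most 2000
epochs, a loss-plateau stop (improvement < 1e−6 over 50 epochs), and uniform
U(−0.5, 0.5) seeded initialisation — all exposed as estimator parameters.
Prediction is the argmax of the linear outputs; exact ties resolve to the
first class label.

Evaluation is repeated stratified k-fold CV (default 10 × 10), a fresh
network per fold, accuracies stored in percent; fold shuffling and network
initialisation derive from one master seed, making the whole protocol
deterministic.

## Statistical comparison

Two accuracy populations are compared by (1) a Lilliefors normality test per
population (statsmodels, table-interpolated p), (2) Bartlett's test of equal
variances (Levene selectable for robustness), and (3) the pooled-variance
two-sample t-test with `n1 + n2 − 2` degrees of freedom, two-sided by default
(a one-sided alternative is a flag). Degenerate zero-variance inputs give
t = 0, p = 1 for equal means and |t| = ∞, p = 0 otherwise.

## Synthetic data: what it emulates and what it does not

`generate_trial` builds each channel as broadband Gaussian noise band-limited
to 0.5–30 Hz (zero-phase 4th-order Butterworth, optional 1/f shaping) plus a
narrowband mu component (8–12 Hz filtered noise) normalised to a target RMS
with ±20% trial-to-trial jitter. During the imagery window (3.5–7.0 s,
matching samples 450–900 at 128 Hz) the mu amplitude of the
class-contralateral channel is multiplied by `1 − erd_depth` and the
ipsilateral one by `1 + erd_depth`. Random draws never depend on the label,
so `erd_depth = 0` makes the classes distributionally identical — the
pipeline's null condition.

Defaults: fs 128 Hz, 9 s trials, noise SD 1.0, mu RMS 1.5 (a subject with a
prominent mu rhythm; it also keeps the mu band dominated by the oscillation
rather than the broadband floor, so the measured ERD power ratio tracks the
constructed `(1 − erd_depth)²`), erd_depth 0.5, 70 trials per class.

The generator reproduces band-limited spectra, ERD/ERS timing and amplitude
jitter. It does **not** model artifacts, volume conduction, gradual ERD
onset (gain switching is instantaneous), nonstationary background, or
between-subject variability — so a passing end-to-end run demonstrates that
the pipeline recovers a band-specific regularity contrast of realistic
magnitude, not that it attains any particular accuracy on recorded EEG.

## Problem sizes

The end-to-end check uses 70 trials per class (the source protocol's
training-set size per class) with 10 × 10-fold CV; oracle-equivalence checks
run 50 sequences of length 20–60 against unvectorised loop implementations;
t-test calibration uses 10⁴ null replicates at n = 15 per group. The null
acceptance band for CV accuracy is the 95% binomial band for the 140
classified trials, 50 ± 8.3 percentage points.

## Known limitations

* Only fuzzy entropy is implemented; approximate/sample/permutation entropy
  comparators are out of scope.
* Only symmetric (linear-phase FIR) weight rules are provided.
* The BP training regime is a reconstruction; other optimisers may change
  absolute accuracies (not the pipeline's contracts).
* Feature values depend on signal amplitude for n ≠ 1 (see scale dependence
  above); classification is unaffected by per-dataset rescaling only insofar
  as the network standardises features.
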