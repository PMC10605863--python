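# Methods

This note documents the models, parameter choices and numerical
conventions behind `pedecg`, and what the synthetic experiments do and
do not establish.

## The analysis in one paragraph

The pipeline asks whether childhood obesity leaves a signature in the
resting lead-I ECG. Each 10-s, 500-Hz record is band-pass filtered,
segmented into complete 300-sample heartbeats around detected R peaks,
and labelled by the child's BMI category (normal vs obese; overweight
excluded). A 1D convolutional network classifies single beats, and
Grad-CAM++ is used to ask *where* on the beat the classifier finds its
evidence. Because the clinical cohort is not redistributable, every
stage is exercised on a synthetic cohort whose class difference is
injected at a known location, turning the explanation stage into a
parameter-recovery experiment.

## Synthetic cohort generator

**Beat model.** A beat is a sum of five Gaussians, one per PQRST
deflection, parameterised by centre (ms relative to the R peak), width
(Gaussian SD, ms) and signed amplitude (mV):

| wave | centre (ms) | width (ms) | amplitude (mV) |
|------|------------:|-----------:|---------------:|
| P    | −140 | 22 | +0.12 |
| Q    | −22  | 9  | −0.10 |
| R    | 0    | 11 | +1.00 |
| S    | +24  | 9  | −0.18 |
| T    | +250 | 25 | +0.30 |

A sum-of-Gaussians model was chosen over a dynamical-system ECG
simulator because the analysis only needs controllable morphology
differences, not physiological realism. The obese template differs
from the normal one only inside a configurable *difference window*
(default +150 to +350 ms after R — the T-wave region): at effect size
`e` the T amplitude is scaled by `1 − 0.5·min(e, 1.8)` and the T peak
delayed by `15·min(e, 1)` ms, with the modified component constrained
to keep ±4 SD of its support inside the window. Where real
obese/normal beats differ is unknown; the window location is a
simulation parameter, not a biological claim. At `e = 0` the classes
are identical by construction (the null configuration).

**Rhythm.** Per-beat heart rate is drawn uniformly from a
configurable range (default 70–100 bpm, a realistic resting range for
9–11-year-olds); a degenerate range gives a perfectly regular rhythm.
The true R-peak sample indices are kept on the record (and in the
cohort manifest) as ground truth for detector oracles; they are never
written into the XML records themselves.

**Noise.** Additive white noise (default SD 0.02 mV), respiratory
baseline wander (0.10 mV at 0.25 Hz), powerline pickup (0.02 mV at
50 Hz) and Poisson-arriving motion-artifact bursts (rate 0.3 per
record, 0.15 s, 0.6 mV RMS). Signals are quantised to integer
microvolts on output, which sets a ~0.5 µV floor on any
reconstruction comparison.

**Anthropometry.** Height is drawn from sex-specific normals
(1.41/1.40 m ± 0.065 m, clipped to 1.20–1.65 m); a BMI is drawn
uniformly inside the target category's interval (15 % margin off the
open boundaries) and weight is solved as `BMI · height²`. This
guarantees by construction that re-deriving the category from the
stored height/weight reproduces the target label. Ages are 9, 10 or
11 completed years at the collection date.

**Reproducibility.** One root seed; each record uses an independent
substream spawned as `SeedSequence([seed, class_index, record_index])`,
so cohorts are byte-identical across runs and invariant to generation
order.

## Preprocessing

**BMI categories.** Sex-specific cutoffs: girls — normal `< 19`,
obese `> 22.6`; boys — normal `< 18.5`, obese `> 21.4`; overweight in
between. Values exactly on a cutoff are assigned to overweight, which
both neighbouring intervals exclude; since overweight subjects are
excluded downstream anyway, the choice has no effect on the final
dataset.

**Filtering.** Linear-phase FIR band-pass, default 0.5–40 Hz,
Hamming-windowed sinc, 2001 taps at 500 Hz. The passband is the usual
diagnostic-ECG band. The tap count is driven by the DC requirement:
with a 0.5 Hz low edge the transition band must be well under 1 Hz
for the DC gain to fall below 1 % (2001 taps give ≈ 0.8 Hz transition
and DC gain 0.004; 501 taps would leave DC at 0.49). Filtering is
centred convolution — forward filtering plus an exact
`(taps − 1)/2` group-delay shift — so R-peak indices refer to the raw
time base.

**R-peak detection.** Hamilton-style: differentiate the band-passed
signal, rectify, integrate over an 80 ms moving window, then pick
peaks against a threshold that adapts between running QRS-level and
noise-level estimates (coefficient 0.45, update rate 0.2), with a
200 ms refractory period; each detection is refined to the local
signal maximum within ±10 samples so the index lands on the R apex.
On noise-free synthetic records the detector recovers every true R
peak exactly; at the default noise profile sensitivity ≥ 0.99
(property-tested over 50 records).

**Beat window.** A complete beat is the half-open window
`[r − 100, r + 200)`: exactly 300 samples (600 ms) with the R peak at
local index 100. "100 samples before plus 200 after plus the peak"
would sum to 301; the half-open convention is what makes the window
exactly 300 samples, and windows that would cross a record boundary
are discarded with a logged reason.

## Dataset construction

Records are excluded if the subject is overweight or the cardiology
report matches a configurable abnormality lexicon (case-insensitive
substring match; seeded with arrhythmia / early repolarisation /
bradycardia / tachycardia / heart block / hypertrophy / axis
deviation). Beats inherit their subject's class. The 70/20/10
train/val/test split is stratified by class and assigned at the
*subject* level by default, so no child's beats cross a split
boundary; a beat-level mode reproduces pipelines that split pooled
beats directly, which lets a subject straddle the divide and inflates
accuracy estimates. Allocation uses largest-remainder counts on
shuffled units, so achieved counts are exact to ±1 unit per class.

## The classifier

Four convolutional blocks on the 300-sample beat — (128, 16, 8, 128)
filters, kernel 3, stride 1, length-preserving padding, activations
ReLU / sigmoid / ReLU+batch-norm / sigmoid, dropouts
0.45 / 0.1 / 0.05 / 0.4 — then flatten (300 × 128 = 38 400 units), a
32-unit ReLU dense block and a 2-class softmax. The printed flatten
width is what pins the padding down: only "same" padding at stride 1
keeps the length at 300 through all four blocks, and a test asserts
this by actual shape propagation. Block-internal order is
conv → batch-norm (if present) → activation → dropout.

The network, backprop and Adam are implemented in numpy (float32;
im2col convolutions over BLAS matmuls). Keeping the engine in-repo
makes the gradient of a class score with respect to any intermediate
feature map a first-class operation — exactly what Grad-CAM++
consumes — and lets the tests check every gradient against central
finite differences (run in float64 for the oracle comparisons).

Training: Adam at 1e-3, batch size 200, categorical cross-entropy on
one-hot labels, Glorot-uniform weights, zero biases. Early stopping
monitors validation accuracy with a patience of 30 evaluations by
default and restores the best-validation weights; the patience unit
can be switched from epochs to optimisation batches, and the
monitored metric to validation loss. Runs are fully seeded and
reproducible.

Two practical observations from the synthetic experiments, both
documented because they shape the recommended problem sizes:

* the loss sits on a plateau near ln 2 for roughly the first hundred
  optimisation steps before the class signal is picked up, so the
  patience must cover that plateau (at ~10 batches/epoch, a patience
  of 10–12 epochs is safe);
* this architecture has a real optimisation hazard at small scale.
  The flatten feeds the dense block 38 400 **all-positive** features
  (the last conv block is a sigmoid), so Adam's early, sign-like
  updates move all of a hidden unit's input weights coherently: a
  single step can shift that unit's pre-activation by ±15–30 and a
  few such steps can drive every dense ReLU unit negative for every
  input — a permanently dead constant predictor (gradient exactly
  zero upstream). Whether a run escapes depends on the (data, seed)
  pair and on how quickly Adam's second-moment estimates accumulate;
  runs with more optimisation steps per epoch escape far more often.
  Learning-rate warmup delays but does not prevent the collapse, and
  a sigmoid dense block avoids death but crawls on the plateau. A
  collapsed run is trivially recognisable (validation accuracy
  pinned at the class prior, `best_epoch` 1, training loss at ln 2
  ≈ 0.693) and should simply be rerun with another seed or more data.

The experiments in the test-suite use 200 subjects (~2700 beats,
10 batches/epoch) and cap training at 25 epochs with patience 12 —
the canonical network reaches ≥ 0.99 validation accuracy on the
strong-effect cohort within that budget, and the chance-level runs
stop early on their own. The analysis drivers run at the same scale;
their default seeds are ones that train cleanly.

## Grad-CAM++

For class score `S_c` (the pre-softmax logit) and last-conv-block
feature maps `A_kl` (filter `k`, beat position `l`):

    alpha_kl = g_kl^2 / (2 g_kl^2 + sum_m A_km g_km^3)
    w_k      = sum_l alpha_kl · relu(g_kl)          with g = dS_c/dA
    CAM_l    = relu( sum_k w_k A_kl )

the usual closed form in which the higher-order derivatives of an
exponential class score reduce to powers of the first derivative
(exact for piecewise-linear tails, an approximation where the tail
crosses the sigmoid dense path). Locations where the denominator
vanishes have zero gradient and get `alpha = 0`. Because every
convolution is stride-1 and length-preserving, the map already lives
on the 300-sample axis and needs no upsampling. Per-beat maps are
normalised to maximum 1 before averaging (a raw mode exists) so
high-amplitude beats do not dominate the class mean; an all-zero map
stays zero. Class profiles average only correctly classified beats of
the class (validation split by default). For permutation-null
controls the correctness filter can be disabled, since a chance-level
model may classify no beat of one class correctly and "correct"
carries no information at chance. The overlap profile is the
pointwise mean of the two class profiles, and the localisation score
of a region is the fraction of total CAM mass inside it.

### Known limitation: localisation through a sigmoid final block

On the synthetic cohort the classifier's *gradients* do concentrate
where the class difference was injected (once trained well past the
accuracy plateau, the T-window share of |dS/dA| rises well above the
window's length share, and the negative-gradient mass concentrates
there 1.6–1.9×). The Grad-CAM++ *map*, however, stays nearly flat,
for two architectural reasons:

1. the last conv block is a **sigmoid**, so its feature maps have a
   high baseline (≈ 0.5 everywhere, observed per-filter window mass
   fractions 0.30–0.36). Any non-negative per-filter weighting of
   such maps — the form of the whole Grad-CAM family — is capped at
   ≈ 1.07× mass enrichment, far from a strong localisation signal;
2. the discriminative event is a *flattened* T wave, i.e. evidence by
   absence: it produces predominantly **negative** class-score
   gradients, which Grad-CAM++'s positive-gradient rectification
   discards.

The implementation follows the standard formulation regardless; the
flat map is a property of this architecture/effect combination, not a
bug, and the permutation-null control (shuffled labels ⇒ no
enrichment anywhere) behaves as expected. Users who need spatial
attribution through sigmoid feature maps should expect gradient-based
saliency (e.g. |dS/dA|) to be more informative than CAM-style maps.

## Architecture search

Random search and an elitist genetic algorithm (tournament size 2,
blockwise crossover, per-field mutation at rate 0.2) over conv-block
count/filters/activation/batch-norm/dropout, dense width, learning
rate and batch size, maximising validation accuracy at the
early-stopped epoch. The `desk` budget (10 trials × 10 epochs)
is what the tests and drivers run; the full-scale reference budget
(400 trials, 200 epochs, 20 generations × 20) is available as the
`paper` preset but is hours of CPU. Crossover and mutation operators
are this package's own choices.

## What the synthetic experiments do and do not show

Passing tests establish that the pipeline is internally correct:
filters and detector meet their stated responses, beats are windowed
exactly, labels are consistent, splits don't leak subjects, the
network learns a strong injected difference (val ≥ 0.99) and is at
chance when no difference exists, and every gradient path agrees with
finite differences. They do **not** establish anything about real
paediatric ECGs: the generator's Gaussian beats lack inter-subject
morphology variance, arrhythmic beats, electrode artefacts beyond the
simple burst model, and any physiological coupling between BMI and
the waveform — the injected T-wave effect is an assumption of the
experiment, not a finding.
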