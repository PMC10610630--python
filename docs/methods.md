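# Methods

## Problem and model

Beat detection in Holter ECG is treated as per-sample classification:
background (0), normal beat (1), premature ventricular contraction (2).
The supervised target is a segmentation mask painted from the beat
annotations: a normal beat labels the samples from 100 ms before to
100 ms after its R peak; a PVC labels 100 ms before to 150 ms after, the
longer tail covering the wide ventricular complex.  Milliseconds convert
to samples by round-half-to-even, so at 125 Hz the normal window spans
25 samples (12 + 1 + 12), matching the first layer's receptive field of
(9−1)·3+1 = 25 samples ≈ 200 ms.  Where label windows overlap, PVC wins:
it is the minority class of clinical interest, and the focal-loss alpha
already up-weights it.

The network is a 1D U-Net variant built from dilated convolutions
(kernel 9, dilation 3, 'same' padding) with batch normalization and
ReLU after every convolution, strided convolutions instead of pooling,
and linear upsampling instead of transposed convolutions:

| stage | layout | width |
|---|---|---|
| stem | k9/d3 conv | 16 |
| encoder ×4 | k9/d3 conv → k2/s2 conv | 16, 32, 64, 128 |
| bottleneck | k9/d3 conv | 128 |
| decoder ×4 | 2× linear upsample → 1×1 conv → concat skip → k9/d3 conv → k3 conv | 128, 64, 32, 16 |
| head | 1×1 conv (with bias) | 3 |

Convolutions carry no bias (batch norm's shift absorbs it); the head
does.  Skips are taken after each encoder block's dilated convolution,
before downsampling, so resolutions match the decoder's upsampled
features.

### How the wiring was fixed

The block structure above is described at the level of "double
convolution blocks, kernel 9, dilation 3, strided downsampling, linear
upsampling, 16 base filters doubling per stage" in the published method;
the exact wiring (downsampler kernel, decoder composition, bias
handling) is not, while two architecture-level constants are published:
836,387 trainable parameters and ≈63 GFLOPs per hour of one-channel
125 Hz ECG.  Those two numbers jointly over-determine the wiring: a
structured search over U-Net variants consistent with the described
block structure (bottleneck width/depth, downsampler kernel, decoder
conv counts and kernels, pointwise projections, bias policy) admits
exactly one member reproducing both — the table above (836,387 exactly;
62 GFLOPs, within 2 %).  Notable consequences: the bottleneck is a
single 128-filter convolution, the downsamplers have kernel 2, and each
decoder block ends in a kernel-3 refinement convolution.  A plain
reading with a double-conv 256-filter bottleneck is arithmetically
impossible — encoder plus such a bottleneck alone exceed the published
parameter count.

Inputs are right-padded with zeros to a multiple of 2^4 = 16 so each
stride-2 stage halves exactly and the output crops back to the input
length (the L×3 contract holds for any L ≥ 400, the enforced minimum).
Note the network is shift-covariant only in steps of 16 samples;
windowed and whole-record inference therefore differ slightly even away
from window seams, which is why the pipeline stitches window
*probabilities* into one record-global matrix before beat extraction.

## numpy implementation

No deep-learning framework is used.  Convolutions run as BLAS matrix
products over im2col patch matrices; backward passes (including batch
norm's batch-statistics terms) are hand-derived and verified in the
test suite by finite differences per layer and, for the full graph, by
an exact jacobian check along the piecewise-linear path (batch norm
patched to identity).  A finite-difference check of the *whole* network
in training mode is deliberately not used as an oracle: with batch-norm
coupling and ReLU kinks the difference quotient itself fails to
converge.  Weights initialize Kaiming-uniform from a recorded seed;
batch norm uses momentum 0.1 and eps 1e-5.  All state is float32;
losses accumulate in float64.

## Preprocessing

Applied to the whole record before windowing, per lead: zero-phase
(forward–backward) order-2 Butterworth high-pass at 0.5 Hz (effective
order 4; removes DC and baseline wander), zero-phase IIR notch at the
mains frequency (default 50 Hz, quality 30), then linear-interpolation
resampling to 125 Hz on a t = 0-anchored grid (output length
`round(n·125/fs)`).  No amplitude normalization anywhere: the chain is
linear, so a ×2 input yields a ×2 output.  Records are then cut into
non-overlapping 30 s windows (3750 samples); only the final window is
zero-padded.  The filter family, order and notch parameters are
configurable defaults — the conditioning steps are named in the
published method but not fully parameterized there.

## Loss, sampling, augmentation

Composite loss 0.5·dice + 0.5·focal.  Dice is soft dice per class with
eps 1e-6, averaged unweighted over the three classes (background
included); focal is −alpha_g (1−p_g)^gamma log p_g averaged over
samples, alpha = (1, 1, 1.5), gamma = 2 (the standard focusing value;
the published settings state only the alphas).  A probability floor of 1e-8 guards
the log.  Windows are drawn with replacement under weights that make
PVC-containing windows half of the expected draw.  Augmentation (each
with p = 0.75): amplitude scale U[0.6, 1.4]; offset U[−0.2, 0.2] mV;
additive noise of a uniformly chosen color (gaussian/pink/brown) with
standard deviation U[0, 0.2] × the window's own standard deviation —
the noise amplitude is read as relative because an absolute range would
duplicate the offset transform's numbers.  Masks are never altered.
Optimizer: Adam, lr 0.001, betas 0.9/0.999, no weight decay; defaults
batch 32, 30 epochs.

## Post-processing

Softmax masks are scanned left to right per class: a region opens at
probability ≥ 0.5 and closes after 2 consecutive sub-threshold samples
(interior 1-sample dips do not terminate) or at the signal end; regions
shorter than 5 samples (40 ms) are discarded; the beat is the floor
midpoint of onset and termination.  Normal and PVC lists merge; when
beats of different classes fall within 150 ms, the one with the higher
own-class probability at its location survives (the conflict rule is an
invention — the published description only says the lists "are merged").  Beats whose
±1 s neighborhood has signal standard deviation below 0.05 mV are
cancelled as pseudobeats on flat (electrode-off) segments; the floor is
configurable.  Multi-lead fusion clusters beats across leads greedily
within 150 ms; a cluster survives with beats from more than half the
leads, at the median position, with the majority class and ties going
to PVC (clinically conservative).

## Evaluation

Reference beats in the first or last 0.2 s are disregarded.  Matching
is one-to-one, nearest-first, within ±75 ms — the "150 ms interval
centered" reading; the defining sentence can also be read as
±150 ms, so the tolerance is exposed as a parameter.  TP/FN come from
matched/unmatched eligible references, FP from unmatched predictions,
and TN for class c counts eligible references of the other classes
with no class-c prediction within tolerance (event detection has no
natural negatives; this cross-class convention operationalizes its
one-line published description).  Se = TP/(TP+FN), Sp = TN/(TN+FP),
BA = (Se+Sp)/2; zero denominators yield NaN, never a silent 0.  Metrics
pool over records (micro-average) and are also available per record.
One published PVC row (Se 0.991, Sp 0.976, BA listed 0.986) is
internally inconsistent with the BA definition, which gives 0.9835; the
test suite checks the 11 self-consistent rows and documents this one.

## Synthetic data

The generator emulates Holter ECG: sinus beats on a jittered RR grid
(mean 0.8 s, jitter 0.04 s) as P-QRS-T Gaussian-bump composites
(R ≈ 1 mV); PVCs replace a sinus beat with probability
`pvc_probability`, fire early at 0.6 of the running RR, have a ~140 ms
wide dominant deflection of opposite polarity with discordant T and no
P wave, and are followed by a full compensatory pause (the RR pair
around the PVC sums to 2 RR).  Because each PVC event also emits the
pause-ending normal beat, the internal event probability is
q = p/(1−p), making the expected PVC *beat* fraction exactly p.
Records default to 360 Hz so the resampling path is always exercised,
with pink noise at 0.05 mV and 0.1 mV sinusoidal baseline drift;
gaussian/brown colors, levels, lead count (with per-lead gain) and all
rates are configurable, and everything derives from one integer seed.
Noise colors are spectrally exact (flat, 1/f, 1/f² power) and scaled to
a target standard deviation.

What the generator does **not** emulate: real QRS morphology variation
between and within patients, atrial arrhythmia, paced rhythms, muscle
artifact and electrode motion, multi-form PVCs, couplets/salvos.
Passing the end-to-end recovery test therefore demonstrates that the
pipeline is implemented correctly and can be trained, not that the
model reaches clinical-grade accuracy on real Holter data.

## Problem sizes in the test suite

The end-to-end recovery check trains the full default network (836,387
parameters) on 300 synthetic 30 s windows (50 records × 180 s, 15 % PVC
beats, default noise) for 6 epochs at batch 32, then evaluates on 50
held-out 60 s records; pooled QRS Se/Sp ≥ 0.95 and PVC Se/Sp ≥ 0.85 are
required (measured values are ≈0.998–1.0).  Determinism is asserted on
a smaller double run (4 records, 2 epochs).  These sizes are the
package's chosen desk-scale regime; the library itself has no scale
assumptions.

## Known limitations

* Training is CPU-bound numpy; desk-scale experiments are minutes, but
  the multi-million-window regime the method was originally trained at is out of reach
  without a GPU framework behind the same module surface.
* The wiring reconstruction above reproduces the published parameter
  count exactly and the FLOP count within 2 %; if the original wiring
  differs in a way that happens to produce the same two numbers,
  per-layer behavior could differ while every published constant still
  matches.
* `match_beats`'s cross-class true-negative convention is one of
  several defensible operationalizations; comparisons against other
  toolkits should align conventions first.
* The WFDB layer covers format-16 signals and MIT-format annotations
  only — enough for the PhysioBank arrhythmia family; other signal
  formats raise a format error rather than being misread.
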