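# Methods

This note documents the models, algorithms and design choices behind
`revadapt`: a package that asks, on fully synthetic data, whether the
temporal structure of auditory receptive fields adapts to room
reverberation the way a normative dereverberation model says it should.

## Virtual rooms and reverberation time

Rooms are rigid cuboids simulated by the image-source method.  For each
mirror image the pressure contribution is `1/d` (spherical spreading) at
delay `d/c`, multiplied per frequency band by `sqrt(1 - alpha)` per
reflection, where `alpha` is the energy absorption coefficient of the
surface hit.  Band components are recombined with a zero-phase filterbank
whose log-frequency masks form a partition of unity, so a frequency-flat
room reduces exactly to the broadband image sum.  Arrival delays are
rounded to the nearest sample (at 48,828 Hz this is a <11 us error,
negligible for energy-decay measurements and a large speed-up).  Because
the sampled image train is all-positive it accumulates a spurious
quasi-DC pedestal; a gentle zero-phase high-pass (cosine roll-off below
100 Hz, far under the 400 Hz lowest cochlear band) removes it, as
image-method implementations conventionally do.

Air absorption is ON by default, using standard atmospheric attenuation
values (about 20 degC, 50% relative humidity), 0.0004-0.37 dB/m across
the octave bands.  Two reasons: physically, the hundreds of metres of
path length behind a multi-second reverberation tail make air loss a
first-order effect at high frequencies; and structurally, it is the only
mechanism that makes reverberation time grow *sub-linearly* with room
size, which is how the three study rooms (exact x2.5 and x5 scalings of
3 x 0.3 x 0.3 m) behave.  Air absorption also supplies most of the
decline of reverberation time with frequency.

The stone surface table is vendored in `data/materials.yaml`.  Published
absorption values for stone-like surfaces span roughly 0.01-0.05; within
that range we fixed alpha = 0.03 (flat across bands) once, as the value
at which this HRTF-free simulator reproduces the study rooms' stated
reverberation times (RT60 = 0.78, 1.5, 2.6 s), and froze it.  Default
impulse-response durations for the presets are 0.4/0.8/1.3 s - roughly
half the expected RT60, enough decay for a stable line fit while keeping
the image lattice tractable (tens of millions of images for the small
room).

Reverberation time is measured through the cochlear model: the impulse
response's cochleagram is computed, and per band a least-squares line is
fitted to the decaying dB power from the band's peak bin to the last bin
above floor + 1 dB; RT60 = 60/|slope| and RT10 = 10/|slope| (one slope,
so RT60 = 6 x RT10 identically).  Bands that do not decay are flagged
invalid and excluded from the room's median.  Two caveats are inherent
to the method: with a truncated impulse response the fit is flagged but
still uses the available decay, and in these extreme-aspect-ratio
corridors the decay is not a single exponential (a slowly decaying
quasi-axial reflection family dominates the low-frequency tail), so the
fitted slope depends mildly on the analysis window.  These are
properties of the measurement definition, not bugs; the
median-over-bands summary is robust to them.

No head-related transfer function is applied: the receiver is a point
microphone at the position of the right ear.  `convolve_stimulus`
accepts any impulse response, so a user-supplied binaural filter can be
composed in, but nothing in the analyses depends on one.

## Cochlear model

The "log-pow" cochleagram: short-time Fourier power with 20 ms Hann
windows and a 10 ms hop (so time bins are 10 ms), pooled into 30
triangular bands whose centres are geometrically spaced from 400 Hz to
19 kHz.  Triangles live on the log-frequency axis with 50% overlap
(each spans the two neighbouring centres; the outer edges extrapolate
one geometric step), and sum to one inside the analysis range.  Band
power is 10*log10(power), floored at -94 dB.  Only full analysis
frames are used: a signal of N samples yields floor((N - window)/hop) + 1
bins.

## Ridge regression core

Both the dereverberation kernels and the neuronal STRFs are solutions of

    y_hat(t) = sum_f sum_h w[f, h] x[f, t - h] + b,      h = 0..19

with squared-error loss and an L2 penalty on `w` (bias free).  The
design matrix holds 20 causal lags of every channel (zero-padded before
the series start; when several stimulus blocks are concatenated the lag
context never crosses a block boundary).  Columns are z-scored for
fitting and the weights mapped back to input units, which matches the
behaviour of standard elastic-net solvers and materially affects the
selected penalty.

The penalty is chosen per target by k-fold cross-validation (default 10)
whose validation segments are unbroken, non-overlapping, contiguous
blocks partitioning the data exactly; the grid is 30 log-spaced values
spanning six decades below the spectral norm of X'X.  The final weights
are refit on all data at the winning penalty.  Everything is computed
through one economy SVD per fold, shared across penalties and targets,
so fitting 200 units against one stimulus costs little more than fitting
one.  Exactly constant targets short-circuit to zero weights and
bias = mean.

## Temporal metrics

A kernel's rectified, frequency-averaged profiles v+ (mean positive
part per lag) and v- (mean negative part) are reduced to:

* centre of mass: the |v|-weighted mean of bin centres (h + 0.5) * 10 ms,
  so both metrics live in [5, 195] ms;
* peak time: the extremum location after band-limited (Fourier)
  interpolation by a factor of 100, searched up to the last bin centre;
  exact ties resolve to the earliest time;
* best frequency: the centre frequency of the channel holding the
  largest weight (ties to the lower frequency).

All-zero profiles yield NaN and are excluded pairwise from population
statistics.  The same centre-of-mass definition, restricted to a
0-100 ms post-onset window, summarises probe-response PSTHs.

## Simulated neurons

The non-adaptive control is a linear-nonlinear-Poisson (LNP) model: a
single STRF fitted to both rooms' data combined, a four-parameter
sigmoid `rho1 / (1 + exp(-(y - rho3)/rho2)) + rho4` fitted to the
observed counts by multi-start nonlinear least squares (thresholds at
the drive quartiles, two slope scales, plus two extreme starts; a
failed fit falls back to a near-linear sigmoid reproducing the best
affine map, flagged), and independent Poisson draws per 10 ms bin with
the rate clamped at zero.  The network-receptive-field (NRF) variant
replaces the linear stage with one hidden layer of 10 sigmoid units and
a scaled sigmoid output, trained full-batch (Adam) on MSE with an L1
weight penalty whose strength is chosen by the same contiguous
cross-validation; training is seeded and restarts at a quarter step on
divergence.

Fit quality uses the normalised correlation coefficient: the covariance
between prediction and trial-mean response divided by
sqrt(Var(prediction) x SP), with signal power
SP = (Var(sum of trials) - sum of per-trial variances) / (N (N - 1)).
A non-positive SP estimate returns NaN.  Trial variability is the Fano
factor: median across bins (with nonzero mean) of variance/mean across
trials; note the median-of-ratios form sits slightly below 1 for an
ideal Poisson process at small trial counts.

## Synthetic data generator

The generator replaces everything the original experiment took from the
world, with planted ground truth:

* **Corpus.** 2 s snippets of four kinds - amplitude-modulated 1/f
  noise, harmonic stacks with vibrato, click trains, band-passed
  textures - each ramped with 0.25 s cosine edges, RMS-normalised,
  concatenated into 40 s blocks and band-passed to 200 Hz-20 kHz
  (8th-order Butterworth).  Modulation rates span 2-64 Hz and click
  rates 8-80/s: natural corpora (speech, footsteps, cracking branches,
  water) are rich in fast transients, and that broadband temporal
  structure is what lets a regression model separate the room's blur
  from the source's own dynamics.  The corpus does *not* attempt
  perceptual realism, long-range syntax, or realistic level statistics.
* **Room renders.** Each block is convolved with each room's impulse
  response and truncated to the block length; all rooms share the
  direct-path delay, so renders are onset-aligned.
* **Probes.** A fixed 500 ms broadband burst is *added* (not room
  filtered) at a uniformly random onset in the last 4 s of a block, on
  7 of 10 repeats, independently across blocks and rooms; its RMS
  matches the block (configurable, as the original level is not
  specified).
* **Switching stimuli.** The two rooms' renders are cut into 4 s
  snippets; duplicated, independently shuffled sets populate the early
  (S1/L1) and late (S2/L2) halves of alternating 8 s epochs in eight
  40 s stimuli (half starting with each room), spliced with 10 ms cosine
  crossfades overlapping 5 ms.
* **Ground-truth neurons.** Each unit's STRF is a Gaussian in
  log-frequency (centre channel 4-26, width 1.2-2.2 channels) times a
  difference of Gaussians in time: excitation at 10-25 ms (width
  4-7 ms) minus inhibition of comparable strength (gain 0.8-1.2, width
  10-16 ms) centred 25-40 ms later.  The lobes are far enough apart
  that a planted shift of the inhibition delay moves the ground-truth
  inhibitory centre of mass by the same amount (to within ~1 ms of
  overlap loss).  "Adaptive" units shift their inhibition delay by
  `adaptation_shift` ms per unit increase in the room's reverberation
  rank (rooms ordered by measured median RT60); "static" units have
  shift 0.  The linear drive is z-scored against a fixed reference (the
  pooled rooms with the rank-0 kernel) - a per-unit constant, so the
  neuron itself has no adaptive component - and passed through a
  per-unit sigmoid (output range 2-4 spikes/bin, slope 1.2-2 drive-SDs,
  threshold 0.4-1.2 SDs, baseline 0.02-0.1) before Poisson sampling.
  In the switching experiment the effective rank relaxes exponentially
  toward the current room's rank (default time constant 3 s), and each
  4 s period uses its time-averaged rank.

All generators are bit-reproducible under their seeds (numpy
`SeedSequence` spawning keeps streams independent across rooms, units
and stages).

## What the estimation pipeline can and cannot recover

Two estimator properties, both computed by the test suite and the
acceptance script, deserve emphasis because they mirror the scientific
logic of the study rather than implementation error:

* **The stimulus-statistics artifact.**  With Poisson noise at 10
  trials the cross-validated ridge penalty is large, and a heavily
  penalised STRF estimate is partially smeared along the *stimulus*
  autocorrelation - which the room itself changes.  Ground-truth
  *static* populations therefore show an apparent inhibitory
  centre-of-mass shift of roughly +4 ms between the small and large
  rooms.  Diagnostically, noiseless linear responses bring the artifact
  under 1 ms, confirming the regression itself is unbiased; the
  artifact is a property of regularised estimation under noise, not of
  the code.  The LNP control exists precisely to cancel it: simulated
  non-adaptive twins inherit the same artifact, and the real-minus-
  simulated residual is statistically nil for static populations while
  remaining clearly positive for adaptive ones.  Peak time is much less
  affected than centre of mass (a local extremum resists smearing
  better than a global integral).
* **Invariance correlations.**  A planted inhibition-delay shift makes
  receptive fields *look* adaptive but does not by itself dereverberate
  the response, so the cross-room response-correlation comparison
  (real vs LNP-simulated) does not favour these synthetic adaptive
  units: the measured median difference is slightly negative (the
  simulation's ridge-smoothed kernel produces smoother, hence more
  cross-room-correlated, responses).  The machinery is exercised on
  constructed responses in the unit tests; on synthetic populations the
  measured value is reported as-is.

Consequently, a passing suite shows that the pipeline recovers planted
temporal-adaptation effects and that its control logic separates them
from estimation artifacts - it does not show that the generator's
neurons are realistic cortical neurons, nor that real cortical data
would yield the same medians.

## Problem sizes and defaults

The end-to-end runners default to the study-scale configuration: audio
at 48,828 Hz; 30-channel cochleagrams; 200 ms kernels (600 weights);
two 40 s blocks per room with the first 36 s of each used for STRF
fitting (the last 4 s host the probes); populations of 100 units with
10 Poisson trials; the dereverberation model trains on 160 s of corpus
and is evaluated on a held-out 40 s.  The training corpus is shorter
than the original 600 s recording set; with the synthetic corpus's
statistics this is ample for 30 well-determined kernels, and all
reported model quantities are computed at this size.  Reduced
configurations (16 kHz, 12 channels, 10 s blocks) are used in unit
tests and accept the same code paths.

## Statistical conventions

Paired room comparisons use two-sided Wilcoxon signed-rank tests on
per-unit differences (NaNs dropped pairwise; all-zero differences give
p = 1; fewer than 5 pairs skips the test).  The three-room analysis is
a Kruskal-Wallis test followed by rank-based Fisher-LSD post hocs
(Conover-Iman: t statistics on rank means with the tie-corrected
pooled rank variance, df = N - k).  No multiple-comparison correction
is applied anywhere, matching the reporting conventions the analyses
are modelled on.
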