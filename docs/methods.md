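# Methods

This note documents the models and procedures implemented in
`snoreforge`, the parameter choices that matter, what the synthetic data
does and does not emulate, and the numerical decisions taken where the
underlying formulations were open.

## Audio front end

Input is mono PCM WAV. Integer samples are scaled by the type's full
range (1/32768 for 16-bit) rather than peak-normalized, so energy-based
features remain comparable across clips; peak normalization is available
as a flag. Everything is resampled to 16 kHz. Analysis frames default to
25 ms with a 10 ms hop and a Hamming window — the standard
paralinguistics convention; frame-domain sign and amplitude features
(ZCR, shimmer, per-frame RMS) use the un-windowed frames, spectral
features the windowed ones. A trailing partial frame is dropped.

Single-channel blind source separation is not attempted: there is no
well-defined independent-component decomposition of one microphone
channel, so no such pre-processing stage exists here.

## Feature domains

Frame-level descriptors are aggregated to clip level as mean and
standard deviation; a handful of features (temporal centroid, log attack
time, autocorrelation periodicity, clip RMS, peak frequency) are defined
directly at clip level. Feature names follow `domain.feature.stat`
(e.g. `freq.centroid.mean`) so a binary selection mask keeps stable
semantics across runs.

Decisions worth knowing:

- ZCR uses the sign convention sgn(p) = 1 for p ≥ 0, else 0, so a
  constant-zero frame has rate 0; the detrended ("modified") variant
  subtracts the frame mean first. The rate is bounded by (N−1)/2N.
- Spectra are magnitudes of the FFT of Hamming-windowed frames; power is
  magnitude squared; every log or ratio is floored at 1e-10. Spectral
  "center" is the median (50%-energy) frequency, distinct from the
  centroid (energy-weighted mean). Spread is the L2 deviation around the
  centroid and bandwidth the L1 deviation, so the two are not redundant.
  Roll-off uses the 0.85 energy quantile. Slope is the least-squares
  slope of magnitude against frequency; decrease the standard weighted
  difference from the first bin. Octave-band spectral contrast uses six
  bands from 125 Hz to 8 kHz and log(peak/valley) with 0.2-quantile
  neighborhoods. Shannon entropy is computed with the conventional minus
  sign and normalized by log(number of bins) to [0, 1].
- F0 is the normalized autocorrelation peak restricted to 50–500 Hz (the
  snore-relevant range), with a voicing threshold of 0.3; unvoiced
  frames are excluded and a fully unvoiced clip reports the documented
  sentinel 0 for F0, jitter and HNR rather than NaN. HNR is
  10·log10(r/(1−r)) at the F0 lag. Jitter and shimmer are mean absolute
  cycle-to-cycle (period, peak-amplitude) differences over their means.
- LPC uses order 12 by Yule–Walker on the biased frame autocorrelation
  (a small diagonal load keeps near-tonal frames solvable), with the
  error-filter sign convention A(z) = 1 + Σ a_k z^−k. Line spectral
  frequencies are the interior root angles of the palindromic /
  anti-palindromic split polynomials, sorted ascending; LSFs are
  computed per frame and averaged, which preserves ordering.
- The DWT uses Daubechies-4, 5 levels, periodization mode (exact
  orthogonal energy partition); per band: relative energy, log10 energy,
  mean |coefficient|, std, and normalized entropy of squared
  coefficients — 30 features. Too-short clips reduce the level with a
  warning.
- Sparse features decompose the mean-magnitude-normalized central 256
  samples on a 2×-overcomplete unit-norm DCT dictionary with a 20-step
  orthogonal matching pursuit (greedy max-correlation atom, least-squares
  refit on the active set, residual update). Reported: residual energy
  fraction at the quartile steps, mean/std of |coefficients|, normalized
  atom-index spread. The hand-rolled loop exists because per-step
  residuals are themselves features; it is cross-checked against
  scikit-learn's OMP in the tests.
- Eigen features are the singular values of the grand-mean-centered
  frame matrix, normalized to sum 1 (top 10 reported, plus top-3
  cumulative energy and spectrum entropy). Grand-mean centering keeps a
  stack of identical frames exactly rank 1.
- Cepstral features: 13 MFCCs from 26 triangular mel filters and an
  orthonormal DCT-II; 13 GTCCs through the same path with a 26-channel
  gammatone bank (4th-order frequency-domain magnitude responses,
  ERB-spaced 50 Hz–8 kHz, bandwidth 1.019·ERB); 13 LPCCs by the standard
  LPC-to-cepstrum recursion; delta-MFCC means via `np.gradient` over
  frames. Silence is floored at 1e-10 before the log.

## Wrapper selection

The selection objective is f(p) = α·γ_p + β·|p|/N with defaults α = 0.8,
β = 0.01 and binarization threshold 0.5. The experimental settings are
followed for these defaults even though the surrounding text elsewhere
ties β to 1−α; both parameters are exposed. γ_p is the balanced error
(1 − UAR) of a sigmoid weighted ELM (50 hidden nodes, ridge 0.01, fixed
seed) under stratified 3-fold cross-validation with pooled predictions,
features z-scored per training fold. The wrapper classifier is
pluggable; fitness values are cached by mask, and a fixed configuration
seed makes every evaluation deterministic.

GEO moves continuous agents in [0, 1]^N: each agent picks a random prey
from the population memory (a random permutation gives a one-to-one
mapping), forms the attack vector V = prey − position, draws a cruise
vector W in the hyperplane orthogonal to V (free coordinates uniform in
[−1, 1], one pinned coordinate solved so V·W = 0 exactly), and steps by
r1∘(c_v V/|V|) + r2∘(c_w W/|W|) with linear schedules c_v: 0.5→2.0 and
c_w: 1.0→0.5 over the run (an exploration-to-exploitation ramp; the
formulation leaves the endpoints open). Positions binarize as bit = 1
iff position ≤ θ — the printed inequality direction is kept even though
it inverts the common convention — and memory updates only on
improvement, so the best-fitness trace is non-increasing.

SSA keeps one leader that samples around the food source with the
decaying factor r1 = 2·exp(−(4i/I)²) and chain followers that move to
the midpoint of themselves and their predecessor. The branch variable of
the leader update is drawn uniform in [0, 1] and branched at 0.5
(equivalent to a symmetric recentring). Binarization is bit = 1 iff
position > 0.5, with an empty mask repaired by setting the coordinate
nearest the threshold.

Refined SSA adds tent-chaotic-map initialization (Bernoulli-shift form
d ← 2d mod 1; degenerate seeds perturbed by 1e-6), stepped inertia
weights in the follower update (w = 0.8 while t/T ≤ 0.2, then 0.6,
inclusive threshold), and simulated-annealing acceptance of food-source
replacements (T0 = the initial population's fitness spread, geometric
cooling 0.95/iteration). A structural property worth knowing: with
w < 1 the follower chain contracts geometrically toward the origin
(follower j settles near w^j × leader), so deep followers explore very
small masks; combined with the annealed food acceptance this makes
single runs noisy. All selectors therefore support independent restarts
keeping the best-fitness mask (`runs`), mirroring the multiple-runs
protocol customary for these metaheuristics; the recovery experiments
use 1 run × 200 iterations for GEO, 3 × 200 for SSA and 10 × 400 for
refined SSA, with 15 agents throughout.

## ELM family

Targets are ±1 one-vs-all. The ridge solution is computed in whichever
branch is cheaper (N ≤ D dual, otherwise primal); the two are
algebraically identical and tested against each other to 1e-8. The
weighted variant multiplies sample rows by √u_i with u_i = 1/class
count — the symmetric equivalent, by the push-through identity, of
inserting the diagonal weight matrix into the solve as usually printed;
agreement with the asymmetric form is unit-tested on random weights.
Kernel WELM stores the training anchors and predicts from the kernel row
against them; the composited kernel blends an RBF on one feature view
with a polynomial kernel on a second view, μK_s + (1−μ)K_w with μ = 0.5
by default. For audio the views are split by feature-name prefix —
clip-aggregate/contextual descriptors (time, DWT, eigen) versus
spectral/cepstral ones — and are configurable. Activation is sigmoid;
hidden size defaults to 100 for standalone use and 50 inside wrappers
and ensembles; the ridge parameter is exposed (the conventional search
grid spans 10^-1..10^-10). Argmax ties break toward the lowest class
index.

## Boosting and the swarm-tuned ensembles

The multiclass boost initializes the sample distribution proportional to
1/class count (each class carries equal mass), folds the distribution
into the weak WELM's sample weights as U = diag(dist·N), and uses
α_t = ln((1−ε_t)/ε_t) + ln(C−1). The printed update multiplies correct
samples by exp(−α) and renormalizes, which is exactly the usual
mistake-up-weighting after normalization; it is implemented in that
printed form. Rounds stop early on a perfect learner (ε capped at 1e-10
for its vote weight) or one no better than chance (ε ≥ (C−1)/C); if no
round survives, a single unboosted learner is kept with a warning.
Prediction is the α-weighted vote. M defaults to 10 rounds.

FA-WELM and CSA-WELM tune the hidden layer: the decision vector is the
flattened D×d input-weight matrix plus D biases, bounded to [−1, 1], and
fitness is 1 − UAR on a stratified validation split of the training
data, with the output weights re-solved in closed form at every
evaluation. The tuned hidden parameters are then frozen and the Adaboost
loop re-solves only the output weights per round. Inner budgets default
to population 12 × 12 iterations — small because the landscape is cheap
to evaluate but high-dimensional, and because the closed-form solve does
most of the work.

The regression-style combiner for several fitted predictors normalizes
per-sample errors of the decision scores (±1 one-vs-all targets,
averaged over classes) by the worst error, computes each predictor's
total error under the running distribution, converts it through
β = ε/(1−ε) and c = ½·log(1/β), drops predictors with ε ≥ 0.5, updates
the distribution by β^(−ε_i) (renormalized), and fuses decision scores
with weights c_k/Σc.

## Continuous optimizers

Firefly: attractiveness β0·exp(−γr²) toward every brighter firefly plus
a random step α·(rand−0.5) scaled by the domain width; the brightest
firefly takes only the random step; α decays by 0.97 per iteration.
Defaults: population 20, β0 = 1, γ = 1/(mean pairwise initial
distance)², α = 0.2. The formulation gives no constants, so these follow
common firefly practice.

Capuchin search: leaders (first half of 45 agents) update velocity
v ← ρv + τz₁r₁(pbest − c) + τz₂r₂(F − c) with ρ = 0.7, z₁ = z₂ = 2 and
the decaying modulation τ = 2·exp(−21(t/T)²) (the printed exponent is
typographically ambiguous; this reading mirrors the salp factor). Each
leader is randomly relocated with probability Pr = 0.4; otherwise an
independent uniform draw selects the movement: jump (ε ≤ 0.2, including
the unassigned low range), leap (≤ 0.3), ground walk (< 0.5, including
the unassigned 0.3–0.4 range), swing (≤ 0.75) or climb. The jumping
angle is θ = (3π/2)·r — the 3π/2 range makes sin(2θ) span [−1, 1], which
is necessary for food-referenced moves to perturb coordinates in either
direction, and the angle is drawn per dimension since the update is
written per coordinate. The v²sin(2θ)/g terms are treated as
dimensionless per-coordinate magnitudes (their units do not reconcile
otherwise). Followers chain-average with their predecessor. Positions
clamp to bounds; the returned optimum is the best-so-far food source.

On the 5-D sphere benchmark both optimizers reach below 1e-2 within 100
iterations at their default populations (firefly 20, capuchin 45); the
test suite asserts this at three fixed seeds.

## Synthetic data

`make_clip` builds a harmonic stack (8 harmonics, 1/h amplitudes) at a
class-specific fundamental (110/180/260/340 Hz), frequency-modulated by
low-pass-filtered noise to emulate jitter (2%) and amplitude-modulated
for shimmer (5%), adds band-pass-filtered noise around a class-specific
formant (500/1000/1800/2800 Hz), applies a linear 10% attack then
exponential-decay envelope, and adds white noise at the target SNR
(20 dB default, RMS-based). A `separability` knob in (0, 1] shrinks the
class templates toward their common mean. The acoustic templates follow
the different-vibration-site rationale qualitatively; they make no
clinical claim, and passing tests on this corpus demonstrates the
machinery, not performance on real snores — real corpora have
within-class variability, recording-channel diversity and class overlap
that this generator deliberately omits.

`make_planted_table` draws i.i.d. standard-normal feature columns and
shifts, in each of 10 informative columns, a random non-trivial
bipartition of the 4 classes by exactly class_sep·σ (default 2). A
single informative column therefore separates only one class grouping
weakly; recovering low error requires most of the informative set, which
makes the table a meaningful test bed for wrapper selection: the
objective value improves monotonically with the number of informative
columns kept (measured 0.045 with all 10 versus ~0.10 with 7).

## Evaluation protocol

UAR — the unweighted mean of per-class recalls — is the headline metric
throughout; stratified 10-fold cross-validation is the default protocol,
with a train/validation split used internally by the swarm-tuned models.
Feature selection and feature scaling are fitted on each fold's training
split only; a canary test plants a column that encodes the labels on the
test rows only and asserts the per-fold selection is bit-identical to an
all-noise version of that column.

Problem sizes in the tests and the acceptance script — 200 clips of 1 s,
refined-SSA selection at 30 iterations inside the 10-fold pipeline, the
selector-recovery protocol above, inner firefly budgets of 12 × 12 — are
the package's chosen study conditions: large enough that every stage is
exercised end to end, small enough that the whole suite runs in minutes
on one CPU.

## Known limitations

- The refined SSA's follower contraction (see above) makes its
  single-run mask quality noisy on high-dimensional tables; restarts
  mitigate but do not eliminate this, and on some random tables fewer
  than 7 of 10 planted features suffice for the optimum, so
  informative-recovery counts fluctuate between 6 and 10.
- The gammatone bank is a frequency-domain magnitude approximation, not
  a time-domain filter implementation; for cepstral summary statistics
  the difference is immaterial, for fine temporal analysis it is not.
- Kernel ELM stores all training anchors; memory grows with the training
  set, as for any kernel method.
- No compressed-audio decoding, no streaming, and no attempt to model
  real airway physiology in the generator.
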