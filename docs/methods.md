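# Methods

This note documents the models implemented in `driftdecode`, the parameter
choices that matter, what the synthetic data generator does and does not
emulate, and the numerical decisions a maintainer should know about.

## Stimulus kinematics (`design`)

The double-drift stimulus is a Gabor (carrier 1 cycle/°, Gaussian envelope
SD 1°) whose envelope travels a vertical path of length 8° at roughly
10°/s, reversing at the endpoints, while the carrier drifts orthogonally at
6.66 Hz. Defaults (all degrees of visual angle, seconds):

| parameter | default | meaning |
|---|---|---|
| `path_length` | 8.0 | vertical extent of the envelope path |
| `traversal_duration` | 1.5 | one full up–down cycle (0.75 s per leg); 8 traversals tile a 12 s block |
| `internal_tf` | 6.66 | carrier drift rate, Hz |
| `eccentricity` | 10.5 | horizontal offset from the pursuit target (midpoint of the 9–12° range) |
| `smoothing_window` | 0.05 | raised-cosine velocity ramp at each endpoint |

Block timing is load-bearing for the GLM, so the 12 s block / 8-traversal
structure is exact and the peak speed is whatever the smoothed velocity
profile requires (`path_length/(leg − τ)` ≈ 11.4°/s on the plateau; the
nominal 10°/s, 8° and 750 ms per leg figures are not mutually consistent,
and timing wins). The endpoint smoothing duration is a modeling choice —
the velocity profile is only described as slightly smoothed — implemented
as a raised-cosine ramp so speed is zero exactly at the reversals.

Carrier drift direction is a signed unit rate that reverses at each
endpoint; its sign sequence defines the conditions (left illusion =
leftward during upward legs). The no-illusion control redraws the direction
at 60 Hz from a dedicated seeded stream, so blocks are reproducible and all
three conditions carry identical total carrier and envelope motion energy.
The local-motion controls reuse the illusion conditions' carrier sequences
with a stationary envelope and no pursuit.

**Perceived path.** Angle judgments are turned into trajectories by a
constant-angle accumulation model: lateral offset grows as
`tan(θ) ×` vertical distance travelled within a leg, with condition sign,
and unwinds on the return leg so the percept closes per cycle. This is a
deliberate simplification — the behavioral experiment yields a single angle
per subject, not a parametric percept model — and it reproduces the key
property that the rightward drift path has a higher, and the leftward path
a lower, time-averaged eccentricity than the veridical stimulus. Whether
the judged line was matched about the path midpoint or endpoint is
unknowable from an angle alone; the model treats the angle as the path
slope from the traversal start.

**Schedules.** Experiments 1/2: 288 s runs, four blocks of each of three
conditions, every 12 s stimulus block preceded by a 12 s fixation block,
order randomized without replacement per run. Experiments 3/4: three
blocks of each of four conditions, same interleaving. Localizers: fixed
14-cycle alternations (9 s on / 9 s off, 252 s). All onsets lie on the
1.5 s TR grid, and schedules tile their run exactly — the constructor
enforces this invariant.

## Synthetic data (`synthdata`)

The generator emulates exactly the statistical structure the analysis
assumes, with ground truth returned alongside:

- **Voxel populations.** Four ROIs (EVC 80, LO 50, V3A/B 50, hMT+ 40
  voxels — scaled-down but in realistic proportion, EVC largest). Half the
  voxels in each ROI respond to the visual stimulus (1% signal per block);
  an independently drawn half respond during pursuit (0.5%), emulating the
  diffuse pursuit response that extends beyond the stimulus
  representation. All condition effects live in stimulus-responsive
  voxels.
- **Condition effects.** `illusion_gain` (default 0.3% in the
  study-effects configuration) raises illusion-block amplitudes over the
  control; `attend_fixation=True` zeroes it in EVC, emulating the removal
  of stimulus-directed attention. `path_pattern_sd` (0.3% in hMT+ only)
  scales a fixed, seeded, zero-mean per-voxel map added to leftward and
  subtracted from rightward blocks — a multivoxel stand-in for the
  perceived-eccentricity difference between the two drift paths, without
  explicit retinotopy. The default `EffectConfig()` is the global null.
- **Forward model.** Per-voxel block amplitudes are multiplied by a
  ground-truth block HRF (canonical difference-of-gammas impulse response
  convolved with a 12 s boxcar, sampled at 16 points of 1.5 s, peak 1)
  placed at each block onset. Noise is AR(1) (stationary SD 1% per TR,
  coefficient 0.3) plus a sinusoidal drift (amplitude 1%, period 128 s —
  just below the 0.01 Hz high-pass cutoff, so the filter stage is
  exercised). Output is in raw scanner units around an ROI baseline;
  percent conversion is the pipeline's job.
- **Eye traces.** 1000 Hz. During pursuit the eye follows the target at
  `pursuit_gain` (0.95); Poisson catch-up saccades (2 Hz) eliminate the
  accumulated lag `(1 − gain) × target displacement since the last
  correction` as ~20 ms raised-cosine steps. Microsaccades (1 Hz during
  fixation, 0.1–0.6°, random direction, return step after 200 ms), blinks
  (0.1 Hz, 150 ms masked gaps — a mask channel, not sentinel values), and
  white tracker noise (0.02°) complete the model. `condition_bias` adds a
  horizontal offset during illusion blocks; it is zero by default, making
  left/right traces exchangeable, which is the null the eye-decoding
  control is calibrated against.

What the generator does **not** emulate: spatial noise correlations,
retinotopic receptive-field structure, motion artifacts, physiological
noise spectra, saccadic main-sequence dynamics, or session-to-session
nonstationarity. Passing tests therefore demonstrate that the analysis
code is correct and calibrated under its own assumptions — not that those
assumptions hold for any particular scanner dataset.

Sessions include 8 task runs (configurable, ≥2 for leave-one-run-out),
3 stimulus localizer runs and 2 pursuit localizer runs; 8 runs give the
typical n = 64 exemplars per pairwise decode (8 runs × 4 blocks × 2
conditions). All randomness derives from a single session seed via
`numpy` seed sequences.

## Preprocessing (`preprocess`)

Percent conversion is `(x/mean − 1)·100` per voxel (exactly zero temporal
mean). The 0.01 Hz high-pass is realized as projection removal of the
orthonormal DCT components below the cutoff (plus the constant) — a linear
operation with no edge transients, appropriate for 288 s runs where a
recursive filter's settling time would span a third of the run. Measured
as amplitude transfer, a 0.002 Hz probe loses > 99% of its amplitude while
the 18 s and 24 s task periodicities pass within 1%.

One consequence the casual reader should not miss: a high-passed time
series fit with *unfiltered* regressors gives biased amplitude estimates
(the filter removes signal components that project onto the block
regressors; the bias depends on the random block order and reached tens of
percent of a condition contrast in simulation). Both GLM stages therefore
project the same drift basis out of their design columns (run intercepts
excepted), which restores exact recovery on noiseless data whether or not
the data were filtered.

## Localizer analysis (`localizer`)

The cosine fit is the closed-form projection onto the sine/cosine pair at
the 18 s task period of the averaged, first-cycle-discarded series; each
voxel gets the correlation r between its series and the fitted cosine, and
the cosine's phase. Selection keeps voxels with r strictly above 0.2. The
optional phase window (default ±π/2) is centered on the *expected onset
phase*, computed as the Fourier phase of the canonical block HRF repeated
at the localizer period — not on a fixed scalar delay, which lands several
radians away from where a hemodynamically delayed block response actually
sits. The pursuit-control selection takes pursuit-localizer voxels minus
the stimulus-localizer selection, guaranteeing disjointness.

## GLM (`glm`)

Stage 1 groups trials into illusion vs control (the left/right distinction
enters only at the decoding stage), builds 16 lagged indicators per group
spanning 24 s, adds one intercept per run, concatenates runs, and solves by
pseudoinverse. Rank deficiency raises an error naming the collinear
groups. Stage 2 models each 12 s block by the single per-ROI HRF placed at
the block onset — not a boxcar convolution, because the deconvolved
response already characterizes a full block. The last block of each run
has its 24 s window truncated by the run end; the pseudoinverse handles
the shortened regressor. R² bookkeeping stores per-run residual and total
sums of squares so fold-restricted R² can be recomputed exactly during
cross-validation.

## Decoding (`decode`)

The classifier is the two-class pooled-diagonal-covariance Gaussian
(diagonal linear discriminant, equal priors); its decision score reduces
to `Σ_f (μ₀−μ₁)(x − (μ₀+μ₁)/2)/σ²`, verified in tests against direct
log-density evaluation. Strictness choices:

- Voxel selection (top 50th R² percentile, ties kept at the boundary) and
  z-scoring (ddof = 1) use training folds only; a config switch
  (`selection_scope="session"`) reproduces the permissive whole-session
  reading, which leaks test-run information and is off by default.
- Runs missing one class of the decoded pair are skipped as test folds
  with a warning; a training fold missing a class is an error.
- Permutations shuffle labels within each run, preserving per-run class
  counts; the entire cross-validation (including fold-wise selection) is
  re-run per permutation. p = (1 + #{null ≥ observed}) / (1 + n_perm);
  significance means exceeding the null's 95th percentile.
- Illusion decoding averages left-vs-control and right-vs-control
  accuracies; its permutation null permutes both pairs and re-averages, so
  the threshold refers to the same statistic as the observation.

## Eye analyses (`eyetrack`)

Blink gaps are linearly interpolated (boundary gaps extended from the
nearest valid sample), channels mean-centered per run, and nothing else —
no smoothing. Saccade detection follows the velocity-threshold approach:
5-point differentiation, per-channel thresholds at λ = 6 times a
median-based velocity SD, elliptic criterion, minimum duration 6 ms.
During pursuit, the known target profile is differentiated with the same
operator and subtracted, so detection runs on pursuit residuals and
perfect noiseless pursuit yields exactly zero events. Event amplitude is
measured with a 3-sample guard band around the supra-threshold interval to
compensate threshold trimming of the saccade's slow tails.

Traversal segmentation takes one traversal-length window (1.5 s = 1500
samples per channel) from the start of each of the six illusion blocks per
run, giving 6 exemplars/run and 48 across 8 runs; this reconciles the
6-per-run exemplar count with blocks that physically contain 8 traversals,
and `per_run` is exposed for other conventions. Fixation exemplars come
from the fixation block preceding each illusion block, labeled with the
upcoming condition (the fixation portion of that trial); local-motion
exemplars from the local-motion blocks. The eye decoder is a linear SVM
(C = 1) on features standardized within training folds, with the same
leave-one-run-out and within-run permutation scheme as the BOLD decoder.

The microsaccade ANOVA (illusion-vs-control × leftward/rightward) is
computed on per-subject mean amplitudes via ordinary least squares; within
a single simulated session the "subject" factor is the run. Count is
available as an alternative dependent variable.

## Staircase (`staircase`)

Transformed 1-up-2-down rule with a fixed additive step (default 0.05 on a
threshold of order 1): wrong → one step easier, two consecutive correct →
one step harder. At equilibrium P(two correct) = ½, so the procedure
converges at p* = 1/√2 ≈ 70.7% correct. The simulated observer is
logistic, `p(correct) = 1/(1 + e^{−slope·(level−θ)})`; threshold estimates
use the mean of the last six reversals, and the asymptotic percent correct
is measured over the final half of the run. The step size trades
convergence speed against oscillation amplitude; 0.05 keeps the
equilibrium bias of the fixed-step rule well under one percentage point at
slope 8.

## Calibration and problem sizes

The test suite and `scripts/acceptance.py` use simulation sizes chosen to
estimate each quantity to well inside its assertion width on one CPU:
30–100 null sessions for the chance level (each decode has a per-session
SD of ~6 percentage points; averaging sessions × 4 ROIs × 2 decoders puts
the standard error near half a point), 200 replicates with 200
permutations each for the type-I error of the permutation test (binomial
SD ≈ 1.5 points around 5%), 20 replicates for the null eye decoder, and
5 replicate sessions per attention mode (1000-permutation inference in the
worked example, 300 in the replicate battery) for the per-ROI effect
pattern, asserted by majority rule for injected effects and a binomial
false-positive allowance for nulls.

## Known limitations

- The percent-conversion mean division rescales amplitudes by
  `1/(1 + m̄/100)` where m̄ is the voxel's mean evoked signal; with ~1%
  responses this is a ~0.5% multiplicative bias on betas (and contrasts),
  invisible to decoding but present in absolute amplitude estimates.
- ROI labels are attached to synthetic voxels; there is no anatomy, no
  registration, and no spatial structure within an ROI.
- The permutation count (1000) bounds the smallest attainable p at
  ~0.001; reported p-values at that floor mean "below resolution".
- The eye simulator's saccades are kinematically simple (raised-cosine
  position steps); detection tests validate thresholds and counting, not
  main-sequence realism.
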