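# Methods

## The viewing-geometry model

When the eye both translates and rotates in a fronto-parallel plane, the
optic flow produced by the eye movement is a rigid rotation of the scene
about a *pivot* that sits between the eye and the fixation point. With the
pivot distance normalized by viewing distance, `p' = p/f`, two familiar
limits appear:

* `p' = 0` — pure eye rotation (R). The flow is depth-invariant and the
  natural computation is a coordinate transformation (CT): world-relative
  object velocity is the vector sum of retinal and eye velocity,
  `w_obj = w_ret + w_eye`.
* `p' = 1` — lateral translation with a compensatory counter-rotation
  about the fixation point (R+T). The flow is depth-dependent and the
  natural computation is depth from motion parallax (MP): for a stationary
  object, `d' = w_ret / w_eye` (the motion-pursuit ratio), with `d'` depth
  normalized by viewing distance (negative = near).

Both are special cases of one linear relation, applied to the horizontal
velocity component (all real/simulated pursuit here is horizontal):

    w_obj = w_ret + (1 - (1 + d') p') * w_eye

This relation is the package's canonical equation engine
(`pivotflow.geometry`). All velocities are in deg/s; screen x is
rightward-positive, y upward-positive; direction angles have up = 0 deg and
increase clockwise.

### A note on the depth-axis convention

The projection simulator (`simulate_flow_field`) is an independent
validation layer: it places a stationary dot cloud in 3D, moves a pinhole
camera along the rigid pivot trajectory, and finite-differences the
projections (default time step one display frame, 1/60 s). Deriving the
projected azimuthal flow analytically gives `flow = w_eye (p - rho) / rho`
for a dot at horizontal-plane distance `rho` from the eye. This matches the
linear engine *exactly* (on the horizontal meridian) when the engine's
depth variable is read as `d' = (f - rho) / rho` — an axis that runs
*toward* the observer, i.e., mirrored relative to metric depth (to first
order `d' = -(rho - f)/f`). `pivotflow.geometry.equation_depth` implements
this correspondence and is what tests use when comparing simulator output
with the engine. Off-meridian discrepancies are of order eccentricity
squared (the cos-azimuth projection factor); over a 20 deg field with
|d'| < 0.3 the ensemble relative L2 disagreement stays below 5% at every
pivot. Nothing downstream depends on the absolute depth-axis direction:
every analysis in the package rests on sign *pairings* (e.g., the
perceived-depth sign inverts when either the retinal or the eye velocity
sign flips), which are convention-independent.

### Stimulus kinematics

Object, background and fixation-target motion follow a Gaussian speed
profile spanning +/-3 sigma over the movement duration (sigma = T/6,
centered at T/2), renormalized after truncation so the discrete
time-integral equals the displacement exactly. For the study's object
displacement (2.67 deg over 1 s) this gives a peak speed of 6.41 deg/s
(the exact +/-3-sigma profile; peak/mean ratio 2.40). The pursuit-target
displacement is a free parameter; the default of 5.3 deg yields a mean
speed of 5.3 deg/s and a peak of ~12.7 deg/s, consistent with the
experiment's printed target speeds (its printed metric displacement is not
simultaneously consistent with those speeds at 57 cm, so the angular
displacement is the exposed knob).

## Observer model (`pivotflow.observer`)

Perception is modeled with two gains: `g_ret`, the fraction of horizontal
retinal motion parsed as motion parallax, and `g_eye`, the fraction of eye
velocity accounted for — both analogous to a flow-parsing gain. With a
geometry `p'` these induce the fitted weights `a_ret = g_ret p'` and
`a_eye = (1 - p') g_eye`:

    perceived w_obj_x = (1 - a_ret) w_ret_x + a_eye w_eye_x   (vertical passes through)
    perceived d'      = (g_ret w_ret_x) / (g_eye w_eye_x)

Real pursuit with gain `g_pursuit` is slip-corrected first:
`w~_eye = g_pursuit w_eye`, `w~_ret_x = w_ret_x + (1 - g_pursuit) w_eye_x`.
When the effective eye velocity is zero (the R percept) depth is an
explicit *ambiguous* state, not a number; synthetic observers then answer
from a prior bias (default 0.8 toward "near", matching the tendency of
observed R-condition behavior).

The mapping from perceived depth to a binary near/far report is a
Bernoulli draw through a cumulative-Gaussian link,
`P(far) = Phi(d'_hat / sigma_depth)`. The link and the von Mises
direction-report noise are modeling choices (the perceptual experiments
constrain only the resulting psychometric shapes); both are parameterized
so alternative noise models can be swapped in.

## Fitting (`pivotflow.behavior`)

* **Observer weights.** Mean cosine error between predicted and reported
  directions with an L1 penalty, `(1/N) sum (1 - cos(Th_hat - Th)) +
  alpha (|a_ret| + |a_eye|)`, weights bounded in [0,1] by a logistic
  reparameterization and minimized by multi-start Nelder-Mead (4 starts:
  one near the origin, the rest random). `alpha` is selected on a
  log-spaced grid (1e-4..1, 8 points) by 5-fold cross-validated cosine
  error with seed-controlled fold assignment; recovery-style analyses that
  need no sparsity selection pass a single-element grid. CIs are
  percentile bootstrap over trials (default 500 resamples).
* **Psychometric functions.** `psi(x) = gamma + (1 - lambda - gamma)
  Phi(C (x - m)/w)` with `C = Phi^-1(0.95) - Phi^-1(0.05) ~ 3.2897`, fit by
  maximum likelihood (L-BFGS-B; lapse and guess rates bounded in [0, 0.1]).
  Because far-rates may fall with direction, both orientations are fit and
  the better likelihood kept; the slope is the analytic derivative of the
  fitted function at `x = m` (units: probability per degree), signed by the
  orientation. Boundary cases (all responses identical) are flagged, with
  slope reported as 0. CIs by per-level bootstrap.
* **Pursuit gain.** Eye velocity by convolution with a
  first-derivative-of-Gaussian kernel (SD 25 ms); samples above 40 deg/s or
  300 deg/s^2 are dropped (not interpolated); pointwise median across
  traces; gain is the ratio of that median profile's peak to the target's
  peak velocity, with the target differentiated through the same kernel so
  the filter's slight peak attenuation cancels (a trace identical to the
  target scores exactly 1). Default sample rate 1000 Hz.
* **Fixation checks** use a configurable rectangular window around the
  (possibly moving) target with a configurable violation tolerance; both
  the online-style +/-5 deg and the analysis-style 10x10 deg windows are
  expressible.
* **Folding** (reflecting directions about the horizontal axis and
  mirroring rightward-eye trials) is provided for visualization only and is
  never applied before fitting.
* **Group statistics.** Two-sided Wilcoxon signed-rank (normal
  approximation; signed Z recovered from the tie-corrected p-value),
  Hodges-Lehmann estimate as the median of Walsh averages with the
  distribution-free order-statistic CI, effect size `r_W = Z / sqrt(n)`;
  Mann-Whitney U for independent samples; and a label-permutation test on
  |psychometric slope| differences for within-participant condition
  comparisons.

## Synthetic data (`pivotflow.synth`)

The generators emulate the study designs: the direction-estimation
experiment (13 retinal directions, -90..270 deg in 30 deg steps, 7
repetitions per direction and eye sign, R / R+T / no-background x Pursuit /
Fixation interleaved under a seeded shuffle) and the depth-discrimination
experiment (13 directions, -90..90 deg in 15 deg steps, 20 repetitions).
Stimulus speeds default to the mean speeds of the Gaussian profiles
(object 2.67, eye 5.3 deg/s). The default 10-observer cohort draws weights
around the observed group tendencies (R: a_eye ~ 0.4, a_ret ~ 0; R+T:
a_ret ~ 0.3, a_eye ~ 0.1; SD 0.1, clipped to [0,1]) so group statistics
are exercisable. Eye traces are gain-scaled target positions plus low-pass
positional noise and injected ~20 ms catch-up saccades (0.5-1.5 deg) that
exceed the 40 deg/s cleaning threshold. Synthetic neurons are Poisson
draws from the joint-tuning rate model on a velocity grid.

What the generators do *not* emulate: serial dependencies and learning
across trials, heterogeneous lapse behavior, fixational eye-movement
microstructure, smooth-pursuit latency/oscillation, and any correlation
structure between observers' motion and depth parameters. Passing
recovery tests therefore demonstrates the estimators are correct under the
model's own assumptions, not that real data satisfy those assumptions.

## Recurrent network (`pivotflow.rnn`)

Continuous-time leaky units, Euler-discretized (tau = 100 ms, dt = 10 ms,
64 units, three inputs, two linear outputs), trained with Adam (lr 1e-3)
on a masked L2 loss over the final 500 ms of 2-s trials (500 ms noise, 1 s
stimulus, 500 ms noise; iid Gaussian input noise, SD 0.5, on every channel
at every step). Geometries are mixed within each batch, and the targets
are the *ideal percepts the theory prescribes for each geometry* — the
network must infer the geometry (and the eye velocity) from the two
background-dot channels alone. In R trials the retinal and eye velocities
are sampled from U(-10, 10), both background channels carry the
depth-invariant flow `-w_eye`, and the targets are
(`w_ret + w_eye`, 0): full coordinate transformation, no depth signal.
In R+T trials the object is stationary in the world: with `d' ~ U(-1, 1)`
and `w_eye ~ U(-10, 10)` its retinal motion is pure parallax
`w_ret = d' w_eye`, the background channels carry `d'_near w_eye` and
`d'_far w_eye` (fixed symmetric dot depths -0.5/+0.5, so the channels are
opposite in sign), and the targets are (0, d'): the horizontal retinal
motion is explained away as depth. Sampling the bounded depth d' (rather
than using the unbounded raw ratio `w_ret / w_eye` as a target) keeps the
L2 objective well-posed.

Gradients are exact backpropagation through time written directly in NumPy
(verified against numerical differentiation to ~1e-7 relative error) — at
this network size explicit gradients are faster to run and fully
deterministic under a fixed seed. Initialization: Gaussian recurrent
weights at spectral radius ~1, zero biases. No recurrent/state noise is
used (input noise only); a noise hook is exposed for parity with common
RNN toolkits. The full-scale preset is 50,000 epochs at batch 128; the
default *scaled-down* configuration used by the tests and the acceptance
script is 5,000 epochs at batch 64 (~2 min per network on one CPU core).
At that scale the coordinate-transformation side of the task is essentially
solved (trained loss < 2% of the untrained loss; probe directions show the
horizontal bias in R and the vertical bias in R+T; unit tuning shifts are
strongly world-centered under R probing and not under R+T), but the
division-like depth computation emerges much later: the depth target is
uncorrelated with every input over the symmetric eye-velocity distribution
(gradient signal is second-order only), so robust eye-sign-inverted R+T
depth psychometrics belong to the full-scale run — at 20,000 epochs the
probe depth slope reaches only ~20% of ideal. Scaled-down results should
be read accordingly.

Behavioral probes replay the psychophysics (directions -90..90 deg step
12, retinal speed 2, eye speed 6, both eye signs and geometries, 20 noisy
repetitions): reported direction is the angle of (estimated horizontal
world velocity, veridical vertical component), the depth report is the
sign of the time-averaged depth output. Joint tuning maps run the
noise-free protocol over the 21x21 velocity grid (-10..10 step 1) and take
each unit's tanh activation at the final time point.

**Tuning-shift metric.** 2D FFT of the mean-subtracted map
(mean-subtraction keeps the DC peak from setting the threshold; the DC bin
cannot contribute to the metric either way), power thresholded at -10 dB
below the peak, then the normalized product of inertia
`100 sum(fx fy P) / sum(|fx fy| P)` over origin-centered frequencies. The
sign convention is calibrated so a ridge along the world-coordinate
(negative) diagonal — a unit tuned to `v_ret + v_eye` — scores +100; a
mirrored ridge scores -100; an exactly separable map scores 0. When all
surviving power lies on the frequency axes the structure is purely
separable and the metric returns 0; a genuinely flat map raises an
explicit undefined-shift error. Note the metric saturates at +/-100 for
pure sheared ridges, so against the fitted shift weight `w` of the neuron
model it is weakly (not strictly) monotone.

## Neuron model (`pivotflow.mt`)

Rate over signed horizontal retinal and eye velocities:
`A [g(v_eye) f(v_ret + w v_eye) + o(v_eye)]+ + B`, with a logistic
multiplicative gain `g` (g(0) = 1), a log-Gaussian speed by von Mises
direction tuning `f` (direction of a signed scalar velocity is +/-90 deg
by sign; the preferred direction phi is kept continuous though it is
effectively binary in 1D), and a bounded logistic additive term `o`
(o(0) = 0). Rectification precedes scaling by A, so the rate never falls
below the baseline B. Fitting minimizes the Poisson negative log
likelihood of per-cell pooled counts (a Poisson sum, with the trial count
as exposure) by multi-start L-BFGS-B (default 10 starts; the first start
is a neutral template at the observed mean rate). Bounds keep the terms
numerically stable (sigma >= 0.05, delta >= 0.01, |w| <= 1, |alpha|,
|beta| <= 1).

## Pipeline (`pivotflow.pipeline`, CLI `pivotflow`)

YAML configs with unknown-key rejection; stages run in dependency order;
every randomized stage gets a sub-seed spawned from the global seed via
`SeedSequence` and recorded, along with SHA-256 digests of all artifacts,
in a JSON run manifest, so deterministic stages are byte-reproducible.
Artifacts are text (CSV/JSON/YAML), including the RNN checkpoint.

## Problem sizes used by the test suite and acceptance script

Chosen to keep a full run on one CPU core within minutes while preserving
the study's design sizes where they matter: observer-weight recovery uses
100 datasets over the 5x5 weight grid at the experiment's trial counts
(13 directions x 7 reps x 2 eye signs, von Mises kappa = 20); psychometric
recovery uses 100 replicates at 20 trials per level; neuron-model recovery
uses 50 synthetic neurons on an 11x11 grid with 20 trials per cell;
network results use three seeds at the scaled-down training preset.

## Known limitations

* The linear engine is first-order in eccentricity and depth; the
  projection simulator is the reference for large fields.
* The depth-report link and direction-noise model are assumptions; only
  the psychometric shapes they induce are constrained by data.
* The scaled-down network preset demonstrates the qualitative phenomena;
  quantitative tuning-shift magnitudes are seed- and scale-dependent.
* Real recorded datasets can be ingested through the same CSV schemas, but
  all bundled results are computed on synthetic data.
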