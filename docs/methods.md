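# Methods

## The model

`afcontour` implements a generative model of visual contours, the matching
ideal-observer inference, and the statistical machinery used to compare such
observers with 2-AFC contour-detection decisions.

### Generative contour process

A contour of length L is a Markov chain of oriented edge elements. The first
edge gets a uniform position in its region and a uniform full-circle
direction; each following edge is drawn from the association field (AF), a
conditional link density over the relative coordinates of an ordered edge
pair:

* `d` — Euclidean distance (DVA),
* `phi` — viewing angle from the source edge's direction to the
  displacement towards the target,
* `dtheta` — direction difference.

The AF factorises as `f(d, phi, dtheta) = R(d) * A(phi, dtheta)` with

* `R(d) ∝ exp(-d/lambda)` truncated to `[0, d_max]` (default `d_max` is the
  field diagonal, 33.3 DVA; `lambda` defaults to 10 DVA),
* `A(phi, dtheta) = 2 * V4(dtheta - 2*phi; sigma_align) * V(dtheta; sigma_curv)`,

where `V(x; sigma)` is a von Mises density with concentration
`kappa = 1/sigma^2` and `V4(x; sigma)` is its half-angle analogue
`exp(kappa cos(x/2)) / (4 pi I0(kappa))` with `kappa = 4/sigma^2`. Both reduce
to Gaussians of width `sigma` in their argument for small `sigma`.

The two angular factors implement the two classic AF principles: link
probability decays (i) with the deviation of `dtheta` from the co-circular
continuation `2*phi` on scale `sigma_align`, and (ii) with the curvature
proxy `dtheta` itself on scale `sigma_curv`. Directions are full-circle
(0..2*pi), not orientations mod pi, so the creation process cannot turn
around by 180 degrees.

**Why the half-angle form.** A plain von Mises in `dtheta - 2*phi` is
pi-periodic in `phi` and therefore places a second, equal mode at
`phi = pi`: steps directly *behind* the source edge. A process with that
kernel folds over itself and does not produce contour-like stimuli, defeating
the purpose of the full-circle direction convention. The half-angle form has
a single forward co-circular mode, integrates to exactly 1 over
`(phi, dtheta) in (-pi, pi]^2`, and is exactly symmetric under reversal of
the edge pair (create the same contour backwards with the same probability)
— a property the test suite asserts to 1e-12 on random pairs.

**Sampling** is exact, not rejection-based: `dtheta`'s marginal under `A` is
von Mises; given `dtheta`, the half-deviation `(dtheta - 2*phi)/2` is von
Mises; `d` is a truncated exponential drawn by inverse CDF. Steps leaving
the region are resampled (never reflected, which would bias the angular
statistics), and a contour that runs into a wall with a concentrated kernel
is restarted from a fresh seed position.

### Hiding contours among distractors

A stimulus hides one contour in the left or right hemifield (split at
x = 0) of a 26.6 x 20 DVA field (maximum eccentricity 16.66 DVA). Alignment
must be the only cue, so first-order position cues are removed:

1. Background edges start on a jittered grid at the contour's density and
   relax as a hard-core (min separation 0.2 DVA, the scale of the rendered
   Gabor footprint) Brownian gas: per epoch every edge proposes a Gaussian
   move of 0.1 x spacing, rejected if it violates the hard core.
   Stationarity is declared when the mean nearest-neighbour (NN) distance
   drifts by < 1 % over consecutive epochs (a successive-epoch KS criterion
   is not usable here: two same-distribution samples of a few hundred NN
   values have typical KS ~ 0.1, so any small KS cut would never fire).
2. An outer loop then redraws the contour's step lengths from the measured
   background NN distribution G. Because an interior contour edge's NN is
   the *minimum* of its two adjacent steps, steps are drawn from the
   distribution H with `1 - H = (1 - G)^(1/2)` (empirical quantile
   transform), which makes that minimum exactly G-distributed; the two end
   steps use exponent 3/4 to split the residual bias between end edges and
   their neighbours. Background grid seeds are also excluded within
   0.4 x spacing of the path, since grid survivors otherwise crowd the path
   boundary.
3. A decoy path — contour positional statistics, uniformly random
   directions — is placed on the opposite hemifield and treated identically
   during matching, removing residual higher-order positional cues.

With the default profile (25 relaxation epochs, 2 matching passes), the
pooled per-ensemble KS statistics between the background-background,
background-contour and contour-contour NN distributions fall below 0.1, and
a classifier using only local density locates the contour at chance; the
acceptance suite verifies both. A `fast` profile (10 epochs, 1 pass) is
used for large simulation campaigns where distance matching is not the
quantity under test.

Masks redraw every direction uniformly at the same positions. Rendering
places a Gaussian-enveloped cosine grating (random phase) at each edge on a
raster reconstructing an 1152-pixel display spanning 26.6 DVA.

### Ideal and optimal observers

Inference inverts the generative process. For the edges of one hemifield,
the link matrix `Q[i, j] = f(e_i -> e_j)` and per-edge salience weights
`w(eps) = 1 - a * (eps/eps_max)^gamma` (eccentricity-dependent edge
visibility; `a = 0` gives the unweighted ideal observer, exactly) define the
iteration

    b(0) = w,   b(n) = diag(w) Q b(n-1),

whose n-th iterate accumulates the evidence of every (n+1)-element path by
one matrix multiplication. The hemifield evidence is
`sum_i b_i(L-1) / M_X`, with `M_X = N(N-1)...(N-L+1)` the count of ordered
contour configurations (the configuration-count normaliser; any
configuration-independent prior factors cancel in the 2-AFC comparison).
The response is the argmax hemifield; exact ties — which occur only for
deliberately symmetric stimuli — fall to a seeded fair coin.

The matrix iteration sums over all edge paths without immediate repetition
(the diagonal of Q is zero); paths revisiting an edge after two or more
steps are included, which is what makes the computation a matrix power. The
brute-force enumeration oracle mirrors that path set and agrees with the
iteration to 1e-10 relative; an optional `distinct=True` mode enumerates
pairwise-distinct tuples only, quantifying the (tiny, for L << N)
approximation gap.

**Iteration depth and SOA.** One matrix multiplication corresponds to the
time a signal needs to bridge the mean element distance `d_bar` at a
constant propagation speed `v`; the default `v = 13.9/200` DVA/ms pins the
largest stimulus-onset asynchrony (200 ms) to the full L-1 iterations when
`d_bar = 13.9/(L-1)`, 13.9 DVA being the mean contour extent of the default
design. Depth for an SOA t is `round(t*v/d_bar)` clamped to `[1, L-1]`.

**Directional symmetry.** The AF is intrinsically one-directional along a
contour (the reverse transition sees the partner at `phi ~ pi` and is
suppressed). `contour_likelihood_dynamics` exposes the resulting
prediction: with the native coupling, the final starting-edge likelihood
peaks at a contour *end* element; symmetrising the link matrix
(`Q <- (Q + Q^T)/2`, traversal-direction invariance) moves the peak to
*interior* elements. The acceptance suite checks both at >= 90 % of 100
simulated ensembles.

### Decision statistics

For two observers with `n_a`, `n_b` correct out of S shared trials, the
independence null distributes the two correct-sets uniformly: the
both-correct overlap m is hypergeometric(S, n_a, n_b) and the
identical-response count is `k = S - n_a - n_b + 2m` (both-correct and
both-wrong trials both yield identical 2-AFC responses). The excess
correlation is the mid-p value

    Phi = P(k' < k_obs) + 0.5 * P(k' = k_obs),

whose expectation under the null is exactly 1/2 — the continuity correction
makes that an identity, `E[Phi] = 1/2 - sum p^2/2 + sum p^2/2`. Degenerate
conditions (`n` equal to 0 or S) give a single-atom null and `Phi = 0.5`;
they are included, not skipped. The hypergeometric construction is verified
against exhaustive enumeration of all correct-set placements for every
`(S <= 8, n_a, n_b)`.

Panel-level quantities: `Phi_HH` (mean over unordered observer pairs and
conditions, with a per-pair matrix), `Phi_MH` (model against each observer),
leave-one-out majority-vote prototypes (a noise-reduced human benchmark;
even-vote ties fall to a seeded coin), a performance score `P_perf` (the
fraction of conditions where the model's correct count reaches the
observers' mean; ties count as reaching), and a shuffle threshold
`Phi_sig`: surrogates permute each observer's correctness pattern across
the stimuli of a condition and re-derive the left/right responses from the
true target sides, preserving per-observer per-condition correct counts
exactly while destroying stimulus-locked agreement.

### Model search

`ObserverGridSearch` scans a grid over `(sigma_align, sigma_curv, a, gamma)`
with `lambda` fixed. Each candidate decides every stimulus once (full
iteration depth); `Phi_MH` and `P_perf` come from that single pass.
Candidates with `P_perf < 0.5` (below the reference mean in more than half
the conditions) are inadmissible — the performance criterion is necessary
because high decision correlation alone does not imply human-level
performance; among admissible candidates the `Phi_MH` maximiser wins. The
pair geometry of each stimulus is cached once (distances plus the two
angular cosines), so a candidate evaluation is one exponential over the
cached arrays and L-1 mat-vec products.

### Synthetic observer panels

Human-like decision tables are emulated by a shared base model (the common
stimulus-dependent difficulty) plus independent symmetric decision noise:
each of M observers flips each base decision with lapse probability
`eta in [0, 0.5]`. `eta = 0` duplicates the base model; `eta = 0.5` is pure
noise with `Phi = 0.5`. Excess correlations among panel members come from
the base model's *errors*, so a panel probing `Phi > 0.5` must use a base
model that errs on a stimulus-dependent subset (e.g. mismatched AF
parameters or strong eccentricity scaling). An optional softmax mode grades
the flip probability by the log-evidence margin.

## Default design and parameter choices

* 6 AF jitter pairs x 7 spacing conditions = 42 ensembles, 48 stimuli each
  (2016 per session), targets balanced 24/24 left/right; SOAs
  {20, 30, 60, 100, 200} ms; maximum eccentricity 16.66 DVA.
* Spacings are geometric from 1.2 to 3.6 DVA; contour length
  `L = round(13.9/spacing) + 1` holds the extent approximately constant at
  13.9 DVA, giving lengths {13, 11, 9, 8, 7, 6, 5}.
* The six jitter pairs (degrees): (8, 8), (8, 25), (15, 15), (15, 35),
  (25, 25), (35, 45) — *reconstructions* spanning straight/aligned to
  curved/jittered; the originally used values, the radial constant, the
  Gabor sizes in DVA and the fitted optimal parameters are not recoverable
  from the available source text, so these defaults are labelled choices,
  all configurable.
* Radial sampling for an ensemble is restricted to (0.7, 1.3) x spacing so
  the mean step sits at the condition's nominal spacing (the full truncated
  exponential would be dominated by the 10-DVA decay constant).
* `min_separation = 0.2` DVA: about the rendered Gabor footprint; it is the
  hard core of the background gas and the overlap-repair threshold.

## What the synthetic data does and does not emulate

The generator reproduces the *structure* of the original design — ensemble
grid, trial counts, hemifield layout, distance-matched distractors, decoys
and masks — and the synthetic panels reproduce shared-difficulty-plus-noise
decision correlations. It does not emulate human perceptual front-ends
(contrast sensitivity, crowding, fixation jitter), sequential effects, or
criterion drifts; passing tests therefore validate the algorithms and their
statistical calibration, not claims about human vision. Human decision
tables in the documented CSV schema can be substituted anywhere a synthetic
table is used.

## Numerical choices and degenerate inputs

* Von Mises densities are evaluated through exponentially scaled Bessel
  functions, stable up to `kappa ~ 4e4` (`sigma ~ 0.01` rad).
* Coincident edge positions raise a degenerate-geometry error (the viewing
  angle is undefined); the link matrix names the offending pair.
* Angle wrapping is `(-pi, pi]` for relative angles, `[0, 2*pi)` for stored
  directions.
* Eccentricities beyond `eps_max` are clamped with a warning; salience
  weights are clipped into `(0, 1]`.
* Exact 2-AFC ties are broken by a seeded coin for determinism under a
  fixed seed.
* Rejection/permutation budgets: 1e5 step proposals per contour (with
  restart after 500 consecutive wall rejections), 2000 permutations for
  overlap repair; exhaustion raises errors carrying the attempt count.

## Problem sizes used by the test suite

Chosen so the full run stays comfortable on a single CPU: the
distance-matching check uses 20 default-profile ensembles x 48 stimuli with
a 200-stimulus density-classifier probe; matched-parameter optimality uses
2000 fast-profile trials across seven spacing conditions; parameter recovery
uses a 4x4x3x3 grid on 10 ensembles x 48 stimuli with a 5-observer,
15 %-lapse reference panel; the directionality check uses 100 ensembles x 4
stimuli. The inference oracle runs 50 random instances with N <= 8, L <= 4;
the null-distribution oracle enumerates every (S <= 8, n_a, n_b).

## Known limitations

* The exact published forms of the AF (and its parameter values) could not
  be recovered from the source text; the implementation follows the stated
  construction principles, and all calibration claims are verified
  internally rather than against published curves.
* The distance matching targets first-order (nearest-neighbour) statistics;
  higher-order spatial statistics are addressed only via the decoy path.
* The Brownian embedding is a finite relaxation, not an exact equilibrium
  sampler; its adequacy is asserted statistically (KS < 0.1 per ensemble),
  not analytically.
* `ObserverGridSearch` evaluates a full factorial grid; no refinement or
  interpolation between grid points is attempted.
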