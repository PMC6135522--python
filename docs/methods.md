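# Methods

This note records the models, parameter choices and numerical decisions
behind `flysoc`, and what the synthetic benchmarks do and do not
demonstrate about real recordings.

## Synthetic arena simulator

The simulator (`flysoc.simulate`) is the ground-truth generator for the
whole test suite. It emulates an infrared walking-arena recording: a
dark field (grey level 10) with one bright (255) filled ellipse per fly,
area ≈ 20 px at a 2.5:1 aspect ratio (semi-axes ≈ 4.0 × 1.6 px, body
length ≈ 8 px), 640×480 px frames at a nominal 30 fps. There is no
sensor noise by default; a Gaussian pixel-noise flag exists for
robustness experiments.

**Motion model.** Flies follow an Ornstein-Uhlenbeck-like heading walk:
per frame the heading receives Gaussian turning noise with standard
deviation `(1 − heading_persistence) · 2` rad (default persistence 0.9)
and the speed is drawn from N(1.0, 0.3) px/frame, truncated at zero;
walls reflect the heading. The field's recordings do not constrain
these values quantitatively, so they are free parameters chosen to give
smooth, bounded, plausibly fly-like paths: ~1 px/frame means a body
length per ~8 frames, comfortably resolvable at 30 fps. A soft
repulsion keeps unscripted flies ≥ ~1.6 body lengths apart (pushes
capped at 1.5 px/frame to preserve smoothness), so accidental occlusions
essentially never occur outside scripted episodes — occlusion load is an
experimental variable, not an uncontrolled nuisance.

**Scripted episodes.** Two episode types carry exact ground truth:

- *Touch*: the interactor is steered toward the interacted fly during a
  150-frame lead-in (standoff of ~1.5 body lengths until the last 15
  frames) and then placed exactly so that its head sits 0.6·r from the
  interacted fly's tail, where r is the touch radius (0.5 body lengths,
  ~4 px). The planted per-frame labels are therefore geometrically
  exact; the generator verifies the head-tail distance on every labelled
  frame and refuses to emit violating ground truth. The touch radius is
  the *definition* of synthetic touch: the real behaviour is defined by
  observation, not geometry, so classifier accuracies measured here are
  accuracies against this planted geometric definition.
- *Crossing*: the second fly holds its center within one body length of
  the first for the scripted duration, sweeping across the target's
  flank (within ±60° of the perpendicular to its heading) with minimum
  separation 0.45 body lengths mid-episode. This produces genuine
  merged components for several frames while avoiding near-total
  along-axis overlap, in which two 20-px bodies would be pixel-wise
  indistinguishable and identity would be unrecoverable in principle.

A single occupancy ledger (`random_episode_specs`) schedules episodes so
no fly serves two overlapping episodes (lead-ins included) and repeat
touches of the same ordered pair are ≥ 60 frames apart, keeping each
planted interaction a distinct maximal run.

**What the simulator does not emulate:** wing/leg kinematics, grooming
and other non-walking behaviours, illumination drift, shadows,
reflections, arena-edge artefacts, jumps and flight. Tests passing on
synthetic video therefore demonstrate the correctness of the algorithmic
machinery (count conservation, assignment optimality, rule semantics,
recovery under controlled occlusion), not robustness to those real-world
nuisances.

## Detection

Background = per-pixel temporal median of frames sampled every 20
frames. Foreground = |frame − background| above a threshold, by default
Otsu's threshold on the difference image (the recording setup's own
threshold is not recoverable; the value is configurable and logged).
Components are 8-connected — 4-connectivity severs thin 1–2 px body
parts at this scale — and components under 4 px are discarded as noise.
The typical single-fly area is the median blob area over frames whose
blob count equals N. Blobs with area > 1.5× typical are merged-blob
candidates; missing flies are distributed over candidates in proportion
to excess area. When blobs are missing but no candidate passes the area
test (deeply overlapped flies shrink the union area), the largest blobs
are duplicated anyway with a warning: count conservation outranks the
area heuristic. Excess blobs (debris, reflections) are dropped keeping
the N largest.

## Tracking

The assignment cost is the Euclidean distance between previous fly
centers and current blob centroids (no velocity extrapolation by
default; prediction is exposed as an option but off, since plain
distance is the simplest model that the benchmark videos support).
`scipy.optimize.linear_sum_assignment` solves the square problem
exactly; its optimality is continuously cross-checked in the tests
against exhaustive permutation enumeration at N ≤ 7.

Merged blobs are split with `sklearn.mixture.GaussianMixture`: full
covariances with `reg_covar = 0.25` px² (floors the pixel-lattice
quantization), at most 100 EM iterations, tolerance 1e-4, means
initialized at the previous centers of the flies assigned to the blob.
An EM run that empties a component is retried once from k-means++ and
then treated as an error. Tied and spherical covariances were evaluated
and are selectable (`TrackConfig.em_covariance`); full covariances
recover elongated overlapping bodies markedly better.

Head/tail disambiguation: per fly, the principal-axis sign is chosen by
the dot product with the velocity averaged over the trailing 5 frames;
below 0.2 px/frame the previous choice is retained (a standing fly does
not flip). The first frame is provisional. On synthetic video the
resulting head matches the generator's head for ≥ 95% of (fly, frame)
states after the first moving frames.

Videos that begin mid-occlusion are anchored at the first frame with N
separated blobs and tracked backwards from there; a video with no such
frame is rejected.

## Interaction detection

Feature vector (22 values) for interactor i, interacted j, frame t:
entries 1–11 are ‖head_i(t+τ) − tail_j(t+τ)‖ for τ = −5…5; entries
12–22 are ‖r(τ) − r(0)‖ with r(τ) = c_i(t+τ) − c_j(t+τ), i.e. the
interactor's displacement from its window-center position in a frame
translated to the interacted fly — the τ = 0 entry is identically 0.
Head-to-tail endpoints are the event's defining geometry;
center-to-center distances are available behind a switch.

The classifier is a `StandardScaler` + RBF-kernel `SVC` pipeline; C and
γ are selected by stratified 5-fold cross-validation over a small grid
(C ∈ {1, 10, 100}, γ ∈ {scale, 0.05}), seeded and deterministic.
Training data are balanced (default 1000 frames per class); negatives
are drawn preferentially from candidate-gated near-miss frames at least
10 frames away from any touch of that pair, so the decision boundary is
learned where it matters.

Scoring all N(N−1) ordered pairs per frame is wasteful (240 pairs at
N = 16); only pairs with head-tail distance ≤ 3 body lengths are scored.
The gate is validated in the tests: widening it to 6 body lengths
changes no positive classification on the fixtures.

Run/gap semantics: gaps shorter than 15 frames are merged *first*, then
runs shorter than 15 frames are dropped. Merge-then-threshold treats a
flickering classifier output as one sustained touch; the opposite order
would fragment it. Edge cases are pinned in the tests: a 14-frame run
yields nothing, 15 frames yield one interaction; two 15-frame runs
separated by 14 frames are one interaction, by 15 frames two.

## Network parameters

The count matrix is normalized by its maximum entry before any
parameter is computed; the raw-count total is exported alongside the
weighted total since figure-level usage of one or the other cannot be
distinguished. Degrees are binary edge counts; strengths sum
normalized weights. The clustering coefficient is Fagiolo's
weighted-directed form (cube-root weights; denominator
2[d_tot(d_tot−1) − 2d↔]; 0 where undefined). Betweenness and global
efficiency use shortest paths with edge length 1/weight (the Brain
Connectivity Toolbox convention), directed, with equal splitting among
tied shortest paths; betweenness is reported as the fraction of
(N−1)(N−2) ordered source-target pairs. Transitivity is the global
closed-to-total directed-triplet ratio on the binarized graph;
assortativity is the Pearson correlation of total binary degrees across
directed edges, reported as NaN (not 0) when the degree variance
vanishes. All nine parameters are verified against independent
definitional loops (including exhaustive path enumeration) on random
6-node digraphs to 1e-10; the oracle fixtures use power-of-two counts
so inverse weights are exact dyadic floats and shortest-path ties are
exact rather than tolerance-dependent.

Node relabeling by out-going activity sorts ascending by weighted
out-degree, ties by weighted in-degree then original index, and returns
the permutation applied.

## Average network construction

Matching minimizes ‖W₁ − P W₂ Pᵀ‖_F over permutations — an NP-hard
quadratic assignment problem — by graduated assignment: a
doubly-stochastic iterate updated by softassign (exponentiated
compatibility gradient Q = W₁MW₂ᵀ + W₁ᵀMW₂, then Sinkhorn row/column
balancing), iterated to a fixed point at each inverse temperature β,
with β annealed geometrically (β₀ = 0.5, rate 1.075) up to β_max = 200.
A ceiling of 200 is needed for the relaxation to sharpen enough to
discretize faithfully; stopping an order of magnitude earlier leaves M
soft and the projection noisy. The exponential is row-shifted before
exponentiation so high β cannot overflow or denormalize. The final M
is projected to the nearest permutation by maximum-weight bipartite
matching and polished by a deterministic 2-opt descent plus a short
iterated local search (60 internally-seeded 3-cycle kicks, each
followed by 2-opt, keeping the best). The identity permutation is
returned whenever it scores at least as well, so matching never
degrades the objective relative to no matching. On random pairs at
n ≤ 6 this attains the exhaustive optimum in ≥ 90% of cases and
recovers planted permutations at n = 8 exactly; exact QAP solving at
N = 16 is out of scope (the exhaustive oracle exists only for tests).

Averaging is the incremental running mean: M starts at the first
network (optionally the one with median total weight) and each
subsequent W_i is aligned to the *current mean* before absorption,
W_i° = R W_i Rᵀ, M ← ((i−1)/i)M + (1/i)W_i°. Conjugating by R (rather
than its inverse) is the orientation under which the aligned objective
can only improve on the unaligned one, and the implementation asserts
exactly that invariant at run time. The stored permutations allow the
batch mean to be recomputed and compared with the incremental result.
The order-dependence of the anchor is acknowledged: input order is
preserved, and the median-total anchor is available for symmetric
treatment.

## Statistics

Mann-Whitney U: midrank ties; exact enumeration when n₁+n₂ ≤ 12 with no
ties, otherwise the normal approximation with tie and continuity
corrections (delegated to `scipy.stats.mannwhitneyu` with the mode
forced accordingly; the exact path is cross-checked against full
permutation enumeration in the tests). Constant pooled data return
p = 1 with a warning.

Scheirer–Ray–Hare: all observations ranked jointly (midranks), two-way
sums of squares on the ranks, H = SS_effect / MS_total with
MS_total = SS_total/(N−1) (equal to N(N+1)/12 without ties,
tie-corrected otherwise), referred to χ² with the effect's df. A
complete crossed layout is required. With a single-level second factor
the first factor's H reduces exactly to the tie-corrected
Kruskal-Wallis statistic, which the tests assert; under the null the
interaction's type-I error at α = 0.05 is calibrated to [0.03, 0.07]
over 1000 simulations.

The correlation map defaults to Pearson coefficients (Spearman by
flag) with a p < 0.01 significance mask; zero-variance columns yield
NaN and are never flagged significant.

## Problem sizes used in the checks

The benchmark suite simulates: a 50-fly, 2,000-frame video with 25
scripted crossings for the constant-count result (one unbroken track
per animal, zero frames with a wrong count); twenty 16-fly, 1,800-frame
videos with 30 planted touches each for end-to-end network recovery
(≥ 95% of ordered adjacency cells correct, classifier trained once on a
separate labelled simulation); 200 assignment instances at N ≤ 7 and
100 matching pairs at n ≤ 6 against exhaustive oracles; 50 averaging
trials with k = 10 noisy permuted copies; and 1,000 null simulations
for the rank-test calibration. These sizes were chosen as the smallest
that exercise each claim convincingly.

## Known limitations

- Identity through deep occlusions is probabilistic: when two 20-px
  bodies overlap almost completely for many frames, no position-only
  tracker can recover identity; the simulator's crossings deliberately
  keep a minimal flank separation, and at high group densities or
  speeds occasional swaps remain possible (count conservation is exact
  regardless).
- The touch classifier is only as good as its labels; trained on the
  simulator's geometric definition it will not transfer to real
  annotated video without retraining.
- MP4/AVI containers require an ffmpeg-backed imageio plugin; the
  native interchange container is the multi-page TIFF stack.
- Appearance-based re-identification, pose, jumps and flight are out of
  scope.
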