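# Methods

## Problem setting

A navigator who has learned a maze can be modeled as carrying either

1. a **non-metric labeled graph**: places as vertices, corridors as
   edges, with independently stored local measurements — leg distances
   `d_ij` and turn angles `α_ijk` for every triplet of neighboring
   places, including backtracks `(i, j, i)` fixed at 180°; or
2. an **embedded graph**: 2D coordinates for the same vertices obtained
   by jointly reconciling all local measurements through stress
   minimization — a metric map that is systematically distorted
   wherever the measurements are mutually inconsistent.

In an ordinary Euclidean maze the two coincide. In a maze with
wormholes — instant teleports that also rotate the walker's heading by
90° without their noticing — the locally measured labels cannot all be
satisfied by any planar configuration, the embedding retains residual
stress, and the two models predict different shortcut directions. That
divergence is what the package measures.

## Egomotion model

Headings are degrees counterclockwise from east; turns are
counterclockwise-positive and normalized to (−180°, 180°]. A wormhole
is a directed pose-to-pose link lying on corridors: crossing the entry
point while moving along the entry heading instantly places the walker
at the exit pose. The walker experiences straight, uninterrupted travel
(no perceived turn, distance = entry approach + exit runout, "shortened
but not zero"), while their world heading silently jumps by the
wormhole's rotation. Reverse crossings are synthesized automatically
(swap entry/exit, flip headings, negate rotation), so edge distance
labels are symmetric by construction and backtracks through a wormhole
still measure exactly 180°. Consequence: dead-reckoning the egomotion
of a route through a wormhole no longer reproduces ground-truth
positions — the environment is non-Euclidean in exactly the sense that
matters for the models.

Graph labels are *measured by walking* (`traverse`), not copied from
geometry, so wormhole-adjacent labels automatically reflect the
experienced, inconsistent geometry. In the wormhole graph variant the
two control-only corners (ids 12 and 35) and their corridors are
dropped and each wormhole contributes one edge; the control variant
keeps all 42 corners and ignores wormholes.

## Stress function and optimization

For each labeled triplet the embedding residuals are
`u·w − d_ij d_jk cos α` and `u⊗w − d_ij d_jk sin α` with `u = x_j − x_i`
(into the pivot) and `w = x_k − x_j` (out of it). This sign convention
is forced by the backtrack requirement: with `i = k`,
`u·w = −|u|²` matches `d² cos 180°` exactly, so a backtrack contributes
zero stress at the correct edge length. The cross-product term carries
chirality: stress is invariant under rotations and translations but not
under reflection, so a consistent graph with at least one genuine turn
recovers its layout with the correct handedness.

Weights default to λ₁ = λ₂ = 1; both terms have the same units
(length²) and there is no evidence in this setting for weighting them
differently. Each restart draws initial coordinates uniformly from
(0, 20)², the conventional choice for maze-scale problems (the replica
spans roughly 15 units).

Minimization: L-BFGS-B with the analytic gradient (gradient tolerance
1e-8, ftol 1e-15, ≤ 5000 iterations), then a Gauss–Newton polish of
each solution (`scipy.optimize.least_squares` on the residual vector
with the analytic Jacobian, tolerances 1e-14). The polish is what
pushes consistent-graph minima from ~1e-10 to ~1e-25 stress, making
recovery checks (stress < 1e-6, Procrustes RMSD < 1e-3) robust rather
than marginal. A polished step is accepted only if it does not increase
the stress, so the final value never exceeds the initial one for any
restart.

Distinct local minima are identified greedily in ascending stress
order: a solution joins an existing minimum if its stress agrees within
1e-6·(1+stress) *and* its reflection-allowed rigid-superposition RMSD
is below 1e-4 of the mean edge length; otherwise it founds a new
minimum. Each reported minimum's representative is the member reached
from the earliest restart, which keeps reports bit-stable when two
restarts tie in stress to the last floating-point digit. Serialized
reports round floats to 10 significant digits for the same reason —
far below meaningful precision, far above numerical jitter.

Downstream analyses use the lowest-stress minimum by default;
`AnalysisConfig.embedding_index` selects any other, and every report
lists the full inventory (stress, basin hit counts) so all minima can
be evaluated.

## Predictions and the local reference frame

- Non-metric model: Dijkstra shortest path by distance labels
  (equal-cost ties broken lexicographically for reproducibility), then
  dead-reckoning vector addition of the labels along the path, seeded
  with the ground-truth orientation of the first path arm.
- Embedded model: straight line between embedded vertices, in the
  embedding's own (arbitrary) frame.
- Ground truth: straight line in the veridical layout.

Estimates and predictions are compared as angles relative to the
starting arm — the arm toward the shortest-path successor, which is the
same physical corridor for the data and both models; for the embedded
model the arm's orientation is taken in the embedding's frame. This
makes every error metric invariant to the embedding's gauge freedom.
Objects located mid-corridor snap to the nearest corner by default;
`object_placement="vertex"` instead splits the corridor and embeds the
object as an extra vertex.

## Statistics

- Angular deviation `AD = √(2(1−R))` (degrees), the standard circular
  spread measure; it is 0 iff the sample is perfectly concentrated and
  is bounded by √2 rad ≈ 81°.
- Rayleigh: `z = nR²`, p by the usual series approximation.
- Watson–Williams: circular one-way ANOVA on per-subject mean errors
  (two models of g groups → df (g−1, N−g); two 10-subject groups give
  df (1, 18), two 11-subject groups (1, 20)), with the concentration
  correction `1 + 3/(8κ̂)`; a warning is raised when κ̂ < 1, where the
  test's assumptions fray. Calibration is verified by simulation
  (type-I error 4.8% at nominal 5% over 2000 runs) and against a
  permutation oracle.
- Effect size: circular analogue of Cohen's d — shortest-arc mean
  difference over the (n−1)-weighted pooled angular deviation.
- Noise model: von Mises fitted by circular mean and the three-branch
  inverse-A(κ) approximation, κ capped at 1e4 (the cap applies to
  *estimation*; the generator treats κ = ∞ as exactly noiseless).
- BIC = k·ln(n) − 2·loglik with the plug-in maximized von Mises
  likelihood, n = number of estimates. Parameter counts: embedded map
  2|V| + 2 (40 navigation vertices → 82 for the replica); non-metric
  graph: one distance per edge + one angle per ordered through-triplet
  + 2 by default (backtrack angles are fixed at 180° and carry no
  freedom). Because independent angle labels could also be counted per
  unordered corner, the convention is configurable
  (`unordered_triplets` counts reversal pairs once); conclusions are
  insensitive to the choice because the non-metric count is far larger
  either way. A per-model (μ, κ) noise pair is fitted; a shared noise
  term is not currently offered.

## Synthetic data generator

The generator emulates the two study designs used for wormhole
shortcut experiments: 10 subjects × 4 object pairs × 2 directions (80
estimates) and 11 subjects × 8 starts × 3 targets (264 estimates).
Each estimate is a generative model's shortcut prediction (mapped to a
global angle through the ground-truth starting arm) plus von Mises
noise with concentration κ (default 4, i.e. an angular sd of ≈ 28.6°,
the order of spread reported for human shortcut estimates from
long-term memory). An optional per-subject von Mises bias
(`kappa_between`, off by default) makes within-subject spread exceed
between-subject spread, as real data show.

What the generator does *not* emulate: learning and exploration order,
distance errors, asymmetric or context-dependent biases, subject
dropout, or any trajectory beyond the initial direction. Passing the
recovery tests therefore shows the pipeline is unbiased and selects
correctly under its own noise assumptions — not that those assumptions
exhaust real human data.

### The wormhole replica maze

A fixed 42-corner environment (the seed argument is accepted for API
symmetry but does not alter it): an irregular corridor network — a
loose grid skeleton with varied corridor lengths and oblique junction
angles, sparsely looped like a hedge maze — with two wormholes whose
entry and exit corridors are constructed exactly perpendicular, so each
crossing imposes exactly ±90°. Corners 12 and 35 exist only in the
wormhole-free control variant; the wormhole variant has 40 navigation
vertices, 43 edges and 4 independent cycles.

The irregular, sparsely-looped geometry is a deliberate design choice:
in highly symmetric rectilinear layouts with dense bracing loops, the
stress landscape of the frustrated graph collapses to a single basin,
whereas irregular corridor networks — like real hedge mazes — support
multiple locally stable ways of absorbing the wormhole inconsistency.
The replica robustly yields two distinct minima (stress ≈ 207.9 and
215.8, basin shares ≈ 30%/70% across optimizer seeds), so analyses that
depend on the existence of competing embeddings can be exercised. The
absolute stress values are properties of this synthetic layout, not of
any original environment.

## Numerical choices and degenerate inputs

- Angle normalization uses the half-open interval (−180°, 180°];
  backtrack turns are set to exactly 180° rather than recomputed from
  headings, avoiding one-ulp sign flips across ±180°.
- Maze validation rejects zero-length and duplicate segments, dangling
  references and disconnected corridor networks, and checks that
  wormhole poses lie on corridors, aligned with them, with rotation
  equal to the entry→exit heading change (tolerance 1e-6).
- Rigid superposition is 2D Kabsch; with reflection disallowed the
  smaller singular direction is flipped when the optimal orthogonal map
  is improper.
- `R = 0` samples: the circular mean is flagged undefined (NaN), the
  angular deviation is still reported; Watson–Williams refuses groups
  with zero resultant.
- Problem sizes used by the bundled verification runs were chosen to
  make each check sharp but quick: 30-corner mazes and 100 restarts for
  recovery, 200 restarts for the replica's minima inventory, 2000
  simulations for test calibration, and the full 264-estimate design
  for pipeline recovery.

## Known limitations

- Only 2D embeddings; no coordinates for non-vertex locations beyond
  the optional object-vertex insertion; no incremental re-embedding as
  labels accumulate.
- The shortest-path model scores only the initial shortcut direction,
  not walked trajectories.
- The deposited-data adapter is column-map driven and deliberately
  refuses to guess angle conventions; converting ground-truth-relative
  angles requires the maze.
- Stress values of distinct local minima can in principle tie while the
  configurations differ; deduplication then relies on the Procrustes
  test, which is why both conditions are required.
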