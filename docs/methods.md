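# Methods

## Coordinate frames and gaze geometry

Two frames are fixed throughout. The **local** (eye-tracker) frame is
right-handed with z pointing forward, x to the wearer's left and y up.
The **world** frame is left-handed with x forward, y to the right and z
up; lengths are unreal units (uu), 1 uu = 1 cm. For a normalized local
gaze g = (x, y, z),

    yaw   = -arccos(z / sqrt(x² + z²)) · 180/π · sgn(x)
    pitch =  arccos(sqrt(x² + z²) / ‖g‖) · 180/π · sgn(y)

with sgn(0) := +1 and yaw := 0 when x = z = 0 (purely vertical gaze —
any yaw is geometrically equivalent there, so the convention is
harmless and deterministic). Yaw lies in [−180°, 180°], pitch in
[−90°, 90°]; an arccos times a sign cannot leave the latter range, so
the implementation enforces it.

`rotate_forward` applies yaw about the head's up axis and pitch about
the post-yaw right axis. In the head basis (f, r, u) this is the closed
form

    f_rotated = cosP·cosY·f + cosP·sinY·r + sinP·u,

which makes the central identity exact rather than approximate: for an
identity head pose, `rotate_forward(identity, gaze_angles(g))` equals
the direct frame conversion (x, y, z) → (z, −x, y). The leading minus
sign and the signum in the yaw formula are precisely what carries the
handedness change between the two frames. This composition matches an
engine-style rotate-vector call whenever head roll is zero (the seated
scenario the defaults emulate); under head roll the yaw axis here
remains the head's own up axis, which is the documented choice.

The gaze ray is `origin = head position`, `endpoint = origin +
f_rotated · k` with k = 25000 uu by default; since casting stops at the
first hit, k only needs to exceed any plausible gaze distance.

## Ray casting

Scenes are ordered lists of named spheres and axis-aligned boxes —
enough to stand in for classroom OOIs; triangle meshes are out of
scope. Sphere hits solve the quadratic |o + t·d − c|² = r²; boxes use
the slab method. The first hit is the minimal strictly positive
distance ≤ k among *collidable* objects; non-collidable objects are
transparent (the software analogue of disabling a hidden object's
collider). Exact distance ties are broken by scene declaration order,
which is deterministic and documented. A ray starting inside an object
hits its exit surface. The test suite checks the caster against an
independent oracle (polynomial-root spheres, face-plane boxes, explicit
minimum) on 1,000 randomized scenes.

## Cleaning and transition extraction

Cleaning drops rows where any configured validity column (default: the
two pupil diameters) equals the placeholder (default −1) or is missing,
then reduces the log to timestamp + gaze target (+ requested
passthrough columns). Unsorted or duplicate timestamps are hard errors
naming the offending row — durations computed from such a log would be
meaningless, and silently merging duplicates would hide a logging bug.

Transition extraction first restricts the log to samples on analysis
OOIs. Each consecutive pair with differing targets yields one
transition: t_start is the time of the last sample on the source (the
earlier endpoint, consistent with how the duration is defined), the
duration is the time gap to the first sample on the target. Samples on
non-analysis objects and dropped invalid samples are *not* endpoints
but do consume time inside a transition; the max-duration filter
(default 1000 ms — a generous saccade-plus-blink allowance; the value
is configurable and recorded in every artifact) is the sole mechanism
excluding such indirect shifts. No gaze-target interpolation and no
fixation/saccade event detection are performed anywhere; the method
deliberately operates on the raw label sequence.

## Networks

Transitions are counted per (source, target) into a directed graph with
integer weights ≥ 1; zero-count pairs are absent, self-loops impossible
by construction, and the total weight always equals the retained
transition count (asserted end to end). Supplying a node roster keeps
never-gazed OOIs as isolated nodes so structural variables are
comparable across participants; this is the default in the pipeline.
The undirected conversion sums reciprocal weights — the only merge rule
under which undirected strength equals total transition involvement.
Storage is an edge-list CSV (sorted, byte-stable) with a JSON sidecar
for the roster and parameters, plus GraphML for interchange; a binary
graph pickle would be smaller but not inspectable or cross-language.

## Structural variables

* **Strength**: weighted in-degree + out-degree. Group strength is by
  default the literal sum of member strengths, so within-group edges
  count twice; `exclude_internal=True` counts only boundary edges once.
  Both are reported because the naive sum is the straightforward
  reading of "sum the centralities" while the boundary variant answers
  a different (between-groups) question.
* **Weighted degree centrality (WDC)**: on the *ascending*-sorted
  outgoing weights w₁ ≤ … ≤ w_DC, with Fc(i) the cumulative weight
  fraction, WDC = 1 + 2·Σ_{i=1}^{DC−1} Fc(i). This is a Lorenz-curve
  area statistic: WDC ∈ [1, DC], equal to DC iff the weights are
  uniform, invariant to rescaling and to input order (the sort is
  internal). Ascending order is required — descending would invert the
  scale so that uniform profiles no longer attain the maximum.
* **Uniformity** U: the negated chi-square statistic of all directed
  edge weights against a uniform expectation (the mean weight),
  computed via `scipy.stats.chisquare`. Only edges present in the graph
  enter; absent OOI pairs are not zero-count categories (a zero
  expected count would be undefined, and the statistic is meant to
  describe the weights the participant actually produced). U ≤ 0, with
  0 iff all weights are equal.
* **Cut size**: total weight of edges crossing a two-set node
  partition, *both directions counted* — the quantity answers "how
  often did gaze move between these two sets". The normalized variant
  divides by the total edge weight of the network, giving a fraction in
  [0, 1]. Note this deliberately differs from the volume-based
  `networkx.normalized_cut_size` of spectral partitioning.
* **Maximal cliques** are enumerated on the undirected conversion
  (directed input raises, pointing at `to_undirected`) over
  positive-weight edges via `networkx.find_cliques`, with a canonical
  sort for determinism. Isolated nodes are singleton maximal cliques by
  the mathematical definition; because counting them is a modelling
  choice, `clique_stats` reports both the all-clique and the
  size-≥ 2 summaries explicitly.

All metrics are pure functions of the network and reproduce
bit-identically across runs.

## Synthetic sessions

The generator emulates a seated lecture recording: a first-order Markov
chain over the OOIs (row-stochastic, zero diagonal — attention always
moves) picks the attended object, dwell times are truncated normal
(lower bound one frame at 25 ms; simple, positive, two parameters — not
claimed to match human dwell distributions), and frames are emitted at
40 fps, fixed-rate by default (a 15-minute session is exactly 36,000
rows; 2,400 per minute). A jittered mode (half-period plus exponential
intervals averaging 25 ms) is available for realism where exact counts
are not needed. Per frame, the direction from the head to the attended
OOI's center is tilted by independent Gaussian angles (default sd 1°,
a typical consumer-HMD eye-tracker accuracy) about two orthogonal axes,
converted into the local eye-tracker frame given the head pose, and
logged with pupil diameters (N(3.5 mm, 0.3 mm)). With probability
`invalid_rate` (default 0.05) the pupil fields are set to −1; the gaze
geometry is still logged, as a real ray-casting pipeline reports a
target whenever head tracking is valid. The head is fixed by default;
a follow mode lets head yaw lazily track the attended object's azimuth.

Everything is a pure function of (config, seed). What the simulator
does **not** model — saccade kinematics, smooth pursuit, vergence,
blinks as pupil artifacts, moving OOIs — bounds what passing tests
show: they verify the processing chain, not human gaze realism.

The default classroom scene (board, teacher, four peers; coordinates in
cm with the viewer near the origin) intentionally places the teacher in
front of the board so that noisy rays near the teacher's edge can hit
the board behind — occlusion is part of the geometry being tested. The
`separated_scene` helper instead fans well-separated spheres so that
label flips are essentially impossible; the Markov parameter-recovery
study uses it with 3 OOIs over 30 simulated minutes (~2,100
transitions), recovering each row of the transition matrix within
total-variation distance 0.05.

## Pipeline

The batch runner processes each participant independently through
staged files (cleaned CSV → transition CSV → edge list/GraphML →
metrics JSON), logging row counts in and out of every stage and all
thresholds. Two audits are enforced, not just logged: raw rows =
cleaned + dropped, and row counts shrink monotonically through the
stages. One participant's failure is recorded in the summary and does
not abort the batch. Re-running with identical config and inputs
produces byte-identical artifacts; all randomness (simulation, plot
layout fallback) flows from explicit seeds.

## Problem sizes in tests

The test suite uses 1,000 random scenes for the ray-caster oracle, 500
random graphs (≤ 8 nodes) for the clique oracle, 10,000 random profiles
for WDC bounds, 1,000 random partitions for cut conservation, and one
30-minute simulated session for parameter recovery — sizes at which the
whole suite completes in well under a minute while leaving the
stochastic checks statistically meaningful.
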