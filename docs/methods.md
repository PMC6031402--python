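# Methods

## Tissue geometry

Basal keratinocytes are modeled as the Voronoi cells of `n_kcs` points
drawn uniformly in a square of side `side_length` (defaults 4000 and
635 µm). The diagram is clipped to the square with the mirror construction
(reflecting the generators across all four sides), which makes every cell
bounded with boundaries lying exactly on the square, so the polygon areas
sum to the square's area to machine precision. Voronoi vertices closer than
1e-9·side are merged into single graph nodes; optional Lloyd relaxation
iterations (`lloyd_iterations`, default 0) regularize the cell-size
distribution. The square is a hard wall: boundary nodes simply have fewer
neighbors, and there is no periodic wrapping, matching a bounded imaging
field of view. Keratinocytes neither move nor divide during a run — the
3 h window is short relative to their cycle.

Melanoblasts live on the polygon vertices (nodes) and hop along polygon
edges. At the default scale the graph has ~8000 nodes of degree ≤ 3 and a
mean edge length of ~6.8 µm, so one 9-minute step corresponds to
~0.75 µm/min for a cell that moves every step.

## Potential dynamics

Every keratinocyte carries a scalar attraction potential Ψ ∈ [0, Ψ_max],
interpreted as the local concentration of secreted attractant. The time
course is the simplest shape consistent with rise-to-threshold/decay-on-
contact behavior: a linear ramp with saturation while free
(Ψ ← min(Ψ + C_f, Ψ_max)) and a linear decay with floor while bound
(Ψ ← max(Ψ − C_b, 0)). A keratinocyte is bound exactly while at least one
melanoblast occupies one of its vertices, and reverts to free (Ψ resumes
rising) the step the cell leaves. Ψ starts at 0 everywhere; with C_f = 0.1
the free cells saturate over the 10 warm-up steps, which is precisely what
the warm-up is for.

Per-cell thresholds are Ψ_max = Ψ_base + α·(perimeter − mean perimeter),
clipped below at 0.1·Ψ_base (defaults Ψ_base = 1, α = 0.01 /µm). The
perimeter term encodes the cell-cycle/size dependence of attractant
production and is frozen for the whole run.

The nodal attraction is the mean Ψ of the polygons meeting at a node.
Protrusion sensing aggregates these nodal values around a candidate node as
a distance-discounted average: weight 1 for the candidate itself and a
total weight γ = 0.5 spread over its graph neighbors (sensing depth 2, the
wild-type default). Depth 1 — the candidate's own attraction only — models
short-protrusion (Rac1-deficient) cells. Anisotropy, when configured, adds
w_D·(1 + cos θ)/2 for the angle θ between the hop displacement and the
favored unit direction; it is off (w_D = 0) by default.

## Repulsion trail

Each node remembers the age k (in steps) since a melanoblast last occupied
it; the trail potential is ρᵏ for k up to a horizon and 0 beyond, entering
the total potential with weight −w_R. Both the vacated and the newly
occupied node are stamped at age 0 each step, so a currently occupied node
always carries trail value 1. The horizon defaults to round(60 /
step_minutes) = 7 steps — 60 min being the observed memory span of the
avoidance effect.

With the trail *disabled* the repulsion term degenerates to the memoryless
form: only currently occupied nodes repel (0/1 by occupancy). Since node
exclusion already forbids moving onto an occupied node, the memoryless
repulsion does not change any choice among free candidates; this is
deliberate, so that "no trail" isolates exactly the memory contribution.
An earlier variant that also penalized just-vacated nodes is a one-step
memory in disguise and suppressed crossings artificially.

## Move rule

Once per step, in a fresh random permutation (which makes the stated node
exclusion structurally impossible to violate), each melanoblast:

1. stays with probability 1 − P (P drawn once per cell, uniform in
   [P_min, 1], default P_min = 0.5 — this is what spreads the cell speeds);
2. otherwise, in the random variants, hops to a uniformly chosen free
   neighbor (`totally_random` always; `partially_random` with probability
   `random_p`, falling through to the deterministic rule otherwise);
3. otherwise hops to the free neighbor with the highest total potential,
   ties broken uniformly at random, staying put only when the current
   node's sensed attraction strictly exceeds every candidate's score. The
   current node is scored by attraction alone: its trail value is the
   cell's own presence, and the anisotropy term needs a displacement.

`totally_random` is implemented as `partially_random` with random_p = 1 on
the same RNG stream, so the variant reduction is exact, not just
distributional.

## Parameter defaults and their provenance

| parameter | default | units | rationale |
| --- | --- | --- | --- |
| side_length | 635 | µm | imaging field |
| n_kcs | 4000 | – | keratinocyte count in the field |
| n_mbs | 157 | – | wild-type melanoblast count |
| warm-up / recorded steps | 10 / 20 | steps | four-phase protocol |
| step_minutes | 9 | min | 3 h over 20 steps |
| Ψ_base, α | 1.0, 0.01 | –, /µm | scale fixed to 1; mild size modulation |
| C_f | 0.1 | /step | free Kcs saturate during warm-up |
| C_b | 0.16 | /step | calibrated (see below) |
| w_R | 0.5 | – | calibrated (see below) |
| ρ, horizon | 0.65, 7 | –, steps | 60 min memory; ρ calibrated |
| γ | 0.5 | – | nearer protrusion signal dominates |
| P_min | 0.5 | – | speed spread ~30% of the mean |
| sensing depth | 2 (1 for Rac1-like) | Kcs | protrusion reach |

The exact values of the potential parameters are not observable, and the
modeling protocol this package implements prescribes calibrating them so
that simulated and tracked trajectories match. Two were calibrated once, at
full scale, against the two published crossing counts (31 crossings among
157 cells without trail memory; 12 among 170 cells with it, both in a 1 h
window): C_b = 0.16 sets the depth of the attractant depletion footprint a
moving cell leaves behind — the dominant control of how strongly cells
avoid each other *without* any trail term — and w_R = 0.5 with ρ = 0.65 sets
the strength/persistence of the trail avoidance. After calibration all
defaults are frozen; multi-batch means land at ~30 and ~11
crossings respectively (a ×2.5–3 reduction). The crossing counts are fully
emergent — nothing in the code stores or targets them at run time.

## Speed calibration

`calibrate(config, target_mean_speed, target_speed_sd)` exploits the fact
that the *coefficient of variation* of per-cell mean speeds depends only on
the move-probability distribution: it bisects P_min until the simulated CV
matches the target, refines with a secant step through the sampled
(P_min, CV) curve, then fixes the physical step duration as (mean simulated
step displacement) / (target mean speed). For P_min = 1 this reduces to
step_minutes = mean edge length / target speed. If the requested spread is
outside the attainable range the nearest endpoint is returned flagged
`attained=False`. `step_minutes_for(180, 20) = 9` gives the canonical
3 h / 20-step conversion.

## Trajectory analysis

**Metrics.** Total path length, Euclidean start–end distance,
directionality = Euclidean/total (undefined, reported as NaN and excluded,
for a stationary cell) and mean speed = total / elapsed time.

**Shape basis.** Trajectories of equal length are start-anchored
(first position subtracted) and written as complex sequences
z_t = x_t + i·y_t. The orthonormal basis of "basic trajectories" is the set
of right singular vectors of the stacked complex matrix — the
least-squares-optimal rank-k approximation for every k. Multiplying a basic
trajectory by a complex coefficient rotates and dilates it, so the mean
coefficient moduli are rotation-invariant descriptors of shape; components
are ordered by decreasing mean modulus, and the log-spectrum slope over the
first 8 components summarizes smoothness (random walks decay slowly,
potential-driven paths quickly). Foreign sets (e.g. simulated trajectories
in an experimental basis) are expanded by orthonormal projection.
Unequal-length experimental tracks are truncated to the common grid by the
importer; tracks shorter than a configurable minimum are dropped.

**Crossings.** A crossing is a geometric intersection between segments of
two *different* cells whose time indices differ by at most `window_steps`
(default round(60/step_minutes) = 7 — the second cell must traverse where
the first passed within about an hour). Intersections are detected with
exact orientation predicates (parallel, collinear-overlap and degenerate
point-segment cases handled explicitly; a collinear overlap contributes its
midpoint). Because several segment pairs can touch the same polygon vertex,
the representative intersection points of each cell pair are single-linkage
clustered at 1e-6 µm and each cluster counts once. The count is symmetric
in the pair order and invariant under rigid motions of the whole set. The
test suite checks it exactly against an exhaustive shapely-based
O(n²T²) oracle.

**Comparison.** `compare_sets` reports per-metric mean ± s.d. and
two-sided Mann–Whitney U p-values (degenerate all-tied samples return
p = 1 with a warning), both coefficient spectra in the basis of the first
set, and both crossing counts.

## Synthetic data

`generate_fixture` emulates manual-tracking exports: 36 frames at 5-minute
intervals (3 h) for ~155 cells in a 635 µm field, with per-cell speeds
drawn from a clipped normal (0.45 ± 0.15 µm/min — realistic embryonic
melanoblast motility). Motion models: `straight` (constant velocity, runs
shortened to stay in the field), `random_walk` (isotropic fixed-length
steps, reflecting walls), `biased_walk` (70% drift + 30% isotropic noise)
and `from_simulator` (a full simulation linearly resampled onto the frame
grid). The generator reproduces the *sampling structure* of tracking data,
not its imperfections: no localization noise by default (configurable
`noise_sd`), no track loss or gaps, no mitosis. A green comparison against
a fixture therefore establishes correctness of the pipeline, not biological
fidelity of the fixture.

## Numerical choices and limitations

- Sequential (randomly permuted) agent updates guarantee exclusion but make
  cell moves order-dependent within a step; all order randomness flows from
  the single run seed, and runs are bit-reproducible given (config, seed).
- Ties in the argmax are broken uniformly; score ties are detected at
  1e-12.
- The Voronoi mirror construction assumes generators strictly inside the
  square; duplicate generators are jittered by 1e-6·side rather than
  rejected.
- Trail stamping and potential stepping happen after all cells have moved,
  so within a step every cell sees the same field.
- The model does not represent cell morphology or forces, keratinocyte
  motion or division, melanoblast division/apoptosis, or 3-D tissue
  structure; the potential is an abstract attractant density, not a
  diffusion PDE.
- Crossing counts at full scale have a seed-to-seed s.d. of ~5–10; single
  runs are indicative only, and all headline numbers are 20-seed means.
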