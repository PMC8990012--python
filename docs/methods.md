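# Methods

This note records the model, its parameters, the numerical choices made
where the design was genuinely open, what the synthetic data does and does
not emulate, and the known limitations.

## Terrain representation

A map is three co-registered rasters over the same square grid: elevation
(m), a boolean linear-feature layer, and a boolean inaccessible layer.  The
reference geometry is a 20 km × 20 km region at 3000 × 3000 cells, i.e.
6.67 m cells, with the IPP at the central cell.  Positions are (x = column,
y = row), x increasing east, y increasing north, 0-based.

Structural features (trails, roads, railroads, powerline easements, stream
center-lines) are rasterized from polylines with Bresenham walks, giving
8-connected chains that match the agent's 8-neighbor motion.  Segment
endpoints are put in a canonical order before drawing so the mask is
independent of traversal direction.  Water polygons are split by a 3×3
binary erosion into an inaccessible interior and a one-cell shoreline ring;
the shoreline joins the feature layer.  When the two layers collide (a
stream crossing a lake interior), inaccessibility wins, keeping the layers
disjoint.

Elevation-derived features (ridge crests, drainages) are Canny edges of the
smoothed gradient magnitude.  The gradient is computed with
derivative-of-Gaussian filters at sigma = 3 cells and the magnitude smoothed
at the same scale; hysteresis thresholds default to the 70th/90th
percentiles of the magnitude field so the detector adapts to relief
amplitude rather than absolute units.  These three values are configuration
parameters, not calibrated constants.  Two consequences of this pipeline
are worth knowing: the smoothing pass partially fills the magnitude minimum
at a summit (the "zero at the peak" is a pronounced minimum, not an exact
zero), and a crest line is detected as the flanks of the magnitude dip
rather than a single center line.

Steep slopes are *not* marked inaccessible; only water interiors are.

## Agent dynamics

State is a continuous position pair (x(t), x(t−1)), a rounded grid cell,
and a heading in one of 8 compass sectors.  Initialization places x(1) at
the IPP and draws x(2) uniformly from the accessible 8-neighborhood; the
initial velocity is their difference.  Each step draws a strategy from the
behavioral profile, builds a provisional cell on the 3×3 body-frame grid
aligned with the heading, and applies the smoothing update

    x(t+1) = (2 − α) x(t) + (α − 1) x(t−1) + α (x̂(t+1) − x(t)).

* **α = 0.55** (smoothing, unitless): one step of velocity memory; set just
  off the even weighting 0.5, where the two memory terms can cancel.
  α = 1 disables memory entirely and reduces the model to its bare
  cell-hopping form.
* **T = 850 steps/hour**: one step spans one 6.67 m cell at the 1.575 m/s
  maximum walking speed (the 3.5 mph ≈ 1.56 m/s average walking pace
  motivates the calibration; diagonal steps cover 6.67·√2 m in the same
  tick and are deliberately not corrected).
* **K = 100 h** simulated duration and **500** Monte Carlo replicates at
  full scale.

Design choices that the source material leaves open, and how they were
resolved:

* Positions stay **continuous** between steps; the map is queried at the
  componentwise-rounded cell (round-half-up).  This preserves the smoothing
  update exactly while keeping all map logic discrete.
* A move whose rounded target is off-map or inaccessible is **rejected**:
  the agent keeps its position *and* its momentum state unchanged for that
  step.  Freezing the momentum prevents the smoothed position from
  tunneling through a thin water strip on the following step.  A side
  effect is that a forward-only profile (pure direction traveling) rammed
  against an obstacle can stall there indefinitely, because the heading
  only updates on accepted displacements; mixtures containing any random
  walking escape.
* **Zero realized velocity retains the previous heading**, so forward-
  looking strategies keep a defined "ahead" after a stall.
* **Route traveling** draws uniformly among only the feature-bearing cells
  of the three forward cells; with none it degrades to a random walk.
* **View enhancing** breaks elevation ties uniformly at random among all
  tied maxima (including the current cell), avoiding directional bias on
  flat ground.
* **Backtracking** proposes x(t−1) on its first draw; each consecutive
  draw walks a cursor one stored position further back through the
  history, skipping positions that were themselves produced by
  backtracking and clamping at the trajectory start.  This realizes a
  sustained walk back along the traveled route rather than a one-cell
  oscillation.
* Smoothing applies to **all** strategies, including staying put, whose
  residual momentum drift decays geometrically (the rounded cell stays
  within ~3 cells of the IPP over a full run; bounded by test).

A provable per-step bound follows from the geometry: the proposal lies
within Chebyshev distance 1 of the rounded cell and the continuous position
is at most half a cell off-center per component, so

    ‖x(t+1) − x(t)‖ ≤ (1 − α)·‖x(t) − x(t−1)‖ + 1.5·α·√2  cells,

with steady state 1.5√2 ≈ 2.1 cells/step; consecutive rounded cells are
within Chebyshev distance 2 in practice.  (A tighter √2 proposal radius
would hold only if positions sat exactly on cell centers.)

Replicate r runs on the child stream of the master seed spawned with key
(r,) (`numpy` SeedSequence), making replicate sets reproducible,
order-stable, and platform-independent at the level of the integer cell
sequence.  The simulation loop is an inlined transcription of the public
`step()` function; a test asserts the two are draw-for-draw identical.

## Fitting

For each incident and candidate profile, the closest point of every
replicate trajectory to the find location (earliest index on ties) forms
the sample X; the find is the single-point sample Y.  The energy statistic
is E = 2A − B with A the mean ‖xᵢ − y‖, B the mean pairwise distance within
X normalized by n² (self-pairs included), and C ≡ 0 for m = 1.  All
distances are in meters (cells × cell size), so the weight w = (d/E)^L is
dimensionless regardless of grid resolution; L = 1/2 emphasizes better
fits.  A zero-energy fit would give an infinite weight; it is capped (1e9
by default) with a warning.  Energy ties across candidates are broken by
the lexicographically smallest profile.  The average profile is the
weighted componentwise sum normalized by its component total (1-norm),
which for nonnegative entries always yields a valid probability vector.

Candidate profiles are the lattice of vectors with entries in multiples of
a step s: C(1/s + 5, 5) profiles for six strategies — 462 at s = 1/6, 56 at
s = 1/3 — in deterministic lexicographic order.

## Validation

Leave-one-out cross-validation retrains the weighted average on N−1
incidents, simulates the held-out incident under the trained profile
(replicates as in fitting), and ranks the resulting energy within the
incident's stored candidate-energy table.  The percentile is the share of
candidates the trained profile *beats* (reference energies ≥ e), so high is
good and the rank is antitone in the energy; ties count in the trained
profile's favor.  Headline summaries are the shares of folds above the 95th
and 50th percentiles.

The effective-speed diagnostic is an unweighted OLS fit of mean
closest-approach time (hours) on IPP-to-find distance (km) restricted to
d < 4 km, where the relation is approximately linear; the inverse slope,
converted to m/s, is the model's net displacement rate.  A non-positive
slope leaves the speed undefined rather than reporting a negative speed.

## Synthetic data: what it emulates and what it does not

The synthetic map generator emulates the *structure* the model consumes:
smooth relief (a seeded sum of Gaussian hills), trail networks (jittered
edge-to-edge polylines), lakes (circular blobs kept away from the center
cell so the standard IPP stays accessible), shorelines, and
elevation-derived feature lines, all bit-reproducible from a seed.  It does
not emulate the statistics of real terrain: drainage networks are not
tree-like, trails do not follow contours, and feature density is uniform
rather than valley-concentrated.  Synthetic incidents are endpoints of
trajectories simulated from a known truth profile, with the find time drawn
uniformly over a mobile window (real incident data carries no timing), and
are re-drawn until they pass the exclusion screening.  Passing the
recovery tests therefore demonstrates that the fitting machinery inverts
the model's own generative process on plausible terrain — not that the
model describes real lost-person data, which requires the real incident
database and GIS layers.

## The scaled recovery study

The full-scale configuration (3000² cells, 462 candidates, 500 replicates,
85,000 steps, 65 incidents) is a cluster-scale computation.  The package's
end-to-end study runs at desk scale: a 300 × 300 map (2 km × 2 km), 15
incidents from the truth profile [0, ⅓, ⅔, 0, 0, 0], the 56-candidate
step-1/3 lattice, and 50 replicates of 2 simulated hours (~1700 steps),
about two minutes on one core.

Two scaled parameters follow the fitting dynamics rather than the map
ratio.  The minimum find distance of the exclusion screen is 400 m: the
diffusive reach of a pure random-walk profile over the 2-hour fitting runs
measures ≈340 m, and the screen must sit above it to preserve the
full-scale design property that admissible finds cannot be explained by
sedentary local wandering (diffusion grows as √time, so scaling the 1 km
threshold linearly with the map would break this).  The boundary margin
scales with the map (10 cells).  The mobile window for generating finds is
1 h, long enough for truth-profile displacements to span the admissible
annulus between the distance floor and the boundary margin.

## Known limitations

* No terrain-dependent speed, fatigue, vision, land cover, weather, or
  group dynamics; the strategy mixture is time-invariant.
* The stall behavior of forward-only profiles at obstacles (above) makes
  one-hot DT trajectories on obstructed maps partially absorbing.
* The closest-point statistic uses the whole trajectory, so fitted
  profiles carry no information about *when* the person reached the find.
* Diagonal steps are 41% longer in meters than cardinal steps but cost the
  same simulated time.
* GeoTIFF reading takes the raster band only; any geo-transform must be
  supplied in the run configuration (no CRS reprojection).
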