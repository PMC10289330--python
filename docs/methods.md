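# Methods

This note documents the model implemented by `fuzzyflow`, the digital
conventions it fixes where a continuous description leaves them open, what
the synthetic scenes do and do not emulate, and the known limitations.

## Flow model

An image is a 2D pixel grid partitioned into object pixels O (nonzero in
the input mask) and background S. Water flows from the image border in a
direction α ∈ {0°, 45°, …, 315°} (0° = east, angles counter-clockwise; rows
increase downward) with divergence half-angle β. A background pixel is
**wet** iff it lies on the upstream border edge(s) for α or is reachable
from a wet pixel by a unit step whose direction deviates from α by at most
β. Seeding only the upstream edges matters: seeding every border would wet
the shadow regions behind obstacles from behind and destroy the island
structure the method relies on.

With the default β = 45° a step may deviate by one compass notch; the
divergence weight cos(θ − α) vanishes at 90°, so β is validated to (0°,
90°) — at exactly 90° a perpendicular step would carry zero pressure while
creating cyclic dependencies inside a propagation wavefront. β < 45°
degenerates to purely axial rays.

Wetting is computed exactly, not iteratively: for axial flows a single
column (or row) sweep closes the reachability relation because every
allowed step advances one column; for diagonal flows a row sweep with a
vectorized in-row fill does the same along anti-diagonals. The test suite
checks the sweeps against a brute-force BFS oracle on hundreds of random
grids, for all eight directions.

## Constriction and pressure

For each wet pixel, `d₁` and `d₂` are the step counts to the first object
pixel along the two directions orthogonal to α; a scan that exits the image
returns a sentinel (the image diagonal, rounded up) — the border is not an
obstacle. `d_max = max(d₁, d₂)`; a pixel with `d_max < τ` is inside a
**channel**.

Constriction accumulates along the flow:

    C(q) = C(p) + Δ(min(d_max(p), τ), d_max(q)),   Δ(a, b) = (a − b) / max(a, b)

where p is the most flow-aligned wet predecessor of q (the axial
predecessor when wet, otherwise the diagonal predecessor with the larger
candidate C). Outside channels C ≡ 0 and ψ ≡ 0.5. Clamping the
predecessor's distance at τ makes the *entry* step measure the narrowing
relative to the channel threshold itself. This choice is deliberate: wide
necks (neck width approaching 2τ) produce channels only one to three
pixels long along the flow, and an entry rule that resets pressure to
baseline leaves them permanently at ψ = 0.5. With the clamp, a channel of
any length registers its narrowness, all invariants are preserved (C = 0
and ψ = 0.5 in open water; ψ ∈ [0, 1]; C non-decreasing along a strictly
narrowing channel), and the measured split rate of separable overlaps rose
from ~83% to 100% on the synthetic benchmark without affecting the
false-split rate (0/100 scenes).

Pressure at a wet channel pixel is the maximum over wet cone predecessors
of σ(C)·cos(θ − α); the flow pressure of the image is the pointwise maximum
of ψ over the eight directions. σ is the unit-slope logistic, so the
open-water baseline is σ(0) = 0.5 exactly.

## Pressure points, pairing, cutting

Pressure zones are 8-connected components of {ψ > 0.5 + ε}, ε = 1e-9
guarding float equality at baseline. The zone maximum is its pressure
point; exact ties go to the lexicographically smallest (row, col).

Two points are **complementary** when their flows oppose. With only eight
quantized directions, the two notches flanking an obliquely oriented neck
pressurize under flows that can be one notch short of opposite (135°), so
opposition is required only up to one notch, combined with a direction
consistency test: the joining segment must run within 67.5° of the first
point's flow and of the reverse of the second's. Strict 180° pairing is
available (`candidate_pairs(..., min_opposition=180)`) but measurably
misses oblique necks.

Candidate gates, in order:

1. the segment between the points must cross at least one object pixel
   (this alone eliminates the open through-channel between two nearby but
   disjoint objects, where both flows pressurize the same throat);
2. `‖p₁ − p₂‖ ≤ max(Tmin N*(p₁), Tmin N*(p₂), crossing span) + 2`, where
   `Tmin N*(p)` is the minimum thickness over obstruction points (background
   pixels touching the object) in p's 8-neighborhood, the crossing span is
   the object extent actually traversed by the rasterized segment (pixel
   count × mean step length), and the +2 covers the one-pixel background
   standoff at each endpoint; pairs whose points have no obstruction
   neighbors at all are rejected;
3. greedy matching by increasing distance, each point used at most once.

**Thickness** at an obstruction point b is the smallest crossing chord
seen from b: the contiguous object run continuing along each axial
direction whose immediate neighbor is object (diagonal entering directions,
scaled by √2, only when the contact is exclusively diagonal). Chords that
merely run tangent to a curved boundary are short without the object being
thin; restricting to entering directions suppresses most of them, but on
necks oriented between the compass axes the fixed-axis reading still errs
in both directions (measured 0.85 vs true ≈0.49 at 20° orientation, 0.15
vs ≈0.49 at 40°). The **acceptance** test therefore uses the
orientation-true reading: a pair is accepted iff

    max(ψ₁, ψ₂) > D(crossing span),   D(T) = min(T / 2τ, 1).

The cap at 1 means an object crossing of 2τ or more can never be cut,
whatever the pressure.

The accepted cut is the inclusive Bresenham segment between the two points;
at every diagonal step an axial companion pixel is added so the one-pixel
cut blocks 8-connected leakage, and the cut is completed up to three steps
past each endpoint through contiguous object. The extension handles a
digital corner case observed at deep overlaps: the union's inner corner
leaves the two lobes touching diagonally *around* the endpoint's background
pixel, so a cut that stops exactly at the pressure point fails to
disconnect. Cut pixels become background; an optional flag
(`reassign_line_pixels`) reassigns them to the nearest instance for
area-preserving output. Final instances are 8-connected components
(4-connectivity available via configuration).

## Parameters

| parameter | default | meaning |
|---|---|---|
| τ | 10 px | channel width threshold; also sets the cut cap 2τ. Roughly half the typical nucleus diameter; a helper choice for new data is half the median equivalent diameter of mask components. |
| β | 45° | divergence half-angle; one compass notch. |
| ε | 1e-9 | strict-inequality tolerance at the ψ = 0.5 baseline. |
| connectivity | 8 | final instance labeling connectivity. |
| f2_mode | standard | F₂ = 5PR/(4P+R); an `as_printed` variant 2PR/(4P+R) is kept for fidelity with an alternative published form. |

## Evaluation and statistics

Metrics are computed from pixel confusion counts with object as the
positive class; per-image computation with averaging across images is the
default aggregation (pooled counts remain available by summing confusion
counts before `metric_suite`). Zero-denominator metrics are NaN with a
warning rather than silently 0. Power is 1 − FN/(TP+FN), the complement of
the pixel-level type-II error rate.

The randomization test flips the signs of paired differences: exact
enumeration of all 2ⁿ patterns for n ≤ 20, otherwise Monte-Carlo with the
add-one estimator (1 + #{mean ≥ observed})/(1 + B), one-sided by default;
it is deterministic given a seed and its null distribution of p-values is
uniform to KS < 0.05 in the calibration test. The Wilcoxon signed-rank test
drops zero differences, midranks ties, uses the exact null for up to 12
untied pairs and the continuity-corrected normal approximation beyond.

## Synthetic scenes

The generator emulates the *output of a coarse semantic segmenter*: unions
of discs in which designated pairs overlap (center distance drawn from
0.8–0.95 of the radius sum unless given explicitly) and all other discs
keep a ≥ 3 px boundary gap. Discs give an exact analytic neck width (the
circle-intersection chord) for every overlapping pair, which the tests use
as the thickness oracle, and a unique ground-truth labeling (contested
pixels to the nearer center, ties to the lower label). A pair is recorded
as *separable* when its neck is narrower than 0.8 of the smaller lobe's
diameter — the testable form of "morphologically separable". Scenes are
bit-reproducible from their seed.

Default study conditions for scene-level checks: 512×512 canvas, 12 nuclei
of radius 8–13 px, 3 overlapping pairs, margin 16 px; the false-split check
uses 256×256 with 8 non-touching discs. These sizes exercise every code
path (shadowing between objects, oblique necks, channels between disjoint
objects) at sub-second per-scene runtimes.

What the scenes do **not** emulate: non-convex or textured nuclei,
segmentation noise on the mask boundary (ragged edges produce spurious
shallow notches whose behavior is untested here), clumps of three or more
mutually overlapping nuclei, and anisotropic pixels. Passing the synthetic
suite therefore demonstrates correctness of the geometry and the flow
mechanics, not segmentation accuracy on real histopathology masks.

## Known limitations

- Clumps of ≥ 3 mutually inseparable nuclei are split only as far as
  pairwise pressure points allow; necks of width ≥ 2τ are never cut by
  design.
- Flow shadowing is real: a notch lying in another object's wet shadow for
  the one flow direction that could pressurize it will be missed. The
  relaxed 135° pairing reduces but does not eliminate this.
- The separation boundary is a straight line; strongly curved interfaces
  between overlapping nuclei are approximated, not traced.
- Pressure points displaced by tie-breaking along a constant-ψ plateau can
  shift a cut by a pixel; the area assigned to each instance is accordingly
  approximate near the neck.
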