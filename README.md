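# fuzzyflow

Fuzzy water-flow separation of merged nuclei in binary segmentation masks.

Semantic segmenters of microscopy images (H&E histopathology,
immunofluorescence) return a single foreground mask in which touching or
overlapping nuclei fuse into one connected component, so instance counts and
per-nucleus morphometrics come out wrong. `fuzzyflow` is a post-processing
library and CLI for that coarse mask: it splits merged components along the
concave necks between overlapping nuclei — without seeds, training, or
intensity information — and returns an instance label map with centroids.

## The model

Hypothetical water is poured across the image from each of the eight compass
directions α ∈ {0°, 45°, …, 315°}, with divergence half-angle β (default
45°). Objects are obstacles; background pixels reachable within the
divergence cone are *wet*. For a wet pixel p, `d₁(p)` and `d₂(p)` are the
pixel distances to the nearest obstacle along the two directions orthogonal
to α, and `d_max(p) = max(d₁, d₂)`. Where `d_max < τ` (default τ = 10 px)
the flow is in a constricted channel and a constriction score accumulates
the fractional narrowing step by step,

    C(q) = C(p) + (min(d_max(p), τ) − d_max(q)) / max(min(d_max(p), τ), d_max(q)),

taken from the most flow-aligned wet predecessor p of q. The fuzzy flow
pressure is

    ψ(q) = σ(C(q))             for the axial step (θ = α),
    ψ(q) = σ(C(q))·cos(θ − α)  for a divergent step,

with σ the unit-slope logistic function, so ψ ∈ [0, 1] with open-water
baseline ψ = σ(0) = 0.5. Clusters of pixels with ψ > 0.5 are *pressure
zones*; the maximum of each zone is a *pressure point* Ψ(p, α). Two points
from (near-)opposite flows sitting in the two notches of a neck are joined
by a straight line; the pair is accepted when `max(ψ₁, ψ₂)` exceeds the
normalized thickness `D = min(T/2τ, 1)` of the object span the line
crosses, and the line is carved into the mask, splitting the conjoint
object. Remaining components are labeled (8-connectivity) and their
centroids (CG points) reported for counting.

The package also provides the pixel-level evaluation suite — Jaccard (JI),
Dice (DC), volume similarity (VS), accuracy, precision, recall, F1, F2, and
power Pr(TP) = 1 − FN/(TP+FN) — plus paired significance tests (sign-flip
randomization test and Wilcoxon signed-rank) for comparing methods across
images, and a seeded synthetic generator of overlapping-disc scenes with
exact instance ground truth and analytic neck widths.

## Worked example

Two discs of radius 10 px with centers 18 px apart overlap into a single
merged component; the circle-intersection chord (the neck) is 2·√19 ≈ 8.72 px.

```python
from fuzzyflow import generate_two_disc, separate_instances, confusion, metric_suite

scene = generate_two_disc(r1=10, r2=10, d=18)
print("analytic neck width:", round(scene.pairs[0].neck_width, 3))

result, lines, fields = separate_instances(scene.merged_mask, tau=10,
                                           return_details=True)
print("instances:", result.count)
print("centroids:", [(round(r, 1), round(c, 1)) for r, c in result.centroids])
print("separation lines:", len(lines))

c = confusion(result.labels > 0, scene.merged_mask)
print("Dice vs merged mask:", round(metric_suite(c).dc, 4))
```

Output:

```
analytic neck width: 8.718
instances: 2
centroids: [(18.0, 17.7), (18.0, 36.3)]
separation lines: 3
Dice vs merged mask: 0.9927
```

The merged dumbbell is split into two instances whose centroids sit at the
two disc centers; three near-coincident cuts across the waist (one per
complementary flow-axis pair that pressurized the notches) remove under 1%
of the object pixels, hence the 0.993 Dice of the labeled output against
the input mask.

## Command line

```
fuzzyflow separate --in coarse_mask.png --tau 10 --out out/
fuzzyflow evaluate --pred preds/ --truth gt/ --baseline other_method/ --out report/
fuzzyflow synth    --n-nuclei 12 --n-pairs 3 --seed 7 --out scene/
fuzzyflow run      --synth-seed 7 --out out/
```

`separate` writes a 16-bit label TIFF, an overlay PNG (green instance
boundaries, blue separation lines, red centroids) and a per-instance CSV.
`evaluate` matches prediction and ground-truth masks by filename stem and
writes per-image metrics (CSV) and a JSON summary with means and, when a
baseline directory is given, paired-test p-values. All parameters (τ, β,
connectivity, F2 variant, seed) can come from a YAML config, with CLI flags
taking precedence.

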