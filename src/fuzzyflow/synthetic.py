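"""Seeded synthetic scenes of overlapping near-circular nuclei.

Emulates the merged coarse mask a semantic segmenter produces: unions of
discs in which designated pairs overlap and appear as one component.  Every
scene carries exact instance ground truth and, for each overlapping pair,
the analytic neck (intersection chord) width — the oracle for channel and
thickness computations downstream.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .separation import InstanceLabelMap

__all__ = [
    "SceneSpec",
    "PairRecord",
    "SyntheticScene",
    "neck_width",
    "generate_two_disc",
    "generate_scene",
    "merge_instances",
]

# A designated overlap is "morphologically separable" when the neck is
# visibly narrower than the smaller lobe: chord < 0.8 * min lobe diameter.
SEPARABLE_NECK_FRACTION = 0.8


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of a random scene.

    Defaults emulate a 512x512 field of view with a dozen nuclei of radius
    8-13 px, three of which form overlapping pairs whose center distance is
    drawn from ``overlap_distance_range`` (if None, uniformly from 0.8-0.95
    of the radius sum, which keeps the pairs merged yet separable).
    """

    height: int = 512
    width: int = 512
    n_nuclei: int = 12
    radius_range: tuple[float, float] = (8.0, 13.0)
    overlap_distance_range: tuple[float, float] | None = None
    n_overlapping_pairs: int = 3
    margin: int = 16
    min_gap: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.radius_range[0] < 3:
            raise ValueError("minimum radius must be at least 3 px")
        if self.margin < 1:
            raise ValueError("margin must be at least 1 px")
        if self.n_overlapping_pairs * 2 > self.n_nuclei:
            raise ValueError("n_overlapping_pairs cannot exceed n_nuclei / 2")


@dataclass(frozen=True)
class PairRecord:
    label_a: int
    label_b: int
    center_distance: float
    neck_width: float
    separable: bool


@dataclass
class SyntheticScene:
    truth_instances: InstanceLabelMap
    merged_mask: np.ndarray
    pairs: list[PairRecord]
    spec: SceneSpec | None = None
    discs: list[tuple[float, float, float]] = field(default_factory=list)

    def sidecar(self) -> str:
        """JSON record of the scene's generation parameters and pairs."""
        payload = {
            "spec": None if self.spec is None else {
                "height": self.spec.height,
                "width": self.spec.width,
                "n_nuclei": self.spec.n_nuclei,
                "radius_range": list(self.spec.radius_range),
                "overlap_distance_range": (
                    None
                    if self.spec.overlap_distance_range is None
                    else list(self.spec.overlap_distance_range)
                ),
                "n_overlapping_pairs": self.spec.n_overlapping_pairs,
                "margin": self.spec.margin,
                "min_gap": self.spec.min_gap,
                "seed": self.spec.seed,
            },
            "discs": [list(d) for d in self.discs],
            "pairs": [
                {
                    "label_a": p.label_a,
                    "label_b": p.label_b,
                    "center_distance": p.center_distance,
                    "neck_width": p.neck_width,
                    "separable": p.separable,
                }
                for p in self.pairs
            ],
        }
        return json.dumps(payload, indent=2)


def neck_width(r1: float, r2: float, d: float) -> float:
    """Intersection chord length of two properly overlapping circles.

    Requires |r1 - r2| < d < r1 + r2.  The chord is the width of the neck
    the merged pair leaves in the union mask.
    """
    if not (abs(r1 - r2) < d < r1 + r2):
        raise ValueError(
            f"circles with r1={r1}, r2={r2} at distance d={d} do not properly overlap"
        )
    a = (d * d + r1 * r1 - r2 * r2) / (2.0 * d)
    return 2.0 * math.sqrt(max(r1 * r1 - a * a, 0.0))


def _is_separable(r1: float, r2: float, neck: float) -> bool:
    return bool(neck < SEPARABLE_NECK_FRACTION * 2.0 * min(r1, r2))


def _paint_labels(
    shape: tuple[int, int], discs: list[tuple[float, float, float]]
) -> np.ndarray:
    """Rasterize discs into a label map; contested pixels go to the nearer
    center, ties to the lower label."""
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w]
    labels = np.zeros(shape, dtype=np.int32)
    best_d2 = np.full(shape, np.inf)
    for k, (cy, cx, r) in enumerate(discs, start=1):
        d2 = (rr - cy) ** 2 + (cc - cx) ** 2
        claim = (d2 <= r * r) & (d2 < best_d2)  # strict: ties keep the earlier label
        labels[claim] = k
        best_d2[claim] = d2[claim]
    return labels


def generate_two_disc(
    r1: float, r2: float, d: float, pad: int = 8, seed: int = 0
) -> SyntheticScene:
    """Canonical dumbbell: two overlapping discs on a horizontal axis.

    Deterministic given the geometry (``seed`` is accepted for interface
    uniformity).  Truth has two instances with contested overlap pixels
    assigned to the nearer center (ties to label 1); the merged mask is
    their union.
    """
    neck = neck_width(r1, r2, d)  # validates overlap
    rmax = max(r1, r2)
    h = int(math.ceil(2 * rmax)) + 2 * pad + 1
    w = int(math.ceil(2 * r1 + d + 2 * r2)) + 2 * pad  # generous
    cy = h // 2
    cx1 = pad + r1
    cx2 = cx1 + d
    w = int(math.ceil(cx2 + r2)) + pad + 1
    discs = [(float(cy), float(cx1), float(r1)), (float(cy), float(cx2), float(r2))]
    labels = _paint_labels((h, w), discs)
    truth = InstanceLabelMap.from_labels(labels)
    pair = PairRecord(
        label_a=1,
        label_b=2,
        center_distance=float(d),
        neck_width=neck,
        separable=_is_separable(r1, r2, neck),
    )
    return SyntheticScene(
        truth_instances=truth,
        merged_mask=labels > 0,
        pairs=[pair],
        spec=None,
        discs=discs,
    )


def generate_scene(spec: SceneSpec) -> SyntheticScene:
    """Random scene per ``spec``: overlapping pairs first, then isolated discs.

    Designated pairs overlap each other only; all other disc pairs keep a
    boundary gap of at least ``spec.min_gap`` pixels.  Placement uses
    bounded rejection sampling and is fully reproducible from the seed.
    """
    rng = np.random.default_rng(spec.seed)
    rmin, rmax = spec.radius_range
    discs: list[tuple[float, float, float]] = []
    groups: list[int] = []  # pair id per disc, -1 for singles
    pair_geoms: list[tuple[float, float, float]] = []  # (r1, r2, d)

    def clear_of_others(cy, cx, r, own_group):
        for (oy, ox, orad), g in zip(discs, groups):
            if g == own_group and g != -1:
                continue
            if math.hypot(cy - oy, cx - ox) < r + orad + spec.min_gap:
                return False
        return True

    max_attempts = 10_000
    for pid in range(spec.n_overlapping_pairs):
        placed = False
        for _ in range(max_attempts):
            r1, r2 = rng.uniform(rmin, rmax, size=2)
            if spec.overlap_distance_range is not None:
                lo, hi = spec.overlap_distance_range
            else:
                lo, hi = 0.8 * (r1 + r2), 0.95 * (r1 + r2)
            d = rng.uniform(lo, hi)
            if not (abs(r1 - r2) < d < r1 + r2):
                continue
            theta = rng.uniform(0.0, 2.0 * math.pi)
            span = (d + r1 + r2) / 2.0 + spec.margin
            cy = rng.uniform(span, spec.height - span)
            cx = rng.uniform(span, spec.width - span)
            dy, dx = (d / 2.0) * math.sin(theta), (d / 2.0) * math.cos(theta)
            c1 = (cy - dy, cx - dx, r1)
            c2 = (cy + dy, cx + dx, r2)
            if clear_of_others(*c1, pid) and clear_of_others(*c2, pid):
                discs.extend([c1, c2])
                groups.extend([pid, pid])
                pair_geoms.append((r1, r2, d))
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not place overlapping pair {pid} within {max_attempts} "
                f"attempts: canvas too crowded for the requested geometry"
            )

    n_single = spec.n_nuclei - 2 * spec.n_overlapping_pairs
    for k in range(n_single):
        placed = False
        for _ in range(max_attempts):
            r = rng.uniform(rmin, rmax)
            cy = rng.uniform(r + spec.margin, spec.height - r - spec.margin)
            cx = rng.uniform(r + spec.margin, spec.width - r - spec.margin)
            if clear_of_others(cy, cx, r, -1):
                discs.append((cy, cx, r))
                groups.append(-1)
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not place isolated disc {k} within {max_attempts} attempts: "
                f"canvas too crowded (min_gap={spec.min_gap})"
            )

    labels = _paint_labels((spec.height, spec.width), discs)
    truth = InstanceLabelMap.from_labels(labels)
    pairs = []
    for pid, (r1, r2, d) in enumerate(pair_geoms):
        neck = neck_width(r1, r2, d)
        pairs.append(
            PairRecord(
                label_a=2 * pid + 1,
                label_b=2 * pid + 2,
                center_distance=d,
                neck_width=neck,
                separable=_is_separable(r1, r2, neck),
            )
        )
    return SyntheticScene(
        truth_instances=truth,
        merged_mask=labels > 0,
        pairs=pairs,
        spec=spec,
        discs=discs,
    )


def merge_instances(truth: InstanceLabelMap) -> np.ndarray:
    """Coarse binary mask: OBJECT wherever any instance label is nonzero."""
    return np.asarray(truth.labels) > 0
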