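"""Splitting conjoint objects at complementary pressure points.

Two overlapping nuclei leave a concave *neck* in the merged mask.  Flows
from opposite directions build pressure zones in the two notches flanking
the neck; the straight line joining the two pressure points — gated by the
local object thickness — is the separation boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.draw import line as draw_line
from skimage.measure import label as cc_label

from .flow import FlowParams, PressureField, compute_all_fields
from .grid import Direction, angular_difference, as_binary_mask

__all__ = [
    "BASELINE_EPS",
    "PressureZone",
    "PressurePoint",
    "ObstacleStats",
    "SeparationCandidate",
    "InstanceLabelMap",
    "find_pressure_zones",
    "pressure_point",
    "thickness",
    "disconnectivity",
    "neighborhood_min_thickness",
    "candidate_pairs",
    "accept_pair",
    "draw_separation",
    "separate_instances",
    "count_instances",
]

# tolerance above the 0.5 baseline for "pressure above normal"
BASELINE_EPS = 1e-9

_EIGHT = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
_SQRT2 = math.sqrt(2.0)


@dataclass
class PressureZone:
    """8-connected cluster of pixels with pressure above baseline."""

    alpha: Direction
    pixels: np.ndarray  # (n, 2) int array of (row, col)
    psi_values: np.ndarray  # (n,) floats, all > 0.5


@dataclass(frozen=True)
class PressurePoint:
    location: tuple[int, int]
    alpha: Direction
    psi: float


@dataclass(frozen=True)
class ObstacleStats:
    """Thickness and normalized disconnectivity at an obstruction point."""

    point: tuple[int, int]
    thickness: float
    disconnectivity: float


@dataclass
class SeparationCandidate:
    point1: PressurePoint
    point2: PressurePoint
    distance: float
    line_pixels: list[tuple[int, int]] = field(default_factory=list)
    accepted: bool = False


@dataclass
class InstanceLabelMap:
    """Integer-labeled instances (0 = background) with centroids."""

    labels: np.ndarray
    count: int
    centroids: list[tuple[float, float]]

    @classmethod
    def from_labels(cls, labels: np.ndarray) -> "InstanceLabelMap":
        labels = np.asarray(labels)
        ids = np.unique(labels)
        ids = ids[ids > 0]
        cents = ndimage.center_of_mass(labels > 0, labels, ids) if ids.size else []
        return cls(
            labels=labels,
            count=int(ids.size),
            centroids=[(float(r), float(c)) for r, c in cents],
        )


def find_pressure_zones(pf: PressureField) -> list[PressureZone]:
    """8-connected components of supra-baseline pressure (psi > 0.5)."""
    above = pf.psi > 0.5 + BASELINE_EPS
    if not above.any():
        return []
    lab, n = cc_label(above, connectivity=2, return_num=True)
    zones = []
    for k in range(1, n + 1):
        rr, cc = np.nonzero(lab == k)
        pix = np.column_stack([rr, cc])
        zones.append(
            PressureZone(alpha=pf.alpha, pixels=pix, psi_values=pf.psi[rr, cc])
        )
    return zones


def pressure_point(zone: PressureZone) -> PressurePoint:
    """Maximum-pressure pixel of a zone; ties go to the smallest (row, col)."""
    if len(zone.pixels) == 0:
        raise ValueError("empty pressure zone")
    best = np.max(zone.psi_values)
    at_max = zone.pixels[zone.psi_values >= best - BASELINE_EPS]
    idx = np.lexsort((at_max[:, 1], at_max[:, 0]))[0]
    loc = (int(at_max[idx, 0]), int(at_max[idx, 1]))
    return PressurePoint(location=loc, alpha=zone.alpha, psi=float(best))


def _directed_run(mask: np.ndarray, o: tuple[int, int], step: tuple[int, int]) -> int:
    """Contiguous object run length starting at ``o`` along ``step``."""
    h, w = mask.shape
    n = 1
    r, c = o
    while True:
        r += step[0]
        c += step[1]
        if not (0 <= r < h and 0 <= c < w) or not mask[r, c]:
            break
        n += 1
    return n


def _nearest_object_neighbor(mask: np.ndarray, b: tuple[int, int]):
    """Object 8-neighbor of ``b`` nearest to it (axial before diagonal,
    then smallest (row, col))."""
    h, w = mask.shape
    cands = []
    for dr, dc in _EIGHT:
        r, c = b[0] + dr, b[1] + dc
        if 0 <= r < h and 0 <= c < w and mask[r, c]:
            cands.append((abs(dr) + abs(dc), r, c))  # 1 = axial, 2 = diagonal
    if not cands:
        return None
    cands.sort()
    return (cands[0][1], cands[0][2])


def thickness(mask, b: tuple[int, int]) -> float:
    """Local object thickness at an obstruction point ``b``.

    ``b`` must be a background pixel 8-adjacent to the object.  The
    thickness is the smallest crossing chord seen from ``b``: for every
    axial direction whose immediate neighbor is an object pixel, the
    contiguous object run continuing along that direction; when the object
    touches ``b`` only diagonally, the diagonal entering runs are used
    instead (scaled by sqrt(2)).  Chords that merely run tangent to a
    curved boundary are deliberately not considered — they are short
    without the object being thin.
    """
    m = as_binary_mask(mask)
    if m[b]:
        raise ValueError(f"{b} is an object pixel, not an obstruction point")
    h, w = m.shape

    def entering_runs(steps, scale):
        runs = []
        for step in steps:
            o = (b[0] + step[0], b[1] + step[1])
            if 0 <= o[0] < h and 0 <= o[1] < w and m[o]:
                runs.append(_directed_run(m, o, step) * scale)
        return runs

    runs = entering_runs([(0, 1), (0, -1), (1, 0), (-1, 0)], 1.0)
    if not runs:
        runs = entering_runs([(1, 1), (1, -1), (-1, 1), (-1, -1)], _SQRT2)
    if not runs:
        raise ValueError(f"{b} has no adjacent object pixel")
    return float(min(runs))


def disconnectivity(t: float, tau: float) -> float:
    """Object disconnectivity D = T / (2 tau), capped at 1."""
    if tau <= 0:
        raise ValueError(f"tau must be positive, got {tau}")
    if t < 0:
        raise ValueError(f"thickness must be nonnegative, got {t}")
    return min(t / (2.0 * tau), 1.0)


def _obstruction_neighbors(mask: np.ndarray, p: tuple[int, int]) -> list[tuple[int, int]]:
    """Background pixels in p's 8-neighborhood that touch the object."""
    h, w = mask.shape
    out = []
    for dr, dc in _EIGHT:
        r, c = p[0] + dr, p[1] + dc
        if not (0 <= r < h and 0 <= c < w) or mask[r, c]:
            continue
        if _nearest_object_neighbor(mask, (r, c)) is not None:
            out.append((r, c))
    return out


def neighborhood_min_thickness(mask, p: tuple[int, int]) -> float | None:
    """Minimum thickness over obstruction points neighboring ``p``.

    Returns None when no neighbor of ``p`` touches the object.
    """
    m = as_binary_mask(mask)
    obs = _obstruction_neighbors(m, p)
    if not obs:
        return None
    return min(thickness(m, b) for b in obs)


def _normalized_thickness(mask: np.ndarray, p: tuple[int, int], tau: float) -> float | None:
    obs = _obstruction_neighbors(mask, p)
    if not obs:
        return None
    return min(disconnectivity(thickness(mask, b), tau) for b in obs)


def _segment_pixels(p1: tuple[int, int], p2: tuple[int, int]) -> list[tuple[int, int]]:
    rr, cc = draw_line(p1[0], p1[1], p2[0], p2[1])
    return list(zip(rr.tolist(), cc.tolist()))


def _points_angle(p: tuple[int, int], q: tuple[int, int]) -> float:
    """Compass angle (degrees, 0 = east, counter-clockwise) of p -> q."""
    return math.degrees(math.atan2(-(q[0] - p[0]), q[1] - p[1])) % 360.0


def candidate_pairs(
    points: list[PressurePoint],
    mask,
    tau: float,
    min_opposition: float = 135.0,
) -> list[SeparationCandidate]:
    """Pair complementary pressure points across the object between them.

    Complementary points come from (near-)opposite flows: with only eight
    flow directions, the two notches flanking an obliquely oriented neck
    pressurize under flows that may quantize to 135° apart rather than
    exactly 180°, so opposition is required only up to one compass notch
    (``min_opposition``) and the joining segment must run along the first
    point's flow and against the second's (within 67.5°).

    Each pair must further cross at least one object pixel and keep its
    Euclidean separation within the local thickness scale:
    ``||p1 - p2|| <= max(Tmin N*(p1), Tmin N*(p2), crossing span) + 2``,
    where the crossing span is the object extent the rasterized segment
    actually traverses (the orientation-true thickness reading; the fixed
    probe axes under-read obliquely oriented necks) and the +2 covers the
    one-pixel background standoff at each endpoint.  A pair is rejected
    outright when neither point has an obstruction neighbor.  Pairs are
    matched greedily by increasing distance, each point used at most once.
    """
    m = as_binary_mask(mask)
    feasible = []
    tmin_cache: dict[tuple[int, int], float | None] = {}

    def tmin(p):
        if p.location not in tmin_cache:
            tmin_cache[p.location] = neighborhood_min_thickness(m, p.location)
        return tmin_cache[p.location]

    for i, a in enumerate(points):
        for b in points[i + 1 :]:
            if angular_difference(a.alpha.value, b.alpha.value) < min_opposition:
                continue
            if a.location == b.location:
                continue
            seg_angle = _points_angle(a.location, b.location)
            if (
                angular_difference(seg_angle, a.alpha.value) > 67.5
                or angular_difference(seg_angle, b.alpha.opposite().value) > 67.5
            ):
                continue
            dist = math.hypot(
                a.location[0] - b.location[0], a.location[1] - b.location[1]
            )
            bounds = [t for t in (tmin(a), tmin(b)) if t is not None]
            if not bounds:
                continue
            seg = _segment_pixels(a.location, b.location)
            n_cross = sum(1 for r, c in seg if m[r, c])
            if n_cross == 0:
                continue
            step_len = dist / (len(seg) - 1) if len(seg) > 1 else 1.0
            if dist > max(*bounds, n_cross * step_len) + 2.0:
                continue
            feasible.append(
                SeparationCandidate(point1=a, point2=b, distance=dist, line_pixels=seg)
            )

    feasible.sort(key=lambda c: (c.distance, c.point1.location, c.point2.location))
    used: set[tuple[tuple[int, int], Direction]] = set()
    chosen = []
    for cand in feasible:
        k1 = (cand.point1.location, cand.point1.alpha)
        k2 = (cand.point2.location, cand.point2.alpha)
        if k1 in used or k2 in used:
            continue
        used.add(k1)
        used.add(k2)
        chosen.append(cand)
    return chosen


def _crossing_span(mask: np.ndarray, cand: SeparationCandidate) -> float:
    """Object extent crossed by the joining segment, in pixels."""
    seg = cand.line_pixels or _segment_pixels(
        cand.point1.location, cand.point2.location
    )
    n_cross = sum(1 for r, c in seg if mask[r, c])
    step_len = cand.distance / (len(seg) - 1) if len(seg) > 1 else 1.0
    return n_cross * step_len


def accept_pair(cand: SeparationCandidate, mask, tau: float) -> bool:
    """Pressure-vs-thickness gate for a candidate pair.

    The pair is accepted when the stronger of the two pressures exceeds the
    normalized thickness of the obstacle being cut: the disconnectivity
    D = min(span / 2 tau, 1) of the joining segment's own object crossing
    span.  The span is the thickness at the pressure points measured along
    the cut itself — the orientation-true reading, where chords probed on
    the fixed compass axes systematically mis-read obliquely oriented necks
    in either direction.  A crossing of 2·tau or more saturates D at 1 and
    can never be cut.  Pairs whose points have no obstruction neighbor at
    all are rejected.
    """
    m = as_binary_mask(mask)
    norms = [
        n
        for n in (
            _normalized_thickness(m, cand.point1.location, tau),
            _normalized_thickness(m, cand.point2.location, tau),
        )
        if n is not None
    ]
    if not norms:
        return False
    threshold = disconnectivity(_crossing_span(m, cand), tau)
    return max(cand.point1.psi, cand.point2.psi) > threshold


def _cut_pixels(cand: SeparationCandidate) -> list[tuple[int, int]]:
    """Rasterized segment plus axial companions at diagonal steps, so a
    1-px cut blocks 8-connected leakage."""
    seg = cand.line_pixels or _segment_pixels(
        cand.point1.location, cand.point2.location
    )
    out = [seg[0]]
    for (r0, c0), (r1, c1) in zip(seg, seg[1:]):
        if r0 != r1 and c0 != c1:
            out.append((r0, c1))
        out.append((r1, c1))
    return out


# steps a cut may continue past an endpoint to sever the residual object
# sliver at a concavity corner (pressure points can sit a pixel or two shy
# of the inner corner, whose lobes touch diagonally around the endpoint)
_ENDPOINT_EXTENSION = 3


def _extend_cut(
    m: np.ndarray, end: tuple[int, int], prev: tuple[int, int]
) -> list[tuple[int, int]]:
    h, w = m.shape
    step = (int(np.sign(end[0] - prev[0])), int(np.sign(end[1] - prev[1])))
    if step == (0, 0):
        return []
    removed = []
    r, c = end
    for _ in range(_ENDPOINT_EXTENSION):
        r2, c2 = r + step[0], c + step[1]
        cells = [(r2, c2)]
        if step[0] != 0 and step[1] != 0:
            cells.append((r, c2))  # diagonal companion
        hits = [p for p in cells if 0 <= p[0] < h and 0 <= p[1] < w and m[p]]
        if not hits:
            break
        removed.extend(hits)
        r, c = r2, c2
    return removed


def draw_separation(mask, cand: SeparationCandidate) -> np.ndarray:
    """Carve the separation line into the mask (object pixels -> background).

    The inclusive digital segment between the two pressure points is
    removed, with an axial companion pixel at every diagonal step so the
    1-px cut blocks 8-connected leakage; the cut is completed past each
    endpoint through any contiguous object sliver (at most
    ``_ENDPOINT_EXTENSION`` steps) so lobes touching diagonally around the
    endpoint corner are severed too.  Idempotent; background pixels on the
    line are unchanged.
    """
    m = as_binary_mask(mask).copy()
    px = _cut_pixels(cand)
    p1, p2 = cand.point1.location, cand.point2.location
    if p1 != p2:
        px = px + _extend_cut(m, p2, p1) + _extend_cut(m, p1, p2)
    rr = np.array([p[0] for p in px])
    cc = np.array([p[1] for p in px])
    m[rr, cc] = False
    cand.line_pixels = px
    return m


def separate_instances(
    mask,
    params: FlowParams | None = None,
    *,
    beta: float = 45.0,
    tau: float = 10.0,
    connectivity: int = 8,
    reassign_line_pixels: bool = False,
    return_details: bool = False,
):
    """End-to-end separation: flows -> zones -> points -> pairs -> cuts -> labels.

    Parameters may be given as a :class:`FlowParams` (its alpha is ignored;
    all eight directions are always run) or as ``beta``/``tau`` keywords.

    Returns an :class:`InstanceLabelMap`; with ``return_details=True`` also
    returns the accepted candidates and the per-direction pressure fields.
    """
    m = as_binary_mask(mask)
    if params is not None:
        beta, tau = params.beta, params.tau
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")

    fields = compute_all_fields(m, beta=beta, tau=tau)
    points = [
        pressure_point(z) for f in fields.values() for z in find_pressure_zones(f)
    ]
    cands = candidate_pairs(points, m, tau)
    accepted = []
    cut = m
    for cand in cands:
        if accept_pair(cand, m, tau):
            cand.accepted = True
            cut = draw_separation(cut, cand)
            accepted.append(cand)

    labels = cc_label(cut, connectivity=2 if connectivity == 8 else 1)
    if reassign_line_pixels and accepted:
        removed = m & ~cut
        if removed.any():
            _, (ir, ic) = ndimage.distance_transform_edt(
                labels == 0, return_indices=True
            )
            rr, cc = np.nonzero(removed)
            labels = labels.copy()
            labels[rr, cc] = labels[ir[rr, cc], ic[rr, cc]]
    result = InstanceLabelMap.from_labels(labels)
    if return_details:
        return result, accepted, fields
    return result


def count_instances(label_map: InstanceLabelMap) -> tuple[int, list[tuple[float, float]]]:
    """Instance count and centroids (CG points) of a label map."""
    fresh = InstanceLabelMap.from_labels(label_map.labels)
    return fresh.count, fresh.centroids
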