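"""Directional water-flow simulation over a binary mask.

Hypothetical water is poured across the image from one of the eight compass
directions.  Object pixels are obstacles; background pixels reached by the
flow (within its divergence cone) are *wet*.  Where the background passage
between obstacles narrows below a distance threshold ``tau`` the flow is in
a *constricted channel*: a constriction score ``C`` accumulates the
fractional narrowing step by step, and the fuzzy flow pressure at a pixel is

    psi = sigmoid(C)            on the flow axis,
    psi = sigmoid(C) * cos(45°) for a diagonal (divergent) step,

anchored at the open-water baseline ``psi = sigmoid(0) = 0.5``.  Pressure
above baseline therefore marks pixels inside narrowing channels — exactly
the necks between merged nuclei.

Wetting and the orthogonal distance probes are computed with vectorized
directional sweeps; only channel pixels (rare) are visited pixel by pixel,
in wavefront order along the flow axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .grid import Direction, as_binary_mask

__all__ = [
    "FlowParams",
    "ChannelProbe",
    "PressureField",
    "sigmoid",
    "wet_propagate",
    "orthogonal_distances",
    "distance_to_object",
    "delta_constriction",
    "pressure_field",
    "compute_all_fields",
    "combine_pressure",
]

_COS45 = math.cos(math.radians(45.0))


@dataclass(frozen=True)
class FlowParams:
    """Parameters of a directional flow.

    Parameters
    ----------
    alpha : Direction
        Flow direction.
    beta : float
        Divergence half-angle in degrees, ``0 < beta < 90``.  With the
        default 45° a flow step may deviate by one compass notch from the
        axis; the diagonal weight cos(θ−α) would vanish at 90°, so the cone
        is capped below the perpendicular.
    tau : float
        Distance threshold in pixels: a pixel is inside a channel when the
        larger of its two orthogonal obstacle distances drops below tau.
    """

    alpha: Direction
    beta: float = 45.0
    tau: float = 10.0

    def __post_init__(self) -> None:
        if not (0 < self.beta < 90):
            raise ValueError(f"beta must be in (0, 90), got {self.beta}")
        if not self.tau > 0:
            raise ValueError(f"tau must be positive, got {self.tau}")


@dataclass(frozen=True)
class ChannelProbe:
    """Orthogonal obstacle distances at one background pixel."""

    d1: float
    d2: float

    @property
    def dmax(self) -> float:
        return max(self.d1, self.d2)


@dataclass
class PressureField:
    """Per-pixel result of one directional flow."""

    alpha: Direction
    wet: np.ndarray
    psi: np.ndarray
    constriction: np.ndarray
    dmax: np.ndarray = field(repr=False)
    tau: float = 10.0


def sigmoid(x):
    """Logistic function 1/(1 + e^-x) with unit slope.

    Accepts scalars or arrays; raises on non-finite input.
    """
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("sigmoid requires finite input")
    out = 1.0 / (1.0 + np.exp(-arr))
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


def unbounded_sentinel(shape: tuple[int, int]) -> float:
    """Distance value returned when an orthogonal scan never meets an object."""
    return float(math.ceil(math.hypot(*shape)))


# --- wetting -----------------------------------------------------------

# Grid symmetries mapping each direction onto the canonical sweep frame
# (east for axial flows, north-east for diagonal ones), with inverses.
_AXIAL_FRAME = {
    Direction.E: (lambda m: m, lambda m: m),
    Direction.W: (np.fliplr, np.fliplr),
    Direction.N: (lambda m: np.fliplr(m.T), lambda m: np.fliplr(m).T),
    Direction.S: (lambda m: m.T, lambda m: m.T),
}
_DIAGONAL_FRAME = {
    Direction.NE: (lambda m: m, lambda m: m),
    Direction.NW: (np.fliplr, np.fliplr),
    Direction.SE: (np.flipud, np.flipud),
    Direction.SW: (lambda m: m[::-1, ::-1], lambda m: m[::-1, ::-1]),
}


def _fill_right(init: np.ndarray, bg: np.ndarray) -> np.ndarray:
    """Close ``init`` under eastward steps inside contiguous background runs."""
    n = bg.size
    idx = np.arange(n)
    last_block = np.maximum.accumulate(np.where(~bg, idx, -1))
    last_init = np.maximum.accumulate(np.where(init & bg, idx, -1))
    return bg & (last_init > last_block)


def _sweep_east(bg: np.ndarray, diverge: bool) -> np.ndarray:
    """Eastward wetting: seeds on the west edge, steps E (and NE/SE)."""
    wet = np.zeros_like(bg)
    wet[:, 0] = bg[:, 0]
    for c in range(1, bg.shape[1]):
        prev = wet[:, c - 1]
        reach = prev.copy()
        if diverge:
            reach[1:] |= prev[:-1]
            reach[:-1] |= prev[1:]
        wet[:, c] = bg[:, c] & reach
    return wet


def _sweep_northeast(bg: np.ndarray, diverge: bool) -> np.ndarray:
    """North-eastward wetting: seeds on the south and west edges."""
    h, w = bg.shape
    wet = np.zeros_like(bg)
    below = np.zeros(w, dtype=bool)
    for r in range(h - 1, -1, -1):
        incoming = np.zeros(w, dtype=bool)
        incoming[0] = True  # west-edge seed
        if r == h - 1:
            incoming[:] = True  # south-edge seeds
        else:
            incoming[1:] |= below[:-1]  # NE step
            if diverge:
                incoming |= below  # N step
        init = bg[r] & incoming
        wet[r] = _fill_right(init, bg[r]) if diverge else init
        below = wet[r]
    return wet


def wet_propagate(mask, params: FlowParams) -> np.ndarray:
    """Boolean map of background pixels wetted by the flow ``params.alpha``.

    A pixel is wet iff it is a background pixel on the upstream border
    edge(s) or is reachable from a wet pixel by a unit step whose direction
    deviates from alpha by at most beta.
    """
    bg = ~as_binary_mask(mask)
    diverge = params.beta >= 45
    if params.alpha.is_diagonal:
        fwd, inv = _DIAGONAL_FRAME[params.alpha]
        return inv(_sweep_northeast(fwd(bg), diverge))
    fwd, inv = _AXIAL_FRAME[params.alpha]
    return np.ascontiguousarray(inv(_sweep_east(fwd(bg), diverge)))


# --- channel probing ---------------------------------------------------


def distance_to_object(mask, step: tuple[int, int]) -> np.ndarray:
    """Per-pixel step count to the first object pixel along ``step``.

    Scans that leave the image without meeting an object return the
    unbounded sentinel (the image border is not an obstacle).  Values on
    object pixels are meaningless for flow purposes but computed uniformly.
    """
    obj = as_binary_mask(mask)
    h, w = obj.shape
    sent = unbounded_sentinel(obj.shape)
    g = np.full((h, w), sent)
    ur, uc = step
    if ur == 0 and uc == 0:
        raise ValueError("step must be a unit direction offset")

    def _row_update(o_nb, g_nb):
        return np.where(o_nb, 1.0, np.minimum(g_nb + 1.0, sent))

    if ur != 0:
        rows = range(h) if ur < 0 else range(h - 1, -1, -1)
        for r in rows:
            rr = r + ur
            if not (0 <= rr < h):
                continue
            o, p = obj[rr], g[rr]
            if uc == 0:
                o_nb, g_nb = o, p
            elif uc > 0:
                o_nb = np.concatenate([o[1:], [False]])
                g_nb = np.concatenate([p[1:], [sent]])
            else:
                o_nb = np.concatenate([[False], o[:-1]])
                g_nb = np.concatenate([[sent], p[:-1]])
            g[r] = _row_update(o_nb, g_nb)
    else:
        cols = range(w) if uc < 0 else range(w - 1, -1, -1)
        for c in cols:
            cc = c + uc
            if not (0 <= cc < w):
                continue
            g[:, c] = _row_update(obj[:, cc], g[:, cc])
    return g


def orthogonal_distances(mask, p: tuple[int, int], alpha: Direction) -> ChannelProbe:
    """Obstacle distances from background pixel ``p`` orthogonal to the flow.

    ``d1`` scans along alpha+90°, ``d2`` along alpha−90°; each is the number
    of unit steps to the first object pixel, or the sentinel if the scan
    exits the image.
    """
    m = as_binary_mask(mask)
    if m[p]:
        raise ValueError(f"orthogonal_distances requires a background pixel, {p} is object")
    sent = unbounded_sentinel(m.shape)

    def scan(step):
        r, c = p
        n = 0
        while True:
            r += step[0]
            c += step[1]
            n += 1
            if not (0 <= r < m.shape[0] and 0 <= c < m.shape[1]):
                return sent
            if m[r, c]:
                return float(n)

    return ChannelProbe(
        d1=scan(alpha.rotated(90).offset),
        d2=scan(alpha.rotated(-90).offset),
    )


def delta_constriction(dmax_p: float, dmax_q: float) -> float:
    """Fractional change in channel width between consecutive flow points.

    Positive when the channel narrows along the flow, negative when it
    widens; bounded in [-1, 1].  The degenerate all-zero case returns 0.
    """
    if dmax_p < 0 or dmax_q < 0:
        raise ValueError("distances must be nonnegative")
    m = max(dmax_p, dmax_q)
    if m == 0:
        return 0.0
    return (dmax_p - dmax_q) / m


# --- pressure ----------------------------------------------------------


def pressure_field(mask, params: FlowParams) -> PressureField:
    """Compute wetting, constriction and fuzzy flow pressure for one flow.

    Wet pixels outside channels (dmax >= tau) carry zero constriction and
    the baseline pressure 0.5.  Inside a channel each pixel takes its
    constriction from its most axis-aligned wet predecessor,
    ``C(q) = C(p) + delta_constriction(min(dmax(p), tau), dmax(q))``
    — the clamp makes the entry step measure narrowing relative to the
    channel threshold itself, so even channels one pixel long along the
    flow register their constriction — and its pressure as the maximum
    sigmoid(C)·cos(θ−α) contribution over all wet predecessors in the
    divergence cone.
    """
    m = as_binary_mask(mask)
    alpha, tau = params.alpha, params.tau
    wet = wet_propagate(m, params)
    d_plus = distance_to_object(m, alpha.rotated(90).offset)
    d_minus = distance_to_object(m, alpha.rotated(-90).offset)
    dmax = np.maximum(d_plus, d_minus)

    psi = np.where(wet, 0.5, 0.0)
    constriction = np.zeros(m.shape)

    channel = wet & (dmax < tau)
    if channel.any():
        h, w = m.shape
        rows, cols = np.nonzero(channel)
        proj = rows * alpha.offset[0] + cols * alpha.offset[1]
        order = np.lexsort((cols, rows, proj))
        cone = [(alpha.offset, 1.0)]
        if params.beta >= 45:
            cone += [
                (alpha.rotated(45).offset, _COS45),
                (alpha.rotated(-45).offset, _COS45),
            ]
        for i in order:
            r, c = int(rows[i]), int(cols[i])
            best = None
            c_axial = None
            c_diag = None
            for (sr, sc), cosf in cone:
                pr, pc = r - sr, c - sc
                if not (0 <= pr < h and 0 <= pc < w) or not wet[pr, pc]:
                    continue
                cq = constriction[pr, pc] + delta_constriction(
                    min(dmax[pr, pc], tau), dmax[r, c]
                )
                contrib = sigmoid(cq) * cosf
                best = contrib if best is None else max(best, contrib)
                if cosf == 1.0:
                    c_axial = cq
                elif c_diag is None or cq > c_diag:
                    c_diag = cq
            if best is None:
                # a border seed inside a channel: virtual open predecessor
                cq = delta_constriction(tau, dmax[r, c])
                constriction[r, c] = cq
                psi[r, c] = sigmoid(cq)
            else:
                constriction[r, c] = c_axial if c_axial is not None else c_diag
                psi[r, c] = best
    return PressureField(
        alpha=alpha, wet=wet, psi=psi, constriction=constriction, dmax=dmax, tau=tau
    )


def compute_all_fields(mask, beta: float = 45.0, tau: float = 10.0) -> dict[Direction, PressureField]:
    """Run the flow in all eight directions."""
    return {
        d: pressure_field(mask, FlowParams(alpha=d, beta=beta, tau=tau))
        for d in Direction
    }


def combine_pressure(fields) -> np.ndarray:
    """Pointwise maximum flow pressure across the eight directional fields."""
    if isinstance(fields, dict):
        field_map = dict(fields)
    else:
        field_map = {f.alpha: f for f in fields}
    missing = [d for d in Direction if d not in field_map]
    if missing:
        raise ValueError(f"missing directions: {missing}")
    shapes = {f.psi.shape for f in field_map.values()}
    if len(shapes) != 1:
        raise ValueError(f"fields have mismatched shapes: {shapes}")
    return np.maximum.reduce([field_map[d].psi for d in Direction])
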