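import numpy as np
import pytest

from fuzzyflow.grid import DIRECTION_OFFSETS, Direction, angular_difference


def bfs_wet(mask: np.ndarray, alpha: Direction, beta: float = 45.0) -> np.ndarray:
    """Brute-force reachability oracle for directional wetting.

    Breadth-first closure over background pixels: seeds are background
    pixels on the upstream border edge(s) for ``alpha``; a move from p to
    an 8-neighbor q is allowed when the step direction deviates from alpha
    by at most beta.  Independent of the sweep-based implementation.
    """
    h, w = mask.shape
    bg = ~mask
    dr, dc = DIRECTION_OFFSETS[alpha]
    seeds = np.zeros_like(bg)
    if dc > 0:
        seeds[:, 0] = True
    if dc < 0:
        seeds[:, -1] = True
    if dr > 0:
        seeds[0, :] = True
    if dr < 0:
        seeds[-1, :] = True
    seeds &= bg
    allowed = [
        off
        for d, off in DIRECTION_OFFSETS.items()
        if angular_difference(d.value, alpha.value) <= beta
    ]
    wet = seeds.copy()
    frontier = list(zip(*np.nonzero(seeds)))
    while frontier:
        nxt = []
        for r, c in frontier:
            for sr, sc in allowed:
                q = (r + sr, c + sc)
                if 0 <= q[0] < h and 0 <= q[1] < w and bg[q] and not wet[q]:
                    wet[q] = True
                    nxt.append(q)
        frontier = nxt
    return wet


def narrowing_channel_fixture():
    """11x21 mask: two wedge obstacles forming an eastward channel whose
    width steps 9 -> 7 -> 5 -> 3 -> 1 around the center row.

    Returns (mask, tau, widths-per-column).
    """
    h, w = 11, 21
    widths = [9] * 5 + [7] * 4 + [5] * 4 + [3] * 4 + [1] * 4
    mask = np.ones((h, w), dtype=bool)
    for c, width in enumerate(widths):
        half = (width - 1) // 2
        mask[5 - half : 5 + half + 1, c] = False
    return mask, 5.0, widths


@pytest.fixture
def channel_fixture():
    return narrowing_channel_fixture()


@pytest.fixture
def dumbbell():
    from fuzzyflow.synthetic import generate_two_disc

    return generate_two_disc(10, 10, 18)


def random_obstacle_mask(rng: np.random.Generator, max_size: int = 12) -> np.ndarray:
    """Small random mask with blob-ish obstacles for oracle comparisons."""
    h = int(rng.integers(3, max_size + 1))
    w = int(rng.integers(3, max_size + 1))
    mask = rng.random((h, w)) < rng.uniform(0.1, 0.45)
    return mask
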