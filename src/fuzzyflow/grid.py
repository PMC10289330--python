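"""Pixel-grid primitives: binary masks, compass directions, border classification.

A binary mask is a 2D :class:`numpy.ndarray` of bool, ``True`` for object
pixels and ``False`` for background.  Coordinates are 0-based ``(row, col)``
with the row index increasing downward, so "north" points toward smaller
rows.  All flow machinery is built on the eight standard compass directions.
"""

from __future__ import annotations

from enum import IntEnum

import numpy as np

__all__ = [
    "Direction",
    "DIRECTION_OFFSETS",
    "OFFSET_DIRECTIONS",
    "angular_difference",
    "neighbor_direction",
    "as_binary_mask",
    "classify_pixels",
]


class Direction(IntEnum):
    """The eight compass directions, valued by their angle in degrees."""

    E = 0
    NE = 45
    N = 90
    NW = 135
    W = 180
    SW = 225
    S = 270
    SE = 315

    @property
    def offset(self) -> tuple[int, int]:
        """(row-delta, col-delta) of a unit step in this direction."""
        return DIRECTION_OFFSETS[self]

    def opposite(self) -> "Direction":
        return Direction((self.value + 180) % 360)

    def rotated(self, degrees: int) -> "Direction":
        return Direction((self.value + degrees) % 360)

    @property
    def is_diagonal(self) -> bool:
        return self.value % 90 != 0


DIRECTION_OFFSETS: dict[Direction, tuple[int, int]] = {
    Direction.E: (0, 1),
    Direction.NE: (-1, 1),
    Direction.N: (-1, 0),
    Direction.NW: (-1, -1),
    Direction.W: (0, -1),
    Direction.SW: (1, -1),
    Direction.S: (1, 0),
    Direction.SE: (1, 1),
}

OFFSET_DIRECTIONS: dict[tuple[int, int], Direction] = {
    off: d for d, off in DIRECTION_OFFSETS.items()
}


def angular_difference(a: float, b: float) -> float:
    """Smallest absolute difference between two angles, in degrees (0..180)."""
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


def neighbor_direction(p: tuple[int, int], q: tuple[int, int]) -> Direction:
    """Direction of the unit vector joining 8-neighbors ``p`` -> ``q``.

    Raises
    ------
    ValueError
        If ``q`` is not one of the eight neighbors of ``p``.
    """
    off = (q[0] - p[0], q[1] - p[1])
    try:
        return OFFSET_DIRECTIONS[off]
    except KeyError:
        raise ValueError(f"{q} is not an 8-neighbor of {p}") from None


def as_binary_mask(mask) -> np.ndarray:
    """Validate and coerce input to a 2D boolean object mask."""
    arr = np.asarray(mask)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError(f"mask must be a non-empty 2D array, got shape {arr.shape}")
    return arr.astype(bool, copy=False)


def classify_pixels(mask) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Partition a mask's grid into border, background and object pixels.

    Returns three boolean arrays ``(border, background, object)``.  The
    border is the outermost frame of the image (independent of pixel class:
    border pixels also belong to background or object); background and
    object partition the grid.
    """
    m = as_binary_mask(mask)
    border = np.zeros(m.shape, dtype=bool)
    border[0, :] = border[-1, :] = True
    border[:, 0] = border[:, -1] = True
    return border, ~m, m
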