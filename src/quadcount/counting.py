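"""Counting point particles captured by a quadrat grid.

The counting rule is the unbiased counting frame ("forbidden line" rule):
every particle must be countable by exactly one quadrat of the full tiling,
so that its inclusion probability under a uniform-random grid offset is
exactly the sampling fraction ``f``.  For zero-extent point particles —
the only particles handled here — the rule reduces to a half-open boundary
convention: within its fundamental tile, a point is counted if and only if
its local coordinates fall in ``[0, t) x [0, t)``.  The closed edges play
the role of the acceptance edges of the frame and the open edges the role
of the forbidden lines; which pair is which is immaterial for points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import BoundingBox, GridPlacement

__all__ = ["PointPattern", "QuadratSample", "locate_point", "is_counted", "sample_pattern"]


@dataclass(frozen=True)
class PointPattern:
    """A finite set of point particles with its bounding box.

    The true population size ``N`` is the number of stored points; it is
    known here by construction (annotated or synthetic patterns), which is
    what allows empirical coefficients of error to be normalized by ``N``.
    """

    points: np.ndarray
    bbox: BoundingBox

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float).reshape(-1, 2)
        object.__setattr__(self, "points", pts)
        if pts.size and not self.bbox.contains(pts).all():
            raise ValueError("all pattern points must lie within the bounding box")

    @property
    def N(self) -> int:
        return self.points.shape[0]

    def __len__(self) -> int:
        return self.N


@dataclass(frozen=True)
class QuadratSample:
    """Per-quadrat counts for one grid placement.

    Attributes
    ----------
    counts
        Map from quadrat anchor ``(i, j)`` to the number of particles it
        captured; only nonempty quadrats appear.
    Q
        Total number of particles sampled, ``sum(counts.values())``.
    n
        Number of nonempty quadrats, ``len(counts)``.
    placement
        The grid placement that produced the sample.
    """

    counts: dict[tuple[int, int], int]
    placement: GridPlacement

    @property
    def Q(self) -> int:
        return int(sum(self.counts.values()))

    @property
    def n(self) -> int:
        return len(self.counts)


def grid_frame_coords(points: np.ndarray, placement: GridPlacement) -> np.ndarray:
    """Map image-frame points into the (tilted) grid frame.

    The grid frame is the image frame rotated by ``theta`` about the
    bounding-box origin, so points are rotated by ``-theta``.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    origin = np.array(placement.bbox.origin)
    return (pts - origin) @ placement.params.rotation()


def locate_point(
    point: tuple[float, float] | np.ndarray, placement: GridPlacement
) -> tuple[tuple[int, int], tuple[float, float]]:
    """Tile index and local coordinates of one point under a placement.

    Returns ``((i, j), (lx, ly))`` with local coordinates in ``[0, T)^2``
    relative to the tile's lower-left corner ``z + (i*T, j*T)`` in the grid
    frame; reconstructing ``z + (i*T + lx, j*T + ly)`` and rotating forward
    recovers the original point.
    """
    u = grid_frame_coords(np.asarray(point, dtype=float), placement)[0]
    T = placement.T
    rel = u - np.array(placement.z)
    idx = np.floor(rel / T).astype(int)
    local = rel - idx * T
    return (int(idx[0]), int(idx[1])), (float(local[0]), float(local[1]))


def is_counted(local: tuple[float, float] | np.ndarray, t: float) -> bool:
    """Forbidden-line decision for a point particle with given tile-local coords.

    True iff the point lies in the half-open quadrat ``[0, t) x [0, t)``
    anchored at the tile's lower-left corner.  A point exactly on an open
    (forbidden) edge, e.g. ``local_x == t``, is not counted.
    """
    lx, ly = float(local[0]), float(local[1])
    return (0.0 <= lx < t) and (0.0 <= ly < t)


def sample_pattern(pattern: PointPattern, placement: GridPlacement) -> QuadratSample:
    """Count the particles of ``pattern`` captured by the placed grid.

    Every point is assigned to the unique tile containing it; it is counted
    iff it falls in the tile's half-open t x t quadrat.  An empty pattern
    yields ``Q = 0, n = 0``.
    """
    if pattern.N == 0:
        return QuadratSample(counts={}, placement=placement)
    u = grid_frame_coords(pattern.points, placement)
    T, t = placement.T, placement.t
    rel = u - np.array(placement.z)
    idx = np.floor(rel / T).astype(np.int64)
    local = rel - idx * T
    hit = (local[:, 0] < t) & (local[:, 1] < t)
    if not hit.any():
        return QuadratSample(counts={}, placement=placement)
    anchors, per_quadrat = np.unique(idx[hit], axis=0, return_counts=True)
    counts = {
        (int(i), int(j)): int(c) for (i, j), c in zip(anchors, per_quadrat)
    }
    return QuadratSample(counts=counts, placement=placement)
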