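"""Tilted systematic grids of square quadrats.

A sampling grid is a periodic lattice of square quadrats of side ``t``
spaced ``T`` apart along both axes, optionally tilted by an angle ``theta``
relative to the image x axis.  Two parametrizations are supported and kept
exactly inter-convertible:

* the geometric pair ``(t, T)`` in pixels, and
* the protocol pair ``(f, n0)`` where ``f = t**2 / T**2`` is the sampling
  fraction (the fraction of the plane covered by quadrats, hence the
  inclusion probability of any particle) and ``n0 = Bx * By / T**2`` is the
  initial number of quadrats expected over a ``Bx x By`` bounding box.

Conventions
-----------
Continuous pixel coordinates, y increasing downward (image convention),
bounding-box origin at its top-left corner.  The grid frame is the image
frame rotated by ``theta`` (counterclockwise, in the mathematical sense)
about the bounding-box origin; points are mapped into it by the inverse
rotation, after which the grid is axis-aligned with a fundamental T x T
tile ``J0``.  The uniform-random offset ``z`` lives in ``J0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BoundingBox",
    "GridParams",
    "GridPlacement",
    "DEFAULT_THETA",
    "params_from_fraction",
    "params_to_fraction",
    "place_grid",
    "enumerate_quadrats",
]

#: Default grid tilt in degrees.  A fixed arbitrary tilt guards against
#: accidental alignment of quadrat rows with particle rows, which would
#: inflate the sampling variance.
DEFAULT_THETA = 30.0


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned rectangle enclosing a point pattern.

    Parameters
    ----------
    width, height
        Side lengths ``Bx``, ``By`` in pixels; must be positive.
    x0, y0
        Image coordinates of the top-left corner (defaults 0, 0).
    """

    width: float
    height: float
    x0: float = 0.0
    y0: float = 0.0

    def __post_init__(self) -> None:
        if not (self.width > 0 and self.height > 0):
            raise ValueError(
                f"bounding box sides must be positive, got {self.width} x {self.height}"
            )

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def origin(self) -> tuple[float, float]:
        return (self.x0, self.y0)

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of points inside the (closed) box."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return (
            (pts[:, 0] >= self.x0)
            & (pts[:, 0] <= self.x0 + self.width)
            & (pts[:, 1] >= self.y0)
            & (pts[:, 1] <= self.y0 + self.height)
        )


@dataclass(frozen=True)
class GridParams:
    """Quadrat geometry: side ``t``, period ``T``, tilt ``theta`` (degrees)."""

    t: float
    T: float
    theta: float = DEFAULT_THETA

    def __post_init__(self) -> None:
        if not (0 < self.t <= self.T and np.isfinite(self.T)):
            raise ValueError(f"require 0 < t <= T < inf, got t={self.t}, T={self.T}")

    @property
    def f(self) -> float:
        """Sampling fraction t^2 / T^2, in (0, 1]."""
        return (self.t / self.T) ** 2

    def n0(self, bbox: BoundingBox) -> float:
        """Initial number of quadrats over ``bbox``: Bx*By / T^2."""
        return bbox.area / self.T**2

    def rotation(self) -> np.ndarray:
        """2x2 matrix mapping grid-frame coordinates to image offsets."""
        rad = np.deg2rad(self.theta)
        c, s = np.cos(rad), np.sin(rad)
        return np.array([[c, -s], [s, c]])


def params_from_fraction(
    f: float, n0: float, bbox: BoundingBox, theta: float = DEFAULT_THETA
) -> GridParams:
    """Build grid parameters from sampling fraction and initial quadrat count.

    Implements ``T = sqrt(Bx*By / n0)`` and ``t = T * sqrt(f)``.

    Parameters
    ----------
    f
        Sampling fraction in (0, 1].
    n0
        Initial number of quadrats (positive; need not be an integer).
    bbox
        Bounding box defining the area ``Bx * By``.
    theta
        Grid tilt in degrees.
    """
    if not (0 < f <= 1):
        raise ValueError(f"sampling fraction must lie in (0, 1], got {f}")
    if not n0 > 0:
        raise ValueError(f"initial quadrat count must be positive, got {n0}")
    T = float(np.sqrt(bbox.area / n0))
    t = T * float(np.sqrt(f))
    return GridParams(t=t, T=T, theta=theta)


def params_to_fraction(params: GridParams, bbox: BoundingBox) -> tuple[float, float]:
    """Return ``(f, n0)`` for the given geometry over ``bbox``."""
    return params.f, params.n0(bbox)


@dataclass(frozen=True)
class GridPlacement:
    """A grid with a concrete uniform-random offset over a bounding box.

    ``z`` is the position of one quadrat's lower-left corner inside the
    fundamental tile ``J0 = [0, T)^2`` of the (tilted) grid frame.  The
    offset is normalized modulo ``T`` on construction, so translating ``z``
    by a whole period yields the identical placement.
    """

    params: GridParams
    bbox: BoundingBox
    z: tuple[float, float]

    def __post_init__(self) -> None:
        T = self.params.T
        zx, zy = (float(v) % T for v in self.z)
        object.__setattr__(self, "z", (zx, zy))

    @property
    def T(self) -> float:
        return self.params.T

    @property
    def t(self) -> float:
        return self.params.t


def place_grid(
    params: GridParams, bbox: BoundingBox, rng: np.random.Generator | int | None = None
) -> GridPlacement:
    """Superimpose the grid uniformly at random: draw ``z ~ U([0,T)^2)``."""
    rng = np.random.default_rng(rng)
    z = rng.uniform(0.0, params.T, size=2)
    return GridPlacement(params=params, bbox=bbox, z=(z[0], z[1]))


def enumerate_quadrats(placement: GridPlacement) -> np.ndarray:
    """Integer anchors ``(i, j)`` of every quadrat that may intersect the box.

    The quadrat with anchor ``(i, j)`` occupies
    ``[z + (i*T, j*T), z + (i*T + t, j*T + t))`` in the grid frame.  A
    conservative superset of the quadrats actually intersecting the bounding
    box is returned (extra empty quadrats are harmless); no duplicates.
    """
    T = placement.T
    bbox = placement.bbox
    R = placement.params.rotation()
    corners = np.array(
        [
            [0.0, 0.0],
            [bbox.width, 0.0],
            [0.0, bbox.height],
            [bbox.width, bbox.height],
        ]
    )
    # bounding box corners in grid-frame coordinates
    g = corners @ R  # (R^-1 @ c^T)^T = c @ R
    zx, zy = placement.z
    # expand by one period on each side so boundary quadrats are included
    i_lo = int(np.floor((g[:, 0].min() - zx) / T)) - 1
    i_hi = int(np.ceil((g[:, 0].max() - zx) / T)) + 1
    j_lo = int(np.floor((g[:, 1].min() - zy) / T)) - 1
    j_hi = int(np.ceil((g[:, 1].max() - zy) / T)) + 1
    ii, jj = np.meshgrid(np.arange(i_lo, i_hi + 1), np.arange(j_lo, j_hi + 1))
    return np.column_stack([ii.ravel(), jj.ravel()])
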