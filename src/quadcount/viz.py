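"""Overlay rendering of a grid placement on a point pattern.

Debug/documentation aid: draws the pattern, the (tilted) quadrat outlines
and highlights the counted points.  Not pixel-exact and not part of the
estimation path.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from matplotlib.patches import Polygon

from .counting import PointPattern, grid_frame_coords, sample_pattern
from .geometry import GridPlacement, enumerate_quadrats

__all__ = ["plot_overlay"]


def plot_overlay(
    pattern: PointPattern,
    placement: GridPlacement,
    out_path: str | Path | None = None,
    image: np.ndarray | None = None,
    ax: "plt.Axes | None" = None,
):
    """Render pattern + grid; counted points in red, quadrats in blue.

    Parameters
    ----------
    pattern, placement
        What to draw.
    out_path
        If given, save a PNG there and close the figure.
    image
        Optional raster (e.g. the source photograph) drawn underneath.
    ax
        Existing axes to draw into; otherwise a new figure is created.
    """
    bbox = pattern.bbox
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 8 * bbox.height / bbox.width))
    if image is not None:
        ax.imshow(
            image,
            extent=(bbox.x0, bbox.x0 + bbox.width, bbox.y0 + bbox.height, bbox.y0),
        )

    sample = sample_pattern(pattern, placement)
    T, t = placement.T, placement.t
    R = placement.params.rotation()
    origin = np.array(bbox.origin)
    zx, zy = placement.z
    unit = np.array([[0.0, 0.0], [t, 0.0], [t, t], [0.0, t]])
    for i, j in enumerate_quadrats(placement):
        corners = (unit + [zx + i * T, zy + j * T]) @ R.T + origin
        ax.add_patch(Polygon(corners, closed=True, fill=False, edgecolor="tab:blue", lw=0.8))

    pts = pattern.points
    if pattern.N:
        u = grid_frame_coords(pts, placement)
        rel = u - [zx, zy]
        local = rel - np.floor(rel / T) * T
        hit = (local[:, 0] < t) & (local[:, 1] < t)
        ax.plot(pts[~hit, 0], pts[~hit, 1], ".", color="0.4", ms=3, label="not counted")
        ax.plot(pts[hit, 0], pts[hit, 1], "o", color="tab:red", ms=4,
                label=f"counted (Q={sample.Q}, n={sample.n})")
        ax.legend(loc="upper right", fontsize=8)

    ax.set_xlim(bbox.x0 - 0.05 * bbox.width, bbox.x0 + 1.05 * bbox.width)
    ax.set_ylim(bbox.y0 + 1.05 * bbox.height, bbox.y0 - 0.05 * bbox.height)  # image y-down
    ax.set_aspect("equal")
    ax.set_xlabel("x [px]")
    ax.set_ylabel("y [px]")
    if out_path is not None:
        ax.figure.savefig(out_path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
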