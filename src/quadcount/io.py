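"""Reading and writing point patterns.

Patterns travel as plain CSV with an ``x,y`` header (pixel units, floating
point).  Bounding box and true size live in an optional YAML sidecar
(``<pattern>.yaml`` next to ``<pattern>.csv``); when absent, the tight
bounding box of the points is used, which is also the convention for
annotated real-world patterns (cropping empty margins costs nothing and
improves efficiency).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .counting import PointPattern
from .geometry import BoundingBox

__all__ = ["read_pattern", "write_pattern", "tight_bbox", "sidecar_path"]


def sidecar_path(csv_path: str | Path) -> Path:
    """Path of the YAML metadata sidecar for a pattern CSV."""
    return Path(csv_path).with_suffix(".yaml")


def tight_bbox(points: np.ndarray, pad: float | None = None) -> BoundingBox:
    """Smallest axis-aligned box containing the points, optionally padded.

    With ``pad=None`` a relative-epsilon pad is applied so that extreme
    points remain inside the box despite floating-point rounding of
    ``x0 + width``.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if pts.shape[0] == 0:
        raise ValueError("cannot infer a bounding box from an empty pattern")
    if pad is None:
        pad = 1e-9 * (1.0 + float(np.abs(pts).max()))
    lo = pts.min(axis=0) - pad
    hi = pts.max(axis=0) + pad
    width, height = np.maximum(hi - lo, 1e-9)
    return BoundingBox(width=float(width), height=float(height), x0=float(lo[0]), y0=float(lo[1]))


def read_pattern(csv_path: str | Path, bbox: BoundingBox | None = None) -> PointPattern:
    """Load a pattern CSV, resolving the bounding box.

    Resolution order: explicit ``bbox`` argument, then the YAML sidecar,
    then the tight bounding box of the points themselves.
    """
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    if not {"x", "y"} <= set(df.columns):
        raise ValueError(f"{csv_path} must have columns 'x' and 'y', got {list(df.columns)}")
    points = df[["x", "y"]].to_numpy(dtype=float)
    if bbox is None:
        meta_path = sidecar_path(csv_path)
        if meta_path.exists():
            meta = yaml.safe_load(meta_path.read_text())
            b = meta["bbox"]
            bbox = BoundingBox(
                width=b["width"], height=b["height"],
                x0=b.get("x0", 0.0), y0=b.get("y0", 0.0),
            )
        else:
            bbox = tight_bbox(points)
    return PointPattern(points=points, bbox=bbox)


def write_pattern(pattern: PointPattern, csv_path: str | Path, **metadata) -> Path:
    """Write a pattern CSV plus its YAML sidecar; returns the CSV path.

    Extra keyword arguments (generator kind, seed, ...) are stored verbatim
    in the sidecar alongside ``n`` and ``bbox``.
    """
    csv_path = Path(csv_path)
    pd.DataFrame(pattern.points, columns=["x", "y"]).to_csv(csv_path, index=False)
    meta = {
        "n": pattern.N,
        "bbox": {
            "width": pattern.bbox.width,
            "height": pattern.bbox.height,
            "x0": pattern.bbox.x0,
            "y0": pattern.bbox.y0,
        },
        **metadata,
    }
    sidecar_path(csv_path).write_text(yaml.safe_dump(meta, sort_keys=False))
    return csv_path
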