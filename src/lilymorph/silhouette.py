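"""Orthographic silhouettes of a flower and convex-hull shape indices.

A flower is projected to the top (X-Y) or side (Y-Z) view, every projected
organ ellipse (and the ovary) is filled and unioned into a binary raster, and
the silhouette is scored with two dimensionless global indices computed from
its convex hull:

* convexity  C = L_c / L_t  (hull perimeter over silhouette perimeter),
* solidity   S = A_t / A_c  (silhouette area over hull area).

Both are 1 for a convex silhouette; notches between organs lower them.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
from PIL import Image, ImageDraw
from scipy.spatial import ConvexHull
from skimage import measure as skmeasure

from .geometry import FlowerGeometry

__all__ = ["Silhouette", "ShapeIndices", "project_silhouette", "shape_indices"]

View = Literal["top", "side"]


@dataclass
class Silhouette:
    """Binary raster of a projected flower."""

    view: View
    pixels: np.ndarray        # bool, True = flower
    resolution: float         # pixels per ovary-radius unit
    origin: tuple[float, float]  # world coordinate of pixel (row=0, col=0) center

    @property
    def foreground_count(self) -> int:
        return int(self.pixels.sum())

    def world_extent(self) -> tuple[float, float]:
        """(width, height) of the foreground bounding box in world units."""
        rows, cols = np.nonzero(self.pixels)
        if rows.size == 0:
            return (0.0, 0.0)
        return (
            float(cols.max() - cols.min() + 1) / self.resolution,
            float(rows.max() - rows.min() + 1) / self.resolution,
        )

    def save_png(self, path: str | Path) -> Path:
        import imageio.v3 as iio

        iio.imwrite(Path(path), (self.pixels.astype(np.uint8) * 255))
        return Path(path)


@dataclass(frozen=True)
class ShapeIndices:
    """Convex-hull shape descriptors of one silhouette (world units)."""

    L_t: float  # perimeter of the silhouette's outer contour
    L_c: float  # perimeter of its convex hull
    A_t: float  # area of the silhouette (largest component)
    A_c: float  # area of the convex hull
    C: float    # convexity  = L_c / L_t
    S: float    # solidity   = A_t / A_c

    def to_dict(self) -> dict[str, float]:
        return {"L_t": self.L_t, "L_c": self.L_c, "A_t": self.A_t, "A_c": self.A_c, "C": self.C, "S": self.S}


def _projected_polygons(geometry: FlowerGeometry, view: View) -> list[np.ndarray]:
    """Organ outlines projected to the view plane, as (V, 2) world coordinates."""
    cols = (0, 1) if view == "top" else (1, 2)  # top: X-Y, side: Y-Z
    return [organ.vertices[:, cols] for organ in geometry.organs]


def project_silhouette(
    geometry: FlowerGeometry, view: View = "top", resolution: float = 256.0
) -> Silhouette:
    """Rasterize the union silhouette of a flower in one orthographic view.

    Every projected organ ellipse is filled (a planar ellipse projects to an
    ellipse, possibly degenerating to a segment, which is drawn as its
    outline); the ovary contributes a disc (top) or rectangle (side). The
    raster tightly crops the silhouette with a 2-pixel margin.
    """
    if resolution < 32:
        raise ValueError("resolution must be >= 32 px per radius unit")
    if view not in ("top", "side"):
        raise ValueError(f"view must be 'top' or 'side', got {view!r}")
    polygons = _projected_polygons(geometry, view)

    r_b, h_b = geometry.r_b, geometry.h_b
    if view == "top":
        base_bounds = np.array([[-r_b, -r_b], [r_b, r_b]], dtype=float)
    else:
        base_bounds = np.array([[-r_b, 0.0], [r_b, h_b]], dtype=float)
    pts = np.vstack([base_bounds] + polygons) if polygons else base_bounds
    lo = pts.min(axis=0)
    hi = pts.max(axis=0)

    margin = 2
    width = int(np.ceil((hi[0] - lo[0]) * resolution)) + 2 * margin + 1
    height = int(np.ceil((hi[1] - lo[1]) * resolution)) + 2 * margin + 1
    canvas = Image.new("1", (width, height), 0)
    painter = ImageDraw.Draw(canvas)

    def to_px(xy: np.ndarray) -> list[tuple[float, float]]:
        cols = (xy[:, 0] - lo[0]) * resolution + margin
        rows = (xy[:, 1] - lo[1]) * resolution + margin
        return list(zip(cols.tolist(), rows.tolist()))

    # ovary footprint
    if view == "top":
        r_px = r_b * resolution
        (cx, cy), = to_px(np.array([[0.0, 0.0]]))
        painter.ellipse([cx - r_px, cy - r_px, cx + r_px, cy + r_px], fill=1, outline=1)
    else:
        corners = np.array([[-r_b, 0.0], [r_b, 0.0], [r_b, h_b], [-r_b, h_b]])
        painter.polygon(to_px(corners), fill=1, outline=1)

    # fill + outline: the outline keeps degenerate (edge-on) projections visible
    for poly in polygons:
        painter.polygon(to_px(poly), fill=1, outline=1)

    pixels = np.asarray(canvas, dtype=bool)
    origin = (float(lo[0] - margin / resolution), float(lo[1] - margin / resolution))
    return Silhouette(view=view, pixels=pixels, resolution=float(resolution), origin=origin)


def shape_indices(sil: Silhouette) -> ShapeIndices:
    """Convexity and solidity of the silhouette's largest connected component.

    The outer contour is extracted by border following (marching squares at
    the 0.5 level) and simplified with Douglas-Peucker at 1-pixel tolerance
    to remove the staircase bias of pixel-chain perimeters; its polygonal
    length gives L_t, the convex hull of the contour gives L_c and A_c, and
    the component's pixel count gives A_t.
    """
    labels = skmeasure.label(sil.pixels)
    if labels.max() == 0:
        raise ValueError("silhouette has no foreground")
    component = labels == np.argmax(np.bincount(labels.ravel())[1:]) + 1

    contours = skmeasure.find_contours(component.astype(float), 0.5)
    outer = max(contours, key=lambda c: _polyline_length(c))
    outer = skmeasure.approximate_polygon(outer, tolerance=1.0)
    L_t_px = _polyline_length(outer, closed=True)
    hull = ConvexHull(outer)
    L_c_px = hull.area      # in 2-D, .area is the hull perimeter
    A_c_px = hull.volume    # and .volume the enclosed area
    A_t_px = float(component.sum())

    scale = 1.0 / sil.resolution
    L_t, L_c = L_t_px * scale, L_c_px * scale
    A_t, A_c = A_t_px * scale**2, A_c_px * scale**2
    return ShapeIndices(L_t=L_t, L_c=L_c, A_t=A_t, A_c=A_c, C=L_c / L_t, S=A_t / A_c)


def _polyline_length(points: np.ndarray, closed: bool = False) -> float:
    d = np.diff(points, axis=0)
    length = float(np.hypot(d[:, 0], d[:, 1]).sum())
    if closed and not np.allclose(points[0], points[-1]):
        length += float(np.hypot(*(points[0] - points[-1])))
    return length
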