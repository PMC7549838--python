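"""3-D assembly of a flower: planar organ ellipses placed around the ovary.

Each organ is a rigid planar ellipse anchored to the lateral surface of the
ovary cylinder at one end of its longitudinal axis, tilted by its elevation
angle from the horizontal plane toward the flower axis (+Z). The assembled
geometry can be exported as an ASCII OBJ/PLY triangle mesh.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import trimesh

from .model import FlowerParams, OrganSpec, build_organ_sequence

__all__ = ["PlacedOrgan", "FlowerGeometry", "place_organ", "build_flower_geometry", "export_mesh"]

Anchor = Literal["base", "center"]


@dataclass(frozen=True)
class PlacedOrgan:
    """One organ's 3-D outline: a closed planar polyline plus its source spec."""

    spec: OrganSpec
    vertices: np.ndarray  # (V, 3) ellipse boundary; closed implicitly
    degenerate: bool      # True when a semi-axis clamped to zero

    @property
    def identity(self) -> str:
        return self.spec.identity


@dataclass
class FlowerGeometry:
    """Assembled flower: ovary cylinder + placed organ ellipses."""

    params: FlowerParams
    organs: list[PlacedOrgan] = field(default_factory=list)

    @property
    def r_b(self) -> float:
        return self.params.r_b

    @property
    def h_b(self) -> float:
        return self.params.h_b


def place_organ(
    spec: OrganSpec,
    params: FlowerParams,
    vertices_per_ellipse: int = 64,
    anchor: Anchor = "base",
) -> np.ndarray:
    """Boundary polyline of one organ ellipse in 3-D, shape (V, 3).

    The attachment point A = (r_b cosφ, r_b sinφ, h) lies on the ovary
    surface. The ellipse spans the tangential direction t̂ = (−sinφ, cosφ, 0)
    (transverse semi-axis x) and the tilted direction
    d̂ = cos(o)·r̂ + sin(o)·ẑ (longitudinal semi-axis y): at o = 0° the organ
    lies flat, at o = 90° it stands parallel to the flower axis. With the
    default ``anchor="base"`` the ellipse touches the ovary at the basal end
    of its longitudinal axis, so its center sits at A + y·d̂.
    """
    if vertices_per_ellipse < 8:
        raise ValueError("vertices_per_ellipse must be >= 8")
    phi = np.deg2rad(spec.phi)
    o = np.deg2rad(spec.o)
    r_hat = np.array([np.cos(phi), np.sin(phi), 0.0])
    t_hat = np.array([-np.sin(phi), np.cos(phi), 0.0])
    d_hat = np.cos(o) * r_hat + np.array([0.0, 0.0, np.sin(o)])
    attachment = params.r_b * r_hat + np.array([0.0, 0.0, spec.h])
    center = attachment + (spec.y * d_hat if anchor == "base" else 0.0)
    theta = np.linspace(0.0, 2.0 * np.pi, vertices_per_ellipse, endpoint=False)
    return (
        center
        + spec.x * np.cos(theta)[:, None] * t_hat
        + spec.y * np.sin(theta)[:, None] * d_hat
    )


def build_flower_geometry(
    params: FlowerParams,
    vertices_per_ellipse: int = 64,
    anchor: Anchor = "base",
) -> FlowerGeometry:
    """Place every organ of the flower; deterministic in the parameters."""
    organs = []
    for spec in build_organ_sequence(params):
        vertices = place_organ(spec, params, vertices_per_ellipse, anchor)
        organs.append(PlacedOrgan(spec=spec, vertices=vertices, degenerate=spec.x == 0 or spec.y == 0))
    return FlowerGeometry(params=params, organs=organs)


def top_view_radial_extent(geometry: FlowerGeometry) -> float:
    """Largest horizontal distance of any organ vertex from the flower axis."""
    radii = [np.hypot(o.vertices[:, 0], o.vertices[:, 1]).max() for o in geometry.organs]
    return max(radii, default=0.0)


def _ellipse_fan(vertices: np.ndarray) -> trimesh.Trimesh:
    """Triangle fan filling a closed planar polyline from its centroid."""
    center = vertices.mean(axis=0)
    pts = np.vstack([center, vertices])
    v = len(vertices)
    faces = [[0, 1 + i, 1 + (i + 1) % v] for i in range(v)]
    return trimesh.Trimesh(vertices=pts, faces=faces, process=False)


def _ovary_mesh(geometry: FlowerGeometry, sections: int = 64) -> trimesh.Trimesh | None:
    if geometry.h_b <= 0:
        return None
    cylinder = trimesh.creation.cylinder(radius=geometry.r_b, height=geometry.h_b, sections=sections)
    cylinder.apply_translation([0.0, 0.0, geometry.h_b / 2.0])  # base at Z = 0
    return cylinder


def as_mesh(geometry: FlowerGeometry) -> trimesh.Trimesh:
    """Triangle mesh of the whole flower (ovary + organ fans, degenerate skipped)."""
    parts = []
    ovary = _ovary_mesh(geometry)
    if ovary is not None:
        parts.append(ovary)
    parts.extend(_ellipse_fan(o.vertices) for o in geometry.organs if not o.degenerate)
    if not parts:
        raise ValueError("geometry has no meshable components")
    return trimesh.util.concatenate(parts)


def export_mesh(geometry: FlowerGeometry, path: str | Path) -> Path:
    """Write the flower as an ASCII OBJ or PLY triangle mesh (by extension)."""
    path = Path(path)
    mesh = as_mesh(geometry)
    suffix = path.suffix.lower()
    if suffix == ".obj":
        mesh.export(path)
    elif suffix == ".ply":
        path.write_bytes(trimesh.exchange.ply.export_ply(mesh, encoding="ascii"))
    else:
        raise ValueError(f"unsupported mesh format {suffix!r}; use .obj or .ply")
    return path


def export_organ_csv(geometry: FlowerGeometry, path: str | Path) -> Path:
    """Dump every organ's polyline vertices as CSV (organ, vertex, x, y, z)."""
    import pandas as pd

    rows = []
    for organ in geometry.organs:
        for j, (x, y, z) in enumerate(organ.vertices):
            rows.append((organ.spec.index, j, x, y, z))
    pd.DataFrame(rows, columns=["organ", "vertex", "x", "y", "z"]).to_csv(path, index=False)
    return Path(path)
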