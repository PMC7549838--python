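"""Theoretical morphospace sweeps over 2-parameter grids.

A sweep varies two model parameters over inclusive grids, builds one flower
per cell, and optionally renders silhouette thumbnails and computes
convexity/solidity per view. Four canonical sweeps are provided as presets:
openness (o_max x o_min), thresholds (t_x x t_y), shortening rates
(s_x1 x s_y1) and initial lengths (x_0 x y_0).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .geometry import build_flower_geometry
from .model import FlowerParams
from .silhouette import Silhouette, project_silhouette, shape_indices

__all__ = ["SweepConfig", "MorphospaceResult", "sweep", "preset", "PRESET_NAMES",
           "render_montage", "index_heatmap"]

_PARAM_NAMES = {f.name for f in dataclasses.fields(FlowerParams)}


def _inclusive_grid(lo: float, hi: float, step: float) -> np.ndarray:
    """Arithmetic sequence from lo to hi inclusive (float-safe endpoint)."""
    count = int(np.floor((hi - lo) / step + 0.5)) + 1
    return lo + step * np.arange(count)


@dataclass
class SweepConfig:
    """Definition of one 2-parameter morphospace sweep."""

    axis1: str
    axis2: str
    values1: np.ndarray
    values2: np.ndarray
    base: FlowerParams = field(default_factory=FlowerParams)
    outputs: tuple[str, ...] = ("indices-top", "indices-side")

    def __post_init__(self) -> None:
        for name in (self.axis1, self.axis2):
            if name not in _PARAM_NAMES:
                raise ValueError(f"{name!r} is not a model parameter")
        self.values1 = np.asarray(self.values1, dtype=float)
        self.values2 = np.asarray(self.values2, dtype=float)
        if self.values1.size == 0 or self.values2.size == 0:
            raise ValueError("sweep axes must contain at least one value")
        for out in self.outputs:
            if out not in ("render", "indices-top", "indices-side"):
                raise ValueError(f"unknown output product {out!r}")

    @classmethod
    def from_ranges(cls, axis1, range1, step1, axis2, range2, step2, **kwargs) -> "SweepConfig":
        return cls(
            axis1=axis1,
            axis2=axis2,
            values1=_inclusive_grid(range1[0], range1[1], step1),
            values2=_inclusive_grid(range2[0], range2[1], step2),
            **kwargs,
        )


#: Canonical sweeps. Ranges and printed resolutions follow the reference
#: parameter table; the openness and threshold grids use 7 and 6 values.
_PRESETS = {
    "openness": dict(axis1="o_max", range1=(0.0, 90.0), step1=15.0,
                     axis2="o_min", range2=(0.0, 90.0), step2=15.0),
    "thresholds": dict(axis1="t_x", range1=(0.0, 1.0), step1=0.2,
                       axis2="t_y", range2=(0.0, 1.0), step2=0.2),
    "shortening": dict(axis1="s_x1", range1=(0.0, 1.0), step1=0.04,
                       axis2="s_y1", range2=(0.0, 3.5), step2=0.14),
    "initial": dict(axis1="x_0", range1=(0.5, 9.0), step1=0.5,
                    axis2="y_0", range2=(0.5, 9.0), step2=0.5),
}
PRESET_NAMES = tuple(_PRESETS)


def preset(name: str, base: FlowerParams | None = None, outputs=("indices-top", "indices-side")) -> SweepConfig:
    """One of the four canonical sweep configurations."""
    if name not in _PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    spec = _PRESETS[name]
    return SweepConfig.from_ranges(
        spec["axis1"], spec["range1"], spec["step1"],
        spec["axis2"], spec["range2"], spec["step2"],
        base=base if base is not None else FlowerParams(),
        outputs=tuple(outputs),
    )


@dataclass
class MorphospaceResult:
    """Complete grid of one sweep: per-cell parameters, indices, thumbnails."""

    config: SweepConfig
    params_grid: list[list[FlowerParams]]                 # [i2][i1]
    indices: dict[str, dict[str, np.ndarray]]             # view -> {"S": M, "C": M}, M[i2, i1]
    thumbnails: list[list[Silhouette | None]] | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return (self.config.values2.size, self.config.values1.size)

    def index_matrix(self, index: Literal["S", "C"], view: str) -> np.ndarray:
        if view not in self.indices or index not in self.indices[view]:
            raise KeyError(f"index {index!r} for view {view!r} was not computed")
        return self.indices[view][index]

    def index_frame(self, index: Literal["S", "C"], view: str) -> pd.DataFrame:
        """Matrix as a labelled DataFrame (rows = axis2 values, cols = axis1 values)."""
        return pd.DataFrame(
            self.index_matrix(index, view),
            index=pd.Index(self.config.values2, name=self.config.axis2),
            columns=pd.Index(self.config.values1, name=self.config.axis1),
        )


def sweep(config: SweepConfig, resolution: float = 128.0, vertices_per_ellipse: int = 64) -> MorphospaceResult:
    """Evaluate every grid cell; deterministic, cells independent."""
    views = [out.split("-")[1] for out in config.outputs if out.startswith("indices-")]
    want_render = "render" in config.outputs
    n2, n1 = config.values2.size, config.values1.size

    params_grid: list[list[FlowerParams]] = []
    indices = {view: {"S": np.empty((n2, n1)), "C": np.empty((n2, n1))} for view in views}
    thumbnails: list[list[Silhouette | None]] | None = [[None] * n1 for _ in range(n2)] if want_render else None

    for i2, v2 in enumerate(config.values2):
        row_params = []
        for i1, v1 in enumerate(config.values1):
            cell = config.base.replace(**{config.axis1: float(v1), config.axis2: float(v2)})
            row_params.append(cell)
            if views or want_render:
                geometry = build_flower_geometry(cell, vertices_per_ellipse=vertices_per_ellipse)
                for view in views:
                    sil = project_silhouette(geometry, view=view, resolution=resolution)
                    idx = shape_indices(sil)
                    indices[view]["S"][i2, i1] = idx.S
                    indices[view]["C"][i2, i1] = idx.C
                    if want_render and view == "top":
                        thumbnails[i2][i1] = sil
                if want_render and "top" not in views:
                    thumbnails[i2][i1] = project_silhouette(geometry, view="top", resolution=resolution)
        params_grid.append(row_params)

    return MorphospaceResult(config=config, params_grid=params_grid, indices=indices, thumbnails=thumbnails)


def render_montage(result: MorphospaceResult, path: str | Path, view: str = "top") -> Path:
    """Grid montage of per-cell silhouette thumbnails with axis labels."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if result.thumbnails is None:
        raise ValueError("sweep was run without the 'render' output")
    n2, n1 = result.shape
    fig, axes = plt.subplots(n2, n1, figsize=(1.2 * n1, 1.2 * n2), squeeze=False)
    for i2 in range(n2):
        for i1 in range(n1):
            ax = axes[n2 - 1 - i2][i1]  # axis2 increases upward
            sil = result.thumbnails[i2][i1]
            ax.imshow(sil.pixels, cmap="gray", origin="lower")
            ax.set_xticks([])
            ax.set_yticks([])
            if i2 == 0:
                ax.set_xlabel(f"{result.config.values1[i1]:g}", fontsize=7)
            if i1 == 0:
                ax.set_ylabel(f"{result.config.values2[i2]:g}", fontsize=7)
    fig.supxlabel(result.config.axis1)
    fig.supylabel(result.config.axis2)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def index_heatmap(
    result: MorphospaceResult,
    index: Literal["S", "C"],
    view: str,
    out_dir: str | Path,
    points: pd.DataFrame | None = None,
) -> tuple[Path, Path]:
    """Write the index matrix as CSV and a heatmap PNG; returns (csv, png).

    ``points`` optionally overlays measured flowers: a DataFrame with columns
    named after the two sweep axes (plus optional ``shape_class``).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frame = result.index_frame(index, view)
    stem = f"{view}_{'solidity' if index == 'S' else 'convexity'}"
    csv_path = out_dir / f"{stem}.csv"
    frame.to_csv(csv_path)

    cfg = result.config
    fig, ax = plt.subplots(figsize=(6, 5))
    extent = [cfg.values1[0], cfg.values1[-1], cfg.values2[0], cfg.values2[-1]]
    im = ax.imshow(frame.to_numpy(), origin="lower", aspect="auto", extent=extent, cmap="viridis")
    if points is not None and {cfg.axis1, cfg.axis2} <= set(points.columns):
        ax.scatter(points[cfg.axis1], points[cfg.axis2], c="red", s=12, edgecolors="white", linewidths=0.4)
    ax.set_xlabel(cfg.axis1)
    ax.set_ylabel(cfg.axis2)
    ax.set_title(f"{'solidity S' if index == 'S' else 'convexity C'} ({view} view)")
    fig.colorbar(im, ax=ax)
    png_path = out_dir / f"{stem}.png"
    fig.savefig(png_path, dpi=120)
    plt.close(fig)
    return csv_path, png_path
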