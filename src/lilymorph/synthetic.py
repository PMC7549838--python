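"""Synthetic measurement fixtures: noisy organ tables, organ-sheet images,
and cohorts of flowers drawn from class-wise parameter distributions.

These generators emulate the measurement pipeline's inputs from the forward
model, so the whole measure → estimate → summarize chain can be exercised and
validated without any external data. All randomness flows from explicit
seeds; identical seeds give bit-identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import draw as skdraw

from .measurement import MeasurementTable
from .model import FlowerParams, organ_sizes

__all__ = [
    "NoiseModel",
    "CohortSpec",
    "synth_measurement_table",
    "synth_organ_sheet",
    "synth_cohort",
    "REFERENCE_CLASS_STATS",
]

#: Default measured ovary radius for synthetic flowers, mm (typical Nymphaea
#: ovary scale on a 300-dpi flatbed scan).
DEFAULT_RB_MM = 10.0


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative Gaussian length noise: length -> length * (1 + eps)."""

    sigma_rel: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_rel < 0:
            raise ValueError("sigma_rel must be non-negative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def synth_measurement_table(
    params: FlowerParams,
    noise: NoiseModel | None = None,
    flower_id: str = "synthetic",
    shape_class: str = "unknown",
    r_b_mm: float = DEFAULT_RB_MM,
    rng: np.random.Generator | None = None,
) -> MeasurementTable:
    """Ordered organ-length table generated from the forward model.

    Full lengths are 2 x (model semi-axis) x r_b_mm, perturbed by the noise
    model; organs are listed outermost first, matching the detachment order
    of a real measurement session.
    """
    noise = noise or NoiseModel(sigma_rel=0.0)
    rng = rng if rng is not None else noise.rng()
    semi = organ_sizes(params)  # ovary-radius units
    full = 2.0 * semi * r_b_mm
    if noise.sigma_rel > 0:
        full = full * (1.0 + rng.normal(0.0, noise.sigma_rel, size=full.shape))
    organs = pd.DataFrame(
        {
            "organ_index": np.arange(params.n),
            "transverse_mm": full[:, 0],
            "longitudinal_mm": full[:, 1],
        }
    )
    return MeasurementTable(
        flower_id=flower_id, organs=organs, r_b=r_b_mm, shape_class=shape_class, scale=None
    )


def synth_organ_sheet(
    table: MeasurementTable,
    scale: float,
    columns: int = 5,
    margin_px: int = 10,
    foreground: int = 220,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Draw the table's organs as filled ellipses on a dark sheet.

    Organs are laid out row-major (reading order) on a black background, the
    longitudinal axis vertical, each inside a cell sized to the largest organ
    plus ``margin_px`` so no two components touch. Returns the uint8 image and
    a ground-truth DataFrame (organ_index, transverse_mm, longitudinal_mm,
    center_r, center_c).
    """
    if margin_px < 2:
        raise ValueError("margin_px must be >= 2 to keep components separated")
    organs = table.organs
    major_px = organs["longitudinal_mm"].to_numpy() / scale
    minor_px = organs["transverse_mm"].to_numpy() / scale

    drawable = (major_px >= 1.0) & (minor_px >= 1.0)
    if not drawable.all():
        warnings.warn(
            f"skipping {int((~drawable).sum())} zero/sub-pixel organ(s) on the sheet",
            stacklevel=2,
        )
    cell_h = int(np.ceil(major_px[drawable].max())) + 2 * margin_px if drawable.any() else 4 * margin_px
    cell_w = int(np.ceil(minor_px[drawable].max())) + 2 * margin_px if drawable.any() else 4 * margin_px
    count = int(drawable.sum())
    if count == 0:
        raise ValueError("no drawable organs in the table")
    rows = int(np.ceil(count / columns))
    image = np.zeros((rows * cell_h, columns * cell_w), dtype=np.uint8)

    truth_rows = []
    slot = 0
    for i in range(len(organs)):
        if not drawable[i]:
            continue
        r_cell, c_cell = divmod(slot, columns)
        center = (r_cell * cell_h + cell_h / 2.0, c_cell * cell_w + cell_w / 2.0)
        rr, cc = skdraw.ellipse(
            center[0], center[1], major_px[i] / 2.0, minor_px[i] / 2.0, shape=image.shape
        )
        image[rr, cc] = foreground
        truth_rows.append(
            {
                "organ_index": int(organs["organ_index"].iloc[i]),
                "transverse_mm": organs["transverse_mm"].iloc[i],
                "longitudinal_mm": organs["longitudinal_mm"].iloc[i],
                "center_r": center[0],
                "center_c": center[1],
            }
        )
        slot += 1
    return image, pd.DataFrame(truth_rows)


#: Class-wise (mean, std) of the four estimated parameters seeding the cohort
#: generator, from the reference measurement summary of 100 specimens.
REFERENCE_CLASS_STATS: dict[str, dict[str, tuple[float, float]]] = {
    "stellate": {"s_y1": (0.919, 0.286), "s_x1": (0.328, 0.140), "y_0": (3.714, 0.531), "x_0": (0.986, 0.166)},
    "cup-like": {"s_y1": (0.780, 0.236), "s_x1": (0.430, 0.130), "y_0": (3.080, 0.469), "x_0": (0.962, 0.151)},
    "other": {"s_y1": (0.508, 0.074), "s_x1": (0.241, 0.081), "y_0": (3.194, 0.399), "x_0": (0.835, 0.084)},
    "unknown": {"s_y1": (0.656, 0.265), "s_x1": (0.255, 0.111), "y_0": (3.110, 0.539), "x_0": (0.877, 0.146)},
}

#: Specimen counts per class in the reference cohort.
REFERENCE_CLASS_COUNTS = {"stellate": 20, "cup-like": 34, "other": 8, "unknown": 38}


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a synthetic cohort of measured flowers.

    Per shape class, (x_0, y_0, s_x1, s_y1) are drawn from independent
    Gaussians truncated at zero; all remaining model parameters stay at their
    defaults (100 organs, 20% tepal threshold). Measurement noise follows the
    cohort's NoiseModel.
    """

    class_stats: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {k: dict(v) for k, v in REFERENCE_CLASS_STATS.items()}
    )
    flowers_per_class: dict[str, int] = field(default_factory=lambda: dict(REFERENCE_CLASS_COUNTS))
    organs_per_flower: int = 100
    noise: NoiseModel = field(default_factory=lambda: NoiseModel(sigma_rel=0.05))
    base: FlowerParams = field(default_factory=FlowerParams)

    def __post_init__(self) -> None:
        for cls, stats in self.class_stats.items():
            for name, (mean, std) in stats.items():
                if mean <= 0:
                    raise ValueError(f"{cls}/{name}: mean must be positive")
                if std < 0:
                    raise ValueError(f"{cls}/{name}: std must be non-negative")
        for cls, count in self.flowers_per_class.items():
            if count < 1:
                raise ValueError(f"{cls}: flower count must be >= 1")
        if self.organs_per_flower < 1:
            raise ValueError("organs_per_flower must be >= 1")

    @property
    def tepal_count(self) -> int:
        return int(np.floor(self.organs_per_flower * max(self.base.t_x, self.base.t_y) + 0.5))


def _draw_truncated(rng: np.random.Generator, mean: float, std: float) -> float:
    """Gaussian draw resampled until positive (truncation at zero)."""
    if std == 0:
        return mean
    for _ in range(1000):
        value = rng.normal(mean, std)
        if value > 0:
            return float(value)
    raise RuntimeError("truncated Gaussian failed to produce a positive draw")


def synth_cohort(
    spec: CohortSpec, seed: int = 0
) -> list[tuple[MeasurementTable, FlowerParams]]:
    """Generate a cohort of (noisy measurement table, true parameters) pairs."""
    rng = np.random.default_rng(seed)
    cohort = []
    for cls, count in spec.flowers_per_class.items():
        stats = spec.class_stats[cls]
        for k in range(count):
            drawn = {name: _draw_truncated(rng, *stats[name]) for name in ("x_0", "y_0", "s_x1", "s_y1")}
            truth = spec.base.replace(n=spec.organs_per_flower, **drawn)
            table = synth_measurement_table(
                truth,
                noise=spec.noise,
                flower_id=f"{cls}-{k:03d}",
                shape_class=cls,
                rng=rng,
            )
            cohort.append((table, truth))
    return cohort
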