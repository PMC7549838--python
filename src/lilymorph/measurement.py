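"""Measuring ordered floral-organ sequences and estimating model parameters.

Organ sheets (flatbed scans of detached organs on a dark background) are
binarized and each organ approximated by its moment-equivalent ellipse; the
resulting ordered length sequences — or CSV tables of the same schema — are
standardized by the ovary radius and fitted by ordinary least squares against
the relative position l_i = i/n to recover the initial lengths (x_0, y_0) and
the tepal-phase shortening rates (s_x1, s_y1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from skimage import filters as skfilters
from skimage import measure as skmeasure

__all__ = [
    "MeasurementTable",
    "RegressionFit",
    "EstimatedParams",
    "measure_organ_sheet",
    "estimate_params",
    "summarize_measurements",
    "read_measurement_csv",
    "write_measurement_csv",
]

SHAPE_CLASSES = ("stellate", "cup-like", "other", "unknown")

#: Column order used by the Table-3-style summary.
PARAM_COLUMNS = ("s_y1", "s_x1", "y_0", "x_0")

Convention = Literal["semi", "full"]


@dataclass
class MeasurementTable:
    """Ordered per-organ measurements of one flower.

    ``organs`` holds one row per organ ordered from the outermost
    (``organ_index`` consecutive from 0) with full axis lengths in mm:
    columns ``organ_index``, ``transverse_mm``, ``longitudinal_mm`` and
    optionally ``touches_border``.
    """

    flower_id: str
    organs: pd.DataFrame
    r_b: float = float("nan")            # measured ovary radius, mm
    shape_class: str = "unknown"
    scale: float | None = None           # mm per pixel when image-derived

    def __post_init__(self) -> None:
        if self.shape_class not in SHAPE_CLASSES:
            raise ValueError(f"shape_class must be one of {SHAPE_CLASSES}, got {self.shape_class!r}")
        required = {"organ_index", "transverse_mm", "longitudinal_mm"}
        if not required <= set(self.organs.columns):
            raise ValueError(f"organs table must have columns {sorted(required)}")
        idx = self.organs["organ_index"].to_numpy()
        if not np.array_equal(idx, np.arange(len(idx))):
            raise ValueError("organ_index must be consecutive from 0")

    @property
    def n(self) -> int:
        return len(self.organs)


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit of standardized organ length against relative position."""

    a_x: float   # slope, transverse
    b_x: float   # intercept, transverse
    a_y: float   # slope, longitudinal
    b_y: float   # intercept, longitudinal
    r2_x: float
    r2_y: float
    n_used: int


@dataclass(frozen=True)
class EstimatedParams:
    """Recovered tepal-phase model parameters, in ovary-radius units."""

    x_0: float
    y_0: float
    s_x1: float
    s_y1: float

    def to_dict(self) -> dict[str, float]:
        return {"x_0": self.x_0, "y_0": self.y_0, "s_x1": self.s_x1, "s_y1": self.s_y1}


# ---------------------------------------------------------------------------
# Image measurement


def measure_organ_sheet(
    image: np.ndarray,
    scale: float,
    flower_id: str = "sheet",
    threshold: float | None = None,
    min_area: int = 100,
) -> MeasurementTable:
    """Measure organ axis lengths from a scanned sheet of detached organs.

    The image (grayscale, organs bright on dark background) is binarized with
    a global threshold (Otsu unless ``threshold`` is given), connected
    components below ``min_area`` pixels are discarded, and each remaining
    component is reduced to its moment-equivalent ellipse: the major axis is
    reported as the longitudinal full length and the minor axis as the
    transverse full length, both calibrated by ``scale`` (mm per pixel).
    Components are ordered row-major by centroid (reading order); components
    touching the image border are flagged in ``touches_border``.
    """
    image = np.asarray(image)
    if image.ndim == 3:
        image = image.mean(axis=2)
    if threshold is None:
        if image.min() == image.max():
            raise ValueError("no organs detected: image is constant")
        threshold = skfilters.threshold_otsu(image)
    binary = image > threshold
    labels = skmeasure.label(binary)
    props = [p for p in skmeasure.regionprops(labels) if p.area >= min_area]
    if not props:
        raise ValueError("no organs detected")

    h, w = binary.shape
    rows = []
    for p in props:
        minr, minc, maxr, maxc = p.bbox
        rows.append(
            {
                "centroid_r": p.centroid[0],
                "centroid_c": p.centroid[1],
                "longitudinal_mm": p.axis_major_length * scale,
                "transverse_mm": p.axis_minor_length * scale,
                "touches_border": minr == 0 or minc == 0 or maxr == h or maxc == w,
                "area_px": p.area,
            }
        )
    frame = pd.DataFrame(rows)

    # Row-major ordering: group centroids into bands within half the median
    # component height, then sort left-to-right inside each band.
    band_height = np.median([p.bbox[2] - p.bbox[0] for p in props])
    frame = frame.sort_values("centroid_r").reset_index(drop=True)
    band = np.zeros(len(frame), dtype=int)
    for i in range(1, len(frame)):
        same = frame.loc[i, "centroid_r"] - frame.loc[i - 1, "centroid_r"] < 0.5 * band_height
        band[i] = band[i - 1] + (0 if same else 1)
    frame["band"] = band
    frame = frame.sort_values(["band", "centroid_c"]).reset_index(drop=True)
    frame["organ_index"] = np.arange(len(frame))

    organs = frame[["organ_index", "transverse_mm", "longitudinal_mm", "touches_border"]]
    return MeasurementTable(flower_id=flower_id, organs=organs, scale=scale)


# ---------------------------------------------------------------------------
# Parameter estimation


def _ols(l: np.ndarray, values: np.ndarray) -> tuple[float, float, float]:
    """(slope, intercept, r²) with r² = 1 for an exactly constant response."""
    if np.unique(l).size < 2:
        raise ValueError("singular fit: all relative positions identical")
    if np.allclose(values, values[0]):
        return 0.0, float(values[0]), 1.0
    fit = stats.linregress(l, values)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue**2)


def estimate_params(
    table: MeasurementTable,
    tepal_count: int | None = None,
    r_b: float | None = None,
    convention: Convention = "semi",
) -> tuple[RegressionFit, EstimatedParams]:
    """Estimate (x_0, y_0, s_x1, s_y1) from an ordered measurement table.

    Lengths are standardized by the measured ovary radius and regressed
    against l_i = i/n (n = total organs in the table) over the tepal range
    (the first ``tepal_count`` organs; all organs when absent). Under the
    default ``convention="semi"`` the regression uses semi-axis (half-length)
    values so the intercepts are the initial semi-axes directly and the
    shortening rates are the slope magnitudes. ``convention="full"`` regresses
    full lengths and applies the literal estimation formulas x_0 = b_x/2,
    s_x1 = a_x (reported as a magnitude).
    """
    r_b = table.r_b if r_b is None else r_b
    if not np.isfinite(r_b) or r_b <= 0:
        raise ValueError("a positive measured ovary radius is required")
    n = table.n
    stop = n if tepal_count is None else min(tepal_count, n)
    if stop < 3:
        raise ValueError("need at least 3 organs in the fitted range")

    sub = table.organs.iloc[:stop]
    l = sub["organ_index"].to_numpy(dtype=float) / n
    trans = sub["transverse_mm"].to_numpy(dtype=float) / r_b
    longi = sub["longitudinal_mm"].to_numpy(dtype=float) / r_b
    if convention == "semi":
        trans, longi = trans / 2.0, longi / 2.0
    elif convention != "full":
        raise ValueError(f"convention must be 'semi' or 'full', got {convention!r}")

    a_x, b_x, r2_x = _ols(l, trans)
    a_y, b_y, r2_y = _ols(l, longi)
    fit = RegressionFit(a_x=a_x, b_x=b_x, a_y=a_y, b_y=b_y, r2_x=r2_x, r2_y=r2_y, n_used=stop)

    if convention == "semi":
        est = EstimatedParams(x_0=b_x, y_0=b_y, s_x1=abs(a_x), s_y1=abs(a_y))
    else:
        est = EstimatedParams(x_0=b_x / 2.0, y_0=b_y / 2.0, s_x1=abs(a_x), s_y1=abs(a_y))
    return fit, est


# ---------------------------------------------------------------------------
# Cohort summaries


@dataclass
class SummaryReport:
    """Class-wise descriptive statistics and parameter correlations."""

    summary: pd.DataFrame       # rows (shape_class, stat), cols s_y1, s_x1, y_0, x_0
    correlations: pd.DataFrame  # 4x4 Pearson matrix (NaN when degenerate)
    estimates: pd.DataFrame     # per-flower estimates used

    def class_mean(self, shape_class: str) -> pd.Series:
        return self.summary.loc[(shape_class, "mean")]


def _estimates_frame(
    items: Iterable[tuple[MeasurementTable, EstimatedParams]] | pd.DataFrame,
) -> pd.DataFrame:
    if isinstance(items, pd.DataFrame):
        frame = items.copy()
    else:
        rows = []
        for table, est in items:
            rows.append({"flower_id": table.flower_id, "shape_class": table.shape_class, **est.to_dict()})
        frame = pd.DataFrame(rows)
    missing = set(PARAM_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"estimates are missing columns {sorted(missing)}")
    if "shape_class" not in frame.columns:
        frame["shape_class"] = "unknown"
    return frame


def summarize_measurements(
    items: Iterable[tuple[MeasurementTable, EstimatedParams]] | pd.DataFrame,
) -> SummaryReport:
    """Per-class and total mean/std/min/max of the four estimated parameters.

    Accepts either ``(table, estimate)`` pairs or a DataFrame with columns
    ``shape_class, s_y1, s_x1, y_0, x_0``. Correlations are Pearson
    coefficients across all flowers; degenerate (zero-variance) parameters
    yield NaN entries.
    """
    frame = _estimates_frame(items)
    if frame.empty:
        raise ValueError("no estimated flowers to summarize")

    stats_order = ("mean", "std", "min", "max")
    blocks = []
    groups = list(frame.groupby("shape_class", sort=False)) + [("total", frame)]
    for name, group in groups:
        values = group[list(PARAM_COLUMNS)]
        block = pd.DataFrame(
            {
                "mean": values.mean(),
                "std": values.std(ddof=1) if len(values) > 1 else pd.Series(0.0, index=values.columns),
                "min": values.min(),
                "max": values.max(),
            }
        ).T.reindex(list(stats_order))
        block.index = pd.MultiIndex.from_product([[name], block.index], names=["shape_class", "stat"])
        blocks.append(block)
    summary = pd.concat(blocks)[list(PARAM_COLUMNS)]

    with np.errstate(divide="ignore", invalid="ignore"):
        correlations = frame[list(PARAM_COLUMNS)].corr(method="pearson")
    return SummaryReport(summary=summary, correlations=correlations, estimates=frame)


def pairs_plot(report: SummaryReport, path: str | Path) -> Path:
    """Pairs plot of the four estimated parameters colored by shape class."""
    import matplotlib

    matplotlib.use("Agg")
    import seaborn as sns

    grid = sns.pairplot(
        report.estimates, vars=list(PARAM_COLUMNS), hue="shape_class", corner=False, height=1.8
    )
    grid.savefig(path, dpi=120)
    return Path(path)


# ---------------------------------------------------------------------------
# CSV schema: flower_id, shape_class, r_b_mm, organ_index, transverse_mm, longitudinal_mm


def write_measurement_csv(tables: Sequence[MeasurementTable], path: str | Path) -> Path:
    rows = []
    for t in tables:
        for _, organ in t.organs.iterrows():
            rows.append(
                {
                    "flower_id": t.flower_id,
                    "shape_class": t.shape_class,
                    "r_b_mm": t.r_b,
                    "organ_index": int(organ["organ_index"]),
                    "transverse_mm": organ["transverse_mm"],
                    "longitudinal_mm": organ["longitudinal_mm"],
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)
    return Path(path)


def read_measurement_csv(path: str | Path) -> list[MeasurementTable]:
    frame = pd.read_csv(path)
    tables = []
    for flower_id, group in frame.groupby("flower_id", sort=False):
        group = group.sort_values("organ_index").reset_index(drop=True)
        organs = group[["organ_index", "transverse_mm", "longitudinal_mm"]]
        tables.append(
            MeasurementTable(
                flower_id=str(flower_id),
                organs=organs,
                r_b=float(group["r_b_mm"].iloc[0]),
                shape_class=str(group["shape_class"].iloc[0]),
            )
        )
    return tables
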