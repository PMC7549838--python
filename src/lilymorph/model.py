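"""Core parametric model of *Nymphaea* (water-lily) floral form.

A flower is described by 16 parameters: piecewise-linear shortening of organ
semi-axes along the ordered organ sequence, golden-angle spiral phyllotaxis on
an ovary cylinder, and linearly interpolated tepal elevation angles. All
lengths are expressed in ovary-radius units (the ovary radius ``r_b`` is the
model's length unit), all angles in degrees.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FlowerParams",
    "OrganSpec",
    "organ_sizes",
    "tepal_count",
    "classify_identity",
    "azimuth_sequence",
    "height_sequence",
    "elevation_sequence",
    "build_organ_sequence",
    "organ_table",
    "load_params",
    "save_params",
]

#: Exponent cap used in the phyllotactic height rule to keep e^{p·φ} finite.
_EXP_CAP = 700.0

AngleUnit = Literal["degrees", "radians"]


@dataclass(frozen=True)
class FlowerParams:
    """The 16 parameters defining one theoretical flower.

    Defaults are the reference parameter set of the model: a 100-organ flower
    with 20 tepals, half-open at 45 degrees.

    Parameters
    ----------
    n : total number of floral organs.
    s_x1, s_x2 : shortening rates of the transverse semi-axis in the tepal and
        stamen phases (ovary-radius units per unit relative position).
    x_0 : initial (outermost tepal) transverse semi-axis length.
    x_t : transverse semi-axis intercept after the transition threshold.
    t_x : relative position at which the transverse size rule switches, in [0, 1].
    s_y1, s_y2, y_0, y_t, t_y : longitudinal analogues of the above.
    o_max, o_min : maximum / minimum tepal elevation angle, degrees in [0, 90];
        90 means parallel to the flower axis (closed), 0 horizontal (flat).
    p : pitch of the spiral phyllotaxis (per-degree rate in the height rule).
    r_b : ovary radius (the length unit; 1 by convention).
    h_b : ovary height, in ovary-radius units.
    """

    n: int = 100
    s_x1: float = 0.80
    s_x2: float = 0.02
    x_0: float = 1.00
    x_t: float = 0.20
    t_x: float = 0.20
    s_y1: float = 1.40
    s_y2: float = 0.28
    y_0: float = 3.50
    y_t: float = 1.20
    t_y: float = 0.20
    o_max: float = 45.0
    o_min: float = 45.0
    p: float = -0.01
    r_b: float = 1.00
    h_b: float = 0.50

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name, value in self.to_dict().items():
            if not math.isfinite(value):
                raise ValueError(f"parameter {name!r} must be finite, got {value!r}")
        if int(self.n) != self.n or self.n < 1:
            raise ValueError(f"n must be a positive integer, got {self.n!r}")
        for name in ("t_x", "t_y"):
            t = getattr(self, name)
            if not 0.0 <= t <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {t!r}")
        for name in ("o_max", "o_min"):
            o = getattr(self, name)
            if not 0.0 <= o <= 90.0:
                raise ValueError(f"{name} must lie in [0, 90] degrees, got {o!r}")
        if self.r_b <= 0:
            raise ValueError(f"r_b must be positive, got {self.r_b!r}")
        if self.h_b < 0:
            raise ValueError(f"h_b must be non-negative, got {self.h_b!r}")

    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "FlowerParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown parameter name(s): {sorted(unknown)}")
        data = dict(data)
        if "n" in data:
            data["n"] = int(data["n"])
        return cls(**data)

    def replace(self, **changes) -> "FlowerParams":
        """Return a copy with the given parameters overridden."""
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class OrganSpec:
    """Derived state of one floral organ in the ordered sequence."""

    index: int           # position in the sequence, 0 = outermost
    l: float             # relative position l_i = i/n
    x: float             # transverse semi-axis, ovary-radius units (>= 0)
    y: float             # longitudinal semi-axis, ovary-radius units (>= 0)
    phi: float           # cumulative azimuth, degrees (not wrapped)
    h: float             # height above the ovary base, ovary-radius units
    o: float             # elevation angle, degrees in [0, 90]
    identity: Literal["tepal", "stamen"]


def organ_sizes(params: FlowerParams) -> np.ndarray:
    """Semi-axis lengths (x_i, y_i) of every organ, shape (n, 2).

    Each axis follows a two-piece linear rule in the relative position
    l_i = i/n: the tepal phase ``x_0 - s_x1*l`` while ``l <= t_x`` and the
    stamen phase ``x_t - s_x2*l`` after the transition (analogously for y).
    Negative values are clamped to zero: the organ vanishes.
    """
    params.validate()
    l = np.arange(params.n, dtype=float) / params.n
    x = np.where(l <= params.t_x, params.x_0 - params.s_x1 * l, params.x_t - params.s_x2 * l)
    y = np.where(l <= params.t_y, params.y_0 - params.s_y1 * l, params.y_t - params.s_y2 * l)
    return np.column_stack([np.clip(x, 0.0, None), np.clip(y, 0.0, None)])


def tepal_count(params: FlowerParams) -> int:
    """Number of tepals N_t = round(n * max(t_x, t_y)).

    The identity border follows the later of the two size transitions, so the
    organ that ends the elevation ramp is the last tepal on either axis.
    """
    return int(math.floor(params.n * max(params.t_x, params.t_y) + 0.5))


def classify_identity(i: int, params: FlowerParams) -> str:
    """Identity of organ ``i``: ``"tepal"`` if i < N_t else ``"stamen"``."""
    if not 0 <= i < params.n:
        raise IndexError(f"organ index {i} out of range [0, {params.n})")
    return "tepal" if i < tepal_count(params) else "stamen"


def azimuth_sequence(params: FlowerParams) -> np.ndarray:
    """Cumulative azimuths φ_i in degrees, shape (n,).

    φ_0 = 0; the first three increments are 90° (the four outer tepals sit in
    a decussate cross) and every later increment is the golden angle 137.5°.
    The sequence is cumulative — it is not wrapped modulo 360°.
    """
    params.validate()
    n = params.n
    increments = np.full(max(n - 1, 0), 137.5)
    increments[: min(3, increments.size)] = 90.0
    return np.concatenate([[0.0], np.cumsum(increments)])


def height_sequence(
    params: FlowerParams,
    azimuths: Sequence[float] | np.ndarray | None = None,
    angle_unit: AngleUnit = "degrees",
) -> np.ndarray:
    """Heights h_i above the ovary base, shape (n,).

    h_0 = 0 and h_{i+1} = h_i + e^{p·φ_i}: each interval between consecutive
    organs shrinks (p < 0) or grows (p > 0) exponentially with the running
    azimuth. φ enters the exponent in degrees by default; pass
    ``angle_unit="radians"`` for the alternative convention. The exponent is
    capped to keep the sum finite for extreme pitches.
    """
    phi = azimuth_sequence(params) if azimuths is None else np.asarray(azimuths, dtype=float)
    if phi.shape != (params.n,):
        raise ValueError(f"expected {params.n} azimuths, got shape {phi.shape}")
    if angle_unit == "radians":
        phi = np.deg2rad(phi)
    elif angle_unit != "degrees":
        raise ValueError(f"angle_unit must be 'degrees' or 'radians', got {angle_unit!r}")
    exponent = np.clip(params.p * phi[:-1], -_EXP_CAP, _EXP_CAP)
    return np.concatenate([[0.0], np.cumsum(np.exp(exponent))])


def elevation_sequence(params: FlowerParams) -> np.ndarray:
    """Elevation angles o_i in degrees, shape (n,).

    The first four tepals lie at o_min; subsequent tepals ramp linearly in
    equal steps of (o_max − o_min)/(N_t − 4) so the last tepal reaches o_max;
    all stamens are parallel to the flower axis (90°). Flowers with four or
    fewer tepals keep them all at o_min.
    """
    params.validate()
    n_t = tepal_count(params)
    o = np.full(params.n, 90.0)
    if n_t > 0:
        o[: min(n_t, 4)] = params.o_min
    if n_t > 4:
        step = (params.o_max - params.o_min) / (n_t - 4)
        o[4:n_t] = params.o_min + step * np.arange(1, n_t - 3)
    return o


def build_organ_sequence(
    params: FlowerParams, angle_unit: AngleUnit = "degrees"
) -> list[OrganSpec]:
    """Assemble the full ordered organ sequence for one flower.

    Pure function of the parameters: identical inputs give identical outputs.
    """
    sizes = organ_sizes(params)
    phi = azimuth_sequence(params)
    h = height_sequence(params, phi, angle_unit=angle_unit)
    o = elevation_sequence(params)
    n_t = tepal_count(params)
    return [
        OrganSpec(
            index=i,
            l=i / params.n,
            x=float(sizes[i, 0]),
            y=float(sizes[i, 1]),
            phi=float(phi[i]),
            h=float(h[i]),
            o=float(o[i]),
            identity="tepal" if i < n_t else "stamen",
        )
        for i in range(params.n)
    ]


def organ_table(params: FlowerParams, angle_unit: AngleUnit = "degrees") -> pd.DataFrame:
    """Organ sequence as a DataFrame (columns: index, l, x, y, phi_deg, h, o_deg, identity)."""
    organs = build_organ_sequence(params, angle_unit=angle_unit)
    return pd.DataFrame(
        {
            "index": [s.index for s in organs],
            "l": [s.l for s in organs],
            "x": [s.x for s in organs],
            "y": [s.y for s in organs],
            "phi_deg": [s.phi for s in organs],
            "h": [s.h for s in organs],
            "o_deg": [s.o for s in organs],
            "identity": [s.identity for s in organs],
        }
    )


# ---------------------------------------------------------------------------
# Parameter-file I/O: flat JSON/YAML keyed by the model symbol names.

def save_params(params: FlowerParams, path: str | Path) -> None:
    path = Path(path)
    data = params.to_dict()
    if path.suffix.lower() in {".yaml", ".yml"}:
        import yaml

        path.write_text(yaml.safe_dump(data, sort_keys=False))
    else:
        path.write_text(json.dumps(data, indent=2) + "\n")


def load_params(path: str | Path) -> FlowerParams:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in {".yaml", ".yml"}:
        import yaml

        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    return FlowerParams.from_dict(data)


def default_params() -> FlowerParams:
    """The packaged reference parameter set."""
    return load_params(Path(__file__).parent / "data" / "default_params.json")
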