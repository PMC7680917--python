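"""Benchmark geometries and labeled-dataset generators.

Three planar classification problems drive the oscillator-network
classifier:

* the Japanese flag: a "sun" disk centred at (0.5, 0.5) whose radius
  r = (2*pi)**-0.5 makes its area exactly half of the unit square, so a
  constant or random answer scores 50%;
* the French flag: three vertical stripes of equal width, a one-dimensional
  three-class problem solvable by a single oscillator;
* the horned region: the area between two even degree-14 polynomial curves
  in the rotated coordinates p = x - y, s = x + y, which describes the shape
  the optimized network actually separates.

All generators are pure functions of (n, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

__all__ = [
    "FlagGeometry", "LabeledDataset", "BoundaryPoly",
    "UPPER_BOUNDARY", "LOWER_BOUNDARY",
    "disk_label", "sample_flag", "eval_boundary", "horn_tip",
    "horned_label", "sample_horned", "french_flag_label", "sample_french_flag",
]

#: disk radius making the sun cover half of the unit square
EQUAL_AREA_RADIUS = 1.0 / math.sqrt(2.0 * math.pi)


@dataclass(frozen=True)
class FlagGeometry:
    """Equal-area sun disk of the Japanese-flag problem."""

    center: tuple[float, float] = (0.5, 0.5)
    radius: float = EQUAL_AREA_RADIUS

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError("radius must be positive")


@dataclass
class LabeledDataset:
    """Records (x, y, g) with binary labels and generator provenance."""

    x: np.ndarray
    y: np.ndarray
    g: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.g = np.asarray(self.g, dtype=int)
        if not (self.x.shape == self.y.shape == self.g.shape):
            raise ValueError("x, y, g must have identical shape")
        if np.any((self.x < 0) | (self.x > 1) | (self.y < 0) | (self.y > 1)):
            raise ValueError("coordinates must lie in the closed unit square")
        if not np.isin(self.g, (0, 1)).all():
            raise ValueError("labels must be binary")

    def __len__(self) -> int:
        return self.x.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"x": self.x, "y": self.y, "g": self.g})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path, meta: dict | None = None) -> "LabeledDataset":
        df = pd.read_csv(path)
        return cls(x=df["x"].to_numpy(), y=df["y"].to_numpy(),
                   g=df["g"].to_numpy(), meta=meta or {"source": str(path)})


def disk_label(x, y, geom: FlagGeometry = FlagGeometry()):
    """1 for points inside or on the sun disk, else 0."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    cx, cy = geom.center
    inside = (x - cx) ** 2 + (y - cy) ** 2 <= geom.radius ** 2
    return inside.astype(int)[()] if inside.ndim == 0 else inside.astype(int)


def sample_flag(n: int, seed: int,
                geom: FlagGeometry = FlagGeometry()) -> LabeledDataset:
    """n i.i.d. uniform points of the unit square with disk labels."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    pts = rng.random((n, 2))
    g = disk_label(pts[:, 0], pts[:, 1], geom)
    return LabeledDataset(pts[:, 0], pts[:, 1], np.atleast_1d(g),
                          meta={"generator": "japan", "n": n, "seed": seed})


@dataclass(frozen=True)
class BoundaryPoly:
    """Even polynomial s = sum_k c_k * p**(2k) bounding the horned region."""

    coeffs: tuple[float, ...]  # powers 0, 2, ..., 2*(len-1)

    def __call__(self, p):
        p2 = np.asarray(p, dtype=float) ** 2
        # Horner in p^2
        acc = np.zeros_like(p2) + self.coeffs[-1]
        for c in self.coeffs[-2::-1]:
            acc = acc * p2 + c
        return acc[()] if acc.ndim == 0 else acc


#: printed fit of the upper boundary of the region the network sees
UPPER_BOUNDARY = BoundaryPoly((1.49928, 5.56776, -81.5484, 503.745,
                               -2275.64, 7512.65, -14690.6, 11764.8))
#: printed fit of the lower boundary
LOWER_BOUNDARY = BoundaryPoly((0.432601, 1.65454, -2.0677, -107.24,
                               1120.59, -3887.3, 5377.69, -2552.69))


def eval_boundary(poly: BoundaryPoly, p):
    """Evaluate a boundary curve at p (in [-1, 1])."""
    return poly(p)


@lru_cache(maxsize=None)
def horn_tip(upper: BoundaryPoly = UPPER_BOUNDARY,
             lower: BoundaryPoly = LOWER_BOUNDARY) -> float:
    """Smallest positive p at which the horned band leaves the unit square.

    Inside the square s = x + y ranges over [|p|, 2 - |p|], so the band
    between the curves has in-square width
    min(F_U, 2 - p) - max(F_D, p).  The width shrinks with |p| and first
    vanishes at the horn tips (p ~ 0.637 for the printed coefficients,
    where F_U crosses the s = p square edge); beyond them the degree-14
    fits oscillate without bounding anything, so the region ends there.
    """
    from scipy.optimize import brentq

    def width(p: float) -> float:
        return (min(float(upper(p)), 2.0 - p)
                - max(float(lower(p)), p))

    if width(0.0) <= 0:
        raise ValueError("band already empty at p=0")
    grid = np.linspace(0.0, 1.0, 2001)
    vals = np.array([width(p) for p in grid])
    neg = np.nonzero(vals <= 0)[0]
    if neg.size == 0:
        return 1.0
    i = neg[0]
    return float(brentq(width, grid[i - 1], grid[i], xtol=1e-12))


def horned_label(x, y, upper: BoundaryPoly = UPPER_BOUNDARY,
                 lower: BoundaryPoly = LOWER_BOUNDARY,
                 clip_at_tips: bool = True):
    """1 for points between the boundary curves (boundary inclusive).

    Uses rotated coordinates p = x - y, s = x + y.  By default the region is
    the connected band that ends at the horn tips where the curves meet;
    with ``clip_at_tips=False`` the raw pointwise condition
    F_D(p) <= s <= F_U(p) is applied over the whole square, which also picks
    up the fit's spurious oscillations beyond the tips.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    p = x - y
    s = x + y
    inside = (lower(p) <= s) & (s <= upper(p))
    if clip_at_tips:
        inside &= np.abs(p) <= horn_tip(upper, lower)
    inside = inside.astype(int)
    return inside[()] if inside.ndim == 0 else inside


def sample_horned(n: int, seed: int, clip_at_tips: bool = True) -> LabeledDataset:
    """n uniform points labeled by the horned-region boundary polynomials."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    pts = rng.random((n, 2))
    g = horned_label(pts[:, 0], pts[:, 1], clip_at_tips=clip_at_tips)
    return LabeledDataset(pts[:, 0], pts[:, 1], np.atleast_1d(g),
                          meta={"generator": "horned", "n": n, "seed": seed})


FRENCH_CLASSES = ("blue", "white", "red")


def french_flag_label(x):
    """Stripe class of the French flag: blue for x < 1/3, white for
    1/3 <= x < 2/3, red for x >= 2/3."""
    x = np.asarray(x, dtype=float)
    if np.any((x < 0) | (x > 1)):
        raise ValueError("x must lie in [0, 1]")
    idx = np.digitize(x, (1.0 / 3.0, 2.0 / 3.0))
    out = np.array(FRENCH_CLASSES, dtype=object)[idx]
    return out if isinstance(out, np.ndarray) else str(out)


def sample_french_flag(n: int, seed: int) -> pd.DataFrame:
    """n uniform x-values with their stripe class, as a DataFrame."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    x = rng.random(n)
    return pd.DataFrame({"x": x, "class": french_flag_label(x)})
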