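"""ImageJ-style shape descriptors for closed leaf contours.

Four dimensionless ratios summarize outline geometry:

- aspect ratio: major/minor axis of the ellipse with the same second central
  moments as the filled polygon (>= 1);
- circularity: 4*pi*A / P**2, 1 for a circle, lower for serrated or lobed
  outlines (clipped at 1 to absorb discretization);
- roundness: 4*A / (pi * major**2); for an exact ellipse this equals
  minor/major = 1/aspect_ratio;
- solidity: A / convex-hull area, < 1 in the presence of lobes or serrations.

Area and perimeter are computed on the polygon itself (shoelace formula and
summed segment lengths), not on pixel counts, so the descriptors are
resolution independent and invariant under translation, rotation and uniform
scaling.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull

from .contours import Contour
from .exceptions import DataError, DegenerateContourError

logger = logging.getLogger(__name__)

__all__ = [
    "ShapeDescriptorSet",
    "polygon_area_perimeter",
    "fit_ellipse_axes",
    "compute_descriptors",
    "aggregate_per_plant",
]

DESCRIPTOR_COLUMNS = ["aspect_ratio", "circularity", "roundness", "solidity"]


@dataclass(frozen=True)
class ShapeDescriptorSet:
    aspect_ratio: float
    circularity: float
    roundness: float
    solidity: float
    area: float
    perimeter: float
    major_axis: float
    minor_axis: float

    def as_dict(self) -> dict[str, float]:
        return {
            "aspect_ratio": self.aspect_ratio,
            "circularity": self.circularity,
            "roundness": self.roundness,
            "solidity": self.solidity,
            "area": self.area,
            "perimeter": self.perimeter,
            "major_axis": self.major_axis,
            "minor_axis": self.minor_axis,
        }


def _pts(contour: Contour | np.ndarray) -> np.ndarray:
    if isinstance(contour, Contour):
        return contour.points
    return np.asarray(contour, dtype=float)


def polygon_area_perimeter(contour: Contour | np.ndarray) -> tuple[float, float]:
    """Shoelace area (absolute) and closed-polyline perimeter."""
    pts = _pts(contour)
    if len(pts) < 3:
        raise DegenerateContourError("polygon needs at least 3 points")
    x, y = pts[:, 0], pts[:, 1]
    area = 0.5 * abs(float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)))
    ring = np.vstack([pts, pts[:1]])
    perimeter = float(np.sum(np.linalg.norm(np.diff(ring, axis=0), axis=1)))
    return area, perimeter


def _polygon_moments(pts: np.ndarray) -> tuple[float, np.ndarray]:
    """Signed area and 2x2 second-central-moment (covariance) matrix of the
    filled polygon, via Green's theorem."""
    x, y = pts[:, 0], pts[:, 1]
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    cross = x * y1 - x1 * y
    a = float(np.sum(cross)) / 2.0
    if a == 0:
        raise DegenerateContourError("polygon has zero area; cannot fit ellipse")
    cx = float(np.sum((x + x1) * cross)) / (6.0 * a)
    cy = float(np.sum((y + y1) * cross)) / (6.0 * a)
    # second moments about the origin
    sxx = float(np.sum((x * x + x * x1 + x1 * x1) * cross)) / 12.0
    syy = float(np.sum((y * y + y * y1 + y1 * y1) * cross)) / 12.0
    sxy = float(np.sum((x * y1 + 2 * x * y + 2 * x1 * y1 + x1 * y) * cross)) / 24.0
    area = abs(a)
    sign = np.sign(a)
    mxx = sign * sxx / area - cx * cx
    myy = sign * syy / area - cy * cy
    mxy = sign * sxy / area - cx * cy
    return area, np.array([[mxx, mxy], [mxy, myy]])


def fit_ellipse_axes(contour: Contour | np.ndarray) -> tuple[float, float]:
    """Full axis lengths (major, minor) of the moment-equivalent ellipse.

    The ellipse has the same area-normalized second central moments as the
    filled polygon; for a circle of radius r this gives major = minor = 2r.
    """
    pts = _pts(contour)
    if len(pts) < 5:
        raise DegenerateContourError("ellipse fit needs at least 5 points")
    _, cov = _polygon_moments(pts)
    eigvals = np.linalg.eigvalsh(cov)
    if eigvals[0] <= 0:
        raise DegenerateContourError("degenerate (collinear) contour; ellipse fit failed")
    minor, major = 4.0 * np.sqrt(eigvals)
    return float(major), float(minor)


def convex_hull_area(contour: Contour | np.ndarray) -> float:
    pts = _pts(contour)
    hull = ConvexHull(pts)
    return float(hull.volume)  # 2D "volume" is the area


def compute_descriptors(
    contour: Contour | np.ndarray,
    *,
    include_pi: bool = True,
    validate: bool = True,
) -> ShapeDescriptorSet:
    """Compute the four shape descriptors for one closed contour.

    ``include_pi=False`` switches circularity to the plain area/perimeter**2
    ratio times 4 (without the pi factor); the default is the ImageJ
    definition 4*pi*A/P**2, clipped at 1.
    """
    pts = _pts(contour)
    area, perimeter = polygon_area_perimeter(pts)
    if validate:
        try:
            from shapely.geometry import Polygon

            if not Polygon(pts).is_valid:
                warnings.warn("self-intersecting contour; area uses |shoelace|", stacklevel=2)
        except ImportError:  # pragma: no cover
            pass
    major, minor = fit_ellipse_axes(pts)
    factor = 4.0 * np.pi if include_pi else 4.0
    circ = min(1.0, factor * area / perimeter**2)
    roundness = min(1.0, 4.0 * area / (np.pi * major**2))
    solidity = min(1.0, area / convex_hull_area(pts))
    return ShapeDescriptorSet(
        aspect_ratio=major / minor,
        circularity=circ,
        roundness=roundness,
        solidity=solidity,
        area=area,
        perimeter=perimeter,
        major_axis=major,
        minor_axis=minor,
    )


def aggregate_per_plant(leaf_table: pd.DataFrame) -> pd.DataFrame:
    """Average per-leaf descriptors to one record per (vine_id, year).

    ``leaf_table`` holds one row per leaf with ``vine_id``, ``year`` and the
    descriptor columns; the output has the unweighted mean of each descriptor
    and the number of contributing leaves. Groups with zero leaves cannot occur
    by construction; empty input returns an empty frame with a warning.
    """
    if not {"vine_id", "year"}.issubset(leaf_table.columns):
        raise DataError("leaf table needs vine_id and year columns")
    if leaf_table.empty:
        warnings.warn("no leaves to aggregate", stacklevel=2)
        return pd.DataFrame(columns=["vine_id", "year", "n_leaves", *DESCRIPTOR_COLUMNS])
    value_cols = [c for c in leaf_table.columns if c not in ("vine_id", "year", "leaf_id")]
    grouped = leaf_table.groupby(["vine_id", "year"], sort=True)
    out = grouped[value_cols].mean()
    out.insert(0, "n_leaves", grouped.size())
    return out.reset_index()
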