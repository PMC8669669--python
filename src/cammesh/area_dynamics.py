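"""Landmark-based CAM area dynamics and capillary-density stability.

Four manually identified landmarks (vessel junctions or branch points)
define the corners of a test region; re-identifying them at every
timepoint yields the relative area change of that piece of membrane.
Capillary density metrics restricted to the quad interior quantify the
stability of the mesh inside the tracked region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely

from .exceptions import ValidationError
from .segmentation import NetworkSegmentation

logger = logging.getLogger(__name__)


@dataclass
class LandmarkQuad:
    """Four ordered landmark coordinates at one timepoint.

    ``points`` is a (4, 2) array of (row, col) coordinates forming a simple
    (non-self-intersecting) polygon in the given order.
    """

    points: np.ndarray
    timepoint_h: float = 0.0

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.shape != (4, 2):
            raise ValidationError(f"a quad needs exactly 4 (row, col) points, got {pts.shape}")
        poly = shapely.Polygon([(c, r) for r, c in pts])  # shapely is (x, y)
        if not poly.is_valid or poly.area == 0.0:
            raise ValidationError(
                "landmark quad is self-intersecting or degenerate; reorder the "
                "points so they traverse the region boundary"
            )
        self.points = pts

    @property
    def polygon(self) -> shapely.Polygon:
        return shapely.Polygon([(c, r) for r, c in self.points])


def quad_area(quad: LandmarkQuad, pixel_size_um: float | None = None) -> float:
    """Shoelace area of the quad, in px² (or µm² if pixel size is given).

    Orientation-independent: clockwise and counter-clockwise orderings give
    the same (absolute) area.
    """
    area = quad.polygon.area
    if pixel_size_um is not None:
        area *= pixel_size_um**2
    return float(area)


def area_series(quads: list[LandmarkQuad]) -> pd.DataFrame:
    """Relative-area trace ``area_t / area_0`` over timepoints.

    Returns a DataFrame with columns ``timepoint_h`` and ``rel_area``; the
    first entry is exactly 1.0.
    """
    if len(quads) < 2:
        raise ValidationError("area_series needs at least 2 timepoints")
    for q in quads:
        if np.asarray(q.points).shape != (4, 2):
            raise ValidationError("all timepoints must carry 4 landmarks")
    areas = np.array([quad_area(q) for q in quads])
    rel = areas / areas[0]
    rel[0] = 1.0
    return pd.DataFrame(
        {"timepoint_h": [q.timepoint_h for q in quads], "rel_area": rel}
    )


def rasterize_quad(quad: LandmarkQuad, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of pixels whose centers lie strictly inside the quad."""
    h, w = shape
    pts = quad.points
    if pts[:, 0].min() < -0.5 or pts[:, 1].min() < -0.5 or pts[:, 0].max() > h - 0.5 or pts[:, 1].max() > w - 0.5:
        raise ValidationError(
            f"quad {pts.tolist()} extends outside image of shape {shape}"
        )
    r0 = max(0, int(np.floor(pts[:, 0].min())))
    r1 = min(h, int(np.ceil(pts[:, 0].max())) + 1)
    c0 = max(0, int(np.floor(pts[:, 1].min())))
    c1 = min(w, int(np.ceil(pts[:, 1].max())) + 1)
    rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    inside = shapely.contains_xy(quad.polygon, cc.ravel(), rr.ravel()).reshape(rr.shape)
    mask = np.zeros(shape, dtype=bool)
    mask[r0:r1, c0:c1] = inside
    return mask


def capillary_density(seg: NetworkSegmentation, quad: LandmarkQuad) -> dict[str, float]:
    """Capillary density metrics inside the quad.

    Returns skeleton length per unit area (``skel_len_density``), vessel
    area fraction (``area_fraction``) and the number of interior pixels
    (``n_px``), all restricted to pixel centers inside the quad.
    """
    mask = rasterize_quad(quad, seg.vessel_mask.shape)
    n = int(mask.sum())
    if n == 0:
        return {"skel_len_density": 0.0, "area_fraction": 0.0, "n_px": 0}
    return {
        "skel_len_density": float(seg.skeleton[mask].sum() / n),
        "area_fraction": float(seg.vessel_mask[mask].sum() / n),
        "n_px": n,
    }


def density_series(
    seg_by_time: list[tuple[float, NetworkSegmentation]],
    quads: list[LandmarkQuad],
) -> pd.DataFrame:
    """Combine relative area and in-quad density metrics per timepoint."""
    if len(seg_by_time) != len(quads):
        raise ValidationError("one segmentation per landmark timepoint required")
    rel = area_series(quads)
    rows = []
    for (t, seg), quad, rel_area in zip(seg_by_time, quads, rel["rel_area"]):
        dens = capillary_density(seg, quad)
        rows.append(
            {
                "timepoint_h": t,
                "rel_area": rel_area,
                "skel_len_density": dens["skel_len_density"],
                "area_fraction": dens["area_fraction"],
            }
        )
    return pd.DataFrame(rows)
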