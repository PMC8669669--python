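"""Temporal projection images: SD "vessel image" and cumulative-change
"perfusion image".

The intensity at a pixel inside a perfused vessel fluctuates as red blood
cells pass (hemoglobin absorbs light), so the per-pixel temporal standard
deviation separates lumen from avascular tissue.  The per-pixel sum of
absolute successive intensity differences instead grows with both amplitude
and frequency of the fluctuation, giving a semi-quantitative perfusion map.
Both products are normalized to the image maximum and therefore show only
relative levels for a given recording.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, replace
from importlib import resources

import numpy as np

from .exceptions import ValidationError
from .io_config import FrameStack

logger = logging.getLogger(__name__)


@dataclass
class ProjectionImage:
    """A per-pixel temporal statistic map over the valid region.

    ``kind`` is ``vessel_sd`` or ``perfusion_cumchange``; ``norm`` is
    ``raw`` (native intensity units) or ``unit`` (divided by the image
    maximum, values in [0, 1]).
    """

    values: np.ndarray
    kind: str
    norm: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValidationError("projection values must be 2-D")
        if self.kind not in {"vessel_sd", "perfusion_cumchange"}:
            raise ValidationError(f"unknown projection kind {self.kind!r}")
        if self.norm not in {"raw", "unit"}:
            raise ValidationError(f"unknown norm {self.norm!r}")


def sd_image(aligned: FrameStack) -> ProjectionImage:
    """Per-pixel population standard deviation over all frames.

    Invariant to temporal reordering: it measures only the extent of
    intensity changes, not their frequency.
    """
    sd = aligned.frames.std(axis=0, ddof=0)
    return ProjectionImage(values=sd, kind="vessel_sd", norm="raw")


def cumulative_change_image(aligned: FrameStack) -> ProjectionImage:
    """Per-pixel cumulative amount of intensity change.

    Sum over t of ``|I(t+1) - I(t)|`` — the product of amplitude and
    frequency of intensity changes, hence related to the number of red
    cells passing per unit time.  Not invariant to frame reordering.
    """
    cum = np.abs(np.diff(aligned.frames, axis=0)).sum(axis=0)
    return ProjectionImage(values=cum, kind="perfusion_cumchange", norm="raw")


def normalize_to_dynamic_range(img: ProjectionImage) -> ProjectionImage:
    """Normalize a projection to the available dynamic range.

    Values are divided by the image maximum so that the maximum maps to
    full range; both statistics have a natural zero, so the minimum is not
    subtracted.  An all-zero image is returned unchanged with a warning.
    """
    if not np.all(np.isfinite(img.values)):
        raise ValidationError("projection contains non-finite values")
    peak = img.values.max() if img.values.size else 0.0
    if peak == 0.0:
        logger.warning("normalizing an all-zero %s image; returned unchanged", img.kind)
        return replace(img, values=img.values.copy(), norm="unit")
    return replace(img, values=img.values / peak, norm="unit")


_LUT_CACHE: np.ndarray | None = None


def _load_lut() -> np.ndarray:
    """256x3 float LUT (dark blue -> yellow, monotone luminance), shipped
    with the package so rendered PNGs are bit-reproducible."""
    global _LUT_CACHE
    if _LUT_CACHE is None:
        ref = resources.files("cammesh").joinpath("data/viridis_lut.csv")
        with ref.open("r", encoding="utf-8") as fh:
            rows = list(csv.reader(fh))
        _LUT_CACHE = np.asarray(rows[1:], dtype=np.float64)
        assert _LUT_CACHE.shape == (256, 3)
    return _LUT_CACHE


def pseudocolor(img: ProjectionImage) -> np.ndarray:
    """Map a unit-normalized projection to an RGB uint8 image.

    Uses the packaged perceptually-uniform LUT; 0 maps to the first entry
    (dark blue), 1 to the last (yellow).  Because inputs are normalized per
    image, each rendering spans the full color range of its own recording.
    """
    if img.norm != "unit":
        raise ValidationError("pseudocolor requires a unit-normalized projection")
    lut = _load_lut()
    idx = np.clip(np.round(img.values * 255), 0, 255).astype(np.intp)
    rgb = lut[idx]
    return np.round(rgb * 255).astype(np.uint8)
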