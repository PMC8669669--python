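"""Reading video stacks and configs, writing image products and tables.

The in-memory containers used across the pipeline live here:

* :class:`FrameStack` — a time-ordered grayscale image sequence ``(t, row,
  col)`` kept on its native intensity scale (8/16-bit integers are promoted
  to float64 without rescaling; normalization is an explicit later step).
* :class:`AnalysisConfig` — every tunable of the analysis pipeline, loadable
  from a TOML file.

Conventions used throughout the package: pixel coordinates are 0-based
``(row, col)`` with row 0 at the top; intervals are half-open; RGB input is
converted to luminance with fixed Rec. 601 weights.
"""

from __future__ import annotations

import json
import logging
import tomllib
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import tifffile

from .exceptions import InputError, ValidationError

logger = logging.getLogger(__name__)

#: Rec. 601 luma weights used for RGB -> grayscale conversion.
REC601 = np.array([0.299, 0.587, 0.114])


@dataclass
class FrameStack:
    """Time-ordered grayscale image sequence.

    Parameters
    ----------
    frames
        3-D array indexed ``(t, row, col)``; promoted to float64 on its
        native intensity scale.
    pixel_size_um
        Micrometers per pixel, if known.
    frame_rate_hz
        Acquisition frame rate, if known.
    """

    frames: np.ndarray
    pixel_size_um: float | None = None
    frame_rate_hz: float | None = None

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=np.float64)
        if frames.ndim != 3:
            raise ValidationError(
                f"frames must be a 3-D (t, row, col) array, got ndim={frames.ndim}"
            )
        if frames.shape[0] < 2:
            raise ValidationError(
                f"a FrameStack needs at least 2 frames, got {frames.shape[0]}"
            )
        if not np.all(np.isfinite(frames)):
            raise ValidationError("frame intensities must be finite")
        if frames.min() < 0:
            raise ValidationError("frame intensities must be non-negative")
        self.frames = frames

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]


@dataclass
class AnalysisConfig:
    """Parameters of the analysis pipeline.

    ``reference_square`` is ``(row, col, size)`` of the high-contrast square
    used for registration (``None`` selects it automatically); 256 and 512
    are the standard sizes for full-resolution recordings, but any size that
    fits inside the frame is accepted so that small crops remain analyzable.
    """

    reference_square: tuple[int, int, int] | None = None
    max_shift_px: int = 6
    gaussian_sigma_px: float = 0.7
    local_window_px: int = 51
    local_offset: float = -0.025
    min_speckle_px: int = 20
    min_island_area_px: int = 30
    morph_radius_px: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_shift_px < 0:
            raise ValidationError("max_shift_px must be non-negative")
        if self.gaussian_sigma_px <= 0:
            raise ValidationError("gaussian_sigma_px must be positive")
        if self.local_window_px < 3 or self.local_window_px % 2 == 0:
            raise ValidationError("local_window_px must be odd and >= 3")
        if self.min_island_area_px <= 0:
            raise ValidationError("min_island_area_px must be positive")
        if self.morph_radius_px <= 0:
            raise ValidationError("morph_radius_px must be positive")
        if self.reference_square is not None:
            r, c, s = self.reference_square
            if s <= 0 or r < 0 or c < 0:
                raise ValidationError(
                    "reference_square must be (row>=0, col>=0, size>0)"
                )
            self.reference_square = (int(r), int(c), int(s))

    def validate_for_frame(self, frame_shape: tuple[int, int]) -> None:
        """Check that the configured reference square fits inside a frame."""
        if self.reference_square is None:
            return
        r, c, s = self.reference_square
        h, w = frame_shape
        if r + s > h or c + s > w:
            raise ValidationError(
                f"reference square {self.reference_square} does not fit inside "
                f"frame of shape {frame_shape}"
            )


def load_config(path: str | Path, **overrides: Any) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from a TOML file.

    Keys may live at top level or under an ``[analysis]`` table; keyword
    overrides win over file values.
    """
    path = Path(path)
    try:
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
    except FileNotFoundError as exc:
        raise InputError(f"config file not found: {path}") from exc
    except tomllib.TOMLDecodeError as exc:
        raise InputError(f"cannot parse TOML config {path}: {exc}") from exc
    if "analysis" in data and isinstance(data["analysis"], dict):
        data = data["analysis"]
    known = set(AnalysisConfig.__dataclass_fields__)
    kwargs = {k: v for k, v in data.items() if k in known}
    unknown = set(data) - known
    if unknown:
        logger.warning("ignoring unknown config keys: %s", sorted(unknown))
    if "reference_square" in kwargs and kwargs["reference_square"] is not None:
        kwargs["reference_square"] = tuple(kwargs["reference_square"])
    kwargs.update(overrides)
    return AnalysisConfig(**kwargs)


def _to_luminance(arr: np.ndarray) -> np.ndarray:
    """Collapse a trailing RGB(A) axis to Rec. 601 luminance."""
    if arr.ndim >= 3 and arr.shape[-1] in (3, 4):
        return arr[..., :3].astype(np.float64) @ REC601
    return np.asarray(arr, dtype=np.float64)


def read_stack(path: str | Path, fmt: str = "auto") -> FrameStack:
    """Read a video recording into a :class:`FrameStack`.

    Parameters
    ----------
    path
        Multi-page TIFF or AVI file.
    fmt
        ``"tiff"``, ``"avi"`` or ``"auto"`` (by extension).

    Integer pixel types are promoted to float64 on their native scale; RGB
    frames are converted to luminance.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"input file not found: {path}")
    if fmt == "auto":
        fmt = "avi" if path.suffix.lower() in {".avi", ".mp4", ".mov"} else "tiff"

    if fmt == "tiff":
        try:
            with tifffile.TiffFile(path) as tf:
                page_shapes = {p.shape for p in tf.pages}
                if len(page_shapes) > 1:
                    raise ValidationError(
                        f"{path}: inconsistent frame sizes {sorted(page_shapes)}"
                    )
                series = tf.series[0]
                arr = series.asarray()
                axes = series.axes  # e.g. 'YX', 'QYX', 'TYX', 'YXS', 'TYXS'
        except ValidationError:
            raise
        except Exception as exc:  # noqa: BLE001 - report decode failure with path
            raise InputError(f"cannot read TIFF {path}: {exc}") from exc
        rgb = axes.endswith("S") and arr.shape[-1] in (3, 4)
        if rgb:
            arr = _to_luminance(arr)
        if arr.ndim == 2:
            raise ValidationError(f"{path}: a video stack needs >= 2 frames, got 1")
        if arr.ndim != 3:
            raise ValidationError(
                f"{path}: cannot interpret axes {axes!r} as a grayscale or RGB video"
            )
        if arr.shape[0] < 2:
            raise ValidationError(
                f"{path}: a video stack needs >= 2 frames, got {arr.shape[0]}"
            )
        return FrameStack(np.asarray(arr, dtype=np.float64))

    if fmt == "avi":
        try:
            import imageio.v3 as iio

            raw = [
                _to_luminance(np.asarray(fr)) for fr in iio.imiter(path)
            ]
        except Exception as exc:  # noqa: BLE001
            raise InputError(
                f"cannot decode video {path}; an ffmpeg-capable imageio backend "
                f"is required for AVI input ({exc})"
            ) from exc
        if len(raw) < 2:
            raise ValidationError(f"{path}: a video needs >= 2 frames, got {len(raw)}")
        shapes = {f.shape for f in raw}
        if len(shapes) > 1:
            raise ValidationError(f"{path}: inconsistent frame sizes {sorted(shapes)}")
        return FrameStack(np.stack(raw))

    raise ValidationError(f"unknown format {fmt!r}; expected tiff, avi or auto")


def _write_png(path: Path, arr: np.ndarray) -> None:
    import imageio.v3 as iio

    iio.imwrite(path, arr)


def unit_to_uint16(values: np.ndarray) -> np.ndarray:
    """Quantize a unit-normalized image to the full 16-bit range."""
    return np.round(np.clip(values, 0.0, 1.0) * 65535).astype(np.uint16)


def unit_to_uint8(values: np.ndarray) -> np.ndarray:
    return np.round(np.clip(values, 0.0, 1.0) * 255).astype(np.uint8)


def write_products(out_dir: str | Path, products: Mapping[str, Any]) -> list[dict]:
    """Write a named set of image/table products and return the manifest.

    Dispatch by value type:

    * unit-scale float images -> 8-bit PNG for display plus lossless 16-bit
      TIFF (full-range quantization);
    * boolean masks -> 8-bit TIFF (0/255);
    * integer label images -> 32-bit TIFF;
    * ``pandas.DataFrame`` -> CSV (comma separator, ``.`` decimal, UTF-8,
      header row);
    * RGB uint8 images (trailing axis 3) -> PNG.

    The manifest (also written as ``manifest.json``) lists every file.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise InputError(f"output directory {out_dir} is not writable: {exc}") from exc

    manifest: list[dict] = []

    def record(name: str, path: Path, kind: str) -> None:
        manifest.append({"name": name, "path": path.name, "kind": kind})

    for name, value in products.items():
        if isinstance(value, pd.DataFrame):
            path = out_dir / f"{name}.csv"
            value.to_csv(path, index=False)
            record(name, path, "table")
        elif isinstance(value, np.ndarray) and value.dtype == bool:
            path = out_dir / f"{name}.tif"
            tifffile.imwrite(path, (value.astype(np.uint8) * 255))
            record(name, path, "mask")
        elif isinstance(value, np.ndarray) and np.issubdtype(value.dtype, np.integer):
            if value.ndim == 3 and value.shape[-1] == 3 and value.dtype == np.uint8:
                path = out_dir / f"{name}.png"
                _write_png(path, value)
                record(name, path, "rgb")
            else:
                path = out_dir / f"{name}.tif"
                tifffile.imwrite(path, value.astype(np.int32))
                record(name, path, "labels")
        elif isinstance(value, np.ndarray):
            u16 = unit_to_uint16(value)
            tif = out_dir / f"{name}.tif"
            tifffile.imwrite(tif, u16)
            record(name, tif, "image16")
            png = out_dir / f"{name}.png"
            _write_png(png, unit_to_uint8(value))
            record(name, png, "image8")
        elif isinstance(value, (dict, list)):
            path = out_dir / f"{name}.json"
            with open(path, "w", encoding="utf-8") as fh:
                json.dump(value, fh, indent=2, default=_json_default)
            record(name, path, "json")
        else:
            raise ValidationError(
                f"product {name!r} has unsupported type {type(value).__name__}"
            )

    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def _json_default(obj: Any) -> Any:
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_landmarks(path: str | Path) -> list:
    """Read a landmark CSV (columns timepoint_h, point_index, row, col).

    Returns a list of :class:`~cammesh.area_dynamics.LandmarkQuad`, one per
    timepoint, sorted by time.
    """
    from .area_dynamics import LandmarkQuad

    path = Path(path)
    if not path.exists():
        raise InputError(f"landmark file not found: {path}")
    df = pd.read_csv(path)
    required = {"timepoint_h", "point_index", "row", "col"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"{path}: landmark CSV needs columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    quads = []
    for t, group in df.groupby("timepoint_h"):
        group = group.sort_values("point_index")
        if list(group["point_index"]) != [0, 1, 2, 3]:
            raise ValidationError(
                f"{path}: timepoint {t} must have point_index 0..3, "
                f"got {list(group['point_index'])}"
            )
        pts = group[["row", "col"]].to_numpy(dtype=float)
        quads.append(LandmarkQuad(points=pts, timepoint_h=float(t)))
    return sorted(quads, key=lambda q: q.timepoint_h)
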