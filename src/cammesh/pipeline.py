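"""Pipeline orchestration and QC reporting.

``run_pipeline`` chains read -> align -> project -> segment -> measure and
emits the three image products (vessel SD image, perfusion image and its
pseudo-color rendering), the network segmentation, per-ROI morphometry and
a QC report.  The QC report carries the displacement trace, all parameters
used, and the fraction of perfusion signal lying outside the (dilated)
vessel mask — the indicator of residual tissue flicker, which produces
small positive perfusion values in avascular areas and cannot be removed
by alignment.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .exceptions import PipelineError, ValidationError
from .io_config import AnalysisConfig, FrameStack, read_stack, write_products
from .projections import (
    ProjectionImage,
    cumulative_change_image,
    normalize_to_dynamic_range,
    pseudocolor,
    sd_image,
)
from .registration import DisplacementTrace, align_stack
from .segmentation import (
    MorphometryRecord,
    NetworkSegmentation,
    measure_network,
    records_to_frame,
    segment_network,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """Everything one pipeline run produces."""

    aligned: FrameStack | None
    trace: DisplacementTrace
    valid_region: tuple[int, int, int, int]
    sd_unit: "ProjectionImage"
    perfusion_unit: "ProjectionImage"
    segmentation: NetworkSegmentation
    records: list[MorphometryRecord]
    qc: dict
    manifest: list[dict] | None = None


def perfusion_outside_mask_fraction(
    perfusion_values: np.ndarray,
    vessel_mask: np.ndarray,
    dilation_px: int = 2,
) -> float:
    """Fraction of total perfusion signal outside the dilated vessel mask.

    Zero when every intensity change happens inside (or within
    ``dilation_px`` of) detected vessels; strictly positive when avascular
    tissue flickers.
    """
    if perfusion_values.shape != vessel_mask.shape:
        raise ValidationError("perfusion and mask shapes differ")
    total = float(perfusion_values.sum())
    if total == 0.0:
        return 0.0
    if dilation_px > 0:
        mask = ndi.binary_dilation(
            vessel_mask, structure=ndi.generate_binary_structure(2, 2), iterations=dilation_px
        )
    else:
        mask = vessel_mask
    return float(perfusion_values[~mask].sum() / total)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


def _content_hash(stack: FrameStack, config: AnalysisConfig) -> str:
    payload = hashlib.sha256()
    payload.update(np.ascontiguousarray(stack.frames).tobytes())
    payload.update(json.dumps(asdict(config), sort_keys=True, default=str).encode())
    return payload.hexdigest()


def run_pipeline(
    video: str | Path | FrameStack,
    config: AnalysisConfig | None = None,
    out_dir: str | Path | None = None,
    roi_id: str = "roi0",
    timepoint_h: float = float("nan"),
    use_cache: bool = True,
) -> PipelineResult:
    """Run the full analysis on one recording.

    Deterministic given inputs and config: there is no hidden randomness.
    When ``out_dir`` is given, all products are written there and a cached
    run (same content hash of frames + config) skips recomputation of the
    written products.
    """
    config = config or AnalysisConfig()
    if isinstance(video, (str, Path)):
        stack = read_stack(video)
    else:
        stack = video

    content = _content_hash(stack, config) if out_dir is not None else None
    if out_dir is not None and use_cache:
        cached = _load_cached(Path(out_dir), content)
        if cached is not None:
            logger.info("cache hit for %s: reusing completed products", out_dir)
            return cached

    aligned, trace, valid_region = _stage("registration")(align_stack)(stack, config)
    sd_raw = _stage("projections")(sd_image)(aligned)
    sd_unit = normalize_to_dynamic_range(sd_raw)
    perf_raw = _stage("projections")(cumulative_change_image)(aligned)
    perf_unit = normalize_to_dynamic_range(perf_raw)

    seg = _stage("segmentation")(segment_network)(
        sd_unit,
        gaussian_sigma_px=config.gaussian_sigma_px,
        local_window_px=config.local_window_px,
        local_offset=config.local_offset,
        min_speckle_px=config.min_speckle_px,
        morph_radius_px=config.morph_radius_px,
        min_island_area_px=config.min_island_area_px,
    )
    record = _stage("morphometry")(measure_network)(
        seg,
        perf_unit,
        pixel_size_um=stack.pixel_size_um,
        roi_id=roi_id,
        timepoint_h=timepoint_h,
    )

    qc = {
        "content_hash": content,
        "params": asdict(config),
        "valid_region": list(valid_region),
        "n_frames": stack.n_frames,
        "frame_shape": list(stack.frame_shape),
        "displacement_trace": trace.to_frame().to_dict(orient="list"),
        "perfusion_outside_mask_fraction": perfusion_outside_mask_fraction(
            perf_unit.values, seg.vessel_mask, dilation_px=config.morph_radius_px
        ),
        "mean_peak_corr": float(trace.peak_corr[1:].mean()) if stack.n_frames > 1 else 1.0,
    }

    manifest = None
    if out_dir is not None:
        products = {
            "vessel_sd": sd_unit.values,
            "perfusion": perf_unit.values,
            "perfusion_pseudocolor": pseudocolor(perf_unit),
            "vessel_mask": seg.vessel_mask,
            "skeleton": seg.skeleton,
            "islands": seg.islands,
            "morphometry": records_to_frame([record]),
            "displacement_trace": trace.to_frame(),
            "qc_report": qc,
        }
        manifest = _stage("write_products")(write_products)(out_dir, products)

    return PipelineResult(
        aligned=aligned,
        trace=trace,
        valid_region=valid_region,
        sd_unit=sd_unit,
        perfusion_unit=perf_unit,
        segmentation=seg,
        records=[record],
        qc=qc,
        manifest=manifest,
    )


def _load_cached(out_dir: Path, content: str | None) -> PipelineResult | None:
    """Reload a completed run whose content hash matches, or None.

    The aligned stack is not persisted, so a cached result carries
    ``aligned=None``; every written product is reloaded from disk.
    """
    import tifffile

    qc_path = out_dir / "qc_report.json"
    needed = [
        "vessel_sd.tif",
        "perfusion.tif",
        "vessel_mask.tif",
        "skeleton.tif",
        "islands.tif",
        "morphometry.csv",
        "displacement_trace.csv",
        "manifest.json",
    ]
    if not qc_path.exists() or not all((out_dir / n).exists() for n in needed):
        return None
    try:
        with open(qc_path, encoding="utf-8") as fh:
            qc = json.load(fh)
        if qc.get("content_hash") != content:
            return None
        sd_vals = tifffile.imread(out_dir / "vessel_sd.tif").astype(float) / 65535.0
        perf_vals = tifffile.imread(out_dir / "perfusion.tif").astype(float) / 65535.0
        seg = NetworkSegmentation(
            vessel_mask=tifffile.imread(out_dir / "vessel_mask.tif") > 0,
            skeleton=tifffile.imread(out_dir / "skeleton.tif") > 0,
            islands=tifffile.imread(out_dir / "islands.tif").astype(np.int32),
            params_used=qc.get("params", {}),
        )
        tr = pd.read_csv(out_dir / "displacement_trace.csv")
        trace = DisplacementTrace(
            shifts=tr[["d_row", "d_col"]].to_numpy(), peak_corr=tr["peak_corr"].to_numpy()
        )
        morph = pd.read_csv(out_dir / "morphometry.csv")
        records = [MorphometryRecord(**row) for row in morph.to_dict(orient="records")]
        with open(out_dir / "manifest.json", encoding="utf-8") as fh:
            manifest = json.load(fh)
        return PipelineResult(
            aligned=None,
            trace=trace,
            valid_region=tuple(qc["valid_region"]),
            sd_unit=ProjectionImage(sd_vals, kind="vessel_sd", norm="unit"),
            perfusion_unit=ProjectionImage(perf_vals, kind="perfusion_cumchange", norm="unit"),
            segmentation=seg,
            records=records,
            qc=qc,
            manifest=manifest,
        )
    except (OSError, KeyError, ValueError, ValidationError):
        return None


def compare_timepoints(
    records_t0: list[MorphometryRecord],
    records_t1: list[MorphometryRecord],
) -> pd.DataFrame:
    """Per-ROI metric deltas and ratios between two timepoints.

    ROIs are matched by ``roi_id``; unmatched ids raise a validation error
    listing them.  Ratios with a zero baseline are reported as missing
    values, not errors.  No inferential statistics are computed.
    """
    f0 = records_to_frame(records_t0).set_index("roi_id")
    f1 = records_to_frame(records_t1).set_index("roi_id")
    missing = sorted(set(f0.index) ^ set(f1.index))
    if missing:
        raise ValidationError(f"unmatched roi_ids between timepoints: {missing}")
    metrics = [
        c for c in f0.columns if c != "timepoint_h" and np.issubdtype(f0[c].dtype, np.number)
    ]
    rows = []
    for roi in f0.index:
        row: dict = {"roi_id": roi}
        for m in metrics:
            v0, v1 = float(f0.loc[roi, m]), float(f1.loc[roi, m])
            row[f"{m}_delta"] = v1 - v0
            row[f"{m}_ratio"] = v1 / v0 if v0 != 0 else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
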