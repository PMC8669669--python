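"""Ground-truthed synthetic CAM scenes and intravital-style videos.

The generator emulates the statistical structure the analysis pipeline
relies on, with full ground truth retained:

* a polygonal, near-isotropic capillary mesh (randomized Voronoi
  tessellation of a jittered grid) enclosing avascular tissue islands;
* hierarchically wider preferential pathways / emergent vessels encoded by
  four phase presets (I isotropic mesh, II preferential pathway, III
  emergent vessel with residual tissue islands, IV established vessel);
* red-cell passage as discrete dark particles advected along segments at
  flow-scaled speeds, with contrast inversely related to vessel diameter
  (absorbance per unit path is strongest in the smallest vessels);
* scripted slow global in-plane drift of the whole scene;
* low-amplitude temporal intensity flicker restricted to avascular tissue;
* additive Gaussian sensor noise everywhere.

All intensities live in the 8-bit-compatible range [0, 255] so rendered
videos exercise the native-scale I/O path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.spatial import Voronoi
from skimage.draw import polygon as draw_polygon

from .exceptions import ValidationError
from .io_config import FrameStack
from .registration import DisplacementTrace
from .segmentation import NetworkSegmentation, _enclosed_background
from skimage.measure import label as sk_label

logger = logging.getLogger(__name__)


@dataclass
class Segment:
    """One vascular segment: a polyline with diameter and relative flow."""

    polyline: np.ndarray  # (n, 2) float, (row, col)
    diameter_px: float
    flow_au: float

    def __post_init__(self) -> None:
        self.polyline = np.asarray(self.polyline, dtype=float)
        if self.diameter_px <= 0:
            raise ValidationError("segment diameter must be positive")
        if self.flow_au < 0:
            raise ValidationError("segment flow must be non-negative")


@dataclass
class SyntheticScene:
    """Ground-truth vascular graph plus island polygons for one field."""

    segments: list[Segment]
    islands: list[np.ndarray]  # interior cell polygons, (k, 2) (row, col)
    frame_shape: tuple[int, int]
    background_intensity: float = 230.0
    vessel_absorbance: float = 15.0
    plasma_tint: float = 8.0
    margin: int = 8
    phase: str = "I"
    seed: int = 0
    pathway_polygon: np.ndarray | None = None  # (4, 2) rect used for phase metrics
    residual_holes: list[tuple[float, float, float]] = field(default_factory=list)

    def diameters(self) -> np.ndarray:
        return np.array([s.diameter_px for s in self.segments])

    def flows(self) -> np.ndarray:
        return np.array([s.flow_au for s in self.segments])


@dataclass
class RenderParams:
    """Rendering knobs for one synthetic video."""

    n_frames: int = 100
    rbc_density_per_px: float = 0.25
    rbc_speed_px_per_frame: float = 1.2
    drift_script: np.ndarray | None = None  # (n_frames, 2) int, [0] == (0, 0)
    tissue_flicker_sd: float = 1.5
    sensor_noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValidationError("n_frames must be >= 2")
        if self.tissue_flicker_sd < 0 or self.sensor_noise_sd < 0:
            raise ValidationError("noise SDs must be non-negative")
        if self.drift_script is not None:
            script = np.asarray(self.drift_script, dtype=int)
            if script.shape != (self.n_frames, 2):
                raise ValidationError(
                    f"drift_script must have shape ({self.n_frames}, 2)"
                )
            if tuple(script[0]) != (0, 0):
                raise ValidationError("drift_script[0] must be (0, 0)")
            self.drift_script = script


def default_drift_script(n_frames: int, amplitude_px: int = 3) -> np.ndarray:
    """Smooth scripted drift: one slow loop of the given amplitude."""
    t = np.arange(n_frames) / n_frames
    dr = np.round(amplitude_px * np.sin(2 * np.pi * t)).astype(int)
    dc = np.round(amplitude_px * (1 - np.cos(2 * np.pi * t)) / 2).astype(int)
    script = np.stack([dr, dc], axis=1)
    script[0] = (0, 0)
    return script


def _reflect_points(pts: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Mirror points across the four box edges so all core Voronoi cells
    are finite and core-core ridges stay inside the box."""
    out = [pts]
    for axis in (0, 1):
        for bound in (lo[axis], hi[axis]):
            ref = pts.copy()
            ref[:, axis] = 2 * bound - ref[:, axis]
            out.append(ref)
    return np.concatenate(out, axis=0)


def generate_mesh_scene(
    frame_shape: tuple[int, int] = (512, 512),
    mean_island_diameter_px: float = 48.0,
    phase_preset: str = "I",
    seed: int = 0,
) -> SyntheticScene:
    """Generate a polygonal capillary-mesh scene for one phase preset.

    Phase presets encode the four stages of mesh-to-vessel maturation:

    * ``I`` — isotropic mesh: near-uniform capillary diameters (3 px
      nominal) and near-homogeneous flows;
    * ``II`` — preferential pathway: segments crossing the horizontal
      midline get larger diameters (x2.2) and flows (x3);
    * ``III`` — emergent vessel: midline mesh segments are replaced by a
      single wide channel (18 px) with high flow; feeder segments near the
      channel are widened; at most 2 residual tissue islands remain inside
      the channel;
    * ``IV`` — established vessel: a wider channel (26 px), no residual
      islands, merged (enlarged) islands adjacent to the vessel, and
      reduced capillary flows elsewhere.

    Determinism: the same seed regenerates the identical scene.
    """
    if phase_preset not in {"I", "II", "III", "IV"}:
        raise ValidationError(f"unknown phase preset {phase_preset!r}")
    if mean_island_diameter_px < 4:
        raise ValidationError("mean_island_diameter_px must be >= 4")
    h, w = frame_shape
    margin = 8
    s = float(mean_island_diameter_px)
    if s > min(h, w) - 2 * margin:
        raise ValidationError(
            f"island diameter {s} does not fit in frame {frame_shape}"
        )
    rng = np.random.default_rng(seed)
    lo = np.array([margin, margin], dtype=float)
    hi = np.array([h - margin, w - margin], dtype=float)

    rows = np.arange(lo[0] + s / 2, hi[0], s)
    cols = np.arange(lo[1] + s / 2, hi[1], s)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    pts = np.stack([rr.ravel(), cc.ravel()], axis=1)
    pts = pts + rng.uniform(-0.22 * s, 0.22 * s, size=pts.shape)
    pts = np.clip(pts, lo + 2, hi - 2)
    n_core = len(pts)

    vor = Voronoi(_reflect_points(pts, lo, hi))

    cy = h / 2.0
    edges: list[tuple[np.ndarray, np.ndarray, int, int]] = []
    for (p, q), verts in zip(vor.ridge_points, vor.ridge_vertices):
        if p >= n_core or q >= n_core or -1 in verts:
            continue
        v0, v1 = vor.vertices[verts[0]], vor.vertices[verts[1]]
        edges.append((v0, v1, p, q))

    diam0 = rng.normal(3.0, 0.25, size=len(edges)).clip(1.8, 4.2)
    flow0 = rng.normal(1.0, 0.05, size=len(edges)).clip(0.5, 1.5)

    def crosses_midline(v0: np.ndarray, v1: np.ndarray) -> bool:
        return (v0[0] - cy) * (v1[0] - cy) <= 0

    def within_band(v0: np.ndarray, v1: np.ndarray, half: float) -> bool:
        return abs(v0[0] - cy) <= half and abs(v1[0] - cy) <= half

    # pathway rectangle used by all phase metrics (channel footprint geometry)
    w3_half, w4_half = 9.0, 13.0
    rect = np.array(
        [[cy - w3_half, lo[1]], [cy - w3_half, hi[1]], [cy + w3_half, hi[1]], [cy + w3_half, lo[1]]]
    )

    segments: list[Segment] = []
    residual_holes: list[tuple[float, float, float]] = []
    drop_pairs: set[frozenset] = set()

    if phase_preset == "IV":
        # merge pairs of cells adjacent to the vessel: drop their shared walls
        band_lo, band_hi = w4_half + 2.0, w4_half + 2.0 + 1.3 * s
        for v0, v1, p, q in edges:
            dp, dq = abs(pts[p][0] - cy), abs(pts[q][0] - cy)
            mid = (v0 + v1) / 2
            if band_lo < dp < band_hi and band_lo < dq < band_hi and abs(mid[0] - cy) > w4_half + 2:
                drop_pairs.add(frozenset((p, q)))

    for (v0, v1, p, q), d, f in zip(edges, diam0, flow0):
        if phase_preset == "II":
            if crosses_midline(v0, v1):
                d, f = d * 2.2, f * 3.0
        elif phase_preset == "III":
            if within_band(v0, v1, w3_half + 1.0):
                continue  # replaced by the channel
            if crosses_midline(v0, v1) or within_band(v0, v1, 0.9 * s):
                d, f = d * 1.8, f * 2.0
        elif phase_preset == "IV":
            if within_band(v0, v1, w4_half + 2.0):
                continue
            if frozenset((p, q)) in drop_pairs:
                continue
            f = f * 0.6
        segments.append(Segment(np.stack([v0, v1]), float(d), float(f)))

    if phase_preset == "III":
        chan = Segment(
            np.array([[cy, lo[1]], [cy, hi[1]]]), 2 * w3_half, 6.0
        )
        segments.append(chan)
        span = hi[1] - lo[1]
        residual_holes = [
            (cy, float(lo[1] + span / 3), 3.5),
            (cy, float(lo[1] + 2 * span / 3), 3.5),
        ]
    elif phase_preset == "IV":
        segments.append(
            Segment(np.array([[cy, lo[1]], [cy, hi[1]]]), 2 * w4_half, 10.0)
        )

    # interior cells (all walls are core-core ridges) are the island ground
    # truth geometry; cells on the mesh border are open to the surround
    islands: list[np.ndarray] = []
    for i in range(n_core):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or not region:
            continue
        poly = vor.vertices[region]
        if (
            poly[:, 0].min() < lo[0]
            or poly[:, 0].max() > hi[0]
            or poly[:, 1].min() < lo[1]
            or poly[:, 1].max() > hi[1]
        ):
            continue
        islands.append(poly)

    return SyntheticScene(
        segments=segments,
        islands=islands,
        frame_shape=(h, w),
        phase=phase_preset,
        seed=seed,
        pathway_polygon=rect,
        residual_holes=residual_holes,
        margin=margin,
    )


def _stroke_lumen(scene: SyntheticScene, shape: tuple[int, int], offset: int) -> np.ndarray:
    """Rasterize the vessel lumen (thick strokes minus residual holes)."""
    lumen = np.zeros(shape, dtype=bool)
    for seg in scene.segments:
        line = shapely.LineString([(c, r) for r, c in seg.polyline])
        poly = line.buffer(seg.diameter_px / 2.0, quad_segs=8)
        ext = np.asarray(poly.exterior.coords)
        rr, cc = draw_polygon(ext[:, 1] + offset, ext[:, 0] + offset, shape=shape)
        lumen[rr, cc] = True
    for r, c, rad in scene.residual_holes:
        yy, xx = np.ogrid[: shape[0], : shape[1]]
        hole = (yy - (r + offset)) ** 2 + (xx - (c + offset)) ** 2 <= rad**2
        lumen[hole] = False
    return lumen


def truth_islands_from_lumen(lumen: np.ndarray, min_area_px: int = 8) -> np.ndarray:
    """Label enclosed background components of a lumen raster (the
    ground-truth tissue islands), dropping slivers below ``min_area_px``."""
    holes = _enclosed_background(lumen.astype(bool))
    labels = sk_label(holes, connectivity=1)
    counts = np.bincount(labels.ravel())
    keep = np.flatnonzero(counts >= min_area_px)
    keep = keep[keep > 0]
    relabel = np.zeros(counts.size, dtype=np.int32)
    relabel[keep] = np.arange(1, keep.size + 1, dtype=np.int32)
    return relabel[labels]


def _particle_contrast(absorbance: float, diameter_px: float) -> float:
    """Darkening per particle.

    Contrast decays with vessel diameter (single red cells matter less in a
    wide column of blood), so the per-pixel SD of intensity is strongest in
    the smallest microvessels; the decay is gentle enough that the
    amplitude x frequency product still grows with flow in wide vessels.
    """
    return absorbance * min(1.0, (3.0 / diameter_px) ** 0.3)


def _disk_offsets(radius: float) -> np.ndarray:
    r = int(np.ceil(radius))
    dr, dc = np.mgrid[-r : r + 1, -r : r + 1]
    keep = dr**2 + dc**2 <= radius**2
    return np.stack([dr[keep], dc[keep]], axis=1)


def render_video(
    scene: SyntheticScene, params: RenderParams
) -> tuple[FrameStack, dict]:
    """Render a synthetic video of the scene and return the ground truth.

    Red-cell passage is modelled as discrete dark particles advected along
    each segment at ``rbc_speed * flow`` px/frame (wrapping at the segment
    end), stamped as disks clipped to the lumen with contrast inversely
    related to diameter.  Every perfused segment carries at least one
    particle when the density is positive.  Scripted global drift shifts
    the whole scene; tissue flicker and sensor noise are added per frame;
    frames are quantized to the 8-bit range.

    Returns ``(stack, truth)`` where ``truth`` holds the pre-drift lumen
    mask, island labels and the drift script.
    """
    h, w = scene.frame_shape
    T = params.n_frames
    script = (
        params.drift_script
        if params.drift_script is not None
        else np.zeros((T, 2), dtype=int)
    )
    max_d = int(np.abs(script).max())
    if max_d > scene.margin:
        raise ValidationError(
            f"drift amplitude {max_d} px exceeds the scene margin "
            f"({scene.margin} px): the mesh would leave the frame"
        )
    pad = max_d
    ch, cw = h + 2 * pad, w + 2 * pad

    lumen_canvas = _stroke_lumen(scene, (ch, cw), offset=pad)
    lumen = lumen_canvas[pad : pad + h, pad : pad + w].copy()
    tissue_canvas = ~lumen_canvas

    base = np.full((ch, cw), scene.background_intensity)
    base[lumen_canvas] -= scene.plasma_tint

    rng = np.random.default_rng(params.seed)

    # per-segment particle populations
    populations = []
    for seg in scene.segments:
        p0, p1 = seg.polyline[0], seg.polyline[-1]
        vec = p1 - p0
        length = float(np.hypot(*vec))
        if length == 0:
            continue
        direction = vec / length
        normal = np.array([-direction[1], direction[0]])
        if params.rbc_density_per_px <= 0:
            continue
        n = max(1, int(rng.poisson(params.rbc_density_per_px * length)))
        s0 = rng.uniform(0, length, size=n)
        stamp_r = min(4.0, seg.diameter_px / 2.0)
        lat_max = max(0.0, seg.diameter_px / 2.0 - stamp_r)
        lat = rng.uniform(-1, 1, size=n) * lat_max
        speed = params.rbc_speed_px_per_frame * seg.flow_au
        contrast = _particle_contrast(scene.vessel_absorbance, seg.diameter_px)
        populations.append(
            (p0, direction, normal, length, s0, lat, speed, contrast, _disk_offsets(stamp_r))
        )

    frames = np.empty((T, h, w))
    flat_shape = ch * cw
    for t in range(T):
        dark = np.zeros(flat_shape)
        for p0, direction, normal, length, s0, lat, speed, contrast, offs in populations:
            s = (s0 + speed * t) % length
            pos = p0[None, :] + s[:, None] * direction[None, :] + lat[:, None] * normal[None, :]
            ij = np.round(pos).astype(int) + pad
            pix = ij[:, None, :] + offs[None, :, :]
            np.clip(pix[..., 0], 0, ch - 1, out=pix[..., 0])
            np.clip(pix[..., 1], 0, cw - 1, out=pix[..., 1])
            np.add.at(dark, (pix[..., 0] * cw + pix[..., 1]).ravel(), contrast)
        frame = base - dark.reshape(ch, cw) * lumen_canvas
        if params.tissue_flicker_sd > 0:
            frame = frame + rng.normal(0, params.tissue_flicker_sd, size=(ch, cw)) * tissue_canvas
        if params.sensor_noise_sd > 0:
            frame = frame + rng.normal(0, params.sensor_noise_sd, size=(ch, cw))
        frame = np.clip(np.round(frame), 0, 255)
        dr, dc = script[t]
        frames[t] = frame[pad - dr : pad - dr + h, pad - dc : pad - dc + w]

    stack = FrameStack(frames, frame_rate_hz=50.0)
    truth = {
        "lumen": lumen,
        "islands": truth_islands_from_lumen(lumen),
        "drift": script.copy(),
        "scene": scene,
    }
    return stack, truth


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice coefficient of two boolean masks (1.0 when both are empty)."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * (a & b).sum() / denom)


def truth_metrics(
    truth: dict,
    seg: NetworkSegmentation,
    trace: DisplacementTrace | None = None,
    valid_region: tuple[int, int, int, int] | None = None,
    island_min_area_px: int = 60,
) -> dict:
    """Score a segmentation against rendered ground truth.

    ``valid_region`` crops the pre-drift truth rasters to the region the
    aligned stack covers, so truth and segmentation are compared on the
    same support (islands are re-derived on the crop: a cropped island that
    touches the new border no longer counts on either side).
    """
    lumen = truth["lumen"]
    if valid_region is not None:
        r0, r1, c0, c1 = valid_region
        lumen = lumen[r0:r1, c0:c1]
    if lumen.shape != seg.vessel_mask.shape:
        raise ValidationError(
            f"truth {lumen.shape} and segmentation {seg.vessel_mask.shape} disagree"
        )
    truth_islands = truth_islands_from_lumen(lumen, min_area_px=8)

    def big_areas(labels: np.ndarray) -> np.ndarray:
        counts = np.bincount(labels.ravel())[1:]
        return counts[counts >= island_min_area_px]

    n_truth = int(big_areas(truth_islands).size)
    n_seg = int(big_areas(seg.islands).size)

    # best-match Jaccard per (large) truth island via label-pair overlap
    jaccards: list[float] = []
    t_counts = np.bincount(truth_islands.ravel())
    s_counts = np.bincount(seg.islands.ravel())
    both = (truth_islands > 0) & (seg.islands > 0)
    if both.any():
        pair = truth_islands[both].astype(np.int64) * (seg.islands.max() + 1) + seg.islands[both]
        pair_ids, overlap = np.unique(pair, return_counts=True)
        t_of = pair_ids // (seg.islands.max() + 1)
        s_of = pair_ids % (seg.islands.max() + 1)
        for ti in range(1, truth_islands.max() + 1):
            if t_counts[ti] < island_min_area_px:
                continue
            sel = t_of == ti
            if not sel.any():
                jaccards.append(0.0)
                continue
            inter = overlap[sel]
            union = t_counts[ti] + s_counts[s_of[sel]] - inter
            jaccards.append(float((inter / union).max()))
    else:
        jaccards = [0.0] * n_truth

    out = {
        "dice": dice(seg.vessel_mask, lumen),
        "n_islands_truth": n_truth,
        "n_islands_seg": n_seg,
        "island_count_error": n_seg - n_truth,
        "island_jaccard_min": float(min(jaccards)) if jaccards else float("nan"),
        "island_jaccard_mean": float(np.mean(jaccards)) if jaccards else float("nan"),
    }
    if trace is not None and "drift" in truth:
        diff = trace.shifts - truth["drift"]
        out["trace_rmse"] = float(np.sqrt(np.mean(diff.astype(float) ** 2)))
        out["trace_exact"] = bool((diff == 0).all())
    return out
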