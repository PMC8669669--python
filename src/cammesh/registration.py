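"""In-plane movement correction by 2-D image correlation.

Every frame of a recording is aligned to the first frame using the
displacement of a high-contrast reference square, estimated by
zero-normalized cross-correlation (ZNCC) over integer pixel shifts.  The
search for frame ``t`` is centered on the shift found for frame ``t - 1``
(blood-film drift is slow and smooth), while the reported displacement is
always relative to frame 0.

Integer shifts only: the temporal statistics computed downstream (per-pixel
SD, cumulative intensity change) would be blurred by sub-pixel
interpolation, so frames are aligned by pure translation and the stack is
cropped to the rectangle covered by every shifted frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import RegistrationError, ValidationError
from .io_config import AnalysisConfig, FrameStack

logger = logging.getLogger(__name__)


@dataclass
class DisplacementTrace:
    """Per-frame integer displacement relative to frame 0.

    ``shifts[t] = (d_row, d_col)`` means the reference content of frame 0 is
    found in frame ``t`` displaced by that vector; ``peak_corr[t]`` is the
    ZNCC score at the chosen shift.
    """

    shifts: np.ndarray  # (T, 2) int
    peak_corr: np.ndarray  # (T,) float

    def __post_init__(self) -> None:
        self.shifts = np.asarray(self.shifts, dtype=int)
        self.peak_corr = np.asarray(self.peak_corr, dtype=float)
        if self.shifts.ndim != 2 or self.shifts.shape[1] != 2:
            raise ValidationError("shifts must be a (T, 2) array")
        if len(self.peak_corr) != len(self.shifts):
            raise ValidationError("peak_corr must have one entry per frame")
        if tuple(self.shifts[0]) != (0, 0):
            raise ValidationError("shifts[0] must be (0, 0)")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": np.arange(len(self.shifts)),
                "d_row": self.shifts[:, 0],
                "d_col": self.shifts[:, 1],
                "peak_corr": self.peak_corr,
            }
        )


def select_reference_square(
    frame0: np.ndarray,
    size: int,
    mode: str = "auto",
    configured: tuple[int, int] | None = None,
    stride: int | None = None,
    margin: int = 0,
) -> tuple[int, int, int]:
    """Choose the corner of the reference square on the first frame.

    ``manual`` returns the configured corner unchanged (validated in
    bounds).  ``auto`` scans corners on a coarse grid and refines locally,
    returning the corner whose square has (near-)maximal intensity SD — the
    "high image contrast" region the registration needs.
    """
    frame0 = np.asarray(frame0, dtype=np.float64)
    h, w = frame0.shape
    if size > h or size > w:
        raise ValidationError(
            f"reference square size {size} exceeds frame shape {(h, w)}"
        )
    if mode == "manual":
        if configured is None:
            raise ValidationError("manual mode requires a configured corner")
        r, c = configured
        if r < 0 or c < 0 or r + size > h or c + size > w:
            raise ValidationError(
                f"configured reference square {(r, c, size)} leaves the frame"
            )
        return int(r), int(c), int(size)
    if mode != "auto":
        raise ValidationError(f"unknown mode {mode!r}")

    # Integral images give the SD of every square corner in O(1).
    csum = np.zeros((h + 1, w + 1))
    csum2 = np.zeros((h + 1, w + 1))
    np.cumsum(np.cumsum(frame0, axis=0), axis=1, out=csum[1:, 1:])
    np.cumsum(np.cumsum(frame0**2, axis=0), axis=1, out=csum2[1:, 1:])

    def sd_at(rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        n = float(size * size)
        s = (
            csum[rows + size][:, cols + size]
            - csum[rows + size][:, cols]
            - csum[rows][:, cols + size]
            + csum[rows][:, cols]
        )
        s2 = (
            csum2[rows + size][:, cols + size]
            - csum2[rows + size][:, cols]
            - csum2[rows][:, cols + size]
            + csum2[rows][:, cols]
        )
        var = np.maximum(s2 / n - (s / n) ** 2, 0.0)
        return np.sqrt(var)

    if stride is None:
        stride = max(1, size // 8)
    # keep a margin so the correlation search window stays in the frame
    if h - size - margin < margin or w - size - margin < margin:
        margin = 0
    rows = np.arange(margin, h - size - margin + 1, stride)
    cols = np.arange(margin, w - size - margin + 1, stride)
    sd = sd_at(rows, cols)
    i, j = np.unravel_index(int(np.argmax(sd)), sd.shape)
    best_sd = sd[i, j]
    # local exhaustive refinement around the coarse winner
    r0 = max(margin, rows[i] - stride)
    r1 = min(h - size - margin, rows[i] + stride)
    c0 = max(margin, cols[j] - stride)
    c1 = min(w - size - margin, cols[j] + stride)
    rr = np.arange(r0, r1 + 1)
    cc = np.arange(c0, c1 + 1)
    sd_fine = sd_at(rr, cc)
    ii, jj = np.unravel_index(int(np.argmax(sd_fine)), sd_fine.shape)
    if sd_fine[ii, jj] == 0.0:
        logger.warning(
            "reference-square auto-selection on a constant image; any corner "
            "is equivalent (SD = 0 everywhere)"
        )
    best = (int(rr[ii]), int(cc[jj]), int(size))
    logger.debug("auto reference square %s (SD %.3f, coarse %.3f)", best, sd_fine[ii, jj], best_sd)
    return best


def zncc(a: np.ndarray, b: np.ndarray) -> float:
    """Zero-normalized cross-correlation of two equal-shaped patches.

    Returns 0.0 when either patch has zero variance (score undefined).
    """
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0.0:
        return 0.0
    return float((a * b).sum() / denom)


def estimate_displacement(
    ref_patch: np.ndarray,
    frame: np.ndarray,
    ref_pos: tuple[int, int],
    prev_shift: tuple[int, int] = (0, 0),
    max_shift_px: int = 6,
) -> tuple[tuple[int, int], float]:
    """Find the integer shift of ``ref_patch`` within ``frame``.

    Candidate shifts span ``prev_shift ± max_shift_px`` in both axes,
    clipped to shifts for which the window stays inside the frame.  Ties in
    the correlation peak are broken toward the smallest ``|d_row| +
    |d_col|``, then lexicographically, so results are deterministic.
    """
    ref_patch = np.asarray(ref_patch, dtype=np.float64)
    frame = np.asarray(frame, dtype=np.float64)
    ph, pw = ref_patch.shape
    h, w = frame.shape
    r0, c0 = ref_pos
    pr, pc = prev_shift

    ref = ref_patch - ref_patch.mean()
    ref_ss = float((ref * ref).sum())

    best: tuple[float, int, int, int] | None = None
    found = False
    for dr in range(pr - max_shift_px, pr + max_shift_px + 1):
        rr = r0 + dr
        if rr < 0 or rr + ph > h:
            continue
        for dc in range(pc - max_shift_px, pc + max_shift_px + 1):
            cc = c0 + dc
            if cc < 0 or cc + pw > w:
                continue
            found = True
            win = frame[rr : rr + ph, cc : cc + pw]
            win = win - win.mean()
            denom = np.sqrt(ref_ss * float((win * win).sum()))
            corr = 0.0 if denom == 0.0 else float((ref * win).sum() / denom)
            key = (-corr, abs(dr) + abs(dc), dr, dc)
            if best is None or key < best:
                best = key
    if not found or best is None:
        raise RegistrationError(
            f"no valid shift: search window around {prev_shift} ± {max_shift_px} "
            f"leaves the frame for a {ph}x{pw} patch at {ref_pos}"
        )
    neg_corr, _, dr, dc = best
    return (dr, dc), -neg_corr


def align_stack(
    stack: FrameStack, config: AnalysisConfig
) -> tuple[FrameStack, DisplacementTrace, tuple[int, int, int, int]]:
    """Align every frame to frame 0 and crop to the common valid region.

    Returns the aligned (cropped) stack, the displacement trace, and
    ``valid_region = (row0, row1, col0, col1)`` — the maximal rectangle (in
    frame-0 coordinates, half-open) covered by all shifted frames.
    Downstream temporal statistics are computed only inside this region.

    Raises :class:`RegistrationError` naming the frame index when a frame's
    displacement exceeds ``max_shift_px`` relative to frame 0.
    """
    frames = stack.frames
    h, w = stack.frame_shape
    config.validate_for_frame((h, w))
    if config.reference_square is not None:
        r0, c0, size = select_reference_square(
            frames[0],
            config.reference_square[2],
            mode="manual",
            configured=config.reference_square[:2],
        )
    else:
        # large enough for robust correlation, small enough to keep the
        # search window inside the frame at every allowed shift
        size = min(256, max(16, (min(h, w) - 2 * config.max_shift_px) * 3 // 4))
        r0, c0, size = select_reference_square(
            frames[0], size, mode="auto", margin=config.max_shift_px
        )

    ref_patch = frames[0, r0 : r0 + size, c0 : c0 + size]
    ms = config.max_shift_px

    shifts = np.zeros((stack.n_frames, 2), dtype=int)
    corrs = np.ones(stack.n_frames)
    prev = (0, 0)
    for t in range(1, stack.n_frames):
        try:
            (dr, dc), corr = estimate_displacement(
                ref_patch, frames[t], (r0, c0), prev_shift=prev, max_shift_px=ms
            )
        except RegistrationError as exc:
            raise RegistrationError(f"frame {t}: {exc}") from exc
        if abs(dr) > ms or abs(dc) > ms:
            raise RegistrationError(
                f"frame {t}: displacement ({dr}, {dc}) exceeds max_shift_px={ms}"
            )
        shifts[t] = (dr, dc)
        corrs[t] = corr
        prev = (dr, dc)

    dr_all = shifts[:, 0]
    dc_all = shifts[:, 1]
    row0 = int(max(0, -dr_all.min()))
    row1 = int(min(h, h - dr_all.max()))
    col0 = int(max(0, -dc_all.min()))
    col1 = int(min(w, w - dc_all.max()))
    if row0 >= row1 or col0 >= col1:
        raise RegistrationError("no common valid region after alignment")

    aligned = np.empty((stack.n_frames, row1 - row0, col1 - col0))
    for t in range(stack.n_frames):
        dr, dc = shifts[t]
        aligned[t] = frames[t, row0 + dr : row1 + dr, col0 + dc : col1 + dc]

    trace = DisplacementTrace(shifts=shifts, peak_corr=corrs)
    out = FrameStack(
        aligned, pixel_size_um=stack.pixel_size_um, frame_rate_hz=stack.frame_rate_hz
    )
    return out, trace, (row0, row1, col0, col1)
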