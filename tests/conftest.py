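"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

import cammesh as cm


def euler_number_bitquad(mask: np.ndarray) -> int:
    """Independent Euler-number oracle for 8-connected foreground.

    Counts the 2x2 bit-quad patterns of the zero-padded image (Gray's
    vertex/edge/face counting formulation): with Q1 = quads with exactly one
    foreground pixel, Q3 = quads with exactly three, and QD = quads with
    exactly two diagonal foreground pixels,

        E8 = (Q1 - Q3 - 2 * QD) / 4.
    """
    m = np.pad(np.asarray(mask).astype(np.uint8), 1)
    a = m[:-1, :-1]
    b = m[:-1, 1:]
    c = m[1:, :-1]
    d = m[1:, 1:]
    total = a + b + c + d
    q1 = int((total == 1).sum())
    q3 = int((total == 3).sum())
    qd = int(((total == 2) & (a == d) & (b == c) & (a != b)).sum())
    num = q1 - q3 - 2 * qd
    assert num % 4 == 0
    return num // 4


def random_blob_mask(rng: np.random.Generator, shape=(64, 64)) -> np.ndarray:
    """Random blobby binary mask (smoothed noise threshold), sometimes with
    a ring punched in to exercise holes."""
    from scipy import ndimage as ndi

    noise = rng.normal(size=shape)
    smooth = ndi.gaussian_filter(noise, rng.uniform(2.0, 5.0))
    mask = smooth > np.quantile(smooth, rng.uniform(0.55, 0.8))
    if rng.random() < 0.3:
        yy, xx = np.ogrid[: shape[0], : shape[1]]
        r0 = rng.uniform(8, 16)
        cy, cx = rng.uniform(16, shape[0] - 16), rng.uniform(16, shape[1] - 16)
        ring = ((yy - cy) ** 2 + (xx - cx) ** 2 <= r0**2) & (
            (yy - cy) ** 2 + (xx - cx) ** 2 >= (r0 - 4) ** 2
        )
        mask |= ring
    return mask


@pytest.fixture(scope="session")
def small_phase1():
    """A small phase-I scene with a rendered default-noise video and truth."""
    scene = cm.generate_mesh_scene((192, 192), 40, "I", seed=11)
    stack, truth = cm.render_video(
        scene, cm.RenderParams(n_frames=40, seed=11, drift_script=cm.default_drift_script(40, 2))
    )
    return scene, stack, truth


@pytest.fixture(scope="session")
def small_phase1_result(small_phase1):
    """Pipeline result for the small phase-I render."""
    _, stack, _ = small_phase1
    return cm.run_pipeline(stack, cm.AnalysisConfig(max_shift_px=3))
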