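"""Synthetic scene generation, video rendering, recovery scoring."""

import numpy as np
import pytest

import cammesh as cm
from cammesh.area_dynamics import LandmarkQuad, rasterize_quad
from cammesh.exceptions import ValidationError
from cammesh.synthetic import truth_islands_from_lumen


class TestSceneGeneration:
    def test_same_seed_reproduces_identical_scene(self):
        a = cm.generate_mesh_scene((256, 256), 48, "I", seed=5)
        b = cm.generate_mesh_scene((256, 256), 48, "I", seed=5)
        assert len(a.segments) == len(b.segments)
        for sa, sb in zip(a.segments, b.segments):
            np.testing.assert_array_equal(sa.polyline, sb.polyline)
            assert sa.diameter_px == sb.diameter_px and sa.flow_au == sb.flow_au

    def test_infeasible_island_size_rejected(self):
        with pytest.raises(ValidationError):
            cm.generate_mesh_scene((64, 64), 200, "I", seed=0)
        with pytest.raises(ValidationError):
            cm.generate_mesh_scene((64, 64), 2, "I", seed=0)

    def test_phase_one_islands_more_uniform_than_phase_four(self):
        """Merged adjacent islands make the phase-IV island-area CV larger."""
        for seed in (1, 2):
            areas = {}
            for ph in ("I", "IV"):
                scene = cm.generate_mesh_scene((384, 384), 48, ph, seed=seed)
                _, truth = cm.render_video(
                    scene, cm.RenderParams(n_frames=2, rbc_density_per_px=0, seed=seed)
                )
                counts = np.bincount(truth["islands"].ravel())[1:]
                counts = counts[counts > 0]
                areas[ph] = counts.std() / counts.mean()
            assert areas["I"] < areas["IV"]

    def test_phase_four_channel_contains_no_islands(self):
        scene = cm.generate_mesh_scene((384, 384), 48, "IV", seed=3)
        _, truth = cm.render_video(
            scene, cm.RenderParams(n_frames=2, rbc_density_per_px=0, seed=3)
        )
        rect = rasterize_quad(LandmarkQuad(scene.pathway_polygon), scene.frame_shape)
        assert not (truth["islands"][rect] > 0).any()

    def test_diameter_cv_ordering_across_presets(self):
        for seed in (1, 2):
            cvs = {}
            for ph in ("I", "II", "III"):
                d = cm.generate_mesh_scene((384, 384), 48, ph, seed=seed).diameters()
                cvs[ph] = d.std() / d.mean()
            assert cvs["I"] < cvs["II"] <= cvs["III"] + 1e-12


class TestRenderVideo:
    def test_null_render_is_static(self):
        scene = cm.generate_mesh_scene((96, 96), 24, "I", seed=2)
        stack, _ = cm.render_video(
            scene,
            cm.RenderParams(
                n_frames=5, rbc_density_per_px=0, tissue_flicker_sd=0, sensor_noise_sd=0, seed=0
            ),
        )
        assert (stack.frames == stack.frames[0]).all()
        assert not cm.sd_image(stack).values.any()

    def test_single_particle_oscillation_cumulative_change(self):
        """A particle hopping between two pixels of a 1-px vessel produces
        the hand-traced cumulative change 3 x contrast at each pixel."""
        seg = cm.Segment(np.array([[5.0, 5.0], [5.0, 7.0]]), diameter_px=1.0, flow_au=1.0)
        scene = cm.SyntheticScene(
            segments=[seg],
            islands=[],
            frame_shape=(12, 12),
            vessel_absorbance=10.0,
            plasma_tint=0.0,
        )
        params = cm.RenderParams(
            n_frames=4,
            rbc_density_per_px=1e-9,  # forces exactly one particle
            rbc_speed_px_per_frame=1.0,
            tissue_flicker_sd=0,
            sensor_noise_sd=0,
            seed=0,
        )
        stack, _ = cm.render_video(scene, params)
        cum = cm.cumulative_change_image(stack).values
        hit = np.argwhere(cum > 0)
        assert len(hit) == 2  # the particle alternates between two pixels
        for r, c in hit:
            series = stack.frames[:, r, c]
            assert sorted(set(series)) == [220.0, 230.0]
            assert cum[r, c] == pytest.approx(30.0)

    def test_seed_contract(self):
        scene = cm.generate_mesh_scene((96, 96), 24, "I", seed=4)
        p = dict(n_frames=6)
        s1, t1 = cm.render_video(scene, cm.RenderParams(seed=1, **p))
        s2, t2 = cm.render_video(scene, cm.RenderParams(seed=1, **p))
        s3, t3 = cm.render_video(scene, cm.RenderParams(seed=2, **p))
        np.testing.assert_array_equal(s1.frames, s2.frames)
        assert (s1.frames != s3.frames).any()
        np.testing.assert_array_equal(t1["lumen"], t3["lumen"])
        np.testing.assert_array_equal(t1["islands"], t3["islands"])

    def test_vessel_pixels_darker_than_tissue(self, small_phase1):
        _, stack, truth = small_phase1
        assert stack.frames[:, truth["lumen"]].mean() < stack.frames[:, ~truth["lumen"]].mean()

    def test_drift_beyond_margin_rejected(self):
        scene = cm.generate_mesh_scene((96, 96), 24, "I", seed=0)
        script = np.zeros((5, 2), dtype=int)
        script[2] = (20, 0)
        with pytest.raises(ValidationError, match="margin"):
            cm.render_video(scene, cm.RenderParams(n_frames=5, drift_script=script))

    def test_islands_live_in_lumen_complement(self, small_phase1):
        _, _, truth = small_phase1
        assert not (truth["islands"] > 0)[truth["lumen"]].any()


class TestTruthMetrics:
    def test_perfect_segmentation_scores_perfectly(self, small_phase1):
        _, _, truth = small_phase1
        lumen = truth["lumen"]
        seg = cm.NetworkSegmentation(
            vessel_mask=lumen,
            skeleton=np.zeros_like(lumen),
            islands=truth_islands_from_lumen(lumen),
        )
        m = cm.truth_metrics(truth, seg)
        assert m["dice"] == 1.0
        assert m["island_count_error"] == 0
        assert m["island_jaccard_min"] == 1.0

    def test_empty_mask_scores_zero_dice(self, small_phase1):
        _, _, truth = small_phase1
        empty = np.zeros_like(truth["lumen"])
        seg = cm.NetworkSegmentation(empty, empty, np.zeros_like(empty, dtype=np.int32))
        assert cm.truth_metrics(truth, seg)["dice"] == 0.0

    def test_random_mask_dice_matches_analytic_expectation(self):
        """Independent random masks at foreground fraction p have expected
        Dice ~ p."""
        rng = np.random.default_rng(8)
        p = 0.3
        truth_mask = rng.random((64, 64)) < p
        dices = [cm.dice(truth_mask, rng.random((64, 64)) < p) for _ in range(100)]
        assert np.mean(dices) == pytest.approx(p, abs=0.02)

    def test_dice_of_empty_pair_is_one(self):
        assert cm.dice(np.zeros((4, 4), bool), np.zeros((4, 4), bool)) == 1.0


class TestRenderParamsValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_frames": 1},
            {"tissue_flicker_sd": -1.0},
            {"n_frames": 4, "drift_script": np.ones((4, 2), dtype=int)},  # [0] != 0
            {"n_frames": 4, "drift_script": np.zeros((3, 2), dtype=int)},  # wrong length
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            cm.RenderParams(**kwargs)
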