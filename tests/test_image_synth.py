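import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from smv import image_synth as isyn
from smv import flow_sim as fs
from smv.flow_sim import FlowRecord, FrameRecord
from smv.vessel_graph import RadiusVelocityTable, synthetic_vessel_template
from tests.conftest import straight_tube_graph


def _static_record(positions, amps, shape=(64, 64), n_frames=1):
    frames = []
    for _ in range(n_frames):
        frames.append(
            FrameRecord(
                positions=np.array(positions, dtype=float),
                amplitudes=np.array(amps, dtype=float),
                velocities=np.zeros((len(amps), 2)),
                mb_ids=np.arange(len(amps)),
            )
        )
    return FlowRecord(frames=frames, shape=shape, dt=1.0)


class TestGaussianPsf:
    def test_peak_is_one_at_centre(self):
        p = isyn.gaussian_psf(3, 5, 21)
        assert p[10, 10] == 1.0
        assert p.max() == 1.0

    def test_symmetric_when_equal_sigmas(self):
        p = isyn.gaussian_psf(4, 4, 17)
        assert np.allclose(p, p.T)

    def test_one_sigma_value(self):
        p = isyn.gaussian_psf(4, 6, 25)
        assert p[12 + 4, 12] == pytest.approx(np.exp(-0.5), rel=1e-6)
        assert p[12, 12 + 6] == pytest.approx(np.exp(-0.5), rel=1e-6)

    def test_even_size_rejected(self):
        with pytest.raises(ValueError):
            isyn.gaussian_psf(2, 2, 10)


class TestExtractPsfBank:
    def test_recovers_known_gaussian(self):
        truth = isyn.gaussian_psf(3, 4, 15)
        rec = _static_record([[20, 20], [40, 45]], [1.0, 0.8])
        seq = isyn.render_sequence(
            rec, truth, grid=(64, 64), cfg=isyn.RenderConfig(rotation_deg=0, scale_jitter=0)
        )
        bank = isyn.extract_psf_bank(seq, isyn.gaussian_psf(3, 4, 15), corr_threshold=0.8)
        assert len(bank) >= 1
        for patch in bank.patches:
            corr = np.corrcoef(patch.ravel(), truth.ravel())[0, 1]
            assert corr > 0.99

    def test_all_zero_frames_error(self):
        seq = isyn.FrameSequence(frames=np.zeros((2, 32, 32)))
        with pytest.raises(ValueError):
            isyn.extract_psf_bank(seq, isyn.gaussian_psf(3, 3, 9), corr_threshold=0.8)

    def test_impossible_threshold_error(self):
        truth = isyn.gaussian_psf(3, 4, 15)
        rec = _static_record([[30, 30]], [1.0])
        seq = isyn.render_sequence(rec, truth, grid=(64, 64),
                                   cfg=isyn.RenderConfig(rotation_deg=0, scale_jitter=0))
        with pytest.raises(ValueError):
            isyn.extract_psf_bank(seq, truth, corr_threshold=1.0 + 1e-6)


class TestRenderSequence:
    def test_single_static_bubble_is_centred_patch(self):
        patch = isyn.gaussian_psf(3, 3, 11)
        rec = _static_record([[32, 32]], [1.0])
        seq = isyn.render_sequence(rec, patch, grid=(64, 64),
                                   cfg=isyn.RenderConfig(rotation_deg=0, scale_jitter=0))
        sub = seq.frames[0][27:38, 27:38]
        assert np.allclose(sub, patch, atol=1e-12)
        assert seq.frames[0].sum() == pytest.approx(patch.sum())

    def test_additivity_over_bubbles(self):
        patch = isyn.gaussian_psf(2, 2, 9)
        cfg = isyn.RenderConfig(rotation_deg=0, scale_jitter=0)
        both = isyn.render_sequence(_static_record([[15, 15], [45, 45]], [1, 1]),
                                    patch, (64, 64), cfg)
        a = isyn.render_sequence(_static_record([[15, 15]], [1]), patch, (64, 64), cfg)
        b = isyn.render_sequence(_static_record([[45, 45]], [1]), patch, (64, 64), cfg)
        assert np.allclose(both.frames[0], a.frames[0] + b.frames[0])

    def test_amplitude_scaling(self):
        patch = isyn.gaussian_psf(2, 2, 9)
        cfg = isyn.RenderConfig(rotation_deg=0, scale_jitter=0)
        full = isyn.render_sequence(_static_record([[30, 30]], [1.0]), patch, (64, 64), cfg)
        half = isyn.render_sequence(_static_record([[30, 30]], [0.5]), patch, (64, 64), cfg)
        assert half.frames[0].max() == pytest.approx(0.5 * full.frames[0].max())

    def test_subpixel_mass_preserved(self):
        patch = isyn.gaussian_psf(2, 2, 9)
        cfg = isyn.RenderConfig(rotation_deg=0, scale_jitter=0)
        rec = _static_record([[30.37, 29.61]], [0.7])
        seq = isyn.render_sequence(rec, patch, (64, 64), cfg)
        assert seq.frames[0].sum() == pytest.approx(0.7 * patch.sum(), rel=1e-6)

    def test_same_patch_kept_across_frames(self):
        bank = isyn.PSFBank(patches=[isyn.gaussian_psf(2, 2, 9), isyn.gaussian_psf(4, 2, 9)])
        rec = _static_record([[30, 30]], [1.0], n_frames=4)
        cfg = isyn.RenderConfig(rotation_deg=0, scale_jitter=0, rng_seed=0)
        seq = isyn.render_sequence(rec, bank, (64, 64), cfg)
        for t in range(1, 4):
            assert np.allclose(seq.frames[t], seq.frames[0])

    def test_out_of_grid_warns(self):
        patch = isyn.gaussian_psf(2, 2, 9)
        rec = _static_record([[-5, 200]], [1.0])
        with pytest.warns(UserWarning):
            isyn.render_sequence(rec, patch, (64, 64),
                                 isyn.RenderConfig(rotation_deg=0, scale_jitter=0))


class TestAddNoise:
    def test_sigma_zero_identity(self):
        seq = isyn.FrameSequence(frames=np.random.rand(2, 16, 16))
        out = isyn.add_noise(seq, 0.0)
        assert np.array_equal(out.frames, seq.frames)

    def test_rayleigh_mean(self):
        seq = isyn.FrameSequence(frames=np.zeros((4, 64, 64)))
        out = isyn.add_noise(seq, 1.0, rng_seed=0)
        assert out.frames.mean() == pytest.approx(np.sqrt(np.pi / 2), rel=0.02)

    def test_reproducible(self):
        seq = isyn.FrameSequence(frames=np.zeros((1, 8, 8)))
        a = isyn.add_noise(seq, 0.5, rng_seed=9)
        b = isyn.add_noise(seq, 0.5, rng_seed=9)
        assert np.array_equal(a.frames, b.frames)

    def test_negative_sigma_rejected(self):
        seq = isyn.FrameSequence(frames=np.zeros((1, 4, 4)))
        with pytest.raises(ValueError):
            isyn.add_noise(seq, -1.0)


class TestAngleScaling:
    @given(st.floats(-np.pi, np.pi))
    @settings(max_examples=100, deadline=None)
    def test_round_trip(self, theta):
        assert isyn.unscale_angle(isyn.scale_angle(theta)) == pytest.approx(theta, abs=1e-12)

    def test_endpoints(self):
        assert isyn.scale_angle(-np.pi) == 0.0
        assert isyn.scale_angle(np.pi) == 1.0
        assert isyn.scale_angle(0.0) == 0.5


class TestRasterizeGroundTruth:
    def test_centerline_magnitude_and_angle(self):
        g = straight_tube_graph(length=60, radius=3.0, v_ref=2.0)
        vm = isyn.rasterize_ground_truth(g)
        assert vm.magnitude[20, 30] == pytest.approx(2.0)
        # flow along +columns: tangent angle 0 -> scaled angle 0.5
        assert vm.angle[20, 30] == pytest.approx(0.5)

    def test_profile_shape_across_vessel(self):
        g = straight_tube_graph(length=60, radius=3.0, v_ref=2.0)
        vm = isyn.rasterize_ground_truth(g, profile_exponent=1)
        profile = vm.magnitude[17:24, 40]
        expected = 2.0 * (1 - np.abs(np.arange(-3, 4)) / 3.0)
        assert np.allclose(profile, expected, atol=1e-9)

    def test_background_zero(self):
        g = straight_tube_graph(length=20, radius=2.0)
        vm = isyn.rasterize_ground_truth(g)
        assert vm.magnitude[0, 0] == 0.0
        assert vm.angle[0, 0] == 0.0

    def test_overlap_max_wins(self):
        g = straight_tube_graph(length=60, radius=3.0, v_ref=1.0)
        g2 = straight_tube_graph(length=60, radius=3.0, v_ref=5.0)
        g.add_edge(g2.edges[0])
        vm = isyn.rasterize_ground_truth(g)
        assert vm.magnitude[20, 30] == pytest.approx(5.0)


class TestMakeTrainingSet:
    def test_shapes_and_determinism(self):
        tmpl = synthetic_vessel_template(48, 48, n_trees=1, radius_range=(2, 4), rng_seed=0)
        cfg = isyn.DatasetConfig(clip_len=4, patch=48, n_bubbles=10)
        a = isyn.make_training_set([tmpl], 2, cfg, rng_seed=5)
        b = isyn.make_training_set([tmpl], 2, cfg, rng_seed=5)
        assert a[0].shape == (2, 4, 48, 48)
        assert a[1].shape == (2, 2, 48, 48)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_inputs_normalized(self):
        tmpl = synthetic_vessel_template(48, 48, n_trees=1, radius_range=(2, 4), rng_seed=1)
        cfg = isyn.DatasetConfig(clip_len=4, patch=48, n_bubbles=10)
        inputs, _, _ = isyn.make_training_set([tmpl], 1, cfg, rng_seed=0)
        assert inputs.max() == pytest.approx(1.0, rel=1e-5)
        assert inputs.min() >= 0.0

    def test_near_zero_velocity_graph_gives_near_zero_target(self):
        tmpl = synthetic_vessel_template(48, 48, n_trees=1, radius_range=(2, 4), rng_seed=2)
        table = RadiusVelocityTable(pairs=[[4.0, 0.0]])  # floor-clipped draws
        cfg = isyn.DatasetConfig(clip_len=4, patch=48, n_bubbles=5, velocity_table=table)
        _, targets, _ = isyn.make_training_set([tmpl], 1, cfg, rng_seed=0)
        from smv.vessel_graph import VELOCITY_FLOOR

        assert targets[0, 0].max() <= VELOCITY_FLOOR + 1e-6

    def test_empty_templates_raise(self):
        with pytest.raises(ValueError):
            isyn.make_training_set([], 1)

    def test_hdf5_round_trip(self, tmp_path):
        tmpl = synthetic_vessel_template(48, 48, n_trees=1, radius_range=(2, 4), rng_seed=0)
        cfg = isyn.DatasetConfig(clip_len=4, patch=48, n_bubbles=5)
        inputs, targets, split = isyn.make_training_set([tmpl], 2, cfg, rng_seed=0)
        path = str(tmp_path / "ds.h5")
        isyn.save_dataset_hdf5(path, inputs, targets, split, seed=0)
        i2, t2, s2, meta = isyn.load_dataset_hdf5(path)
        assert np.array_equal(inputs, i2)
        assert np.array_equal(targets, t2)
        assert s2 == split
        assert meta["pixel_size"] == 4.9
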