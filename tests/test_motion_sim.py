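"""Sampling order, motion tracks, rigid transforms and k-space simulation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import kscrub as ks
from kscrub.errors import ConfigurationError, DegenerateInputError
from kscrub.phantoms import as_pixels
from tests.conftest import simulate_small


class TestSamplingOrder:
    def test_full_center_fraction_is_sequential(self):
        order = ks.make_sampling_order(256, center_fraction=1.0, seed=0)
        assert np.array_equal(order.order, np.arange(256))

    def test_centered_block_placement(self):
        # numPE=20, cf=0.15: block of floor(3) lines at 10 - 1 = 9
        order = ks.make_sampling_order(20, center_fraction=0.15, seed=4)
        assert list(order.order[:3]) == [9, 10, 11]
        assert sorted(order.order.tolist()) == list(range(20))

    @settings(max_examples=25, deadline=None)
    @given(
        num_pe=st.integers(8, 64),
        cf=st.floats(0.05, 1.0),
        seed=st.integers(0, 2**20),
    )
    def test_always_a_permutation(self, num_pe, cf, seed):
        order = ks.make_sampling_order(num_pe, center_fraction=cf, seed=seed)
        assert sorted(order.order.tolist()) == list(range(num_pe))
        block = int(np.floor(cf * num_pe))
        start = num_pe // 2 - block // 2
        assert list(order.order[:block]) == list(range(start, start + block))

    def test_gaussian_stage_prefers_center(self):
        """Averaged over seeds, edge lines are sampled later than lines just
        outside the center block."""
        num_pe, n_seeds = 64, 100
        t_edge, t_near = 0.0, 0.0
        for seed in range(n_seeds):
            order = ks.make_sampling_order(num_pe, seed=seed)
            times = order.times()
            t_edge += times[:8].mean() + times[-8:].mean()
            t_near += times[12:20].mean() + times[44:52].mean()
        assert t_edge > t_near

    def test_determinism(self):
        a = ks.make_sampling_order(64, seed=9)
        b = ks.make_sampling_order(64, seed=9)
        assert np.array_equal(a.order, b.order)

    def test_bad_center_fraction(self):
        with pytest.raises(ConfigurationError):
            ks.make_sampling_order(64, center_fraction=0.0)
        with pytest.raises(ConfigurationError):
            ks.make_sampling_order(64, center_fraction=1.5)


class TestMotionTrack:
    def test_no_motion_track_is_all_zero(self):
        track = ks.make_motion_track(64, start_fraction=1.0, seed=0)
        assert np.all(track.poses == 0)
        assert track.start_index == 64

    def test_start_index_rounding(self):
        track = ks.make_motion_track(256, start_fraction=0.35, seed=0)
        assert track.start_index == 90
        assert np.all(track.poses[:90] == 0)
        assert np.all(track.poses[90:] != 0)

    @pytest.mark.parametrize("seed", [0, 1, 17])
    def test_pose_bounds(self, seed):
        track = ks.make_motion_track(256, 0.35, max_translation=5, max_rotation=5, seed=seed)
        moving = track.poses[track.start_index :]
        assert np.abs(moving[:, :2]).max() <= 5.0
        assert np.abs(moving[:, 2]).max() <= 5.0

    def test_negative_bounds_rejected(self):
        with pytest.raises(ConfigurationError):
            ks.make_motion_track(64, 0.5, max_translation=-1)


class TestApplyRigid:
    def test_identity_pose(self, ellipses64):
        out = ks.apply_rigid(ellipses64, 0, 0, 0)
        assert np.array_equal(as_pixels(out), ellipses64.pixels)

    def test_integer_shift_round_trip(self, ellipses64):
        img = ellipses64.pixels
        shifted = as_pixels(ks.apply_rigid(img, 3, -2, 0))
        # moved pixels are exact
        assert np.allclose(shifted[0:62, 3:64], img[2:64, 0:61])
        back = as_pixels(ks.apply_rigid(shifted, -3, 2, 0))
        assert np.allclose(back[5:-5, 5:-5], img[5:-5, 5:-5])

    @pytest.mark.parametrize("theta", [10.0, 33.3, -45.0])
    def test_rotation_of_circular_phantom_invariant(self, theta):
        rr, cc = np.mgrid[0:64, 0:64].astype(float)
        r = np.hypot(rr - 31.5, cc - 31.5)  # centered on the rotation axis
        blob = np.exp(-((r / 10.0) ** 2))
        out = ks.apply_rigid(blob, 0, 0, theta)
        rms = np.sqrt(np.mean((out - blob) ** 2))
        assert rms < 1e-3


class TestSimulateKspace:
    def test_zero_track_reproduces_reference(self, ellipses64):
        order = ks.make_sampling_order(64, seed=0)
        track = ks.make_motion_track(64, start_fraction=1.0, seed=0)
        acq = ks.simulate_kspace(ellipses64, order, track)
        assert np.array_equal(acq.k_motion, ks.fft2c(ellipses64.pixels))
        img = ks.corrupted_image(acq)
        assert np.allclose(img.pixels, ellipses64.pixels, atol=1e-10)

    def test_pre_motion_columns_exact(self):
        acq = simulate_small(seed=21, start_fraction=0.35)
        k_ref = ks.fft2c(as_pixels(acq.reference))
        for t in range(acq.true_start):
            pe = acq.order.order[t]
            assert np.array_equal(acq.k_motion[:, pe], k_ref[:, pe])

    def test_center_block_motion_free(self):
        """With center sampled first and motion starting at >= 35%, every
        center-block line is untouched."""
        acq = simulate_small(seed=33, start_fraction=0.35)
        k_ref = ks.fft2c(as_pixels(acq.reference))
        block = int(np.floor(0.15 * 64))
        for pe in acq.order.order[:block]:
            assert np.array_equal(acq.k_motion[:, pe], k_ref[:, pe])

    def test_motion_lowers_psnr(self, ellipses64):
        order = ks.make_sampling_order(64, seed=1)
        still = ks.make_motion_track(64, 1.0, seed=2)
        moving = ks.make_motion_track(64, 0.35, seed=2)
        img_still = ks.corrupted_image(ks.simulate_kspace(ellipses64, order, still))
        img_moving = ks.corrupted_image(ks.simulate_kspace(ellipses64, order, moving))
        p_moving = ks.psnr(img_moving, ellipses64)
        assert np.isfinite(p_moving)
        assert ks.psnr(img_still, ellipses64) > p_moving

    def test_earlier_motion_means_more_ghosting(self):
        """Mean absolute deviation from the reference is larger when motion
        starts at 35% than at 50% of sampling time (20 seed pairs)."""
        mad35, mad50 = 0.0, 0.0
        for seed in range(20):
            for frac, acc in ((0.35, "a"), (0.50, "b")):
                acq = simulate_small(seed=seed, start_fraction=frac)
                err = np.mean(
                    np.abs(ks.corrupted_image(acq).pixels - as_pixels(acq.reference))
                )
                if frac == 0.35:
                    mad35 += err
                else:
                    mad50 += err
        assert mad35 > mad50

    def test_length_mismatch_rejected(self, ellipses64):
        order = ks.make_sampling_order(32, seed=0)
        track = ks.make_motion_track(64, 0.5, seed=0)
        with pytest.raises(ConfigurationError):
            ks.simulate_kspace(ellipses64, order, track)

    def test_all_zero_kspace_rejected(self):
        acq = simulate_small(seed=2)
        acq.k_motion = np.zeros_like(acq.k_motion)
        with pytest.raises(DegenerateInputError):
            ks.corrupted_image(acq)

    def test_simulator_deterministic(self):
        a = simulate_small(seed=42)
        b = simulate_small(seed=42)
        assert np.array_equal(a.k_motion, b.k_motion)

    def test_corrupted_image_max_is_one(self):
        acq = simulate_small(seed=3)
        assert ks.corrupted_image(acq).pixels.max() == 1.0
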