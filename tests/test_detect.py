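"""Per-line k-space scoring, Otsu thresholding and motion-start detection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import kscrub as ks
from kscrub.detect import compute_psnr_k, detect_lines, detect_motion_start, otsu_threshold
from kscrub.errors import ConfigurationError, DegenerateInputError
from kscrub.motion import SamplingOrder
from kscrub.phantoms import as_pixels
from tests.conftest import simulate_small


def _order(seq):
    seq = np.asarray(seq, dtype=np.int64)
    return SamplingOrder(order=seq, center_fraction=0.15, sigma=len(seq) / 6)


def brute_force_otsu(values):
    """Independent oracle: maximize between-class variance over all splits."""
    v = np.sort(np.asarray(values, float))
    n = len(v)
    best_bcv, best_thr = -1.0, None
    for i in range(1, n):
        if v[i - 1] == v[i]:
            continue
        lo, hi = v[:i], v[i:]
        bcv = (len(lo) / n) * (len(hi) / n) * (lo.mean() - hi.mean()) ** 2
        if bcv > best_bcv:
            best_bcv = bcv
            best_thr = (v[i - 1] + v[i]) / 2.0
    return best_thr


class TestPsnrK:
    def test_identical_lines_are_infinite(self):
        k = np.array([[1 + 1j, 2], [3, 4j]])
        assert np.all(np.isposinf(compute_psnr_k(k, k.copy())))

    def test_two_sample_hand_case(self):
        k_motion = np.array([[1.0 + 0j], [0.0 + 0j]])
        k_filtered = np.zeros((2, 1), dtype=complex)
        score = compute_psnr_k(k_motion, k_filtered)[0]
        assert score == pytest.approx(10 * np.log10(2), abs=1e-9)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(16, 8)) + 1j * rng.normal(size=(16, 8))
        b = rng.normal(size=(16, 8)) + 1j * rng.normal(size=(16, 8))
        assert np.allclose(compute_psnr_k(a, b), compute_psnr_k(3.7 * a, 3.7 * b))

    def test_all_zero_line_flagged_minus_inf(self, caplog):
        a = np.zeros((4, 2), dtype=complex)
        a[:, 1] = 1.0
        b = np.ones((4, 2), dtype=complex)
        with caplog.at_level("WARNING"):
            scores = compute_psnr_k(a, b)
        assert np.isneginf(scores[0])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ConfigurationError):
            compute_psnr_k(np.zeros((4, 4)), np.zeros((4, 5)))


class TestOtsu:
    def test_two_clusters(self):
        thr = otsu_threshold([1, 1, 1, 10, 10, 10])
        assert 1 < thr < 10

    def test_singleton_upper_class(self):
        thr = otsu_threshold([0, 0, 0, 0, 100])
        assert 0 < thr < 100
        assert thr == brute_force_otsu([0, 0, 0, 0, 100])

    def test_matches_brute_force_on_random_sets(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(2, 65))
            vals = rng.normal(size=n) * rng.uniform(0.5, 20)
            if np.unique(vals).size < 2:
                continue
            assert otsu_threshold(vals) == pytest.approx(brute_force_otsu(vals))

    def test_against_histogram_otsu(self):
        """Cross-check with scikit-image's 256-bin histogram Otsu: the exact
        all-splits optimizer must achieve at least the between-class
        variance of the binned approximation on every random score set."""
        from skimage.filters import threshold_otsu as histogram_otsu

        def bcv_at(vals, thr):
            v = np.asarray(vals, float)
            lo, hi = v[v < thr], v[v >= thr]
            if not lo.size or not hi.size:
                return 0.0
            n = v.size
            return (lo.size / n) * (hi.size / n) * (lo.mean() - hi.mean()) ** 2

        rng = np.random.default_rng(11)
        for _ in range(100):
            n_lo, n_hi = rng.integers(10, 60, size=2)
            vals = np.concatenate([
                rng.normal(0, 1, size=n_lo),
                rng.normal(6, 1, size=n_hi),
            ])
            thr = otsu_threshold(vals)
            sk = histogram_otsu(vals, nbins=256)
            # the exact optimizer is never worse than the binned approximation
            assert bcv_at(vals, thr) >= bcv_at(vals, sk) - 1e-9

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(DegenerateInputError):
            otsu_threshold([3.0, 3.0, 3.0])
        with pytest.raises(DegenerateInputError):
            otsu_threshold([1.0])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=40).filter(
        lambda v: np.unique(v).size >= 2))
    def test_threshold_between_class_means(self, values):
        thr = otsu_threshold(values)
        v = np.asarray(values)
        lo, hi = v[v < thr], v[v >= thr]
        assert lo.size and hi.size
        assert lo.mean() < thr < hi.mean()


class TestDetectMotionStart:
    def test_two_consecutive_ones(self):
        scores = np.array([9.0, 9, 9, 9, 1, 1, 1, 9])
        order = _order(range(8))
        res = detect_motion_start(scores, 5.0, order, n_exclude_per_side=0)
        assert res.detected_start == 4
        assert np.array_equal(res.retained_mask, order.times() < 4)

    def test_isolated_one_tolerated(self):
        # time-ordered labels 0,0,0,1,0,1,1 -> start at the pair, not time 3
        scores = np.array([9.0, 9, 9, 1, 9, 1, 1])
        res = detect_motion_start(scores, 5.0, _order(range(7)), 0)
        assert res.detected_start == 5

    def test_no_motion_all_retained(self):
        scores = np.full(16, 30.0)
        res = detect_motion_start(scores, 5.0, _order(range(16)), 2)
        assert res.detected_start is None
        assert res.retained_mask.all()

    def test_excluded_lines_removed_from_sequence(self):
        # PE 0 is affected but excluded: the pair must come from kept lines
        scores = np.array([1.0, 9, 9, 9, 1, 1, 9, 9])
        res = detect_motion_start(scores, 5.0, _order(range(8)), n_exclude_per_side=1)
        assert res.detected_start == 4
        assert res.excluded[0] and res.excluded[-1]

    def test_excluded_gap_before_pair_moves_start_earlier(self):
        # time order: PE 3 (kept, 0), PE 0 (excluded, affected), PE 4,5 (1,1)
        scores = np.array([1.0, 9, 9, 9, 1, 1, 9, 9])
        order = _order([3, 0, 4, 5, 6, 7, 2, 1])
        res = detect_motion_start(scores, 5.0, order, n_exclude_per_side=1)
        # earliest time consistent with the last known-good line
        assert res.detected_start == 1
        assert np.array_equal(res.retained_mask, order.times() < 1)

    def test_labels_against_threshold(self):
        scores = np.array([np.inf, 10.0, 2.0, -np.inf])
        res = detect_motion_start(scores, 5.0, _order(range(4)), 0)
        assert res.labels.tolist() == [0, 0, 1, 1]

    def test_lowering_threshold_never_decreases_unaffected(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(10, 5, size=32)
        order = _order(range(32))
        n_prev = -1
        for thr in np.linspace(30, -10, 9):
            res = detect_motion_start(scores, thr, order, 0)
            n_zero = int(np.sum(res.labels == 0))
            assert n_zero >= n_prev
            n_prev = n_zero

    def test_excessive_exclusion_rejected(self):
        with pytest.raises(ConfigurationError):
            detect_motion_start(np.zeros(8), 0.0, _order(range(8)), 4)


class TestOracleFilterDetection:
    def test_oracle_scores_pre_motion_infinite(self):
        acq = simulate_small(seed=9, start_fraction=0.4)
        k_ref = ks.fft2c(as_pixels(acq.reference))
        scores = compute_psnr_k(acq.k_motion, k_ref)
        times = acq.order.times()
        assert np.all(np.isposinf(scores[times < acq.true_start]))
        assert np.all(np.isfinite(scores[times >= acq.true_start]))

    @pytest.mark.parametrize("frac", [0.35, 0.5])
    def test_retained_lines_truly_motion_free(self, frac):
        for seed in range(5):
            acq = simulate_small(seed=60 + seed, start_fraction=frac)
            k_ref = ks.fft2c(as_pixels(acq.reference))
            res = detect_lines(acq.k_motion, k_ref, acq.order, n_exclude_per_side=10)
            times = acq.order.times()
            assert not np.any(res.retained_mask & (times >= acq.true_start))

    def test_identity_filter_degenerates_to_all_retained(self):
        acq = simulate_small(seed=70)
        res = detect_lines(acq.k_motion, acq.k_motion.copy(), acq.order, 10)
        assert res.detected_start is None
        assert res.retained_mask.all()
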