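"""Spot detection, tandem-reporter classification, densities, kymographs."""

import numpy as np
import pytest

from saltadyn.phases import Phase, PhaseSegmentation, PhaseState
from saltadyn.puncta import (
    ClassifyConfig,
    DetectionConfig,
    Punctum,
    classify_secondary,
    detect_puncta,
    kymograph,
    match_to_truth,
    percent_autophagosome,
    phase_density,
)
from saltadyn.synthio import (
    PunctaSceneParams,
    render_puncta_stack,
    render_transport_movie,
    spawn_seeds,
)

MIG, STAT = PhaseState.MIG, PhaseState.STAT


def _gaussian_spot(shape, y, x, amp, sigma):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return amp * np.exp(-((rr - y) ** 2 + (cc - x) ** 2) / (2 * sigma**2))


class TestDetectPuncta:
    def test_blank_frame_empty(self):
        assert detect_puncta(np.zeros((64, 64))) == []

    def test_blank_noisy_frame_empty(self):
        rng = np.random.default_rng(0)
        img = 100.0 + 10.0 * rng.standard_normal((64, 64))
        assert detect_puncta(img) == []

    def test_single_spot_snr10(self):
        rng = np.random.default_rng(1)
        img = 100.0 + 10.0 * rng.standard_normal((64, 64))
        img += _gaussian_spot((64, 64), 30.0, 40.0, 100.0, 1.5)
        det = detect_puncta(img)
        assert len(det) == 1
        assert np.hypot(det[0].y - 30.0, det[0].x - 40.0) <= 1.0

    def test_sigma_too_large(self):
        with pytest.raises(ValueError, match="sigma"):
            detect_puncta(np.zeros((16, 16)), DetectionConfig(psf_sigma=10.0))

    def test_noise_free_scene_recovered_exactly_once(self):
        p = PunctaSceneParams(n_puncta=40, noise_sd=0.0, peak_snr=5.0, seed=3)
        # zero noise: amplitude comes from peak_snr * noise_sd, so force one
        p = PunctaSceneParams(n_puncta=40, noise_sd=1e-9, peak_snr=5e10, seed=3)
        stack, truth = render_puncta_stack(p)
        det = detect_puncta(stack[0])
        pos = np.array([[d["y"], d["x"]] for d in truth.puncta_list])
        tp, fp, fn = match_to_truth(det, pos)
        assert (tp, fp, fn) == (len(truth.puncta_list), 0, 0)

    def test_detection_f1_at_snr5(self):
        tps = fps = fns = 0
        for s in spawn_seeds(17, 8):
            stack, truth = render_puncta_stack(PunctaSceneParams(seed=s))
            det = detect_puncta(stack[0])
            pos = np.array([[d["y"], d["x"]] for d in truth.puncta_list])
            tp, fp, fn = match_to_truth(det, pos)
            tps, fps, fns = tps + tp, fps + fp, fns + fn
        f1 = 2 * tps / (2 * tps + fps + fns)
        assert f1 >= 0.95

    def test_cross_check_against_reference_blob_detector(self):
        # an established LoG blob detector finds the same spots on a clean scene
        from skimage.feature import blob_log

        p = PunctaSceneParams(n_puncta=25, noise_sd=1e-9, peak_snr=5e10, seed=8)
        stack, _ = render_puncta_stack(p)
        det = detect_puncta(stack[0])
        ref = blob_log(
            stack[0] - stack[0].min(), min_sigma=1.5, max_sigma=1.5,
            num_sigma=1, threshold=1.0,
        )
        assert len(det) == len(ref)
        d = np.linalg.norm(
            np.array([[q.y, q.x] for q in det])[:, None]
            - ref[None, :, :2], axis=2,
        )
        assert d.min(axis=1).max() <= 1.0


class TestClassifySecondary:
    def test_zero_secondary_adds_no_labels(self):
        stack, _ = render_puncta_stack(PunctaSceneParams(n_puncta=20, seed=4))
        det = detect_puncta(stack[0])
        classify_secondary(det, np.zeros_like(stack[1]))
        assert all("GFP+" not in p.labels for p in det)

    def test_copy_of_detection_channel_labels_all(self):
        stack, _ = render_puncta_stack(PunctaSceneParams(n_puncta=20, seed=4))
        det = detect_puncta(stack[0])
        classify_secondary(det, stack[0].copy())
        assert all("GFP+" in p.labels for p in det)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            classify_secondary(
                [], np.zeros((8, 8)), reference_shape=(16, 16)
            )

    def test_dual_fraction_recovered(self):
        est, truth_frac = [], []
        for s in spawn_seeds(23, 10):
            stack, truth = render_puncta_stack(
                PunctaSceneParams(frac_dual=0.355, seed=s)
            )
            det = detect_puncta(stack[0])
            classify_secondary(det, stack[1])
            est.append(percent_autophagosome(det) / 100.0)
            truth_frac.append(np.mean([d["dual"] for d in truth.puncta_list]))
        # recovered pooled fraction close to the realized truth
        assert abs(np.mean(est) - np.mean(truth_frac)) < 0.03

    def test_intensity_scaling_invariance(self):
        stack, _ = render_puncta_stack(
            PunctaSceneParams(n_puncta=30, frac_dual=0.5, seed=6)
        )
        det1 = detect_puncta(stack[0])
        classify_secondary(det1, stack[1])
        det2 = detect_puncta(7.3 * stack[0])
        classify_secondary(det2, 7.3 * stack[1])
        assert percent_autophagosome(det1) == percent_autophagosome(det2)


class TestPercentAutophagosome:
    def _puncta(self, n_dual, n_total):
        out = []
        for i in range(n_total):
            p = Punctum(frame=0, y=float(i), x=0.0)
            if i < n_dual:
                p.labels.add("GFP+")
            out.append(p)
        return out

    def test_half_dual(self):
        assert percent_autophagosome(self._puncta(2, 4)) == pytest.approx(50.0)

    def test_all_dual(self):
        assert percent_autophagosome(self._puncta(5, 5)) == pytest.approx(100.0)

    def test_no_rfp_undefined(self):
        with pytest.raises(ValueError, match="RFP"):
            percent_autophagosome([])


class TestPhaseDensity:
    def _seg(self, phases):
        return PhaseSegmentation(
            cell_id="cell-0", phases=[Phase(s, a, b) for s, a, b in phases]
        )

    def test_constant_density_all_100(self):
        t = np.arange(0.0, 3600.0, 30.0)
        counts = np.full(t.size, 30.0)
        seg = self._seg(
            [(STAT, 0.0, 1200.0), (MIG, 1200.0, 2400.0), (STAT, 2400.0, 3570.0)]
        )
        res = phase_density(counts, 100.0, seg, t)
        np.testing.assert_allclose(res.normalized, 100.0)

    def test_first_stationary_is_exactly_100(self):
        rng = np.random.default_rng(1)
        t = np.arange(0.0, 3600.0, 30.0)
        counts = rng.integers(10, 60, t.size).astype(float)
        seg = self._seg([(MIG, 0.0, 900.0), (STAT, 900.0, 2100.0),
                         (MIG, 2100.0, 3570.0)])
        res = phase_density(counts, 50.0, seg, t)
        assert res.normalized[1] == 100.0

    def test_programmed_contrast(self):
        t = np.arange(0.0, 3600.0, 30.0)
        seg = self._seg([(STAT, 0.0, 1800.0), (MIG, 1800.0, 3570.0)])
        counts = np.where(t < 1800.0, 50.0, 33.0)
        res = phase_density(counts, 100.0, seg, t)
        assert res.normalized[0] == 100.0
        assert res.normalized[1] == pytest.approx(66.0)

    def test_three_point_sampling_equals_brute_force_on_constant(self):
        t = np.arange(0.0, 1200.0, 30.0)
        counts = np.full(t.size, 12.0)
        seg = self._seg([(STAT, 0.0, 600.0), (MIG, 600.0, 1170.0)])
        res = phase_density(counts, 10.0, seg, t)
        for d in res.densities:
            assert d.density == pytest.approx(1.2)

    def test_short_phase_flagged(self):
        t = np.arange(0.0, 600.0, 30.0)
        counts = np.full(t.size, 5.0)
        seg = self._seg([(STAT, 0.0, 45.0), (MIG, 45.0, 570.0)])
        res = phase_density(counts, 10.0, seg, t)
        assert res.densities[0].flagged  # only 2 frames available
        assert not res.densities[1].flagged

    def test_no_stationary_phase_errors(self):
        t = np.arange(0.0, 600.0, 30.0)
        seg = self._seg([(MIG, 0.0, 570.0)])
        with pytest.raises(ValueError, match="stationary"):
            phase_density(np.full(t.size, 5.0), 10.0, seg, t)

    def test_sparse_counts_missing_frame_errors(self):
        t = np.arange(0.0, 600.0, 30.0)
        seg = self._seg([(STAT, 0.0, 570.0)])
        with pytest.raises(ValueError, match="frame"):
            phase_density({0: 5.0}, 10.0, seg, t)


class TestKymograph:
    _path = np.array([[32.0, 5.0], [32.0, 120.0]])

    def test_static_spot_horizontal_line(self):
        stack = render_transport_movie(
            self._path, n_frames=20, start_s=[40.0], speed_s=[0.0],
            amplitude=100.0,
        )
        k = kymograph(stack, self._path)
        rows = k.argmax(axis=0)
        assert np.all(rows == rows[0])

    def test_moving_spot_slope_matches_speed(self):
        speed = 2.0  # px / frame
        stack = render_transport_movie(
            self._path, n_frames=30, start_s=[10.0], speed_s=[speed],
            amplitude=100.0,
        )
        k = kymograph(stack, self._path)
        rows = k.argmax(axis=0).astype(float)
        fitted = np.polyfit(np.arange(30), rows, 1)[0]
        assert fitted == pytest.approx(speed, abs=0.1)

    def test_bidirectional_transport_both_slopes(self):
        stack = render_transport_movie(
            self._path, n_frames=25, start_s=[10.0, 100.0],
            speed_s=[2.0, -2.0], amplitude=100.0,
        )
        k = kymograph(stack, self._path)
        # track each punctum at its predicted arc position
        for f in (0, 12, 24):
            assert k[int(10 + 2 * f), f] > 50.0
            assert k[int(100 - 2 * f), f] > 50.0

    def test_degenerate_path(self):
        with pytest.raises(ValueError, match="2 points"):
            kymograph(np.zeros((3, 16, 16)), np.array([[4.0, 4.0]]))


class TestMatchToTruth:
    def test_duplicates_not_double_counted(self):
        truth = np.array([[10.0, 10.0]])
        det = [Punctum(0, 10.2, 10.1), Punctum(0, 10.4, 9.8)]
        tp, fp, fn = match_to_truth(det, truth)
        assert (tp, fp, fn) == (1, 1, 0)
        assert det[0].truth_link == 0 and det[1].truth_link is None

    def test_radius_enforced(self):
        truth = np.array([[10.0, 10.0]])
        det = [Punctum(0, 15.0, 10.0)]
        assert match_to_truth(det, truth, radius=2.0) == (0, 1, 1)
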