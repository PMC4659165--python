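"""Detector: HOG features vs a brute-force oracle, dense/windowed score
consistency, hard-negative-mining equivalence, suppression."""

import numpy as np
import pytest

from voxcyto.detect import (
    DetectorConfig,
    WindowFeaturizer,
    fit_linear_svm,
    load_model,
    nonmax_suppress,
    save_model,
    scan_detect,
    train_svm_with_mining,
)
from voxcyto.stacks import DetectionSet, VoxelStack

CFG = DetectorConfig()


def brute_force_feature(fz: WindowFeaturizer, center):
    """Independent double-loop HOG implementation sharing only the
    gradient definition (full-volume central differences)."""
    cx, cy, cz = center
    X, Y, Z = fz.data.shape
    g = fz.cfg.grid
    nb = fz.cfg.n_bins
    out = []
    # brightness over the xy window
    total = 0.0
    for i in range(cx - fz.wx // 2, cx - fz.wx // 2 + fz.wx):
        for j in range(cy - fz.wy // 2, cy - fz.wy // 2 + fz.wy):
            if 0 <= i < X and 0 <= j < Y:
                total += fz.data[i, j, cz]
    out.append(total / (fz.wx * fz.wy))

    def block(mag, bins, c0, c1, w0, w1, fixed):
        s0, s1 = w0 // g, w1 // g
        feats = []
        for bi in range(g):
            for bj in range(g):
                hist = np.zeros(nb)
                for i in range(c0 - w0 // 2 + bi * s0, c0 - w0 // 2 + bi * s0 + s0):
                    for j in range(c1 - w1 // 2 + bj * s1, c1 - w1 // 2 + bj * s1 + s1):
                        if fixed[0] == "z":
                            if 0 <= i < X and 0 <= j < Y:
                                hist[bins[i, j, fixed[1]]] += mag[i, j, fixed[1]]
                        else:
                            if 0 <= i < X and 0 <= j < Z:
                                hist[bins[i, fixed[1], j]] += mag[i, fixed[1], j]
                norm = np.sqrt((hist**2).sum())
                feats.extend(hist / (norm + 1e-12))
                feats.append(norm)
        return feats

    out.extend(block(fz.mag_xy, fz.bin_xy, cx, cy, fz.wx, fz.wy, ("z", cz)))
    out.extend(block(fz.mag_xz, fz.bin_xz, cx, cz, fz.wx, fz.wz, ("y", cy)))
    return np.array(out)


class TestFeatures:
    def test_constant_window_zero_gradients(self):
        fz = WindowFeaturizer(np.full((40, 40, 30), 3.0), (0.3, 0.3, 0.3), CFG)
        v = fz.feature((20, 20, 15))
        assert v[0] == pytest.approx(3.0)
        # every histogram entry zero, every norm zero
        assert np.allclose(v[1:], 0.0)

    def test_ramp_concentrates_in_one_bin(self):
        data = np.tile(np.arange(40.0)[:, None, None], (1, 40, 8))
        fz = WindowFeaturizer(data, (0.3, 0.3, 0.3), CFG)
        v = fz.feature((20, 20, 4))
        nb, g = CFG.n_bins, CFG.grid
        xy = v[1 : 1 + g * g * (nb + 1)].reshape(g * g, nb + 1)
        hists = xy[:, :nb]
        # gradient along +x everywhere: all mass in a single bin
        assert np.count_nonzero(hists.sum(axis=0) > 1e-9) == 1

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(4)
        data = rng.uniform(0, 1, (30, 28, 26))
        fz = WindowFeaturizer(data, (0.3, 0.3, 0.3), CFG)
        for center in [(15, 14, 13), (3, 20, 5), (0, 0, 0)]:
            assert np.allclose(
                fz.feature(center), brute_force_feature(fz, center), atol=1e-10
            )

    def test_dense_score_equals_windowed_score(self):
        rng = np.random.default_rng(5)
        data = rng.uniform(0, 1, (24, 24, 20))
        fz = WindowFeaturizer(data, (0.3, 0.3, 0.3), CFG)
        w = rng.normal(size=CFG.feature_length)
        sv = fz.score_volume(w)
        for c in [(12, 12, 10), (2, 20, 3), (23, 0, 19)]:
            assert sv[c] == pytest.approx(float(w @ fz.feature(c)), abs=1e-9)

    def test_translation_covariance_of_scores(self):
        rng = np.random.default_rng(6)
        data = rng.uniform(0, 1, (36, 30, 24))
        w = rng.normal(size=CFG.feature_length)
        s0 = WindowFeaturizer(data, (0.3, 0.3, 0.3), CFG).score_volume(w)
        shifted = np.roll(data, (3, 2, 1), axis=(0, 1, 2))
        s1 = WindowFeaturizer(shifted, (0.3, 0.3, 0.3), CFG).score_volume(w)
        m = 14  # exclude window-sized borders
        assert np.allclose(
            s1[3 + m : -m, 2 + m : -m, 1 + m : -m],
            s0[m : -m - 3, m : -m - 2, m : -m - 1],
            atol=1e-9,
        )


class TestTraining:
    def test_separable_clusters(self):
        rng = np.random.default_rng(7)
        pos = rng.normal(3, 0.3, (30, 10))
        neg = rng.normal(-3, 0.3, (60, 10))
        w = fit_linear_svm(
            np.vstack([pos, neg]),
            np.concatenate([np.ones(30), -np.ones(60)]),
            DetectorConfig(),
        )
        assert (pos @ w).min() > (neg @ w).max()

    def test_mining_equivalent_to_full_training(self):
        rng = np.random.default_rng(8)
        dim = 20
        pos = rng.normal(0.8, 1.0, (40, dim))
        neg = rng.normal(-0.8, 1.0, (160, dim))
        cfg = DetectorConfig(mining_init=20, mining_add=30, mining_rounds=50, svm_tol=1e-9)
        w_mined, log = train_svm_with_mining(pos, neg, cfg)
        w_full = fit_linear_svm(
            np.vstack([pos, neg]),
            np.concatenate([np.ones(len(pos)), -np.ones(len(neg))]),
            cfg,
        )
        cos = w_mined @ w_full / (np.linalg.norm(w_mined) * np.linalg.norm(w_full))
        assert cos > 0.999
        assert log["n_negatives"] <= len(neg)

    def test_latent_recentring_improves_offset_labels(self, trained_detector):
        # training log records a positive total latent shift: labelled
        # centres moved toward response maxima
        shifts = [rec["total_shift_um"] for rec in trained_detector.log["latent"]]
        assert len(shifts) == trained_detector.config.latent_passes
        assert shifts[0] >= 0.0


class TestScan:
    def test_infinite_threshold_empty(self, trained_detector, tube_phantom):
        dets = scan_detect(
            tube_phantom.dna, trained_detector, tau=np.inf, scales=[1.0]
        )
        assert len(dets) == 0

    def test_detections_near_every_truth(self, detection_run):
        dets, test_ph = detection_run
        truth = test_ph.truth.centers_um
        assert len(dets) >= len(truth)
        from scipy.spatial.distance import cdist

        d = cdist(truth, dets.coords_um)
        assert (d.min(axis=1) <= 1.5).all()

    def test_model_json_roundtrip(self, trained_detector, tmp_path):
        save_model(trained_detector, tmp_path / "m.json")
        back = load_model(tmp_path / "m.json")
        assert np.allclose(back.w, trained_detector.w)
        assert back.config == trained_detector.config


class TestSuppression:
    def test_close_pair_keeps_higher_score(self):
        dets = DetectionSet(
            np.array([[0.0, 0, 0], [0.5, 0, 0]]), np.array([1.0, 2.0])
        )
        out = nonmax_suppress(dets, radius_um=1.5)
        assert len(out) == 1 and out.scores[0] == 2.0

    def test_far_detections_untouched(self):
        coords = np.array([[0.0, 0, 0], [10.0, 0, 0], [20.0, 0, 0]])
        out = nonmax_suppress(DetectionSet(coords, np.array([1.0, 2.0, 3.0])), 1.5)
        assert len(out) == 3

    def test_matches_quadratic_oracle(self):
        rng = np.random.default_rng(9)
        coords = rng.uniform(0, 10, (100, 3))
        scores = rng.normal(size=100)
        out = nonmax_suppress(DetectionSet(coords, scores), radius_um=1.2)
        # O(n^2) greedy oracle
        order = np.argsort(-scores, kind="stable")
        kept = []
        for i in order:
            if all(np.linalg.norm(coords[i] - coords[j]) > 1.2 for j in kept):
                kept.append(i)
        expected = coords[kept]
        assert len(out) == len(expected)
        assert np.allclose(np.sort(out.coords_um, axis=0), np.sort(expected, axis=0))

    def test_zero_radius_rejected(self):
        with pytest.raises(ValueError):
            nonmax_suppress(DetectionSet(np.zeros((1, 3)), np.ones(1)), 0.0)
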