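"""Guide preprocessing: sliding-square normalization, Hessian
sheet enhancement, and the two guide routes."""

import numpy as np
import pytest
from scipy import ndimage

from voxcyto.preprocess import (
    GuideParams,
    fit_embryo_gain,
    make_guide_embryo,
    make_guide_worm,
    sharpen_normalize,
    sheetness,
    sheetness_from_eigenvalues,
)
from voxcyto.stacks import VoxelStack


def _brute_local_mean(plane, window):
    h = window // 2
    out = np.empty_like(plane, dtype=float)
    for i in range(plane.shape[0]):
        for j in range(plane.shape[1]):
            sub = plane[max(i - h, 0) : i + h + 1, max(j - h, 0) : j + h + 1]
            out[i, j] = sub.mean()
    return out


class TestSharpenNormalize:
    def test_constant_image_becomes_ones(self):
        stack = VoxelStack(np.full((10, 10, 4), 7.0), (1, 1, 1))
        out = sharpen_normalize(stack, window_um=3)
        assert np.allclose(out.data, 1.0)

    def test_z_gain_cancels(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(1, 2, (12, 12, 1))
        data = np.concatenate([base * g for g in (1.0, 0.3, 2.5)], axis=2)
        out = sharpen_normalize(VoxelStack(data, (1, 1, 1)), window_um=5)
        for z in (1, 2):
            assert np.allclose(out.data[:, :, z], out.data[:, :, 0], rtol=1e-10)

    def test_matches_brute_force_sliding_mean(self):
        rng = np.random.default_rng(1)
        plane = rng.uniform(0.5, 2.0, (5, 5))
        plane[2, 2] = 50.0
        stack = VoxelStack(plane[:, :, None], (1, 1, 1))
        out = sharpen_normalize(stack, window_um=3)
        expected = plane / _brute_local_mean(plane, 3)
        assert np.allclose(out.data[:, :, 0], expected, rtol=1e-10)

    def test_global_gain_invariance(self):
        rng = np.random.default_rng(2)
        data = rng.uniform(0, 1, (10, 10, 3))
        a = sharpen_normalize(VoxelStack(data, (1, 1, 1)), 3)
        b = sharpen_normalize(VoxelStack(4.2 * data, (1, 1, 1)), 3)
        assert np.allclose(a.data, b.data, rtol=1e-9)

    def test_window_too_large(self):
        with pytest.raises(ValueError):
            sharpen_normalize(VoxelStack(np.zeros((4, 4, 2)), (1, 1, 1)), window_um=10)


class TestSheetness:
    def test_pure_sheet_eigenvalues(self):
        assert sheetness_from_eigenvalues(-2.0, 0.0, 0.0) == pytest.approx(2.0)

    def test_isotropic_blob_eigenvalues(self):
        # (-2,-2,-2): ratios 1/2, response 2 e^{-1/4} e^{-1/4}
        expected = 2.0 * np.exp(-0.5)
        assert sheetness_from_eigenvalues(-2.0, -2.0, -2.0) == pytest.approx(expected)

    def test_nonnegative_eigenvalue_gives_zero(self):
        assert sheetness_from_eigenvalues(0.0, 1.0, 2.0) == 0.0
        assert sheetness_from_eigenvalues(1.0, 2.0, 3.0) == 0.0

    def test_bright_slab_peaks_at_plane(self):
        z0 = 10
        zz = np.arange(24)
        slab = np.exp(-((zz - z0) ** 2) / (2 * 1.5**2))
        data = np.tile(slab, (20, 20, 1))
        out = sheetness(VoxelStack(data, (1, 1, 1)))
        resp = out.data[10, 10, :]
        assert abs(int(np.argmax(resp)) - z0) <= 1
        # isotropic blob of the same peak responds much less
        xx, yy, zz3 = np.meshgrid(*[np.arange(24)] * 3, indexing="ij")
        blob = np.exp(-(((xx - 12) ** 2 + (yy - 12) ** 2 + (zz3 - 12) ** 2)) / (2 * 1.5**2))
        blob_out = sheetness(VoxelStack(blob, (1, 1, 1)))
        # equal-amplitude, equal-sigma blob is suppressed by the factor
        # e^{-1/2} relative to the sheet
        ratio = blob_out.data[12, 12, 12] / resp.max()
        assert ratio < 0.65
        assert ratio == pytest.approx(np.exp(-0.5), abs=0.05)

    def test_eigenvalues_match_brute_force_solver(self):
        rng = np.random.default_rng(3)
        data = ndimage.gaussian_filter(rng.normal(size=(12, 12, 12)), 1.5)
        spacing = (0.5, 0.5, 0.8)
        from voxcyto.preprocess import _hessian_eigenvalues

        eigs = _hessian_eigenvalues(data, spacing)
        gx, gy, gz = np.gradient(data, *spacing)
        hxx, hxy, hxz = np.gradient(gx, *spacing)
        _, hyy, hyz = np.gradient(gy, *spacing)
        hzz = np.gradient(gz, spacing[2], axis=2)
        for idx in [(2, 3, 4), (6, 6, 6), (10, 1, 8)]:
            H = np.array(
                [
                    [hxx[idx], hxy[idx], hxz[idx]],
                    [hxy[idx], hyy[idx], hyz[idx]],
                    [hxz[idx], hyz[idx], hzz[idx]],
                ]
            )
            expected = np.sort(np.linalg.eigvalsh(H))
            assert np.allclose(eigs[idx], expected, atol=1e-8)


class TestWormGuide:
    def test_constant_image_gives_zero_guide(self):
        out = make_guide_worm(VoxelStack(np.full((16, 16, 8), 3.0), (1, 1, 1)))
        assert np.allclose(out.data, 0.0)

    def test_deterministic(self, tube_phantom):
        a = make_guide_worm(tube_phantom.membrane)
        b = make_guide_worm(tube_phantom.membrane)
        assert np.array_equal(a.data, b.data)

    def test_boundary_contrast_on_phantom(self, clean_phantom):
        guide = make_guide_worm(clean_phantom.membrane)
        lab = clean_phantom.truth.labels
        boundary = np.zeros(lab.shape, bool)
        for ax in range(3):
            a = np.swapaxes(lab, 0, ax)
            d = (a[1:] != a[:-1]) & ((a[1:] != 0) | (a[:-1] != 0))
            b = np.swapaxes(boundary, 0, ax)
            b[1:] |= d
            b[:-1] |= d
        interior = (lab > 0) & (
            ndimage.distance_transform_edt(~boundary, sampling=(0.3, 0.3, 0.3)) > 0.8
        )
        assert guide.data[boundary].mean() > 3 * guide.data[interior].mean()
        assert np.all(guide.data >= 0) and np.all(np.isfinite(guide.data))


class TestEmbryoGuide:
    def _stack_from_model(self, coef, shape=(24, 24, 12), spacing=(0.5, 0.5, 1.0)):
        xs = np.arange(shape[0]) * spacing[0]
        ys = np.arange(shape[1]) * spacing[1]
        zs = np.arange(shape[2]) * spacing[2]
        m = np.exp(coef[0] * zs[None, None, :]) * (
            coef[1] * xs[:, None, None] + coef[2] * ys[None, :, None] + coef[3]
        )
        return VoxelStack(m, spacing)

    def test_constant_case(self):
        stack = VoxelStack(np.full((20, 20, 10), 5.0), (0.5, 0.5, 1.0))
        dets = np.array([[2, 2, 4], [6, 6, 4], [2, 6, 6], [6, 2, 6], [4, 4, 2.0]])
        coef = fit_embryo_gain(dets, np.full(5, 5.0))
        assert coef[0] == pytest.approx(0.0, abs=1e-6)
        assert coef[3] == pytest.approx(5.0, rel=1e-6)
        # default k = 1/3 applies threshold m0 / 3
        guide = make_guide_embryo(stack, dets, GuideParams())
        assert np.isfinite(guide.data).all()

    def test_parameter_recovery(self):
        true = np.array([0.08, 0.05, -0.03, 2.0])
        stack = self._stack_from_model(true)
        rng = np.random.default_rng(5)
        dets = rng.uniform([1, 1, 2], [10, 10, 9], size=(40, 3))
        means = []
        spacing = np.asarray(stack.spacing)
        for p in dets:
            c = np.rint(p / spacing).astype(int)
            means.append(stack.data[c[0], c[1], c[2]] * (1 + rng.normal(0, 0.01)))
        coef = fit_embryo_gain(dets, np.asarray(means))
        assert np.allclose(coef, true, rtol=0.05, atol=0.01)

    def test_all_background_gives_constant_guide(self):
        stack = VoxelStack(np.full((20, 20, 10), 1.0), (0.5, 0.5, 1.0))
        dets = np.array([[2, 2, 4], [6, 6, 4], [2, 6, 6], [6, 2, 6.0]])
        # threshold k*m0 = 1/3 < 1, so everything is foreground -> after
        # invert+blur the guide is constant
        guide = make_guide_embryo(stack, dets, GuideParams())
        assert np.ptp(guide.data) == pytest.approx(0.0, abs=1e-12)

    def test_too_few_detections(self):
        with pytest.raises(ValueError):
            fit_embryo_gain(np.zeros((3, 3)), np.ones(3))

    def test_degenerate_fit_falls_back(self):
        dets = np.array([[1, 1, 1], [2, 2, 2], [3, 3, 3], [4, 4, 4.0]])
        with pytest.warns(UserWarning):
            coef = fit_embryo_gain(dets, np.array([1.0, -1.0, 1.0, -1.0]))
        assert coef[0] == 0.0
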