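import numpy as np
import pytest

import surseg as ss
from surseg.features import compute_channel


def _impulse(shape=(15, 15, 15)):
    v = np.zeros(shape, dtype=np.float32)
    v[tuple(s // 2 for s in shape)] = 1.0
    return v


def _gauss_kernel_1d(sigma):
    """Explicit truncated, normalised discrete Gaussian (4-sigma radius)."""
    r = int(4 * sigma + 0.5)
    x = np.arange(-r, r + 1)
    k = np.exp(-x ** 2 / (2.0 * sigma ** 2))
    return k / k.sum()


class TestGaussian:
    def test_sigma_zero_identity(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=(6, 6, 6)).astype(np.float32)
        assert np.array_equal(ss.gaussian(v, 0), v)

    def test_constant_preserved(self):
        out = ss.gaussian(np.full((8, 8, 8), 3.5), 2.0)
        assert np.allclose(out, 3.5, atol=1e-5)

    def test_impulse_matches_separable_kernel(self):
        out = ss.gaussian(_impulse(), 1.0)
        k = _gauss_kernel_1d(1.0)
        expected = k[:, None, None] * k[None, :, None] * k[None, None, :]
        centre = tuple(s // 2 for s in (15, 15, 15))
        r = len(k) // 2
        sl = tuple(slice(c - r, c + r + 1) for c in centre)
        assert np.allclose(out[sl], expected, atol=1e-6)
        assert out.sum() == pytest.approx(1.0, abs=1e-5)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            ss.gaussian(np.zeros((4, 4, 4)), -1.0)


class TestTV:
    def test_constant_unchanged(self):
        out = ss.tv_denoise(np.full((8, 8, 8), 2.0), weight=0.2)
        assert np.allclose(out, 2.0, atol=1e-6)

    def test_weight_to_zero_is_identity(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=(8, 8, 8)).astype(np.float32)
        out = ss.tv_denoise(v, weight=1e-6, tol=1e-6)
        assert np.abs(out - v).max() < 1e-3

    def test_step_edge_denoised_and_preserved(self):
        """Noise within each side shrinks; the step stays within 1 voxel."""
        rng = np.random.default_rng(2)
        step = np.zeros((8, 8, 16))
        step[..., 8:] = 1.0
        noisy = step + rng.normal(0, 0.15, step.shape)
        out = ss.tv_denoise(noisy, weight=0.15)
        for sl in (np.s_[..., :7], np.s_[..., 9:]):
            assert out[sl].var() < noisy[sl].var()
        profile = out.mean(axis=(0, 1))
        edge = int(np.argmax(np.diff(profile)))
        assert abs(edge - 7) <= 1

    def test_rof_objective_decreases(self):
        """The denoised volume has lower ROF objective than the input."""
        rng = np.random.default_rng(3)
        v = rng.normal(size=(10, 10, 10))
        w = 0.2

        def rof(u):
            g = np.array(np.gradient(u))
            tv = np.sqrt((g ** 2).sum(axis=0)).sum()
            return tv + ((u - v) ** 2).sum() / (2 * w)

        out = ss.tv_denoise(v, weight=w)
        assert rof(out) < rof(v)

    def test_nonpositive_weight(self):
        with pytest.raises(ValueError):
            ss.tv_denoise(np.zeros((4, 4, 4)), weight=0.0)


class TestDerivatives:
    def test_constant_zero_first_order(self):
        out = ss.gaussian_derivative(np.full((8, 8, 8), 4.0), 1.0, (0, 0, 1))
        assert np.allclose(out, 0.0, atol=1e-5)

    def test_ramp_slope_recovered(self):
        x = np.broadcast_to(np.arange(16.0), (8, 8, 16)).copy()
        out = ss.gaussian_derivative(3.0 * x, 1.0, (0, 0, 1))
        interior = out[:, :, 5:-5]
        assert np.allclose(interior, 3.0, atol=1e-3)

    def test_order_zero_equals_gaussian(self):
        rng = np.random.default_rng(4)
        v = rng.normal(size=(8, 8, 8)).astype(np.float32)
        assert np.allclose(ss.gaussian_derivative(v, 1.5, (0, 0, 0)),
                           ss.gaussian(v, 1.5), atol=1e-6)

    def test_total_order_capped(self):
        with pytest.raises(ValueError):
            ss.gaussian_derivative(np.zeros((4, 4, 4)), 1.0, (1, 1, 1))


class TestDoGLoG:
    def test_dog_is_definitional_subtraction(self):
        rng = np.random.default_rng(5)
        v = rng.normal(size=(10, 10, 10)).astype(np.float32)
        out = ss.difference_of_gaussians(v, 1.0, 2.0)
        assert np.allclose(out, ss.gaussian(v, 1.0) - ss.gaussian(v, 2.0))

    def test_dog_constant_zero(self):
        out = ss.difference_of_gaussians(np.full((8, 8, 8), 7.0), 1.0, 2.0)
        assert np.allclose(out, 0.0, atol=1e-5)

    def test_dog_impulse_centre_is_kernel_peak_difference(self):
        out = ss.difference_of_gaussians(_impulse(), 1.0, 2.0)
        peak1 = _gauss_kernel_1d(1.0).max() ** 3
        peak2 = _gauss_kernel_1d(2.0).max() ** 3
        assert out[7, 7, 7] == pytest.approx(peak1 - peak2, rel=1e-4)

    def test_dog_sigma_order_enforced(self):
        with pytest.raises(ValueError):
            ss.difference_of_gaussians(np.zeros((4, 4, 4)), 2.0, 1.0)

    def test_log_constant_and_ramp_zero(self):
        # kernel truncation leaves ~1e-4 relative residual on constants
        assert np.allclose(
            ss.laplacian_of_gaussian(np.full((8, 8, 8), 2.0), 1.0), 0, atol=1e-3)
        x = np.broadcast_to(np.arange(16.0), (8, 8, 16)).copy()
        out = ss.laplacian_of_gaussian(x, 1.0)
        assert np.allclose(out[:, :, 5:-5], 0.0, atol=5e-3)

    def test_log_blob_negative_extremum_at_centre(self):
        """LoG of a Gaussian blob of matching scale dips at the blob centre."""
        z, y, x = np.mgrid[:21, :21, :21] - 10.0
        s = 2.0
        blob = np.exp(-(x**2 + y**2 + z**2) / (2 * s**2))
        out = ss.laplacian_of_gaussian(blob, s)
        assert out[10, 10, 10] == out.min() < 0
        # analytic: LoG of Gaussian at centre = -3 / (2s)^2 * peak of G_{s*sqrt2}
        combined = np.sqrt(2) * s
        analytic = -3.0 / combined**2 * (s**3 / combined**3)
        assert out[10, 10, 10] == pytest.approx(analytic, rel=0.05)


class TestGradientMagnitude:
    def test_constant_zero(self):
        assert np.allclose(ss.gradient_magnitude(np.full((8, 8, 8), 1.0), 1.0),
                           0.0, atol=1e-5)

    def test_ramp_abs_slope(self):
        x = np.broadcast_to(np.arange(16.0), (8, 8, 16)).copy()
        out = ss.gradient_magnitude(-2.0 * x, 1.0)
        assert np.allclose(out[:, :, 5:-5], 2.0, atol=1e-3)

    def test_flip_symmetry(self):
        rng = np.random.default_rng(6)
        v = rng.normal(size=(9, 9, 9)).astype(np.float32)
        out = ss.gradient_magnitude(v, 1.0)
        flipped = ss.gradient_magnitude(v[::-1, :, :].copy(), 1.0)
        assert np.allclose(out[::-1, :, :], flipped, atol=1e-5)


class TestEigenvalueFilters:
    def test_hessian_constant_zero(self):
        out = ss.hessian_eigenvalues(np.full((8, 8, 8), 3.0), 1.0)
        assert out.shape == (3, 8, 8, 8)
        assert np.allclose(out, 0.0, atol=1e-3)

    def test_hessian_quadratic_bowl(self):
        z, y, x = np.mgrid[:17, :17, :17] - 8.0
        a = 0.5
        v = a * (x**2 + y**2 + z**2)
        out = ss.hessian_eigenvalues(v, 1.5)
        interior = out[:, 6:11, 6:11, 6:11]
        assert np.allclose(interior, 2 * a, atol=0.05)

    def test_hessian_sorted_descending(self):
        rng = np.random.default_rng(7)
        out = ss.hessian_eigenvalues(rng.normal(size=(8, 8, 8)), 1.0)
        assert (np.diff(out, axis=0) <= 1e-9).all()

    def test_structure_tensor_constant_zero(self):
        out = ss.structure_tensor_eigenvalues(np.full((8, 8, 8), 1.0), 1.0, 2.0)
        assert np.allclose(out, 0.0, atol=1e-6)

    def test_structure_tensor_planar_edge_one_dominant(self):
        step = np.zeros((12, 12, 12))
        step[..., 6:] = 1.0
        out = ss.structure_tensor_eigenvalues(step, 1.0, 2.0)
        centre = out[:, 6, 6, 5:7]
        assert (centre[0] > 10 * np.abs(centre[1:]).max()).all()

    def test_structure_tensor_nonnegative(self):
        rng = np.random.default_rng(8)
        out = ss.structure_tensor_eigenvalues(rng.normal(size=(8, 8, 8)), 1.0, 1.5)
        assert (out >= 0).all()

    def test_structure_tensor_oracle_direct_assembly(self):
        """Eigenvalues match a direct dense tensor assembly at a spot."""
        from scipy import ndimage as ndi
        rng = np.random.default_rng(9)
        v = rng.normal(size=(10, 10, 10))
        sg, sw = 1.0, 1.5
        grads = [ndi.gaussian_filter(v, sg, order=tuple(np.eye(3, dtype=int)[i]),
                                     mode="reflect") for i in range(3)]
        T = np.empty((3, 3))
        for i in range(3):
            for j in range(3):
                T[i, j] = ndi.gaussian_filter(grads[i] * grads[j], sw,
                                              mode="reflect")[5, 5, 5]
        expected = np.sort(np.linalg.eigvalsh(T))[::-1]
        out = ss.structure_tensor_eigenvalues(v, sg, sw)[:, 5, 5, 5]
        assert np.allclose(out, np.clip(expected, 0, None), atol=1e-5)


class TestInvariant:
    def test_single_scale_equals_normalised_base(self):
        rng = np.random.default_rng(10)
        v = rng.normal(size=(8, 8, 8)).astype(np.float32)
        out = ss.invariant_response(v, "gradient_magnitude", [1.5])
        assert np.allclose(out, np.abs(ss.gradient_magnitude(v, 1.5)) * 1.5)

    def test_blob_argmax_scale(self):
        """The best-responding scale tracks the blob's intrinsic scale.

        For a 3D Gaussian blob of scale s the gamma-normalised LoG response
        sigma^2 * |LoG| peaks at sigma = sqrt(2/3) * s (continuous-scale
        calculus), so the winning ladder scale must bracket that value.
        """
        z, y, x = np.mgrid[:33, :33, :33] - 16.0
        s = 3.0
        blob = np.exp(-(x**2 + y**2 + z**2) / (2 * s**2))
        ladder = [1.0, 1.5, 2.25, 3.375, 5.0]
        _, best = ss.invariant_response(blob, "laplacian_of_gaussian",
                                        ladder, return_argmax=True)
        theory = np.sqrt(2.0 / 3.0) * s
        assert abs(best[16, 16, 16] - theory) <= 0.75

    def test_empty_scale_list(self):
        with pytest.raises(ValueError):
            ss.invariant_response(np.zeros((4, 4, 4)), "gaussian", [])


def test_channel_recompute_bit_identical():
    """Recomputing any channel from its stored params reproduces it exactly."""
    rng = np.random.default_rng(11)
    v = rng.normal(size=(8, 8, 8)).astype(np.float32)
    for name, params in [("gaussian", {"sigma": 1.2}),
                         ("tv", {"weight": 0.1}),
                         ("log", {"sigma": 1.0}),
                         ("gradient_magnitude", {"sigma": 2.0})]:
        a = compute_channel(v, name, **params)
        b = compute_channel(v, name, **params)
        assert np.array_equal(a, b)


def test_feature_stack_contract(toy_stack):
    assert toy_stack.names == ["a", "b"]
    with pytest.raises(ValueError, match="duplicate"):
        toy_stack.add("a", np.zeros(toy_stack.shape))
    with pytest.raises(ValueError, match="shape"):
        ss.FeatureStack(shape=(4, 4, 4)).add("bad", np.zeros((2, 2, 2)))
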