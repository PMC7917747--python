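"""Restoration energy, its operators, and the HQS/BB solver."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from microdeblur import (
    Image2D,
    PSFKernel,
    RegularizationParams,
    SolverConfig,
    convolve_psf,
    gaussian_psf,
    grad_forward,
    hard_threshold,
    restore,
)
from microdeblur.psf import delta_kernel
from microdeblur import _operators as ops


class TestConvolve:
    def test_delta_identity(self, rng):
        img = Image2D(rng.random((16, 16)))
        out = convolve_psf(img, delta_kernel(5))
        np.testing.assert_allclose(out.pixels, img.pixels, rtol=1e-12, atol=1e-12)

    def test_matches_nested_sum_oracle(self, rng):
        img = rng.random((6, 6))
        k = rng.random((3, 3))
        k /= k.sum()
        got = convolve_psf(Image2D(img), PSFKernel(k)).pixels
        # oracle: flip kernel, slide over mirror-padded image
        h = 1
        padded = np.pad(img, h, mode="symmetric")
        expect = np.zeros_like(img)
        for i in range(6):
            for j in range(6):
                acc = 0.0
                for a in range(3):
                    for b in range(3):
                        acc += k[a, b] * padded[i + 2 - a, j + 2 - b]
                expect[i, j] = acc
        np.testing.assert_allclose(got, expect, atol=1e-10)

    def test_constant_preserved_by_normalized_kernel(self):
        img = Image2D(np.full((12, 12), 0.42))
        out = convolve_psf(img, gaussian_psf(5, 1.0))
        np.testing.assert_allclose(out.pixels, 0.42, atol=1e-12)

    def test_linearity(self, rng):
        u, v = rng.random((10, 10)), rng.random((10, 10))
        k = gaussian_psf(5, 1.2)
        lhs = convolve_psf(Image2D(2.0 * u + 3.0 * v), k).pixels
        rhs = 2.0 * convolve_psf(Image2D(u), k).pixels + 3.0 * convolve_psf(Image2D(v), k).pixels
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_kernel_larger_than_image_rejected(self):
        with pytest.raises(ValueError):
            convolve_psf(Image2D(np.zeros((4, 4))), gaussian_psf(5, 1.0))


class TestGradient:
    def test_constant_and_ramp(self):
        gx, gy = grad_forward(Image2D(np.full((8, 8), 0.3)))
        assert not gx.pixels.any() and not gy.pixels.any()
        ramp = np.tile(np.arange(8.0), (8, 1))
        gx, gy = grad_forward(Image2D(ramp))
        np.testing.assert_allclose(gx.pixels[:, :-1], 1.0)
        np.testing.assert_allclose(gx.pixels[:, -1], 0.0)
        np.testing.assert_allclose(gy.pixels, 0.0)

    def test_matches_differencing_oracle(self, rng):
        img = rng.random((4, 4))
        gx, gy = grad_forward(Image2D(img))
        np.testing.assert_array_equal(gx.pixels[:, :-1], img[:, 1:] - img[:, :-1])
        np.testing.assert_array_equal(gy.pixels[:-1, :], img[1:, :] - img[:-1, :])

    def test_adjoint_identity(self, rng):
        f = rng.normal(size=(9, 7))
        px = rng.normal(size=(9, 7))
        py = rng.normal(size=(9, 7))
        gx, gy = ops.grad_forward_raw(f)
        lhs = np.vdot(gx, px) + np.vdot(gy, py)
        rhs = np.vdot(f, ops.grad_adjoint_raw(px, py))
        assert abs(lhs - rhs) < 1e-12 * max(abs(lhs), 1.0)


class TestHardThreshold:
    def test_zero_threshold_is_identity(self, rng):
        gx = rng.normal(size=(6, 6))
        gy = rng.normal(size=(6, 6))
        dx, dy = hard_threshold(Image2D(gx), Image2D(gy), 0.0)
        np.testing.assert_array_equal(dx.pixels, gx)
        np.testing.assert_array_equal(dy.pixels, gy)

    def test_huge_threshold_zeroes_everything(self, rng):
        gx = rng.normal(size=(6, 6))
        dx, dy = hard_threshold(Image2D(gx), Image2D(gx), 1e9)
        assert not dx.pixels.any() and not dy.pixels.any()

    def test_enumeration_oracle(self):
        mags = np.array([[0.1, 0.5, 0.9]] * 3)
        dx, dy = hard_threshold(Image2D(mags), Image2D(np.zeros_like(mags)), 0.5)
        np.testing.assert_array_equal(dx.pixels[:, 0], 0.0)  # below threshold
        np.testing.assert_array_equal(dx.pixels[:, 1], 0.5)  # tie kept
        np.testing.assert_array_equal(dx.pixels[:, 2], 0.9)

    @given(
        hnp.arrays(np.float64, (5, 5), elements=st.floats(-1, 1)),
        st.floats(0, 1.5),
    )
    def test_group_threshold_property(self, gx, t):
        gy = gx * 0.5
        dx, dy = hard_threshold(Image2D(gx), Image2D(gy), t)
        mag2 = gx**2 + gy**2
        kept = (dx.pixels != 0) | (dy.pixels != 0)
        assert np.all(kept == ((mag2 >= t * t) & ((gx != 0) | (gy != 0))))


def _small_problem(rng, n=24, ks=5, noise=0.01):
    img = np.zeros((n, n))
    img[n // 3 : 2 * n // 3, n // 4 : 3 * n // 4] = 1.0  # a box: piecewise constant
    k = gaussian_psf(ks, 1.0)
    g = convolve_psf(Image2D(img), k).pixels
    if noise:
        g = g + rng.normal(0, np.sqrt(noise), g.shape)
    return Image2D(img), Image2D(g), k


class TestRestore:
    def test_fidelity_dominated_limit(self, rng):
        _, g, _ = _small_problem(rng, noise=0.0)
        reg = RegularizationParams(alpha=1e-6)
        cfg = SolverConfig(dtype="float64", gpbb_iterations=60, box_high=2.0)
        f, _ = restore(g, delta_kernel(5), reg, cfg)
        rel = np.linalg.norm(f.pixels - g.pixels) / np.linalg.norm(g.pixels)
        assert rel < 1e-3

    def test_output_respects_box_exactly(self, rng):
        _, g, k = _small_problem(rng)
        cfg = SolverConfig(dtype="float64", box_low=0.1, box_high=0.9)
        f, _ = restore(g, k, RegularizationParams(), cfg)
        assert f.pixels.min() >= 0.1 and f.pixels.max() <= 0.9

    def test_fixed_gamma_energy_non_increasing(self, rng):
        _, g, k = _small_problem(rng)
        cfg = SolverConfig(dtype="float64")
        _, trace = restore(g, k, RegularizationParams(), cfg)
        for rec in trace.pass_records:
            assert rec["phi_end"] <= rec["phi_start"] + 1e-8
        assert all(np.isfinite(v) for v in trace.objective_values)

    def test_determinism(self, rng):
        _, g, k = _small_problem(rng)
        f1, _ = restore(g, k, RegularizationParams(), SolverConfig())
        f2, _ = restore(g, k, RegularizationParams(), SolverConfig())
        np.testing.assert_array_equal(f1.pixels, f2.pixels)

    def test_gradient_sparsity_monotone_in_alpha(self, rng):
        """Stronger regularization keeps fewer nonzero gradients in the
        auxiliary field (sparsity increases with alpha)."""
        _, g, k = _small_problem(rng, n=48)
        counts = []
        for alpha in (50.0, 500.0, 5000.0):
            _, trace = restore(g, k, RegularizationParams(alpha=alpha), SolverConfig(dtype="float64"))
            counts.append(trace.pass_records[-1]["d_l0"])
        assert counts[0] >= counts[1] >= counts[2]

    def test_zero_kernel_rejected(self, rng):
        _, g, _ = _small_problem(rng)
        with pytest.raises(ValueError):
            restore(g, PSFKernel(np.zeros((5, 5))), RegularizationParams(), SolverConfig())

    def test_l1_matches_projected_gradient_reference(self, rng):
        """BB solution of the Huber-smoothed l1 problem lands within 1% of
        an exhaustive multi-start projected-gradient run on an 8x8 image."""
        img = np.zeros((8, 8))
        img[2:6, 3:7] = 1.0
        k = gaussian_psf(3, 0.8)
        g = convolve_psf(Image2D(img), k).pixels + rng.normal(0, 0.05, (8, 8))
        reg = RegularizationParams(mode="l1")
        cfg = SolverConfig(dtype="float64", gpbb_iterations=100, hqs_passes=4)
        f, trace = restore(Image2D(g), k, reg, cfg)
        ours = trace.pass_records[-1]["phi_end"]

        # reference: plain projected gradient, step 1/L, several starts
        from microdeblur.restore import DATA_WEIGHT, _RestoreProblem, _huber, _huber_grad

        problem = _RestoreProblem(g, k.weights, np.float64)
        delta = 1e-4
        L = DATA_WEIGHT + 8.0 * reg.alpha * reg.beta_f / delta
        w1 = reg.alpha * reg.beta_f

        def energy(x):
            gx, gy = ops.grad_forward_raw(x)
            return 0.5 * DATA_WEIGHT * problem.data_grad_and_sq(x)[1] + w1 * (
                _huber(gx, delta).sum() + _huber(gy, delta).sum()
            )

        def grad(x):
            gx, gy = ops.grad_forward_raw(x)
            return DATA_WEIGHT * problem.data_grad_and_sq(x)[0] + w1 * ops.grad_adjoint_raw(
                _huber_grad(gx, delta), _huber_grad(gy, delta)
            )

        starts = [
            ops.pad_symmetric_to(g, problem.pshape)[0],
            np.zeros(problem.pshape),
            np.full(problem.pshape, 0.5),
            rng.random(problem.pshape),
        ]
        best = np.inf
        for x in starts:
            x = np.clip(x, 0.0, 1.2)
            for _ in range(10000):
                x = np.clip(x - (1.0 / L) * grad(x), 0.0, 1.2)
            best = min(best, energy(x))
        assert ours <= best * 1.01

    def test_lambda_zero_threshold_zero_is_box_least_squares(self, rng):
        """With the prior switched off the solver must reproduce the
        box-constrained least-squares solution of the data term."""
        from scipy.optimize import lsq_linear
        from microdeblur.restore import _RestoreProblem

        img = np.zeros((8, 8))
        img[2:6, 2:5] = 0.8
        k = gaussian_psf(3, 0.9)
        g = convolve_psf(Image2D(img), k).pixels + rng.normal(0, 0.03, (8, 8))
        reg = RegularizationParams(alpha=1e-9, beta_f=1e-12, lambda_f=0.0)
        cfg = SolverConfig(
            dtype="float64", gpbb_iterations=2000, hqs_passes=1,
            hqs_gamma0=1e-12, box_low=0.0, box_high=1.0,
        )
        f, _ = restore(Image2D(g), k, reg, cfg)

        problem = _RestoreProblem(g, k.weights, np.float64)
        npix = problem.pshape[0] * problem.pshape[1]
        cols = []
        from scipy import fft as _fft

        for i in range(npix):
            e = np.zeros(npix)
            e[i] = 1.0
            cols.append(
                _fft.irfft2(problem.otf * _fft.rfft2(e.reshape(problem.pshape)), problem.pshape).ravel()
            )
        A = np.column_stack(cols)
        sol = lsq_linear(A, problem.g_pad.ravel(), bounds=(0.0, 1.0), tol=1e-12)
        ref = ops.crop(sol.x.reshape(problem.pshape), problem.offset, (8, 8))
        np.testing.assert_allclose(f.pixels, ref, atol=1e-4)
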