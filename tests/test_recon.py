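"""Reconstruction: objective oracle, operators, solver limits, sensitivities."""

import numpy as np
import pytest

from aortacs.operators import SenseOperator, WaveletTransform, fft_c, ifft_c
from aortacs.phantom import (
    KSpaceAcquisition,
    SenseMaps,
    build_phantom,
    coil_sensitivities,
    simulate_acquisition,
)
from aortacs.recon import (
    ReconConfig,
    estimate_sensitivities,
    nrmse,
    objective,
    reconstruct_cs,
    reconstruct_reference,
    soft_threshold,
    sweep_recon_params,
    zero_filled,
)
from aortacs.sampling import SamplingMask, full_mask, poisson_disc_mask

from conftest import all_ones_mask, small_spec


def brute_force_dft3(x: np.ndarray) -> np.ndarray:
    """Centred orthonormal 3D DFT by explicit summation (oracle)."""
    n0, n1, n2 = x.shape
    out = np.zeros((n0, n1, n2), dtype=complex)
    for k0 in range(n0):
        for k1 in range(n1):
            for k2 in range(n2):
                acc = 0.0 + 0.0j
                for m0 in range(n0):
                    for m1 in range(n1):
                        for m2 in range(n2):
                            phase = -2j * np.pi * (
                                (k0 - n0 // 2) * (m0 - n0 // 2) / n0
                                + (k1 - n1 // 2) * (m1 - n1 // 2) / n1
                                + (k2 - n2 // 2) * (m2 - n2 // 2) / n2
                            )
                            acc += x[m0, m1, m2] * np.exp(phase)
                out[k0, k1, k2] = acc / np.sqrt(n0 * n1 * n2)
    return out


def haar_decompose_1level(x: np.ndarray) -> np.ndarray:
    """Hand-written separable orthonormal Haar step (oracle), ndim=3."""
    s = x
    for ax in (0, 1, 2):
        a = np.moveaxis(s, ax, 0)
        lo = (a[0::2] + a[1::2]) / np.sqrt(2)
        hi = (a[0::2] - a[1::2]) / np.sqrt(2)
        s = np.moveaxis(np.concatenate([lo, hi], axis=0), 0, ax)
    return s


class TestObjectiveOracle:
    def test_brute_force_4x4_single_coil(self):
        # independent evaluation: explicit DFT sums for the fidelity term,
        # hand-written Haar transform for the sparsity term
        rng = np.random.default_rng(12)
        x = rng.standard_normal((4, 4, 4)) + 1j * rng.standard_normal((4, 4, 4))
        maps = SenseMaps(maps=np.ones((1, 4, 4, 4), complex), support=np.ones((4, 4, 4), bool))
        mask = all_ones_mask(4, 4)
        y = rng.standard_normal((1, 4, 4, 4)) + 1j * rng.standard_normal((1, 4, 4, 4))
        acq = KSpaceAcquisition(data=y, mask=mask)
        wav = WaveletTransform((4, 4, 4), wavelet="haar", levels=1)

        got = objective(x, acq, maps, lam=0.37, wavelet=wav)

        k = brute_force_dft3(x)
        fidelity = 0.0
        for i in range(4):
            for j in range(4):
                for l in range(4):
                    fidelity += 0.5 * abs(y[0, i, j, l] - k[i, j, l]) ** 2
        sparsity = np.sum(np.abs(haar_decompose_1level(x)))
        total = fidelity + 0.37 * sparsity
        assert got["fidelity"] == pytest.approx(fidelity, rel=1e-12)
        assert got["sparsity"] == pytest.approx(sparsity, rel=1e-12)
        assert got["total"] == pytest.approx(total, rel=1e-12)

    def test_zero_image(self):
        rng = np.random.default_rng(5)
        y = rng.standard_normal((2, 8, 8, 4)) + 1j * rng.standard_normal((2, 8, 8, 4))
        maps = coil_sensitivities((8, 8, 4), 2, seed=1)
        acq = KSpaceAcquisition(data=y, mask=all_ones_mask(8, 4))
        got = objective(np.zeros((8, 8, 4), complex), acq, maps, lam=1.0)
        assert got["fidelity"] == pytest.approx(0.5 * np.sum(np.abs(y) ** 2), rel=1e-12)
        assert got["sparsity"] == 0.0

    def test_ground_truth_zero_cost(self):
        ph = build_phantom(small_spec())
        maps = coil_sensitivities(ph.intensity.shape, 3, seed=2)
        acq = simulate_acquisition(ph, maps, all_ones_mask(48, 16), noise_sd=0.0, seed=0)
        got = objective(ph.intensity.astype(complex), acq, maps, lam=0.0)
        assert got["total"] <= 1e-10 * np.sum(np.abs(acq.data) ** 2)


class TestAdjointAndWavelet:
    def test_sense_operator_adjoint_identity(self):
        rng = np.random.default_rng(3)
        maps = coil_sensitivities((8, 8, 4), 3, seed=4)
        mask = poisson_disc_mask(8, 4, 2, calib_fraction=0.1, tol=0.2, seed=0)
        op = SenseOperator(maps.maps, mask.grid)
        x = rng.standard_normal((8, 8, 4)) + 1j * rng.standard_normal((8, 8, 4))
        y = rng.standard_normal((3, 8, 8, 4)) + 1j * rng.standard_normal((3, 8, 8, 4))
        lhs = np.vdot(y, op.forward(x))
        rhs = np.vdot(op.adjoint(y), x)
        assert abs(lhs - rhs) <= 1e-10 * max(abs(lhs), 1.0)

    def test_wavelet_orthonormal_roundtrip(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal((32, 32, 8)) + 1j * rng.standard_normal((32, 32, 8))
        w = WaveletTransform(x.shape)
        coeffs = w.forward(x)
        assert np.linalg.norm(coeffs) == pytest.approx(np.linalg.norm(x), rel=1e-10)
        np.testing.assert_allclose(w.inverse(coeffs), x, atol=1e-10)


class TestSoftThreshold:
    def test_real_example(self):
        assert soft_threshold(3.0 + 0j, 1.0) == pytest.approx(2.0)

    def test_below_threshold_is_zero(self):
        assert soft_threshold(0.3 - 0.2j, 1.0) == 0.0

    def test_phase_preserved(self):
        z = 2.0 * np.exp(1j * 0.7)
        out = soft_threshold(z, 0.5)
        assert np.angle(out) == pytest.approx(0.7)
        assert abs(out) == pytest.approx(1.5)

    def test_grid_search_prox_oracle(self):
        # argmin over a dense grid of 0.5 (x - z)^2 + t |x|
        z, t = 1.7, 0.4
        grid = np.linspace(-3, 3, 120001)
        cost = 0.5 * (grid - z) ** 2 + t * np.abs(grid)
        x_star = grid[np.argmin(cost)]
        assert soft_threshold(complex(z), t).real == pytest.approx(x_star, abs=1e-4)

    def test_negative_threshold_raises(self):
        with pytest.raises(ValueError):
            soft_threshold(1.0 + 0j, -0.1)


class TestReconstruction:
    def test_exact_limit_full_sampling(self):
        # fully (rectangularly) sampled, lambda=0, uniform coil: the
        # zero-filled image is already the least-squares solution
        ph = build_phantom(small_spec())
        maps = coil_sensitivities(ph.intensity.shape, 1)
        acq = simulate_acquisition(ph, maps, all_ones_mask(48, 16), noise_sd=0.0, seed=0)
        res = reconstruct_cs(acq, maps, ReconConfig(lam=0.0, iterations=5))
        direct = np.abs(ifft_c(acq.data[0]))
        err = np.linalg.norm(res.magnitude - direct) / np.linalg.norm(direct)
        assert err < 1e-6
        trace = res.total_trace
        assert len(trace) == 6
        assert np.all(np.diff(trace) <= 1e-12)

    def test_cost_trace_consistency(self):
        ph = build_phantom(small_spec(noise_sd=0.02))
        maps = coil_sensitivities(ph.intensity.shape, 2, seed=3)
        mask = poisson_disc_mask(48, 16, 3, seed=1, tol=0.02)
        acq = simulate_acquisition(ph, maps, mask, noise_sd=0.02, seed=2)
        res = reconstruct_cs(acq, maps, ReconConfig(iterations=6))
        assert len(res.cost_trace) == 7
        for c in res.cost_trace:
            assert c["total"] == pytest.approx(
                c["fidelity"] + res.config.lam * c["sparsity"], rel=1e-8
            )
        assert np.all(np.diff(res.total_trace) <= 1e-12)

    def test_fixed_point_at_zero_fidelity(self):
        # lambda=0 and an exactly consistent zero-filled solution: iterations
        # leave the image unchanged
        rng = np.random.default_rng(1)
        x = rng.standard_normal((8, 8, 4))
        maps = coil_sensitivities((8, 8, 4), 1)
        acq = simulate_acquisition(x, maps, all_ones_mask(8, 4), noise_sd=0.0, seed=0)
        res = reconstruct_cs(acq, maps, ReconConfig(lam=0.0, iterations=4))
        start = zero_filled(acq, maps)
        np.testing.assert_allclose(res.image, start, atol=1e-12 * np.abs(start).max())

    def test_lambda_shrinks_toward_least_squares(self):
        ph = build_phantom(small_spec())
        maps = coil_sensitivities(ph.intensity.shape, 2, seed=5)
        acq = simulate_acquisition(ph, maps, all_ones_mask(48, 16), noise_sd=0.0, seed=0)
        sens = maps
        ls = np.abs(zero_filled(acq, sens))
        errs = []
        for lam in (0.0, 0.002, 0.02):
            res = reconstruct_cs(acq, sens, ReconConfig(lam=lam, iterations=8))
            errs.append(nrmse(res.magnitude, ls))
        assert errs[0] <= errs[1] <= errs[2]
        assert errs[0] < 1e-6

    def test_divergence_detection_without_safeguard(self):
        ph = build_phantom(small_spec())
        maps = coil_sensitivities(ph.intensity.shape, 2, seed=6)
        bad = SenseMaps(maps=3.0 * maps.maps, support=maps.support)  # L = 9, step 1
        acq = simulate_acquisition(ph, bad, all_ones_mask(48, 16), noise_sd=0.0, seed=0)
        cfg = ReconConfig(lam=0.0, iterations=10, monotone=False, power_iterations=0)
        with pytest.raises(RuntimeError, match="diverged"):
            reconstruct_cs(acq, bad, cfg)

    def test_non_finite_data_raises(self):
        maps = coil_sensitivities((8, 8, 4), 1)
        data = np.full((1, 8, 8, 4), np.nan, dtype=complex)
        acq = KSpaceAcquisition(data=data, mask=all_ones_mask(8, 4))
        with pytest.raises(ValueError):
            reconstruct_cs(acq, maps)

    def test_deterministic_given_inputs(self):
        ph = build_phantom(small_spec(noise_sd=0.02))
        maps = coil_sensitivities(ph.intensity.shape, 2, seed=7)
        mask = poisson_disc_mask(48, 16, 3, seed=2, tol=0.02)
        acq = simulate_acquisition(ph, maps, mask, noise_sd=0.02, seed=3)
        a = reconstruct_cs(acq, maps, ReconConfig(iterations=4))
        b = reconstruct_cs(acq, maps, ReconConfig(iterations=4))
        np.testing.assert_array_equal(a.image, b.image)


class TestReferenceReconstruction:
    def test_single_uniform_coil_exact(self):
        ph = build_phantom(small_spec())
        maps = coil_sensitivities(ph.intensity.shape, 1)
        acq = simulate_acquisition(ph, maps, all_ones_mask(48, 16), noise_sd=0.0, seed=0)
        rec = reconstruct_reference(acq, maps)
        err = np.linalg.norm(rec - ph.intensity) / np.linalg.norm(ph.intensity)
        assert err < 1e-6

    def test_multicoil_true_maps_exact_on_support(self):
        ph = build_phantom(small_spec())
        maps = coil_sensitivities(ph.intensity.shape, 4, seed=8)
        acq = simulate_acquisition(ph, maps, all_ones_mask(48, 16), noise_sd=0.0, seed=0)
        rec = reconstruct_reference(acq, maps)
        sup = maps.support
        err = np.linalg.norm((rec - ph.intensity)[sup]) / np.linalg.norm(ph.intensity[sup])
        assert err < 1e-6

    def test_undersampled_input_rejected(self):
        ph = build_phantom(small_spec())
        maps = coil_sensitivities(ph.intensity.shape, 2, seed=9)
        mask = poisson_disc_mask(48, 16, 3, seed=0, tol=0.02)
        acq = simulate_acquisition(ph, maps, mask, noise_sd=0.0, seed=0)
        with pytest.raises(ValueError):
            reconstruct_reference(acq, maps)

    def test_noise_propagation_matches_parseval(self):
        # with the orthonormal transform the coil-combined image noise SD
        # equals the k-space complex noise SD; Monte-Carlo over 20 seeds
        x = np.zeros((16, 16, 8))
        maps = coil_sensitivities((16, 16, 8), 4, seed=10)
        sd = 0.05
        stds = []
        for seed in range(20):
            acq = simulate_acquisition(x, maps, all_ones_mask(16, 8), noise_sd=sd, seed=seed)
            imgs = np.stack([ifft_c(acq.data[n]) for n in range(4)])
            combined = np.sum(np.conj(maps.maps) * imgs, axis=0)
            stds.append(np.sqrt(np.mean(np.abs(combined) ** 2)))
        assert np.mean(stds) == pytest.approx(sd, rel=0.10)


class TestSensitivityEstimation:
    def test_single_uniform_coil_recovered(self, default_phantom):
        maps = coil_sensitivities(default_phantom.intensity.shape, 1)
        ny, nz = default_phantom.intensity.shape[1:]
        acq = simulate_acquisition(default_phantom, maps, full_mask(ny, nz), noise_sd=0.0, seed=0)
        est = estimate_sensitivities(acq)
        assert np.max(np.abs(np.abs(est.maps[0][est.support]) - 1.0)) < 1e-3

    def test_rss_bounded_everywhere(self, default_phantom, coil_maps4, noiseless_full_acq):
        est = estimate_sensitivities(noiseless_full_acq)
        rss = np.sqrt((np.abs(est.maps) ** 2).sum(axis=0))
        assert rss.max() <= 1.0 + 1e-6
        np.testing.assert_allclose(rss[est.support], 1.0, atol=1e-3)

    def test_four_coil_maps_recovered(self, default_phantom, coil_maps4, noiseless_full_acq):
        # frozen accuracy of the estimator at the calibration resolution:
        # mean error < 0.02 on support, max < 0.05 away from the support
        # fringe (the boundary is one-sided extrapolation); per-voxel phase
        # aligned by the optimal common phase
        from scipy.ndimage import binary_erosion

        est = estimate_sensitivities(noiseless_full_acq)
        true = coil_maps4
        inner = np.sum(est.maps * np.conj(true.maps), axis=0)
        phi = np.exp(-1j * np.angle(np.where(inner == 0, 1, inner)))
        err = np.abs(est.maps * phi - true.maps).max(axis=0)
        sup = est.support & true.support
        core = binary_erosion(sup, iterations=4)
        assert err[sup].mean() < 0.02
        assert err[core].max() < 0.05

    def test_empty_calibration_region_raises(self):
        grid = np.ones((8, 4), dtype=bool)
        mask = SamplingMask(
            grid=grid,
            ellipse_semi_axes=(4, 2),
            calib_semi_axes=(0.0, 0.0),
            target_accel=1.0,
            achieved_fraction=1.0,
        )
        data = np.ones((1, 8, 8, 4), dtype=complex)
        with pytest.raises(ValueError, match="calibration"):
            estimate_sensitivities(KSpaceAcquisition(data=data, mask=mask))


class TestSweep:
    def test_grid_shape_and_iteration_saturation(self):
        ph = build_phantom(small_spec(noise_sd=0.01))
        maps = coil_sensitivities(ph.intensity.shape, 2, seed=11)
        mask = poisson_disc_mask(48, 16, 3, seed=4, tol=0.02)
        acq = simulate_acquisition(ph, maps, mask, noise_sd=0.01, seed=5)
        sens = estimate_sensitivities(acq)
        table = sweep_recon_params(acq, sens, ph.intensity)
        assert len(table) == 12
        assert set(table["lambda"]) == {0.0005, 0.001, 0.002, 0.004}
        assert set(table["iterations"]) == {10, 20, 40}
        sub = table[table["lambda"] == 0.002].set_index("iterations")["nrmse"]
        assert abs(sub[40] - sub[10]) <= 0.02
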