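"""Pre-whitening, GRAPPA calibration, unmixing and SNR-unit reconstruction."""

import numpy as np
import pytest

from snraware.fourier import fft2c, ifft2c
from snraware.phantom import (NoisePreScan, PhantomConfig, grid_lines,
                              make_coil_maps, make_phantom_series,
                              synthesize_kspace)
from snraware.recon import (CalibrationError, NoiseCovariance, ReconImage,
                            apply_prewhitening, calibrate_grappa,
                            compute_prewhitener, estimate_coil_maps,
                            estimate_noise_covariance, grappa_fill_kspace,
                            kernel_to_unmixing, pseudo_replica_noise_sd,
                            reconstruct_snr_unit, zero_fill_resize)


class TestNoiseCovariance:
    def test_identity_covariance_recovered(self, rng):
        x = (rng.standard_normal((8, 100_000))
             + 1j * rng.standard_normal((8, 100_000))) / np.sqrt(2)
        cov = estimate_noise_covariance(NoisePreScan(samples=x))
        assert np.abs(cov.psi - np.eye(8)).max() < 0.05

    def test_duplicated_coil_raises_with_pair(self, rng):
        x = (rng.standard_normal((4, 5000))
             + 1j * rng.standard_normal((4, 5000))) / np.sqrt(2)
        x[3] = x[0]
        with pytest.raises(ValueError, match=r"\(0, 3\)"):
            estimate_noise_covariance(NoisePreScan(samples=x))

    def test_concatenation_is_sample_weighted_average(self, rng):
        a = (rng.standard_normal((4, 4000)) + 1j * rng.standard_normal((4, 4000)))
        b = (rng.standard_normal((4, 8000)) + 1j * rng.standard_normal((4, 8000)))
        ca = estimate_noise_covariance(NoisePreScan(a)).psi
        cb = estimate_noise_covariance(NoisePreScan(b)).psi
        cc = estimate_noise_covariance(NoisePreScan(np.concatenate([a, b], axis=1))).psi
        expected = (4000 * ca + 8000 * cb) / 12000
        assert np.abs(cc - expected).max() < 1e-12


class TestPrewhitener:
    def test_identity_psi_gives_identity_whitener(self):
        wt = compute_prewhitener(NoiseCovariance(np.eye(4) + 0j, 1000))
        assert np.allclose(wt.w, np.eye(4))

    def test_diagonal_closed_form(self):
        wt = compute_prewhitener(NoiseCovariance(np.diag([4.0, 1.0]) + 0j, 1000))
        assert np.allclose(wt.w, np.diag([0.5, 1.0]))

    def test_whitening_contract_random_psd(self, rng):
        a = rng.standard_normal((6, 6)) + 1j * rng.standard_normal((6, 6))
        psi = a @ a.conj().T + 6 * np.eye(6)
        wt = compute_prewhitener(NoiseCovariance(psi, 1000))
        assert np.abs(wt.w @ psi @ wt.w.conj().T - np.eye(6)).max() < 1e-10

    def test_bandwidth_scale_squares_into_covariance(self):
        psi = np.diag([4.0, 1.0]) + 0j
        wt = compute_prewhitener(NoiseCovariance(psi, 1000), bandwidth_scale=2.0)
        assert np.allclose(wt.w @ psi @ wt.w.conj().T, 4 * np.eye(2))

    def test_identity_whitener_is_bitwise_noop(self, acquisition):
        ksp = acquisition[0]
        from snraware.recon import WhiteningTransform
        out = apply_prewhitening(ksp, WhiteningTransform(w=np.eye(8) + 0j))
        assert np.array_equal(out.data, ksp.data)

    def test_whitened_noise_has_identity_covariance(self, whitened, acquisition):
        white, cov, wt = whitened
        prescan = acquisition[1]
        ws = wt.w @ prescan.samples
        emp = ws @ ws.conj().T / ws.shape[1]
        assert np.abs(emp - np.eye(8)).max() < 0.05

    def test_roundtrip_invertible(self, acquisition, whitened):
        ksp = acquisition[0]
        white, _, wt = whitened
        from snraware.recon import WhiteningTransform
        back = apply_prewhitening(
            white, WhiteningTransform(w=np.linalg.inv(wt.w)))
        assert np.abs(back.data - ksp.data).max() < 1e-10 * np.abs(ksp.data).max()

    def test_coil_count_mismatch_rejected(self, acquisition):
        from snraware.recon import WhiteningTransform
        with pytest.raises(ValueError, match="coils"):
            apply_prewhitening(acquisition[0],
                               WhiteningTransform(w=np.eye(4) + 0j))


class TestGrappaCalibration:
    def test_exact_interpolating_kernel_reached(self, rng):
        # low-rank harmonic k-space: an exact GRAPPA kernel exists (each line
        # IS a fixed linear combination of its neighbours), so the fit must
        # reach ~zero residual
        C, Ny, Nx, M = 4, 24, 48, 8
        y, x = np.arange(Ny)[:, None], np.arange(Nx)[None, :]
        acs = np.zeros((C, Ny, Nx), dtype=complex)
        for _ in range(M):
            z1, z2 = np.exp(2j * np.pi * rng.uniform(size=2))
            s = rng.standard_normal(C) + 1j * rng.standard_normal(C)
            acs += s[:, None, None] * (z1**y * z2**x)[None]
        kern = calibrate_grappa(acs, accel=2, kernel_size=(2, 5),
                                regularization=1e-12)
        assert max(kern.provenance["residuals"].values()) < 1e-8

    def test_single_coil_high_residual_flagged(self, whitened):
        white, _, _ = whitened
        kern = calibrate_grappa(white.acs[:1], accel=2)
        assert kern.provenance["high_residual"]
        assert max(kern.provenance["residuals"].values()) > 0.1

    def test_ridge_limit_shrinks_weights(self, whitened):
        white, _, _ = whitened
        small = calibrate_grappa(white.acs, 2, regularization=1e-4)
        huge = calibrate_grappa(white.acs, 2, regularization=1e12)
        assert np.abs(huge.weights).max() < 1e-6 * np.abs(small.weights).max()

    def test_acs_too_small_raises_with_minimum(self):
        acs = np.ones((8, 18, 40), dtype=complex)
        with pytest.raises(CalibrationError, match="required minimum"):
            calibrate_grappa(acs, accel=6, kernel_size=(4, 5))


class TestCoilMapEstimation:
    def test_matches_simulator_ground_truth(self, est_coil_maps, acquisition,
                                            whitened, object_mask):
        # maps are estimated from pre-whitened data, so the reference is the
        # whitened true sensitivity W b, unit-normalized per pixel
        true_maps = acquisition[3]
        _, _, wt = whitened
        tw = np.einsum("ij,jyx->iyx", wt.w, true_maps)
        tw = tw / np.sqrt((np.abs(tw) ** 2).sum(axis=0))
        ip = np.abs((np.conj(est_coil_maps) * tw).sum(axis=0))
        assert ip[object_mask].min() > 0.99

    def test_unit_norm_everywhere(self, est_coil_maps):
        norm = (np.abs(est_coil_maps) ** 2).sum(axis=0)
        assert np.allclose(norm, 1.0, atol=1e-9)

    def test_reference_coil_phase_zero(self, est_coil_maps):
        ref = est_coil_maps[0]
        nonzero = np.abs(ref) > 1e-12
        assert np.abs(np.angle(ref[nonzero])).max() < 1e-9

    def test_all_zero_acs_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            estimate_coil_maps(np.zeros((4, 24, 64), complex), (64, 64))


class TestUnmixing:
    def test_identity_kernel_gives_conjugate_maps(self, whitened, est_coil_maps,
                                                  phantom_cfg):
        white, _, _ = whitened
        kern = calibrate_grappa(white.acs, accel=1)
        um = kernel_to_unmixing(kern, est_coil_maps, phantom_cfg.matrix_size)
        assert np.allclose(um.u, np.conj(est_coil_maps), atol=1e-10)
        assert np.allclose((np.abs(um.u) ** 2).sum(axis=0), 1.0, atol=1e-9)

    def test_two_path_equivalence(self, whitened, est_coil_maps, phantom_cfg):
        white, _, _ = whitened
        H, W = phantom_cfg.matrix_size
        kern = calibrate_grappa(white.acs, accel=2)
        um = kernel_to_unmixing(kern, est_coil_maps, (H, W))
        gm = np.zeros(H, dtype=bool)
        gm[grid_lines(H, 2)] = True
        kgrid = white.data[:, :, :, 0] * gm[None, :, None]
        filled = grappa_fill_kspace(kgrid, kern)
        img_k = np.einsum("cyx,cyx->yx", np.conj(est_coil_maps),
                          ifft2c(filled, axes=(1, 2)))
        img_u = np.einsum("cyx,cyx->yx", um.u, ifft2c(kgrid, axes=(1, 2)))
        assert np.abs(img_k - img_u).max() < 1e-8 * np.abs(img_k).max()

    def test_flipped_embedding_breaks_equivalence(self, whitened,
                                                  est_coil_maps, phantom_cfg):
        # deliberate-bug guard: embedding the kernel with the opposite
        # displacement sign must NOT satisfy the two-path oracle
        white, _, _ = whitened
        H, W = phantom_cfg.matrix_size
        kern = calibrate_grappa(white.acs, accel=2)
        C = 8
        kemb = np.zeros((C, C, H, W), dtype=complex)
        cy, cx = H // 2, W // 2
        for i, dy in enumerate(kern.dy_offsets):
            for j, dx in enumerate(kern.dx_offsets):
                kemb[:, :, (cy + dy) % H, (cx + dx) % W] += kern.weights[:, :, i, j]
        for t in range(C):
            kemb[t, t, cy, cx] += 1.0
        kimg = np.sqrt(H * W) * ifft2c(kemb, axes=(2, 3))
        u_flipped = np.einsum("tyx,tcyx->cyx", np.conj(est_coil_maps), kimg)

        gm = np.zeros(H, dtype=bool)
        gm[grid_lines(H, 2)] = True
        kgrid = white.data[:, :, :, 0] * gm[None, :, None]
        img_k = np.einsum("cyx,cyx->yx", np.conj(est_coil_maps),
                          ifft2c(grappa_fill_kspace(kgrid, kern), axes=(1, 2)))
        img_f = np.einsum("cyx,cyx->yx", u_flipped, ifft2c(kgrid, axes=(1, 2)))
        assert np.abs(img_k - img_f).max() > 1e-3 * np.abs(img_k).max()

    def test_unnormalized_maps_rejected(self, whitened, phantom_cfg):
        white, _, _ = whitened
        kern = calibrate_grappa(white.acs, accel=2)
        bad = 2.0 * np.ones((8,) + phantom_cfg.matrix_size, dtype=complex)
        with pytest.raises(ValueError, match="unit-norm"):
            kernel_to_unmixing(kern, bad, phantom_cfg.matrix_size)


class TestSnrUnitRecon:
    def test_noise_sd_unity_at_r1(self, whitened, est_coil_maps, phantom_cfg):
        white, _, _ = whitened
        kern = calibrate_grappa(white.acs, accel=1)
        um = kernel_to_unmixing(kern, est_coil_maps, phantom_cfg.matrix_size)
        sd = pseudo_replica_noise_sd(um, 128, np.random.default_rng(0))
        assert abs(sd.mean() - 1.0) < 0.03

    def test_noiseless_r2_matches_fully_sampled(self):
        cfg2 = PhantomConfig(accel=2, n_acs=24, n_frames=2)
        imgs, _ = make_phantom_series(cfg2)
        maps = make_coil_maps(cfg2)
        cfg1 = PhantomConfig(accel=1, n_acs=24, n_frames=2)

        def recon_of(cfg):
            ksp = synthesize_kspace(imgs, maps, cfg)
            em = estimate_coil_maps(ksp.acs, cfg.matrix_size)
            kern = calibrate_grappa(ksp.acs, cfg.accel)
            um = kernel_to_unmixing(kern, em, cfg.matrix_size)
            rec = reconstruct_snr_unit(ksp, um)
            return rec.data / rec.meta["snr_unit_scale"]

        full, r2 = recon_of(cfg1), recon_of(cfg2)
        nrmse = np.linalg.norm(r2 - full) / np.linalg.norm(full)
        assert nrmse < 0.05

    def test_zero_input_gives_zero_output(self, whitened, unmix_r2):
        white, _, _ = whitened
        from snraware.phantom import MultiCoilKSpace
        zero = MultiCoilKSpace(data=np.zeros_like(white.data), mask=white.mask,
                               acs=white.acs, accel=2, n_acs=white.n_acs)
        rec = reconstruct_snr_unit(zero, unmix_r2)
        assert np.all(rec.data == 0)

    def test_linearity(self, whitened, unmix_r2):
        white, _, _ = whitened
        from snraware.phantom import MultiCoilKSpace

        def rec(data):
            k = MultiCoilKSpace(data=data, mask=white.mask, acs=white.acs,
                                accel=2, n_acs=white.n_acs)
            return reconstruct_snr_unit(k, unmix_r2).data

        a, b = white.data, np.roll(white.data, 1, axis=3)
        lhs = rec(2 * a + 3 * b)
        rhs = 2 * rec(a) + 3 * rec(b)
        assert np.abs(lhs - rhs).max() < 1e-9 * np.abs(lhs).max()

    def test_mask_inconsistent_with_accel_rejected(self, whitened, unmix_r2):
        white, _, _ = whitened
        from snraware.phantom import MultiCoilKSpace
        mask = white.mask.copy()
        mask[::2, :] = 0  # knock out grid lines
        bad = MultiCoilKSpace(data=white.data * mask[None, :, None, :],
                              mask=mask, acs=white.acs, accel=2,
                              n_acs=white.n_acs)
        with pytest.raises(ValueError, match="grid lines"):
            reconstruct_snr_unit(bad, unmix_r2)


class TestZeroFillResize:
    def test_identity_at_same_size(self, recon_r2):
        out = zero_fill_resize(recon_r2, recon_r2.matrix_size)
        assert np.array_equal(out.data, recon_r2.data)

    def test_shrink_rejected(self, recon_r2):
        with pytest.raises(ValueError, match="shrink"):
            zero_fill_resize(recon_r2, (32, 32))

    def test_noise_sd_preserved(self):
        rng = np.random.default_rng(5)
        reps = []
        for _ in range(128):
            w = (rng.standard_normal((64, 64, 1))
                 + 1j * rng.standard_normal((64, 64, 1))) / np.sqrt(2)
            img = ReconImage(data=w, native_g=np.ones((64, 64)), meta={})
            reps.append(zero_fill_resize(img, (96, 96)).data)
        st = np.stack(reps)
        sd = np.sqrt(st.real.var(0) + st.imag.var(0))
        assert abs(sd.mean() - 1.0) < 0.03

    def test_constant_image_stays_constant(self):
        img = ReconImage(data=np.full((64, 64, 1), 2.5 + 0j),
                         native_g=np.ones((64, 64)), meta={})
        out = zero_fill_resize(img, (96, 96))
        interior = out.data[8:-8, 8:-8, 0]
        assert np.abs(interior - 2.5).max() < 1e-6

    def test_gmap_resampled_via_variance(self, recon_r2):
        out = zero_fill_resize(recon_r2, (96, 96))
        assert out.native_g.shape == (96, 96)
        assert out.native_g.min() > 0
        # central region keeps the g level of the original center
        assert abs(out.native_g[48, 48] - recon_r2.native_g[32, 32]) < 0.1
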