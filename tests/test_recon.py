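"""Phase retrieval, reconstruction, PSF estimation and registration."""

import warnings

import numpy as np
import pytest

from classim import (
    ObjectImage,
    ScreenParams,
    class_phase_retrieval,
    class_phase_retrieval_dense,
    covariance,
    estimate_apsfs,
    estimate_frame_psfs,
    fix_gauge,
    frames_to_spectral_matrix,
    iclass_reconstruct,
    model_covariance,
    registered_correlation,
    simulate_coherent_stack,
    simulate_incoherent_stack,
)
from classim.fourier import cfft2, centered_delta, icfft2
from classim.screens import IntensityPSF
from classim.simulate import FrameStack


def _phase_residual(psi_hat, spectrum_true):
    """Wrapped phase residual after removing the constant + ramp gauge."""
    amp = np.abs(spectrum_true)
    S_hat, _ = fix_gauge(amp * np.exp(1j * psi_hat))
    S_true, _ = fix_gauge(spectrum_true)
    return np.angle(np.exp(1j * (np.angle(S_hat) - np.angle(S_true))))


class TestExactModelRecovery:
    """Covariance synthesised exactly from the factorisation: closed-form limit."""

    @pytest.mark.parametrize("n", [8, 16])
    def test_dense_recovers_phase_to_machine_precision(self, n):
        rng = np.random.default_rng(1)
        obj = rng.random((n, n)) + 0.2
        O = cfft2(obj.astype(complex))
        var = np.zeros((n, n))
        var[n // 2 + 1, n // 2 + 2] = 1.0  # PSF variance at a single point
        C = model_covariance(O, var)
        res = class_phase_retrieval_dense(C, (n, n), n_iter=500, tol=1e-12)
        resid = _phase_residual(res.phase, O)
        assert np.abs(resid).max() < 1e-6

    def test_real_positive_spectrum_is_fixed_point(self):
        """psi == 0 stays 0 when the object spectrum is real positive."""
        n = 8
        rng = np.random.default_rng(2)
        a = rng.random((n, n)) + 0.5  # real positive spectrum
        var = np.ones((n, n))
        C = model_covariance(a.astype(complex), var)
        res = class_phase_retrieval_dense(C, (n, n), n_iter=1, tol=0)
        assert np.allclose(res.phase, 0.0, atol=1e-12)

    def test_all_zero_covariance_rejected(self):
        with pytest.raises(ValueError):
            class_phase_retrieval_dense(np.zeros((16, 16), complex), (4, 4))


class TestFrameDomainEquivalence:
    def test_matches_dense_oracle(self, small_incoherent_stack):
        """Memory-efficient path reproduces the dense-covariance updates."""
        _, stack, _ = small_incoherent_stack
        A = frames_to_spectral_matrix(stack)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fast = class_phase_retrieval(A, n_iter=20, tol=0)
            dense = class_phase_retrieval_dense(
                covariance(A).dense(), A.grid_shape, n_iter=20, tol=0
            )
        d = np.angle(np.exp(1j * (fast.phase - dense.phase)))
        assert np.abs(d).max() < 1e-8
        assert np.allclose(fast.kernel.t, dense.kernel.t, atol=1e-10)

    def test_all_zero_matrix_rejected(self):
        from classim.matrixops import MeasurementMatrix

        A = MeasurementMatrix(
            columns=np.zeros((16, 3), complex), grid_shape=(4, 4), mode="incoherent"
        )
        with pytest.raises(ValueError):
            class_phase_retrieval(A)


class TestReconstruction:
    def test_delta_psfs_reproduce_object_exactly(self):
        """No scattering: reconstruction equals the object (static fallback)."""
        rng = np.random.default_rng(3)
        obj = ObjectImage(values=rng.random((16, 16)))
        delta = IntensityPSF(psf=centered_delta((16, 16)))
        stack, _ = simulate_incoherent_stack(obj, 4, psfs=[delta] * 4)
        res = iclass_reconstruct(stack, n_iter=10)
        r = registered_correlation(obj.values, res.object_image).r
        assert r == pytest.approx(1.0, abs=1e-6)

    def test_trace_monotone_on_exact_model(self):
        """On a noiseless (exact-model) covariance the update decays monotonically
        after burn-in; empirical covariances add sampling noise and only the
        trend is guaranteed."""
        n = 8
        rng = np.random.default_rng(4)
        O = cfft2((rng.random((n, n)) + 0.2).astype(complex))
        var = np.zeros((n, n))
        var[n // 2 + 1, n // 2 - 2] = 1.0
        C = model_covariance(O, var)
        res = class_phase_retrieval_dense(C, (n, n), n_iter=100, tol=1e-12)
        trace = res.trace
        burn = max(1, len(trace) // 4)  # declared burn-in window
        assert np.all(np.diff(trace[burn:]) <= 1e-12)

    def test_shift_equivariance(self):
        """Cyclically shifting every frame shifts the reconstruction only."""
        rng = np.random.default_rng(6)
        obj = ObjectImage(values=rng.random((16, 16)))
        stack, _ = simulate_incoherent_stack(
            obj, 25, ScreenParams(corr_len_px=2, rms_rad=2 * np.pi), seed=6
        )
        shifted = FrameStack(
            frames=np.roll(stack.frames, shift=(3, 5), axis=(1, 2)),
            mode="incoherent",
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r0 = iclass_reconstruct(stack, n_iter=40)
            r1 = iclass_reconstruct(shifted, n_iter=40)
        c0 = registered_correlation(obj.values, r0.object_image)
        c1 = registered_correlation(obj.values, r1.object_image)
        assert c1.r == pytest.approx(c0.r, abs=1e-6)


class TestFramePsfEstimation:
    def test_delta_object_returns_normalised_frames(self):
        rng = np.random.default_rng(7)
        frames = rng.random((3, 16, 16)) + 0.1
        stack = FrameStack(frames=frames, mode="incoherent")
        est = estimate_frame_psfs(stack, centered_delta((16, 16)))
        for p, f in zip(est, frames):
            assert np.allclose(p.psf, f / f.sum(), atol=1e-6)
            assert p.psf.sum() == pytest.approx(1.0, abs=1e-12)

    def test_round_trip_with_true_object(self):
        """Wiener deconvolution with the true object recovers every PSF."""
        obj = ObjectImage(values=np.clip(np.random.default_rng(8).random((64, 64)), 0.05, None))
        stack, psfs = simulate_incoherent_stack(
            obj, 5, ScreenParams(corr_len_px=4, rms_rad=3 * np.pi), seed=9
        )
        est = estimate_frame_psfs(stack, obj.values, reg_eps=1e-6)
        for e, t in zip(est, psfs):
            assert registered_correlation(t.psf, e.psf).r >= 0.99

    def test_zero_object_rejected(self):
        stack = FrameStack(frames=np.ones((2, 8, 8)), mode="incoherent")
        with pytest.raises(ValueError):
            estimate_frame_psfs(stack, np.zeros((8, 8)))


class TestApsfEstimation:
    def test_identical_field_gives_delta_apsf(self):
        rng = np.random.default_rng(10)
        spec = np.zeros((32, 32), complex)
        spec[8:25, 8:25] = rng.normal(size=(17, 17)) + 1j * rng.normal(size=(17, 17))
        field = icfft2(spec)  # band-limited field
        stack = FrameStack(frames=np.stack([field, field]), mode="coherent")
        apsfs = estimate_apsfs(stack, field, support_thresh=1e-6)
        for a in apsfs:
            peak = np.abs(a.field).max()
            assert np.abs(a.field[16, 16]) == pytest.approx(peak)
            assert np.sum(np.abs(a.field) ** 2) == pytest.approx(1.0, abs=1e-12)

    def test_round_trip_with_true_object(self):
        """Given the true effective object, per-frame APSFs are recovered."""
        rng = np.random.default_rng(11)
        mask = np.zeros((64, 64))
        mask[20:44, 16:52] = 1.0
        refl = ObjectImage(values=(mask * (0.5 + 0.5 * rng.random((64, 64)))).astype(complex))
        stack, apsfs = simulate_coherent_stack(
            refl, n_frames=6, screen_params=ScreenParams(corr_len_px=4, rms_rad=2 * np.pi), seed=12
        )
        est = estimate_apsfs(stack, np.asarray(refl.values))
        rs = [
            registered_correlation(np.abs(t.field), np.abs(e.field)).r
            for t, e in zip(apsfs, est)
        ]
        assert min(rs) >= 0.9

    def test_incoherent_stack_rejected(self):
        stack = FrameStack(frames=np.ones((2, 8, 8)), mode="incoherent")
        with pytest.raises(ValueError):
            estimate_apsfs(stack, np.ones((8, 8)))


class TestRegisteredCorrelation:
    def test_self_correlation_is_one(self):
        img = np.random.default_rng(13).random((32, 32))
        assert registered_correlation(img, img).r == pytest.approx(1.0)

    def test_invariant_to_cyclic_shift(self):
        img = np.random.default_rng(14).random((32, 32))
        rolled = np.roll(img, shift=(5, -7), axis=(0, 1))
        reg = registered_correlation(img, rolled)
        assert reg.r == pytest.approx(1.0)
        assert not reg.reflected

    def test_detects_point_reflection(self):
        img = np.random.default_rng(15).random((32, 32))
        reg = registered_correlation(img, img[::-1, ::-1])
        assert reg.r == pytest.approx(1.0)
        assert reg.reflected

    def test_independent_noise_uncorrelated(self):
        """Monte-Carlo: white images have small registered correlation."""
        rs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            a = rng.normal(size=(64, 64))
            b = rng.normal(size=(64, 64))
            rs.append(registered_correlation(a, b).r)
        # the registration maximises over ~2*64*64 shifts, so the expected
        # maximum of null correlations is ~sqrt(2 ln(8192))/64 ~ 0.066
        assert np.mean(rs) < 0.1

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError):
            registered_correlation(np.ones((8, 8)), np.random.rand(8, 8))
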