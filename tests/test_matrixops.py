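"""Measurement matrix, covariance structure, and the model factorisation."""

import numpy as np
import pytest

from classim import (
    ObjectImage,
    apply_intensity_modulation,
    covariance,
    frames_to_spectral_matrix,
    model_covariance,
    psf_diagonality,
    simulate_incoherent_stack,
)
from classim.fourier import cfft2, icfft2
from classim.simulate import FrameStack


def _stack(frames, mode="incoherent"):
    return FrameStack(frames=np.asarray(frames), mode=mode)


class TestIntensityModulation:
    def test_identity_when_bounds_equal(self, small_incoherent_stack):
        _, stack, _ = small_incoherent_stack
        out = apply_intensity_modulation(stack, 1.0, 1.0)
        assert np.array_equal(out.frames, stack.frames)

    def test_endpoint_factors_over_150_frames(self):
        frames = np.ones((150, 4, 4))
        out = apply_intensity_modulation(_stack(frames), 1.0, 2.0)
        assert out.frames[0].sum() == pytest.approx(16 * 1.0)
        assert out.frames[-1].sum() == pytest.approx(16 * 2.0)
        factors = out.meta["modulation"]["factors"]
        assert np.allclose(np.diff(factors), factors[1] - factors[0])

    def test_creates_energy_variance_on_conserving_stack(self):
        """Phase-only screens conserve frame energy; the ramp breaks that."""
        obj = ObjectImage(values=np.random.default_rng(0).random((32, 32)))
        stack, _ = simulate_incoherent_stack(obj, 20, seed=1)
        before = np.var(stack.frames.sum(axis=(1, 2)))
        after = np.var(apply_intensity_modulation(stack).frames.sum(axis=(1, 2)))
        assert before == pytest.approx(0.0, abs=1e-16 * obj.values.sum() ** 2)
        assert after > 0

    def test_invalid_scalars(self, small_incoherent_stack):
        _, stack, _ = small_incoherent_stack
        with pytest.raises(ValueError):
            apply_intensity_modulation(stack, 0.0, 2.0)
        with pytest.raises(ValueError):
            apply_intensity_modulation(stack, 2.0, 1.0)


class TestSpectralMatrix:
    def test_identical_frames_mean_subtracted_to_zero(self):
        f = np.random.default_rng(1).random((4, 8, 8))
        f[:] = f[0]
        A = frames_to_spectral_matrix(_stack(f), subtract_mean=True)
        assert np.allclose(A.columns, 0, atol=1e-10)

    def test_columns_match_brute_force_dft(self):
        """Oracle: direct O(N^4) centred DFT of each mean-subtracted frame."""
        rng = np.random.default_rng(2)
        f = rng.random((5, 8, 8))
        A = frames_to_spectral_matrix(_stack(f))
        work = f - f.mean(axis=0)
        n, c = 8, 4
        for m in range(5):
            brute = np.zeros((n, n), complex)
            for ky in range(n):
                for kx in range(n):
                    acc = 0.0j
                    for y in range(n):
                        for x in range(n):
                            acc += work[m, y, x] * np.exp(
                                -2j
                                * np.pi
                                * ((ky - c) * (y - c) + (kx - c) * (x - c))
                                / n
                            )
                    brute[ky, kx] = acc
            assert np.allclose(A.columns[:, m].reshape(n, n), brute, atol=1e-8)

    def test_construction_invertible(self):
        """Inverse transform of a column plus the mean frame returns the frame."""
        rng = np.random.default_rng(3)
        f = rng.random((4, 16, 16))
        A = frames_to_spectral_matrix(_stack(f))
        for m in range(4):
            rec = icfft2(A.columns[:, m].reshape(16, 16)).real + A.mean_frame
            assert np.allclose(rec, f[m], atol=1e-10)

    def test_k_index_is_bijective_and_centred(self):
        f = np.random.default_rng(4).random((2, 8, 8))
        A = frames_to_spectral_matrix(_stack(f))
        k = A.k_index
        assert len(np.unique(k, axis=0)) == 64
        assert tuple(k[8 * 4 + 4]) == (0, 0)  # centre row maps to zero frequency

    def test_lowpass_crop(self):
        f = np.random.default_rng(5).random((3, 16, 16))
        A = frames_to_spectral_matrix(_stack(f), lowpass_frac=0.5)
        assert A.grid_shape == (8, 8)
        full = frames_to_spectral_matrix(_stack(f))
        sub = full.columns.reshape(16, 16, 3)[4:12, 4:12].reshape(64, 3)
        assert np.allclose(A.columns, sub)


class TestCovariance:
    def test_rank_one(self):
        cols = np.zeros((16, 3), complex)
        v = np.arange(1, 17) + 1j
        cols[:, 1] = v
        from classim.matrixops import MeasurementMatrix

        A = MeasurementMatrix(columns=cols, grid_shape=(4, 4), mode="incoherent")
        C = covariance(A).dense()
        assert np.allclose(C, np.outer(v, v.conj()) / 2)

    def test_hermitian_psd_real_diagonal(self, small_incoherent_stack):
        _, stack, _ = small_incoherent_stack
        C = covariance(frames_to_spectral_matrix(stack)).dense()
        assert np.allclose(C, C.conj().T, atol=1e-10)
        ev = np.linalg.eigvalsh(C)
        assert ev.min() >= -1e-8 * np.trace(C).real / C.shape[0]
        d = np.diagonal(C)
        assert np.all(d.real >= 0) and np.allclose(d.imag, 0, atol=1e-12)

    def test_operator_matches_dense_matvec(self, small_incoherent_stack):
        _, stack, _ = small_incoherent_stack
        cov = covariance(frames_to_spectral_matrix(stack))
        rng = np.random.default_rng(0)
        v = rng.normal(size=64) + 1j * rng.normal(size=64)
        dense = cov.dense() @ v
        implicit = cov.matvec(v)
        assert np.allclose(dense, implicit, rtol=1e-10)
        assert np.allclose(np.diagonal(cov.dense()).real, cov.diagonal())

    def test_dense_refused_above_limit(self):
        from classim.matrixops import MeasurementMatrix

        cols = np.ones((128 * 128, 2), complex)
        A = MeasurementMatrix(columns=cols, grid_shape=(128, 128), mode="incoherent")
        with pytest.raises(MemoryError):
            covariance(A).dense()

    def test_single_frame_rejected(self):
        from classim.matrixops import MeasurementMatrix

        A = MeasurementMatrix(columns=np.ones((4, 1), complex), grid_shape=(2, 2), mode="incoherent")
        with pytest.raises(ValueError):
            covariance(A)


class TestModelCovariance:
    @staticmethod
    def _empirical(obj, var_profile, M, seed):
        """Frames from pixelwise-independent PSF noise with variance map."""
        rng = np.random.default_rng(seed)
        n = obj.shape[0]
        # exponential (speckle-like) pixel intensities: Var = mean^2
        mean_map = np.sqrt(var_profile)
        psf = rng.exponential(1.0, (M, n, n)) * mean_map
        frames = np.stack(
            [icfft2(cfft2(obj.astype(complex)) * cfft2(p.astype(complex))).real for p in psf]
        )
        return frames

    def test_empirical_converges_to_model_at_root_M_rate(self):
        """Cov(A) -> diag(O~) T diag(O~)* with residual ~ 1/sqrt(M)."""
        n = 16
        rng = np.random.default_rng(7)
        obj = rng.random((n, n)) + 0.1
        var = np.ones((n, n))
        var[: n // 2] = 2.0  # non-trivial variance profile
        O = cfft2(obj.astype(complex))
        model = model_covariance(O, var)
        resid = []
        for M in (500, 2000, 8000):
            frames = self._empirical(obj, var, M, seed=M)
            A = frames_to_spectral_matrix(_stack(frames), subtract_mean=True)
            C = covariance(A).dense()
            resid.append(np.mean(np.abs(C - model)))
        slope = np.polyfit(np.log([500, 2000, 8000]), np.log(resid), 1)[0]
        assert slope == pytest.approx(-0.5, abs=0.12)

    def test_point_variance_gives_rank_one_kernel(self):
        n = 8
        O = cfft2((np.random.default_rng(0).random((n, n)) + 0.2).astype(complex))
        var = np.zeros((n, n))
        var[5, 6] = 1.0
        C = model_covariance(O, var)
        s = np.linalg.svd(C, compute_uv=False)
        assert s[1] < 1e-10 * s[0]


class TestPsfDiagonality:
    def test_white_stack_scores_near_one(self):
        rng = np.random.default_rng(0)
        stack = rng.exponential(1.0, (4000, 4, 4))
        score = psf_diagonality(stack)
        n_pix = 16
        assert score > 1 - 2 * n_pix / np.sqrt(4000)

    def test_identical_stack_degenerate(self):
        p = np.random.default_rng(1).random((1, 8, 8))
        with pytest.raises(ValueError):
            psf_diagonality(np.repeat(p, 5, axis=0))

    def test_correlated_screens_score_lower(self):
        from classim import ScreenParams, simulate_incoherent_stack

        obj = ObjectImage(values=np.ones((32, 32)))
        sp = ScreenParams(corr_len_px=1, rms_rad=2 * np.pi)
        _, p0 = simulate_incoherent_stack(obj, 100, sp, frame_correlation=0.0, seed=3)
        _, p9 = simulate_incoherent_stack(obj, 100, sp, frame_correlation=0.9, seed=3)
        s0 = psf_diagonality(np.stack([p.psf for p in p0]))
        s9 = psf_diagonality(np.stack([p.psf for p in p9]))
        assert s9 < s0
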