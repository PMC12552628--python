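"""Measurement matrix A, its covariance, and the model factorisation.

Arranging the Fourier-transformed frames as columns of a matrix **A**, the
stack of convolutions I_m = P_m * O becomes, column by column,
A[:, m] = diag(O~) P~_m, so that with PSF realizations whose centred pixels
are mutually uncorrelated,

    Cov(A) = diag(O~) . T . diag(O~)*,

where T(k1, k2) = t(k1 - k2) is the (circulant) Toeplitz kernel given by
the Fourier transform of the per-pixel PSF variance map.  The object's
Fourier phase and amplitude are then recoverable from Cov(A) by the CLASS
family of algorithms (see :mod:`classim.recon`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .fourier import cfft2, icfft2
from .simulate import FrameStack

__all__ = [
    "MeasurementMatrix",
    "CovarianceMatrix",
    "apply_intensity_modulation",
    "frames_to_spectral_matrix",
    "covariance",
    "model_covariance",
    "psf_diagonality",
]

DENSE_LIMIT = 4096  # rows above which the dense covariance is never materialised


def apply_intensity_modulation(
    stack: FrameStack, s_min: float = 1.0, s_max: float = 2.0
) -> FrameStack:
    """Multiply frame m by the fixed scalar s_min + (s_max-s_min)(m-1)/(M-1).

    Phase-only (energy-conserving) screens give every raw frame the same
    total intensity, which induces residual correlations between the PSF
    realizations; a deterministic linear intensity ramp across the stack
    breaks that degeneracy before the covariance is formed.
    """
    if s_min <= 0 or s_max < s_min:
        raise ValueError("require s_max >= s_min > 0")
    m = stack.n_frames
    factors = s_min + (s_max - s_min) * np.arange(m) / (m - 1)
    frames = stack.frames * factors[:, None, None]
    meta = dict(stack.meta)
    meta["modulation"] = {"s_min": s_min, "s_max": s_max, "factors": factors.tolist()}
    return replace(stack, frames=frames, meta=meta)


@dataclass(frozen=True)
class MeasurementMatrix:
    """Frames as columns in the Fourier domain.

    ``columns[:, m]`` is the vectorised centred 2-D Fourier transform of
    frame m (mean-subtracted first in incoherent mode), flattened row-major
    over the (possibly low-pass-cropped) centred k-grid.
    """

    columns: np.ndarray  # (N_k, M) complex
    grid_shape: tuple[int, int]
    mode: str
    mean_frame: np.ndarray | None = None
    lowpass_frac: float | None = None

    def __post_init__(self):
        nk, m = self.columns.shape
        if nk != self.grid_shape[0] * self.grid_shape[1]:
            raise ValueError("row count inconsistent with grid shape")

    @property
    def n_frames(self) -> int:
        return self.columns.shape[1]

    @property
    def k_index(self) -> np.ndarray:
        """(N_k, 2) map row -> centred frequency offset (ky, kx) in samples."""
        h, w = self.grid_shape
        ky = np.arange(h) - h // 2
        kx = np.arange(w) - w // 2
        g = np.stack(np.meshgrid(ky, kx, indexing="ij"), axis=-1)
        return g.reshape(-1, 2)

    def spectra(self) -> np.ndarray:
        """Columns reshaped to an (M, H, W) stack of centred spectra."""
        h, w = self.grid_shape
        return np.moveaxis(self.columns.reshape(h, w, -1), -1, 0)


def _lowpass_crop(spec: np.ndarray, frac: float) -> np.ndarray:
    """Centred square crop of a centred spectrum to ``frac`` of its extent."""
    h, w = spec.shape[-2:]
    nh = max(2, int(round(h * frac)))
    nw = max(2, int(round(w * frac)))
    y0 = h // 2 - nh // 2
    x0 = w // 2 - nw // 2
    return spec[..., y0 : y0 + nh, x0 : x0 + nw]


def frames_to_spectral_matrix(
    stack: FrameStack,
    subtract_mean: bool | None = None,
    lowpass_frac: float | None = None,
) -> MeasurementMatrix:
    """Build the measurement matrix **A** from a frame stack.

    Incoherent mode subtracts the temporal mean frame before transforming
    (removing the dominant static haze term, the analogue of centring the
    PSF ensemble); coherent speckle fields are zero-mean so no subtraction
    is applied by default.  ``lowpass_frac`` optionally crops the centred
    spectra to a sub-grid (Fourier-domain downsampling, as used on
    high-pixel-count cameras).
    """
    if subtract_mean is None:
        subtract_mean = stack.mode == "incoherent"
    frames = np.asarray(stack.frames)
    mean_frame = frames.mean(axis=0)
    work = frames - mean_frame if subtract_mean else frames
    spec = cfft2(work.astype(complex))
    if lowpass_frac is not None:
        if not 0 < lowpass_frac <= 1:
            raise ValueError("lowpass_frac must be in (0, 1]")
        if lowpass_frac < 1:
            spec = _lowpass_crop(spec, lowpass_frac)
    m = spec.shape[0]
    grid = spec.shape[1:]
    return MeasurementMatrix(
        columns=np.moveaxis(spec, 0, -1).reshape(grid[0] * grid[1], m),
        grid_shape=grid,
        mode=stack.mode,
        mean_frame=mean_frame if subtract_mean else None,
        lowpass_frac=lowpass_frac,
    )


class CovarianceMatrix:
    """Cov(A) = A A^H / (M-1), dense or as an implicit operator.

    Dense storage is refused above ``DENSE_LIMIT`` rows; the operator form
    backed by A produces identical matrix-vector products without ever
    materialising the N_k x N_k array.
    """

    def __init__(self, A: MeasurementMatrix):
        if A.n_frames < 2:
            raise ValueError("need at least 2 frames to form a covariance")
        self._A = A.columns
        self.grid_shape = A.grid_shape
        self.n_rows = A.columns.shape[0]
        self.n_frames = A.n_frames
        self._dense: np.ndarray | None = None

    @property
    def is_dense_allowed(self) -> bool:
        return self.n_rows <= DENSE_LIMIT

    def dense(self) -> np.ndarray:
        if not self.is_dense_allowed:
            raise MemoryError(
                f"dense covariance refused for {self.n_rows} rows "
                f"(limit {DENSE_LIMIT}); use matvec/diagonal"
            )
        if self._dense is None:
            self._dense = self._A @ self._A.conj().T / (self.n_frames - 1)
        return self._dense

    def matvec(self, v: np.ndarray) -> np.ndarray:
        return self._A @ (self._A.conj().T @ v) / (self.n_frames - 1)

    def diagonal(self) -> np.ndarray:
        return np.sum(np.abs(self._A) ** 2, axis=1) / (self.n_frames - 1)


def covariance(A: MeasurementMatrix) -> CovarianceMatrix:
    """Covariance of the measurement matrix (1/(M-1) normalisation)."""
    return CovarianceMatrix(A)


def model_covariance(
    object_spectrum: np.ndarray, psf_variance_map: np.ndarray
) -> np.ndarray:
    """Dense model covariance diag(O~) . T . diag(O~)* from ground truth.

    ``object_spectrum`` is the centred spectrum O~(k) (H x W); the Toeplitz
    kernel is t(q) = sum_r Var_P(r) exp(-i 2pi q.r / N), the centred Fourier
    transform of the per-pixel PSF variance map, and T(k1, k2) = t(k1 - k2)
    with circular frequency differences.  Used as the analytic oracle for
    both the covariance builder and the phase retrieval.
    """
    o = np.asarray(object_spectrum, dtype=complex)
    h, w = o.shape
    if psf_variance_map.shape != (h, w):
        raise ValueError("variance map grid must match spectrum grid")
    t = cfft2(psf_variance_map.astype(complex))  # centred kernel over q
    ky = np.arange(h) - h // 2
    kx = np.arange(w) - w // 2
    gy, gx = np.meshgrid(ky, kx, indexing="ij")
    k1y = gy.reshape(-1)[:, None]
    k1x = gx.reshape(-1)[:, None]
    qy = (k1y - k1y.T) % h  # circular frequency difference, uncentred index
    qx = (k1x - k1x.T) % w
    t_uncentered = np.fft.ifftshift(t)
    T = t_uncentered[qy, qx]
    d = o.reshape(-1)
    return d[:, None] * T * d.conj()[None, :]


def psf_diagonality(psf_stack: np.ndarray) -> float:
    """Diagonal-dominance score of the PSF ensemble covariance, in [0, 1].

    The stack (M, H, W) is centred over realizations; with Cov_P the pixel
    by pixel covariance, the score is sum_i |Cov_P(i,i)| / sum_ij |Cov_P(i,j)|.
    Mutually uncorrelated, pixelwise-independent PSFs score ~1 (up to a
    finite-M sampling floor ~ N_pix / sqrt(M)); temporally correlated or
    structured stacks score lower.
    """
    p = np.asarray(psf_stack)
    if p.ndim != 3 or p.shape[0] < 2:
        raise ValueError("need an (M >= 2, H, W) stack")
    m = p.shape[0]
    x = p.reshape(m, -1)
    x = x - x.mean(axis=0)
    scale = np.abs(p).max()
    if scale == 0 or np.abs(x).max() < 1e-12 * scale:
        raise ValueError("degenerate stack: identical realizations")
    cov = x.T @ x.conj() / (m - 1)
    total = np.sum(np.abs(cov))
    return float(np.sum(np.abs(np.diagonal(cov))) / total)
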