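"""CLASS-type reconstruction: object Fourier phase and amplitude from Cov(A).

Because convolution commutes, frames of a *static* object seen through a
*dynamic* scatterer obey the same matrix equation as frames of a static
scatterer under dynamic illumination, with the roles of object and PSF
interchanged.  The closed-loop accumulation (CLASS) update therefore
retrieves the object's Fourier phase from the covariance of the
measurement matrix; adding the amplitude estimate from the covariance
diagonal (the I-CLASS variant) yields the full object spectrum.

The normative algorithm alternates:

  (a) kernel:  t(q)     =  sum_k  C(k+q, k) e^{-i psi(k+q)} e^{+i psi(k)}
  (b) phase:   psi(k1) <-  arg( sum_k2 C(k1, k2) e^{+i psi(k2)} t*(k1-k2) )

with all frequency differences circular.  The production path
(:func:`class_phase_retrieval`) evaluates both sums through frame-domain
FFT correlations so the dense covariance is never formed;
:func:`class_phase_retrieval_dense` applies the same updates literally to a
dense covariance and serves as the oracle the fast path is tested against.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .fourier import cfft2, icfft2
from .matrixops import (
    MeasurementMatrix,
    apply_intensity_modulation,
    covariance,
    frames_to_spectral_matrix,
)
from .screens import APSF, IntensityPSF
from .simulate import FrameStack

__all__ = [
    "ToeplitzKernel",
    "ReconResult",
    "PhaseRetrievalResult",
    "class_phase_retrieval",
    "class_phase_retrieval_dense",
    "fix_gauge",
    "iclass_reconstruct",
    "estimate_frame_psfs",
    "estimate_apsfs",
    "registered_correlation",
    "RegistrationResult",
]


@dataclass(frozen=True)
class ToeplitzKernel:
    """Estimated kernel t(q) over centred frequency differences q = k1 - k2.

    Proportional to the Fourier transform of the PSF-ensemble variance map;
    normalised so t(0) = 1 (t(0) is real positive by construction: it is a
    sum of squared magnitudes).
    """

    t: np.ndarray

    def __post_init__(self):
        c = self.t[self.t.shape[0] // 2, self.t.shape[1] // 2]
        if not (abs(c.imag) < 1e-8 * (abs(c) + 1e-300) and c.real > 0):
            raise ValueError("kernel t(0) must be real positive")


class PhaseRetrievalResult(NamedTuple):
    phase: np.ndarray  # centred retrieved Fourier phase (radians)
    kernel: ToeplitzKernel
    trace: np.ndarray  # mean |wrapped phase update| per iteration
    converged: bool
    n_iter: int


def _retrieve_frame_domain(a: np.ndarray, n_iter: int, tol: float, work_dtype=None):
    """CLASS updates via frame-domain correlations.

    ``a``: (M, H, W) *uncentred* frame spectra.  Per iteration, with
    b_m = a_m e^{-i psi} and B_m = IFFT2(b_m):

        t(q)    = sum_m FFT2(|B_m|^2)(q)          (k-space autocorrelation)
        s_m(k1) = IFFT2( conj(B_m) . FFT2(conj t) )(k1)
                = sum_k2 conj(b_m(k2)) t*(k1-k2)   (up to a positive factor)
        psi(k1) = arg( sum_m a_m(k1) s_m(k1) )

    which reproduces the dense-covariance updates exactly (positive scale
    factors do not affect the argument).
    """
    if work_dtype is not None:
        a = a.astype(work_dtype)
    _, h, w = a.shape
    psi = np.zeros((h, w), dtype=a.real.dtype)
    trace = []
    t = np.ones((h, w), complex)
    for it in range(n_iter):
        b = a * np.exp(-1j * psi)
        B = np.fft.ifft2(b, axes=(-2, -1))
        t = np.fft.fft2(np.abs(B) ** 2, axes=(-2, -1)).sum(axis=0)
        s = np.fft.ifft2(
            np.conj(B) * np.fft.fft2(np.conj(t))[None], axes=(-2, -1)
        )
        num = (a * s).sum(axis=0)
        psi_new = np.angle(num)
        d = np.angle(np.exp(1j * (psi_new - psi)))
        trace.append(float(np.abs(d).mean()))
        psi = psi_new
        if trace[-1] < tol:
            break
    return psi.astype(float), t.astype(complex), np.asarray(trace)


def class_phase_retrieval(
    A: MeasurementMatrix,
    n_iter: int = 1000,
    tol: float = 1e-6,
    work_dtype=None,
) -> PhaseRetrievalResult:
    """Retrieve the object's Fourier phase from the measurement matrix.

    Memory-efficient: works on the frames (columns of A) directly and never
    materialises Cov(A).  Deterministic — no randomness enters the
    iteration.  Non-convergence within ``n_iter`` produces a warning status
    in the result, not an exception.  The default iteration budget is 1000.
    ``work_dtype=np.complex64`` halves memory traffic in the FFT loop; the
    per-iteration phase rounding (~1e-6 rad) is far below the statistical
    error of realistic ensembles (double precision remains the default and
    matches the dense oracle to ~1e-14).
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if not np.any(A.columns):
        raise ValueError("degenerate input: measurement matrix is all zeros")
    spectra = A.spectra()
    a = np.fft.ifftshift(spectra, axes=(-2, -1))
    psi, t, trace = _retrieve_frame_domain(a, n_iter, tol, work_dtype=work_dtype)
    converged = bool(trace[-1] < tol)
    if not converged:
        warnings.warn(
            f"phase retrieval did not reach tol={tol:g} in {len(trace)} "
            f"iterations (last update {trace[-1]:.3g} rad)",
            RuntimeWarning,
        )
    t0 = t[0, 0].real
    kernel = ToeplitzKernel(t=np.fft.fftshift(t) / t0)
    return PhaseRetrievalResult(
        phase=np.fft.fftshift(psi),
        kernel=kernel,
        trace=trace,
        converged=converged,
        n_iter=len(trace),
    )


def class_phase_retrieval_dense(
    C: np.ndarray,
    grid_shape: tuple[int, int],
    n_iter: int = 1000,
    tol: float = 1e-6,
) -> PhaseRetrievalResult:
    """Reference implementation applying the updates to a dense covariance.

    ``C`` is indexed by the flattened centred k-grid (row-major), as
    produced by :class:`classim.matrixops.CovarianceMatrix.dense` or
    :func:`classim.matrixops.model_covariance`.  Literal but slow — the
    test oracle for :func:`class_phase_retrieval`.
    """
    h, w = grid_shape
    if C.shape != (h * w, h * w):
        raise ValueError("covariance shape inconsistent with grid")
    if not np.any(C):
        raise ValueError("degenerate input: covariance is all zeros")
    # centred rows -> uncentred 4-D tensor C4[k1y, k1x, k2y, k2x]
    C4 = np.fft.ifftshift(C.reshape(h, w, h, w), axes=(0, 1, 2, 3))
    yy, xx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    ky = yy.reshape(-1)
    kx = xx.reshape(-1)
    qy = (ky[:, None] - ky[None, :]) % h  # uncentred circular difference
    qx = (kx[:, None] - kx[None, :]) % w
    Cm = C4.reshape(h * w, h * w)
    psi = np.zeros((h, w))
    trace = []
    t = np.ones((h, w), complex)
    for _ in range(n_iter):
        E = np.exp(1j * psi)
        G = Cm * np.conj(E).reshape(-1)[:, None] * E.reshape(-1)[None, :]
        G4 = G.reshape(h, w, h, w)
        t = np.zeros((h, w), complex)
        for uy in range(h):
            for ux in range(w):
                rolled = np.roll(G4, shift=(-uy, -ux), axis=(0, 1))
                t[uy, ux] = np.einsum("ijij->", rolled)
        tq = np.conj(t)[qy, qx]
        num = (Cm * tq) @ E.reshape(-1)
        psi_new = np.angle(num).reshape(h, w)
        d = np.angle(np.exp(1j * (psi_new - psi)))
        trace.append(float(np.abs(d).mean()))
        psi = psi_new
        if trace[-1] < tol:
            break
    t0 = t[0, 0].real
    return PhaseRetrievalResult(
        phase=np.fft.fftshift(psi),
        kernel=ToeplitzKernel(t=np.fft.fftshift(t) / t0),
        trace=np.asarray(trace),
        converged=bool(trace[-1] < tol),
        n_iter=len(trace),
    )


def fix_gauge(spectrum: np.ndarray) -> tuple[np.ndarray, dict]:
    """Remove the unobservable gauge: global phase and linear phase ramp.

    A linear ramp in the Fourier phase is a cyclic spatial shift of the
    reconstruction; the slope is estimated as the amplitude-weighted mean
    phase increment between neighbouring frequency samples (exact for a
    pure ramp), then the DC phase is zeroed.  Returns the gauge-fixed
    spectrum and the removed (slope_y, slope_x, global_phase).
    """
    s = np.asarray(spectrum, dtype=complex)
    h, w = s.shape
    dy = np.angle(np.sum(np.roll(s, -1, axis=0) * np.conj(s)))
    dx = np.angle(np.sum(np.roll(s, -1, axis=1) * np.conj(s)))
    ky = (np.arange(h) - h // 2)[:, None]
    kx = (np.arange(w) - w // 2)[None, :]
    out = s * np.exp(-1j * (dy * ky + dx * kx))
    phi0 = np.angle(out[h // 2, w // 2])
    if out[h // 2, w // 2] == 0:
        phi0 = 0.0
    out = out * np.exp(-1j * phi0)
    return out, {"slope_y": float(dy), "slope_x": float(dx), "global_phase": float(phi0)}


@dataclass
class ReconResult:
    """Output of :func:`iclass_reconstruct`.

    ``object_spectrum`` is the gauge-fixed amplitude-and-phase estimate of
    O~(k) on the centred grid; ``object_image`` its inverse transform —
    magnitude in incoherent mode, complex field in coherent mode (the
    recovered effective object at the scattering-layer plane).
    """

    object_spectrum: np.ndarray
    object_image: np.ndarray
    phase_trace: np.ndarray
    n_iter: int
    mode: str
    kernel: ToeplitzKernel | None = None
    converged: bool = True
    meta: dict = field(default_factory=dict)


def _psf_power_correction(
    stack: FrameStack,
    object_image: np.ndarray,
    amp: np.ndarray,
    reg_eps: float,
    wiener_eps: float,
) -> np.ndarray:
    """Self-consistent amplitude refinement.

    The covariance diagonal estimates |O~(k)|^2 . s(k) with s(k) the
    PSF-ensemble spectral power — a quantity the data itself reveals:
    Wiener-deconvolving each frame by the current reconstruction recovers
    the per-frame PSFs (up to the common shift of the reconstruction,
    which cancels in their power spectra), whose centred spectral power
    gives s(k).  The amplitude is then Wiener-divided by sqrt(s(k)).
    """
    est = estimate_frame_psfs(stack, object_image, reg_eps=reg_eps)
    if stack.mode == "incoherent":
        p = np.stack([e.psf for e in est])
        factors = stack.meta.get("modulation", {}).get("factors")
        if factors is not None:
            p = p * np.asarray(factors)[:, None, None]
        p = p - p.mean(axis=0)
    else:
        p = np.stack(est)
    s = np.mean(np.abs(cfft2(p.astype(complex))) ** 2, axis=0)
    c = np.sqrt(np.clip(s, 0, None))
    peak = c.max()
    if peak == 0:
        return amp
    c = c / peak
    return amp * c / (c**2 + wiener_eps)


def iclass_reconstruct(
    stack: FrameStack,
    n_iter: int = 1000,
    tol: float = 1e-6,
    modulation: tuple[float, float] | None = None,
    lowpass_frac: float | None = None,
    subtract_mean: bool | None = None,
    amp_refine: bool = True,
    amp_refine_eps: float = 0.05,
    reg_eps: float = 1e-6,
    work_dtype=np.complex64,
) -> ReconResult:
    """Full I-CLASS pipeline: frames -> A -> phase retrieval -> object.

    The Fourier amplitude starts from the square root of the covariance
    diagonal (the moment estimator consistent with the factorised model;
    the unknown kernel constant t(0) is absorbed into the global scale).
    That diagonal carries the PSF-ensemble spectral power s(k) as a
    multiplicative weighting, so by default one self-consistent refinement
    step estimates s(k) from the per-frame PSFs recovered by deconvolution
    and Wiener-divides it out (``amp_refine``).  In incoherent mode the
    mean-subtracted pipeline loses the DC term; it is restored from the
    temporal-mean frame, with the AC amplitude rescaled by matching the
    lowest nonzero frequencies of the mean-frame spectrum (where the
    PSF-envelope transfer is close to unity).
    """
    if modulation is not None:
        stack = apply_intensity_modulation(stack, *modulation)
    A = frames_to_spectral_matrix(
        stack, subtract_mean=subtract_mean, lowpass_frac=lowpass_frac
    )
    # No frame-to-frame variation (no scattering, or a static medium): the
    # covariance carries no information and the mean frame is the estimate.
    mean_frame = np.asarray(stack.frames).mean(axis=0)
    frame_scale = np.abs(stack.frames).max()
    if frame_scale == 0:
        raise ValueError("degenerate input: all frames are zero")
    if np.abs(np.asarray(stack.frames) - mean_frame).max() < 1e-9 * frame_scale:
        spectrum = cfft2(mean_frame.astype(complex))
        image = mean_frame if stack.mode == "incoherent" else mean_frame.astype(complex)
        return ReconResult(
            object_spectrum=spectrum,
            object_image=image,
            phase_trace=np.zeros(1),
            n_iter=0,
            mode=stack.mode,
            kernel=None,
            converged=True,
            meta={"static_fallback": True},
        )
    pr = class_phase_retrieval(A, n_iter=n_iter, tol=tol, work_dtype=work_dtype)
    h, w = A.grid_shape
    amp = np.sqrt(np.clip(covariance(A).diagonal(), 0, None)).reshape(h, w)
    refined = False
    if amp_refine and (lowpass_frac is None or lowpass_frac == 1):
        img0 = np.abs(icfft2(amp * np.exp(1j * pr.phase)))
        if np.any(img0):
            amp = _psf_power_correction(
                stack, img0, amp, reg_eps=reg_eps, wiener_eps=amp_refine_eps
            )
            refined = True
    spectrum = amp * np.exp(1j * pr.phase)
    spectrum, gauge = fix_gauge(spectrum)
    meta = {"gauge": gauge, "lowpass_frac": lowpass_frac, "amp_refined": refined}
    if stack.mode == "incoherent":
        mean_frame = np.asarray(stack.frames).mean(axis=0)
        mean_spec = cfft2(mean_frame.astype(complex))
        if lowpass_frac is not None and lowpass_frac < 1:
            from .matrixops import _lowpass_crop

            mean_spec = _lowpass_crop(mean_spec, lowpass_frac)
        cy, cx = h // 2, w // 2
        neigh = [(cy - 1, cx), (cy + 1, cx), (cy, cx - 1), (cy, cx + 1)]
        num = np.mean([np.abs(mean_spec[i, j]) for i, j in neigh])
        den = np.mean([np.abs(spectrum[i, j]) for i, j in neigh])
        scale = num / den if den > 0 else 1.0
        spectrum = spectrum * scale
        spectrum[cy, cx] = np.abs(mean_spec[cy, cx])
        img = icfft2(spectrum)
        clipped = float(np.mean(img.real < -1e-12 * np.abs(img).max()))
        object_image = np.abs(img)
        meta.update({"dc_scale": float(scale), "negative_fraction": clipped})
    else:
        object_image = icfft2(spectrum)
    return ReconResult(
        object_spectrum=spectrum,
        object_image=object_image,
        phase_trace=pr.trace,
        n_iter=pr.n_iter,
        mode=stack.mode,
        kernel=pr.kernel,
        converged=pr.converged,
        meta=meta,
    )


def estimate_frame_psfs(
    stack: FrameStack, object_estimate: np.ndarray, reg_eps: float = 1e-6
) -> list[IntensityPSF] | list[np.ndarray]:
    """Per-frame PSFs by Wiener deconvolution of the raw frames with the
    reconstructed object.

        P_m = IFFT[ I~_m(k) O~*(k) / (|O~(k)|^2 + reg_eps max|O~|^2) ]

    Incoherent estimates are clipped to >= 0 and renormalised to unit sum
    and returned as :class:`IntensityPSF`; coherent estimates are returned
    as raw complex arrays.
    """
    if reg_eps <= 0:
        raise ValueError("reg_eps must be > 0")
    obj = np.asarray(object_estimate)
    if not np.any(obj):
        raise ValueError("degenerate input: all-zero object estimate")
    O = cfft2(obj.astype(complex))
    wiener = np.conj(O) / (np.abs(O) ** 2 + reg_eps * np.max(np.abs(O)) ** 2)
    out = []
    for f in stack.frames:
        p = icfft2(cfft2(np.asarray(f, dtype=complex)) * wiener)
        if stack.mode == "incoherent":
            p = np.clip(p.real, 0, None)
            s = p.sum()
            if s == 0:
                raise ValueError("deconvolution produced an all-zero PSF")
            out.append(IntensityPSF(psf=p / s))
        else:
            out.append(p)
    return out


def estimate_apsfs(
    stack: FrameStack,
    object_estimate: np.ndarray,
    support_thresh: float = 1e-3,
    min_support_px: int = 16,
) -> list[APSF]:
    """Per-frame amplitude PSFs from the scatterer phase each frame imprints.

    At the scattering-layer plane (the Fourier domain of the camera grid)
    each measured field is the object field multiplied by the scatterer
    transmission, so dividing frame spectra by the reconstructed object
    spectrum isolates the per-realization diffuser phase:

        phi_m = arg( E~_m(k) / O~(k) )   on the support |O~| > thresh . max

    and the APSF estimate is the centred Fourier transform of e^{i phi_m}
    restricted to that support, energy-normalised.
    """
    if stack.mode != "coherent":
        raise ValueError("APSF estimation requires a coherent field stack")
    obj = np.asarray(object_estimate, dtype=complex)
    if not np.any(obj):
        raise ValueError("degenerate input: all-zero object estimate")
    O = cfft2(obj)
    valid = np.abs(O) > support_thresh * np.abs(O).max()
    if valid.sum() < min_support_px:
        raise ValueError(
            f"object-spectrum support has {int(valid.sum())} pixels "
            f"(< {min_support_px}); cannot estimate the scatterer phase"
        )
    out = []
    for f in stack.frames:
        ratio = np.zeros_like(O)
        Ef = cfft2(np.asarray(f, dtype=complex))
        ratio[valid] = Ef[valid] / O[valid]
        # a band-limiting pupil makes |ratio| ~ pupil: restrict the phase map
        # to the passband so stop-band noise does not masquerade as phase.
        # |ratio| is bimodal (passband level vs ~0 stop band); anchor the
        # threshold on its upper tail, which is robust to the passband
        # occupying only a small fraction of the grid.
        level = np.percentile(np.abs(ratio[valid]), 99.5)
        support = valid & (np.abs(ratio) > 0.1 * level)
        if support.sum() < min_support_px:
            raise ValueError(
                "scatterer passband support too small to estimate the phase"
            )
        phi = np.angle(ratio)
        field = cfft2(np.exp(1j * phi) * support)
        energy = np.sum(np.abs(field) ** 2)
        out.append(APSF(field=field / np.sqrt(energy)))
    return out


class RegistrationResult(NamedTuple):
    r: float
    shift: tuple[int, int]  # cyclic shift applied to b to best match a
    reflected: bool


def registered_correlation(
    image_a: np.ndarray, image_b: np.ndarray
) -> RegistrationResult:
    """Pearson correlation maximised over cyclic shifts and the twin copy.

    Fourier-phase reconstructions are defined only up to a cyclic
    translation and, in some modes, a point-reflected conjugate twin; this
    registers over both before correlating.  Inputs must be real and
    non-constant (pass magnitudes for complex fields).
    """
    a = np.asarray(image_a, dtype=float)
    b = np.asarray(image_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("images must share a shape")
    a0 = a - a.mean()
    b0 = b - b.mean()
    na = np.linalg.norm(a0)
    nb = np.linalg.norm(b0)
    if na == 0 or nb == 0:
        raise ValueError("degenerate input: constant image")
    Fa = np.fft.fft2(a0)
    best = (-np.inf, (0, 0), False)
    for reflected in (False, True):
        bb = b0[::-1, ::-1] if reflected else b0
        cc = np.fft.ifft2(Fa * np.conj(np.fft.fft2(bb))).real
        idx = np.unravel_index(np.argmax(cc), cc.shape)
        r = cc[idx] / (na * nb)
        if r > best[0]:
            best = (float(r), (int(idx[0]), int(idx[1])), reflected)
    return RegistrationResult(*best)
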