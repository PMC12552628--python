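"""Forward models: frame stacks of a static object seen through a dynamic scatterer.

Each short-exposure frame is the circular convolution of the static object
with that frame's PSF realization,

    incoherent:  I_m = P_m * O                      (real intensities)
    coherent:    E_m = P_m^coh * (O . E_ill)        (complex fields)

with the PSFs drawn from independent (or optionally temporally correlated)
random phase screens.  Circular convolution is deliberate: it makes the
forward model match the Fourier-domain covariance factorisation used by the
reconstruction exactly; a ``linear=True`` flag zero-pads for realism tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import fftconvolve

from .fourier import circular_convolve
from .screens import (
    APSF,
    IntensityPSF,
    PhaseScreen,
    Pupil,
    _filtered_gaussian_field,
    _rescale_phase,
    apsf_to_ipsf,
    screen_to_apsf,
)

__all__ = [
    "ObjectImage",
    "IlluminationField",
    "FrameStack",
    "ScreenParams",
    "NoiseParams",
    "screen_sequence",
    "simulate_incoherent_stack",
    "simulate_coherent_stack",
    "simulate_offaxis_hologram",
]


@dataclass(frozen=True)
class ObjectImage:
    """The static hidden target O(r).

    Real non-negative intensity in incoherent mode; complex reflectivity in
    coherent mode.
    """

    values: np.ndarray
    pitch_um: float = 1.0

    def __post_init__(self):
        v = np.asarray(self.values)
        if not np.all(np.isfinite(v)):
            raise ValueError("object contains non-finite values")
        if not np.any(v != 0):
            raise ValueError("object must have at least one nonzero pixel")
        if not np.iscomplexobj(v) and np.min(v) < 0:
            raise ValueError("real (incoherent) object must be non-negative")

    @property
    def is_coherent(self) -> bool:
        return np.iscomplexobj(self.values)


@dataclass(frozen=True)
class IlluminationField:
    """Complex illumination field at the object plane (fixed across frames)."""

    field: np.ndarray

    def __post_init__(self):
        f = np.asarray(self.field)
        if not np.all(np.isfinite(f)):
            raise ValueError("illumination contains non-finite values")
        if np.sum(np.abs(f) ** 2) == 0:
            raise ValueError("illumination has zero energy")


@dataclass(frozen=True)
class FrameStack:
    """M measured frames: the sole input the reconstruction sees.

    ``frames`` has shape (M, H, W); real intensities in incoherent mode,
    complex fields in coherent mode.
    """

    frames: np.ndarray
    mode: str  # "incoherent" | "coherent"
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        f = np.asarray(self.frames)
        if f.ndim != 3 or f.shape[0] < 2:
            raise ValueError("frame stack must be (M >= 2, H, W)")
        if self.mode not in ("incoherent", "coherent"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "coherent" and not np.iscomplexobj(f):
            raise ValueError("coherent stack must be complex-valued")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass(frozen=True)
class ScreenParams:
    """Phase-screen statistics shared by all frames of a stack.

    ``pupil_radius_frac`` sets the circular aperture (fraction of the
    Nyquist radius); ``None`` applies no aperture at all (phase-only
    screens).  Unit-sum PSF normalisation makes every frame conserve
    energy exactly in either case.
    """

    corr_len_px: float = 4.0
    rms_rad: float = 3 * np.pi
    pupil_radius_frac: float | None = 1.0


@dataclass(frozen=True)
class NoiseParams:
    """Detection noise: Poisson shot noise at a photon budget plus Gaussian
    read noise (both disabled by default)."""

    photons_per_frame: float | None = None
    read_noise: float = 0.0


def screen_sequence(
    shape: tuple[int, int],
    n: int,
    params: ScreenParams,
    frame_correlation: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> list[PhaseScreen]:
    """Draw ``n`` phase screens, optionally correlated from frame to frame.

    ``frame_correlation`` in [0, 1) mixes each new screen's underlying
    Gaussian with the previous one (AR(1): g_m = c g_{m-1} + sqrt(1-c^2) w_m)
    before the RMS is re-normalised; 0 gives mutually independent screens.
    """
    if not 0 <= frame_correlation < 1:
        raise ValueError("frame_correlation must be in [0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ell = params.corr_len_px * max(params.rms_rad, 1.0)
    c = frame_correlation
    screens = []
    g = None
    for _ in range(n):
        w = _filtered_gaussian_field(shape, ell, rng)
        w = w / (w.std() or 1.0)
        g = w if g is None else c * g + np.sqrt(1 - c**2) * w
        screens.append(
            PhaseScreen(
                phase=_rescale_phase(g.copy(), params.rms_rad),
                corr_len_px=params.corr_len_px,
                rms_rad=params.rms_rad,
            )
        )
    return screens


def _convolve(obj: np.ndarray, ker: np.ndarray, linear: bool) -> np.ndarray:
    if linear:
        return fftconvolve(obj, ker, mode="same")
    return circular_convolve(obj, ker)


def simulate_incoherent_stack(
    obj: ObjectImage,
    n_frames: int,
    screen_params: ScreenParams = ScreenParams(),
    frame_correlation: float = 0.0,
    noise: NoiseParams = NoiseParams(),
    seed: int = 0,
    psfs: list[IntensityPSF] | None = None,
    linear: bool = False,
) -> tuple[FrameStack, list[IntensityPSF]]:
    """Render an incoherent stack I_m = P_m * O and return the true PSFs.

    PSFs are derived from random phase screens unless an explicit ``psfs``
    list is supplied (useful for delta-kernel controls).  Deterministic per
    seed.  Noise, when enabled, scales each clean frame to the requested
    photon budget, draws Poisson counts and adds Gaussian read noise.
    """
    if obj.is_coherent:
        raise ValueError("incoherent simulation requires a real non-negative object")
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    shape = obj.values.shape
    ss = np.random.SeedSequence(seed)
    s_screens, s_noise = ss.spawn(2)
    if psfs is None:
        pupil = (
            None
            if screen_params.pupil_radius_frac is None
            else Pupil(shape=shape, radius_frac=screen_params.pupil_radius_frac)
        )
        screens = screen_sequence(
            shape,
            n_frames,
            screen_params,
            frame_correlation,
            np.random.default_rng(s_screens),
        )
        psfs = [apsf_to_ipsf(screen_to_apsf(s, pupil)) for s in screens]
    elif len(psfs) != n_frames:
        raise ValueError("psfs list length must equal n_frames")
    frames = np.stack([_convolve(obj.values, p.psf, linear) for p in psfs])
    frames = np.clip(frames, 0, None)  # clip convolution round-off
    if noise.photons_per_frame or noise.read_noise:
        rng = np.random.default_rng(s_noise)
        noisy = []
        for f in frames:
            if noise.photons_per_frame:
                scale = noise.photons_per_frame / (f.sum() or 1.0)
                f = rng.poisson(f * scale) / scale
            if noise.read_noise:
                f = f + rng.normal(0.0, noise.read_noise, f.shape)
            noisy.append(f)
        frames = np.stack(noisy)
    stack = FrameStack(
        frames=frames,
        mode="incoherent",
        seed=seed,
        meta={
            "screen_params": screen_params.__dict__,
            "frame_correlation": frame_correlation,
            "noise": noise.__dict__,
            "linear": linear,
        },
    )
    return stack, psfs


def simulate_coherent_stack(
    reflectivity: ObjectImage,
    illumination: IlluminationField | None = None,
    n_frames: int = 180,
    screen_params: ScreenParams = ScreenParams(rms_rad=2 * np.pi),
    frame_correlation: float = 0.0,
    seed: int = 0,
    apsfs: list[APSF] | None = None,
) -> tuple[FrameStack, list[APSF]]:
    """Render a coherent stack E_m = P_m^coh * (O . E_ill) and the true APSFs.

    The illumination is fixed across realizations (the focused-spot
    condition: the beam waist on the scatterer is smaller than its
    correlation length, so the object sees an effectively constant field).
    """
    shape = np.asarray(reflectivity.values).shape
    if illumination is None:
        illumination = IlluminationField(field=np.ones(shape, complex))
    if np.asarray(illumination.field).shape != shape:
        raise ValueError("illumination grid does not match object grid")
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    eff_obj = np.asarray(reflectivity.values).astype(complex) * illumination.field
    if apsfs is None:
        pupil = (
            None
            if screen_params.pupil_radius_frac is None
            else Pupil(shape=shape, radius_frac=screen_params.pupil_radius_frac)
        )
        screens = screen_sequence(
            shape,
            n_frames,
            screen_params,
            frame_correlation,
            np.random.default_rng(np.random.SeedSequence(seed)),
        )
        apsfs = [screen_to_apsf(s, pupil) for s in screens]
    elif len(apsfs) != n_frames:
        raise ValueError("apsfs list length must equal n_frames")
    frames = np.stack([circular_convolve(a.field, eff_obj) for a in apsfs])
    stack = FrameStack(
        frames=frames,
        mode="coherent",
        seed=seed,
        meta={
            "screen_params": screen_params.__dict__,
            "frame_correlation": frame_correlation,
        },
    )
    return stack, apsfs


def simulate_offaxis_hologram(
    field: np.ndarray,
    carrier_cycles: tuple[float, float],
    ref_amplitude: float = 1.0,
) -> np.ndarray:
    """Off-axis hologram: interference of ``field`` with a tilted plane-wave
    reference.

    ``carrier_cycles = (cy, cx)`` is the reference tilt in cycles per pixel
    (must stay below Nyquist, 0.5, and above the field bandwidth so the
    sidebands separate).  The reference is ``A exp(-i 2pi (cy y + cx x))``,
    which places the sideband carrying the field at +carrier in the
    hologram spectrum; :func:`classim.optics.demodulate_offaxis` inverts it.
    """
    field = np.asarray(field, dtype=complex)
    cy, cx = carrier_cycles
    if abs(cy) >= 0.5 or abs(cx) >= 0.5:
        raise ValueError("carrier must be below Nyquist (0.5 cycles/pixel)")
    h, w = field.shape
    y = np.arange(h)[:, None]
    x = np.arange(w)[None, :]
    ref = ref_amplitude * np.exp(-2j * np.pi * (cy * y + cx * x))
    return np.abs(field + ref) ** 2
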