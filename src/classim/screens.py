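"""Random phase screens and the speckle point-spread functions they produce.

A thin dynamic scatterer (rotating diffuser, flowing bead suspension) is
modelled as a random phase screen in the pupil plane.  The amplitude
point-spread function (APSF) of the system is the centred Fourier transform
of the pupil-masked screen transmission ``exp(i*phase)``; the incoherent
intensity PSF is its squared modulus.  For deep screens (RMS phase of a few
radians and up) the PSFs are fully developed speckle patterns, and screens
drawn with independent seeds give mutually uncorrelated PSF realizations —
the regime the covariance reconstruction relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fourier import cfft2

__all__ = [
    "PhaseScreen",
    "Pupil",
    "APSF",
    "IntensityPSF",
    "generate_phase_screen",
    "screen_to_apsf",
    "apsf_to_ipsf",
]


@dataclass(frozen=True)
class PhaseScreen:
    """A single realization of the scatterer's phase profile (radians).

    ``corr_len_px`` is the correlation length of the complex transmission
    ``exp(i*phase)`` — the quantity that sets the speckle-PSF envelope —
    not of the raw phase.  See :func:`generate_phase_screen`.
    """

    phase: np.ndarray
    corr_len_px: float
    rms_rad: float
    seed: int | None = None

    def __post_init__(self):
        if not np.all(np.isfinite(self.phase)):
            raise ValueError("phase screen contains non-finite values")

    @property
    def transmission(self) -> np.ndarray:
        return np.exp(1j * self.phase)


@dataclass(frozen=True)
class Pupil:
    """Binary circular aperture, centred on the zero-frequency sample.

    ``radius_frac`` is the aperture radius as a fraction of the Nyquist
    radius (half the grid); it sets the diffraction limit of the system.
    """

    shape: tuple[int, int]
    radius_frac: float = 1.0

    def __post_init__(self):
        if not 0 < self.radius_frac <= 1:
            raise ValueError("radius_frac must be in (0, 1]")

    @property
    def mask(self) -> np.ndarray:
        h, w = self.shape
        y = np.arange(h) - h // 2
        x = np.arange(w) - w // 2
        r2 = (y[:, None] / (h / 2)) ** 2 + (x[None, :] / (w / 2)) ** 2
        return (r2 <= self.radius_frac**2 + 1e-12).astype(float)


@dataclass(frozen=True)
class APSF:
    """Complex field amplitude PSF, normalised to unit total energy."""

    field: np.ndarray

    def __post_init__(self):
        if not np.all(np.isfinite(self.field)):
            raise ValueError("APSF contains non-finite values")
        e = float(np.sum(np.abs(self.field) ** 2))
        if not np.isclose(e, 1.0, rtol=1e-9):
            raise ValueError(f"APSF energy {e} != 1; normalise before wrapping")


@dataclass(frozen=True)
class IntensityPSF:
    """Real non-negative intensity PSF, normalised to unit sum."""

    psf: np.ndarray

    def __post_init__(self):
        if np.min(self.psf) < 0:
            raise ValueError("intensity PSF must be non-negative")
        s = float(np.sum(self.psf))
        if not np.isclose(s, 1.0, rtol=1e-9):
            raise ValueError(f"intensity PSF sum {s} != 1")


def _filtered_gaussian_field(
    shape: tuple[int, int], corr_len_px: float, rng: np.random.Generator
) -> np.ndarray:
    """Zero-mean unit-ish variance Gaussian field with Gaussian autocorrelation
    ``exp(-r^2 / corr_len_px^2)`` (1/e half-width ``corr_len_px``)."""
    white = rng.standard_normal(shape)
    fy = np.fft.fftfreq(shape[0])[:, None]
    fx = np.fft.fftfreq(shape[1])[None, :]
    # amplitude filter = sqrt of the target power spectrum exp(-(pi l f)^2)
    g = np.exp(-0.5 * (np.pi * corr_len_px) ** 2 * (fy**2 + fx**2))
    return np.fft.ifft2(np.fft.fft2(white) * g).real


def _rescale_phase(raw: np.ndarray, rms_rad: float) -> np.ndarray:
    raw = raw - raw.mean()
    std = raw.std()
    if rms_rad == 0 or std == 0:
        return np.zeros_like(raw)
    return raw * (rms_rad / std)


def generate_phase_screen(
    shape: tuple[int, int],
    corr_len_px: float,
    rms_rad: float,
    seed: int | np.random.Generator = 0,
) -> PhaseScreen:
    """Draw a Gaussian random phase screen.

    The screen is white Gaussian noise filtered by a Gaussian kernel in the
    Fourier domain and rescaled to the exact sample RMS ``rms_rad``.  The
    underlying phase correlation length is internally stretched by
    ``max(rms_rad, 1)`` so that the complex transmission ``exp(i*phase)``
    decorrelates over approximately ``corr_len_px`` pixels regardless of the
    screen depth — matching how diffuser correlation lengths are quoted and
    keeping the speckle-grain statistics independent of RMS.

    Deterministic: the same ``seed`` and parameters give a bit-identical
    screen.
    """
    h, w = int(shape[0]), int(shape[1])
    if h <= 0 or w <= 0:
        raise ValueError("screen dimensions must be positive")
    if h != w:
        raise ValueError("screen grid must be square")
    if corr_len_px < 1:
        raise ValueError("corr_len_px must be >= 1")
    if rms_rad < 0:
        raise ValueError("rms_rad must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ell = corr_len_px * max(rms_rad, 1.0)
    raw = _filtered_gaussian_field((h, w), ell, rng)
    phase = _rescale_phase(raw, rms_rad)
    return PhaseScreen(
        phase=phase,
        corr_len_px=corr_len_px,
        rms_rad=rms_rad,
        seed=seed if isinstance(seed, int) else None,
    )


def screen_to_apsf(screen: PhaseScreen, pupil: Pupil | None = None) -> APSF:
    """Amplitude PSF of a pupil-masked phase screen.

    ``APSF = cfft2(pupil * exp(i*phase))``, energy-normalised.  ``pupil=None``
    applies no aperture (full square stop): a flat screen then gives a
    single-pixel delta at the centre (the diffraction-limited system), and a
    phase-only screen gives a unitary transfer that conserves frame energy.
    """
    if pupil is None:
        mask = np.ones(screen.phase.shape)
    else:
        if pupil.shape != screen.phase.shape:
            raise ValueError(
                f"pupil grid {pupil.shape} does not match screen {screen.phase.shape}"
            )
        mask = pupil.mask
    field = cfft2(mask * screen.transmission)
    energy = np.sum(np.abs(field) ** 2)
    if energy == 0:
        raise ValueError("degenerate pupil: zero transmitted energy")
    return APSF(field=field / np.sqrt(energy))


def apsf_to_ipsf(apsf: APSF) -> IntensityPSF:
    """Intensity PSF ``|APSF|^2``, renormalised to unit sum."""
    p = np.abs(apsf.field) ** 2
    s = p.sum()
    if s == 0:
        raise ValueError("degenerate APSF: zero energy")
    return IntensityPSF(psf=p / s)
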