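"""Coherent-optics utilities: Fresnel propagation and off-axis demodulation.

Paraxial free-space propagation over a distance dz is applied in the
spatial-frequency domain through the Fresnel transfer function

    H(fx, fy; dz) = exp(i 2 pi dz / lambda) . exp(-i pi lambda dz (fx^2 + fy^2)),

a phase-only filter: propagation preserves energy exactly, is inverted by
flipping the sign of dz, and composes (H(dz1) H(dz2) = H(dz1 + dz2))
because the constant phase factor is retained.  Frequencies are in cycles
per micrometre on centred grids, consistent with the rest of the package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .fourier import cfft2, centered_freq_grid, icfft2

__all__ = [
    "PropagationConfig",
    "ComplexField",
    "fresnel_transfer",
    "fresnel_propagate",
    "demodulate_offaxis",
]

ALIASING_GUARD = 0.5  # warn when lambda |dz| / (N pitch^2) exceeds this


@dataclass(frozen=True)
class PropagationConfig:
    """Geometry of a propagation step.

    ``dz_um = z_obj - z_scatt``: positive dz propagates from the
    scattering-layer plane towards the object plane; negating dz inverts
    the step.
    """

    wavelength_um: float
    pitch_um: float
    dz_um: float
    shape: tuple[int, int]

    def __post_init__(self):
        if self.wavelength_um <= 0 or self.pitch_um <= 0:
            raise ValueError("wavelength and pitch must be positive")

    @property
    def freq_grids(self):
        """Centred (fy, fx) grids in cycles/um."""
        return centered_freq_grid(self.shape, d=self.pitch_um)


@dataclass(frozen=True)
class ComplexField:
    """A complex field sample with its plane label and pixel pitch."""

    field: np.ndarray
    pitch_um: float = 1.0
    plane: str = "scatt"  # "scatt" | "obj" | "camera"

    def __post_init__(self):
        if not np.all(np.isfinite(self.field)):
            raise ValueError("field contains non-finite values")

    @property
    def intensity(self) -> np.ndarray:
        return np.abs(self.field) ** 2


def fresnel_transfer(config: PropagationConfig) -> np.ndarray:
    """The Fresnel transfer function H on the centred frequency grid.

    Phase-only (|H| = 1 everywhere); H = 1 identically at dz = 0.
    """
    fy, fx = config.freq_grids
    lam, dz = config.wavelength_um, config.dz_um
    return np.exp(2j * np.pi * dz / lam) * np.exp(
        -1j * np.pi * lam * dz * (fx**2 + fy**2)
    )


def fresnel_propagate(field: ComplexField, config: PropagationConfig) -> ComplexField:
    """Propagate a field by dz: IFFT( FFT(E) . H ).

    Forward and backward propagation differ only in the sign of dz.  When
    the quadratic phase becomes badly sampled
    (lambda |dz| / (N pitch^2) > 0.5) a warning is emitted — the result is
    still returned, since smooth band-limited fields remain accurate well
    beyond the guard.
    """
    if field.field.shape != config.shape:
        raise ValueError("field grid does not match propagation config")
    if not np.isclose(field.pitch_um, config.pitch_um):
        raise ValueError("field pitch does not match propagation config")
    n = min(config.shape)
    ratio = config.wavelength_um * abs(config.dz_um) / (n * config.pitch_um**2)
    if ratio > ALIASING_GUARD:
        warnings.warn(
            f"Fresnel kernel badly sampled (lambda|dz|/(N pitch^2) = "
            f"{ratio:.2f} > {ALIASING_GUARD}); expect wrap-around artefacts",
            RuntimeWarning,
        )
    out = icfft2(cfft2(field.field.astype(complex)) * fresnel_transfer(config))
    if config.dz_um == 0:
        plane = field.plane
    else:
        plane = "obj" if config.dz_um > 0 else "scatt"
    return ComplexField(field=out, pitch_um=field.pitch_um, plane=plane)


def demodulate_offaxis(
    hologram: np.ndarray,
    carrier_cycles: tuple[float, float],
    crop_radius_frac: float = 0.25,
) -> np.ndarray:
    """Recover the complex field from an off-axis hologram.

    Fourier-transforms the hologram, crops a disk of radius
    ``crop_radius_frac`` (fraction of the Nyquist radius) around the
    sideband carrying the field, recentres it to zero frequency and
    inverse-transforms.  The result equals the original field up to a
    constant complex factor (the reference amplitude).  A warning is
    emitted when significant energy sits where the sideband and the DC
    autocorrelation term overlap.
    """
    holo = np.asarray(hologram, dtype=float)
    h, w = holo.shape
    cy, cx = carrier_cycles
    if abs(cy) >= 0.5 or abs(cx) >= 0.5:
        raise ValueError("carrier must be below Nyquist (0.5 cycles/pixel)")
    if not 0 < crop_radius_frac <= 0.5:
        raise ValueError("crop_radius_frac must be in (0, 0.5]")
    spec = cfft2(holo.astype(complex))
    sy = int(round(cy * h))  # sideband offset in samples from centre
    sx = int(round(cx * w))
    yy = np.arange(h)[:, None] - (h // 2 + sy)
    xx = np.arange(w)[None, :] - (w // 2 + sx)
    rad = crop_radius_frac * min(h, w) / 2
    disk = (yy**2 + xx**2) <= rad**2
    # overlap check: annulus midway between sideband and DC
    mid_y = np.arange(h)[:, None] - (h // 2 + sy / 2)
    mid_x = np.arange(w)[None, :] - (w // 2 + sx / 2)
    annulus = (mid_y**2 + mid_x**2) <= (rad / 2) ** 2
    e_ann = np.sum(np.abs(spec[annulus]) ** 2)
    e_side = np.sum(np.abs(spec[disk]) ** 2)
    if e_side > 0 and e_ann > 0.5 * e_side:
        warnings.warn(
            "off-axis sideband and DC term overlap; increase the carrier or "
            "reduce crop_radius_frac",
            RuntimeWarning,
        )
    side = np.where(disk, spec, 0)
    side = np.roll(side, shift=(-sy, -sx), axis=(0, 1))
    return icfft2(side)
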