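"""Centered FFT conventions shared across the package.

Every spatial and spatial-frequency grid in this package places the origin
at the centre sample ``(H // 2, W // 2)``.  :func:`cfft2` / :func:`icfft2`
wrap numpy's FFTs so that both domains stay centred, and circular
convolution implemented as a product of centred transforms is then exact:
convolving with a centred delta is the identity.

Transforms are unnormalised on the forward side (numpy convention), so
Parseval reads ``sum |X|^2 = H*W * sum |x|^2``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "cfft2",
    "icfft2",
    "circular_convolve",
    "centered_delta",
    "centered_freqs",
    "centered_freq_grid",
]

_AXES = (-2, -1)


def cfft2(x: np.ndarray, axes=_AXES) -> np.ndarray:
    """Centred 2-D DFT: origin at the centre sample in both domains."""
    return np.fft.fftshift(
        np.fft.fft2(np.fft.ifftshift(x, axes=axes), axes=axes), axes=axes
    )


def icfft2(x: np.ndarray, axes=_AXES) -> np.ndarray:
    """Inverse of :func:`cfft2`."""
    return np.fft.fftshift(
        np.fft.ifft2(np.fft.ifftshift(x, axes=axes), axes=axes), axes=axes
    )


def circular_convolve(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Circular (cyclic) convolution of two arrays on the same grid.

    Computed as a product of centred Fourier transforms; the convolution
    origin is the centre sample, so a centred delta kernel acts as the
    identity.  Broadcasts over leading axes.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape[-2:] != b.shape[-2:]:
        raise ValueError(f"grid mismatch: {a.shape[-2:]} vs {b.shape[-2:]}")
    out = icfft2(cfft2(a) * cfft2(b))
    if np.isrealobj(a) and np.isrealobj(b):
        return out.real
    return out


def centered_delta(shape: tuple[int, int], dtype=float) -> np.ndarray:
    """Unit impulse at the centre sample — the identity convolution kernel."""
    d = np.zeros(shape, dtype=dtype)
    d[shape[0] // 2, shape[1] // 2] = 1
    return d


def centered_freqs(n: int, d: float = 1.0) -> np.ndarray:
    """Centred frequency axis in cycles per unit of ``d`` (zero at ``n//2``)."""
    return np.fft.fftshift(np.fft.fftfreq(n, d=d))


def centered_freq_grid(shape: tuple[int, int], d: float = 1.0):
    """Centred 2-D frequency grids ``(fy, fx)`` in cycles per unit of ``d``."""
    fy = centered_freqs(shape[0], d)[:, None]
    fx = centered_freqs(shape[1], d)[None, :]
    return fy, fx
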