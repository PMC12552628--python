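"""Programmatic test targets (resolution-chart-like binary masks, bead fields).

These stand in for the physical targets imaged in scattering experiments:
bar charts (USAF-style three-bar groups), a Siemens spoke star, and sparse
fluorescent-bead fields.  All are generated on demand — no image files.
"""

from __future__ import annotations

import numpy as np

__all__ = ["bars_target", "spokes_target", "beads_target", "make_object"]


def bars_target(n: int = 64) -> np.ndarray:
    """Binary three-bar groups at two orientations plus a square landmark."""
    img = np.zeros((n, n))
    bw = max(n // 16, 2)  # bar width
    gap = bw
    # horizontal triplet, upper-left
    y0, x0 = n // 8, n // 8
    for i in range(3):
        y = y0 + i * (bw + gap)
        img[y : y + bw, x0 : x0 + 5 * bw] = 1.0
    # vertical triplet, lower-right
    y1, x1 = n // 2, n // 2 + n // 8
    for i in range(3):
        x = x1 + i * (bw + gap)
        img[y1 : y1 + 5 * bw, x : x + bw] = 1.0
    # asymmetric landmark (breaks point symmetry)
    img[n // 8 : n // 8 + 2 * bw, n - n // 4 : n - n // 4 + 2 * bw] = 1.0
    return img


def spokes_target(n: int = 64, n_spokes: int = 8, r_frac: float = 0.42) -> np.ndarray:
    """Siemens-star-like spoke pattern (binary)."""
    y = np.arange(n) - n // 2
    x = np.arange(n) - n // 2
    yy, xx = np.meshgrid(y, x, indexing="ij")
    theta = np.arctan2(yy, xx)
    r = np.hypot(yy, xx)
    img = ((np.cos(n_spokes * theta) > 0) & (r < r_frac * n) & (r > 2)).astype(float)
    return img


def beads_target(
    n: int = 64, n_beads: int = 12, radius: float = 2.0, seed: int = 0
) -> np.ndarray:
    """Sparse field of disk 'beads' (fluorescence-microscopy analogue)."""
    rng = np.random.default_rng(seed)
    img = np.zeros((n, n))
    y = np.arange(n)[:, None]
    x = np.arange(n)[None, :]
    lo, hi = int(0.15 * n), int(0.85 * n)
    for _ in range(n_beads):
        cy, cx = rng.integers(lo, hi, size=2)
        img[(y - cy) ** 2 + (x - cx) ** 2 <= radius**2] = 1.0
    return img


def make_object(name: str, n: int = 64, seed: int = 0) -> np.ndarray:
    """Look up a named target generator."""
    if name == "bars":
        return bars_target(n)
    if name == "spokes":
        return spokes_target(n)
    if name == "beads":
        return beads_target(n, seed=seed)
    raise ValueError(f"unknown object {name!r}; choose bars, spokes or beads")
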