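"""Level-1 2D Haar decomposition and the LL-sub-band energy texture.

The discrete Haar filter bank in the orthonormal convention is
``low = (1/sqrt(2), 1/sqrt(2))``, ``high = (1/sqrt(2), -1/sqrt(2))``.
Applied separably along rows and columns and downsampled by 2, a 2x2
block ``(a, b; c, d)`` maps to

    LL = (a + b + c + d) / 2      (approximation)
    LH = (a - b + c - d) / 2      (vertical detail: high-pass columns)
    HL = (a + b - c - d) / 2      (horizontal detail: high-pass rows)
    HH = (a - b - c + d) / 2      (diagonal detail)

Under this convention the transform is orthogonal: reconstruction is
exact and the sum of squares over the four sub-bands equals the sum of
squares of the (even-cropped) input, so the "energy" texture is energy
in the literal Parseval sense. An unnormalized averaging convention
(``LL`` = block mean) is exposed for sensitivity checks; Parseval does
not hold there.

Odd trailing rows/columns are cropped before the transform. The energy
texture is a 3x3 sliding mean of squared LL coefficients with symmetric
edge padding, so the output keeps LL resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError, RoiError
from .raster_io import PlotROI

__all__ = [
    "HaarFilterBank",
    "WaveletDecomposition",
    "EnergyImage",
    "haar_decompose",
    "reconstruct",
    "energy_texture",
    "plot_energy",
]

_NORM_SCALE = {"orthonormal": 0.5, "average": 0.25}


@dataclass(frozen=True)
class HaarFilterBank:
    """1D analysis filters of the discrete Haar wavelet."""

    normalization: str = "orthonormal"

    def __post_init__(self) -> None:
        if self.normalization not in _NORM_SCALE:
            raise InputError(
                f"unknown normalization {self.normalization!r}; "
                f"choose from {sorted(_NORM_SCALE)}"
            )

    @property
    def low(self) -> np.ndarray:
        c = np.sqrt(0.5) if self.normalization == "orthonormal" else 0.5
        return np.array([c, c])

    @property
    def high(self) -> np.ndarray:
        c = np.sqrt(0.5) if self.normalization == "orthonormal" else 0.5
        return np.array([c, -c])


@dataclass
class WaveletDecomposition:
    """The four level-1 sub-band images of one band."""

    ll: np.ndarray
    lh: np.ndarray
    hl: np.ndarray
    hh: np.ndarray
    wavelength: int | None = None
    normalization: str = "orthonormal"

    def __post_init__(self) -> None:
        shapes = {self.ll.shape, self.lh.shape, self.hl.shape, self.hh.shape}
        if len(shapes) != 1:
            raise InputError(f"sub-band shapes differ: {shapes}")


def haar_decompose(
    band_image: np.ndarray,
    wavelength: int | None = None,
    normalization: str = "orthonormal",
) -> WaveletDecomposition:
    """Single-level 2D Haar transform of an ``H x W`` image.

    Trailing odd row/column are cropped; sub-bands have shape
    ``floor(H/2) x floor(W/2)``. Requires ``H >= 2`` and ``W >= 2``.
    """
    if normalization not in _NORM_SCALE:
        raise InputError(f"unknown normalization {normalization!r}")
    x = np.asarray(band_image, dtype=np.float64)
    if x.ndim != 2:
        raise InputError(f"expected a 2D image, got shape {x.shape}")
    h, w = x.shape
    if h < 2 or w < 2:
        raise InputError(f"image must be at least 2x2, got {h}x{w}")
    x = x[: h - h % 2, : w - w % 2]
    a = x[0::2, 0::2]
    b = x[0::2, 1::2]
    c = x[1::2, 0::2]
    d = x[1::2, 1::2]
    s = _NORM_SCALE[normalization]
    return WaveletDecomposition(
        ll=(a + b + c + d) * s,
        lh=(a - b + c - d) * s,
        hl=(a + b - c - d) * s,
        hh=(a - b - c + d) * s,
        wavelength=wavelength,
        normalization=normalization,
    )


def reconstruct(decomp: WaveletDecomposition) -> np.ndarray:
    """Inverse level-1 transform; exact up to floating-point rounding."""
    s = _NORM_SCALE[decomp.normalization]
    ll, lh, hl, hh = decomp.ll, decomp.lh, decomp.hl, decomp.hh
    hs, ws = ll.shape
    out = np.empty((2 * hs, 2 * ws), dtype=np.float64)
    inv = 1.0 / (4.0 * s)
    out[0::2, 0::2] = (ll + lh + hl + hh) * inv
    out[0::2, 1::2] = (ll - lh + hl - hh) * inv
    out[1::2, 0::2] = (ll + lh - hl - hh) * inv
    out[1::2, 1::2] = (ll - lh - hl + hh) * inv
    return out


@dataclass
class EnergyImage:
    """3x3 windowed mean of squared LL coefficients, at LL resolution."""

    values: np.ndarray
    wavelength: int | None = None
    window: int = 3


def energy_texture(decomp: WaveletDecomposition) -> EnergyImage:
    """Energy texture of the LL sub-band.

    Each output pixel is the mean of the nine squared LL coefficients in
    its 3x3 neighborhood; borders use symmetric (edge-repeating reflect)
    padding so the output has LL shape. LL must be at least 3x3.
    """
    ll = decomp.ll
    h, w = ll.shape
    if h < 3 or w < 3:
        raise InputError(f"LL sub-band must be at least 3x3, got {h}x{w}")
    sq = np.pad(ll * ll, 1, mode="symmetric")
    acc = np.zeros((h, w), dtype=np.float64)
    for di in range(3):
        for dj in range(3):
            acc += sq[di : di + h, dj : dj + w]
    return EnergyImage(values=acc / 9.0, wavelength=decomp.wavelength)


def plot_energy(energy: EnergyImage, roi: PlotROI) -> float:
    """Plot-level Ene: mean of the energy image over the ROI.

    The full-resolution ROI is mapped to LL resolution by integer
    halving (floor) of all four bounds; it must stay non-empty.
    """
    r0, c0 = roi.row_min // 2, roi.col_min // 2
    r1, c1 = roi.row_max // 2, roi.col_max // 2
    if r1 <= r0 or c1 <= c0:
        raise RoiError(
            f"ROI {roi.plot_id!r} collapses to zero pixels at LL resolution"
        )
    h, w = energy.values.shape
    if r1 > h or c1 > w:
        raise RoiError(f"ROI {roi.plot_id!r} exceeds energy image {h}x{w}")
    return float(energy.values[r0:r1, c0:c1].mean())
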