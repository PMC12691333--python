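"""Image filter bank: Laplacian-of-Gaussian at physical scales and one-level
3D separable wavelet decomposition.

LoG responses are computed in physical units: per-axis Gaussian second
derivatives with sigma converted from mm to voxels and each term divided by
the squared axis spacing, summed over axes.  Wavelet subbands follow the
(z, y, x) letter convention: subband ``LHH`` applies the low-pass filter
along z and the high-pass filter along y and x.  The default transform is
undecimated (stationary) with symmetric boundary padding; an orthonormal
decimated mode (via PyWavelets ``dwtn``) is available for energy-conservation
checks.
"""

from __future__ import annotations

import warnings
from itertools import product

import numpy as np
import pywt
from scipy import ndimage

from ..io import VolumeImage

__all__ = ["log_filter", "wavelet_decompose", "WAVELET_SUBBANDS"]

WAVELET_SUBBANDS = tuple(
    "".join(b) for b in product("LH", repeat=3)
)  # LLL, LLH, ..., HHH


def log_filter(image: VolumeImage, sigma_mm: float) -> VolumeImage:
    """Laplacian-of-Gaussian response at physical scale ``sigma_mm``.

    Computed as the sum over axes of the Gaussian second derivative along
    that axis, with spacing-aware sigma and derivative scaling, so the result
    approximates d2/dz2 + d2/dy2 + d2/dx2 of the sigma-smoothed image in
    1/mm^2 units.
    """
    if sigma_mm <= 0:
        raise ValueError("sigma_mm must be positive")
    spacing = np.asarray(image.spacing, dtype=float)
    if sigma_mm < spacing.min() / 2:
        warnings.warn(
            f"LoG sigma {sigma_mm} mm is below half the voxel spacing "
            f"{tuple(spacing)}; the response is dominated by discretization",
            stacklevel=2,
        )
    sigma_vox = sigma_mm / spacing
    out = np.zeros_like(image.values)
    for axis in range(3):
        order = [0, 0, 0]
        order[axis] = 2
        # truncate high enough that the derivative kernel sums to ~0 and a
        # constant image maps to (numerically) zero response
        out += ndimage.gaussian_filter(
            image.values, sigma=sigma_vox, order=order, mode="reflect",
            truncate=8.0,
        ) / spacing[axis] ** 2
    return VolumeImage(out, image.spacing, image.origin, image.direction)


def _convolve_axis(values: np.ndarray, taps: np.ndarray, axis: int) -> np.ndarray:
    # true convolution (kernel flipped), symmetric half-sample padding;
    # origin chosen so even-length kernels center like np.convolve "same"
    origin = -1 if len(taps) % 2 == 0 else 0
    return ndimage.convolve1d(values, taps, axis=axis, mode="reflect",
                              origin=origin)


def wavelet_decompose(
    image: VolumeImage | np.ndarray,
    wavelet: str = "coif1",
    decimated: bool = False,
) -> dict[str, np.ndarray]:
    """One-level 3D separable wavelet transform into 8 subbands.

    Returns ``{"LLL": array, ..., "HHH": array}``; letter i of the subband
    name selects the low/high-pass filter applied along array axis i, i.e.
    (z, y, x) order.  The default is the undecimated (stationary) transform:
    each axis is convolved with the wavelet's decomposition filters under
    symmetric padding, so every subband has the input's shape.  With
    ``decimated=True`` the standard downsampled DWT (PyWavelets ``dwtn``) is
    used instead; with an orthonormal wavelet its subband energies sum to the
    input energy.
    """
    values = image.values if isinstance(image, VolumeImage) else np.asarray(image)
    if values.ndim != 3 or min(values.shape) < 2:
        raise ValueError("need a 3D volume with every axis >= 2")

    if decimated:
        coeffs = pywt.dwtn(values, wavelet, mode="symmetric")
        return {
            key.upper().replace("A", "L").replace("D", "H"): arr
            for key, arr in coeffs.items()
        }

    w = pywt.Wavelet(wavelet)
    lo = np.asarray(w.dec_lo, dtype=np.float64)
    hi = np.asarray(w.dec_hi, dtype=np.float64)
    bank = {"L": lo, "H": hi}
    out: dict[str, np.ndarray] = {}
    # Share the axis-0 pass across the 4 subbands that reuse it, etc.
    for l0 in "LH":
        pass0 = _convolve_axis(values, bank[l0], axis=0)
        for l1 in "LH":
            pass1 = _convolve_axis(pass0, bank[l1], axis=1)
            for l2 in "LH":
                out[l0 + l1 + l2] = _convolve_axis(pass1, bank[l2], axis=2)
    return out
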