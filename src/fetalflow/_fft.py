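"""Centered, orthonormal FFT helpers shared by the simulator and reconstruction.

Conventions used throughout the package:

* image axes are ``(x, y, z)`` with the readout direction along ``x``;
* k-space index ``m`` on an axis of length ``N`` corresponds to the discrete
  frequency ``m - N // 2`` (DC at the center after ``fftshift``);
* all transforms are orthonormal (``norm="ortho"``) so that the sensing
  operator built on them has unit spectral norm for a fully sampled,
  single-visit pattern.
"""

from __future__ import annotations

import numpy as np
from scipy import fft as spfft


def cfftn(x: np.ndarray, axes=(-3, -2, -1)) -> np.ndarray:
    """Centered orthonormal n-dimensional FFT over ``axes``."""
    return spfft.fftshift(
        spfft.fftn(spfft.ifftshift(x, axes=axes), axes=axes, norm="ortho"),
        axes=axes,
    )


def cifftn(k: np.ndarray, axes=(-3, -2, -1)) -> np.ndarray:
    """Inverse of :func:`cfftn`."""
    return spfft.fftshift(
        spfft.ifftn(spfft.ifftshift(k, axes=axes), axes=axes, norm="ortho"),
        axes=axes,
    )


def shift_phase_ramp(shape, shift_voxels) -> np.ndarray:
    """k-space phase ramp implementing a circular image shift.

    Multiplying the centered k-space of an image by this ramp shifts the image
    content by ``shift_voxels`` (in voxels, one entry per axis): the shifted
    image is ``img(r - d)``, i.e. content moves toward increasing index for
    positive ``d``.
    """
    shift_voxels = np.asarray(shift_voxels, dtype=float)
    ramp = np.ones(shape, dtype=complex)
    for ax, (n, d) in enumerate(zip(shape, shift_voxels)):
        freq = np.arange(n) - n // 2
        ax_ramp = np.exp(-2j * np.pi * freq * d / n)
        sl = [None] * len(shape)
        sl[ax] = slice(None)
        ramp = ramp * ax_ramp[tuple(sl)]
    return ramp
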