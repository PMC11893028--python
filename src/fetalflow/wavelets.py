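"""Undecimated (shift-invariant) 4D wavelet transform over 3D space + cardiac time.

Built on PyWavelets' stationary wavelet transform in its energy-preserving
(``norm=True``) mode, which makes the composed transform a Parseval tight
frame: ``inverse(forward(x)) == x`` to machine precision and coefficient
energy equals image energy. The spatial axes get a 2-level transform and the
cardiac axis a 1-level transform with circular (periodic) boundary handling,
which is the natural choice for a cyclic cardiac dimension.
"""

from __future__ import annotations

import warnings
from typing import List

import numpy as np
import pywt


class UndecimatedWavelet4D:
    """Separable undecimated wavelet transform for stacks ``(T, ..., x, y, z)``.

    ``spatial_axes`` are transformed with ``spatial_levels`` levels and
    ``time_axis`` with ``temporal_levels`` levels; any other axes are carried
    along as batch dimensions (the four velocity-encoding segments travel as
    such a channel axis). Coefficients are returned as a flat list of arrays,
    each the size of the input (undecimated).
    """

    def __init__(
        self,
        wavelet: str = "db2",
        spatial_levels: int = 2,
        temporal_levels: int = 1,
        spatial_axes=(-3, -2, -1),
        time_axis: int = 0,
    ):
        self.wavelet = wavelet
        self.spatial_levels = spatial_levels
        self.temporal_levels = temporal_levels
        self.spatial_axes = tuple(spatial_axes)
        self.time_axis = time_axis
        self._struct1 = None
        self._struct2 = None
        self._do_time = True

    # -- structure bookkeeping ------------------------------------------------
    def _check(self, x):
        t_len = x.shape[self.time_axis]
        do_time = self.temporal_levels > 0
        if do_time and (t_len < 2 or t_len % (2**self.temporal_levels)):
            warnings.warn(
                "temporal axis not transformable "
                f"(length {t_len}); temporal wavelet stage skipped"
            )
            do_time = False
        for ax in self.spatial_axes:
            if x.shape[ax] % (2**self.spatial_levels):
                raise ValueError(
                    "spatial sizes must be divisible by "
                    f"2^{self.spatial_levels} for the undecimated transform"
                )
        self._do_time = do_time

    @staticmethod
    def _flatten(coeffs):
        """pywt trim_approx nested list -> (flat arrays, structure template)."""
        arrays = [coeffs[0]]
        struct = [None]
        for li, d in enumerate(coeffs[1:]):
            for key in sorted(d):
                arrays.append(d[key])
                struct.append((li, key))
        return arrays, struct

    def _rebuild(self, arrays, struct, n_levels):
        out = [arrays[0]]
        dicts = [dict() for _ in range(n_levels)]
        for arr, tag in zip(arrays[1:], struct[1:]):
            li, key = tag
            dicts[li][key] = arr
        out.extend(dicts)
        return out

    # -- public API -----------------------------------------------------------
    def forward(self, x: np.ndarray) -> List[np.ndarray]:
        self._check(x)
        c1 = pywt.swtn(
            x, self.wavelet, level=self.spatial_levels, axes=self.spatial_axes,
            trim_approx=True, norm=True,
        )
        arrays1, self._struct1 = self._flatten(c1)
        if not self._do_time:
            return arrays1
        out = []
        for arr in arrays1:
            c2 = pywt.swtn(
                arr, self.wavelet, level=self.temporal_levels,
                axes=(self.time_axis,), trim_approx=True, norm=True,
            )
            arrays2, self._struct2 = self._flatten(c2)
            out.extend(arrays2)
        return out

    def inverse(self, coeffs: List[np.ndarray]) -> np.ndarray:
        if self._struct1 is None:
            raise RuntimeError("call forward() once before inverse()")
        if self._do_time:
            per = len(self._struct2)
            arrays1 = []
            for i in range(0, len(coeffs), per):
                nested = self._rebuild(coeffs[i : i + per], self._struct2,
                                       self.temporal_levels)
                arrays1.append(
                    pywt.iswtn(nested, self.wavelet, axes=(self.time_axis,),
                               norm=True)
                )
        else:
            arrays1 = coeffs
        nested = self._rebuild(arrays1, self._struct1, self.spatial_levels)
        return pywt.iswtn(nested, self.wavelet, axes=self.spatial_axes, norm=True)

    # -- helpers used by the solvers -----------------------------------------
    @staticmethod
    def l1_norm(coeffs: List[np.ndarray]) -> float:
        return float(sum(np.abs(c).sum() for c in coeffs))

    @staticmethod
    def soft_threshold(coeffs: List[np.ndarray], tau: float) -> List[np.ndarray]:
        out = []
        for c in coeffs:
            mag = np.abs(c)
            scale = np.maximum(mag - tau, 0.0) / np.maximum(mag, 1e-30)
            out.append(c * scale)
        return out
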