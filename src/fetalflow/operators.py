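"""Linear sensing operator mapping image stacks to per-readout k-space lines.

The forward model is: per-coil sensitivity weighting, centered orthonormal 3D
FFT, and extraction of the fully sampled kx line at each readout's
``(ky, kz)`` for the readout's (bin-or-frame, encoding-segment) image. The
adjoint is the exact conjugate transpose (scatter-add of lines, inverse FFT,
conjugate-sensitivity combination). Because the FFT is orthonormal and the
coil sensitivities are sum-of-squares normalized, the operator's squared
spectral norm is bounded by the maximum number of times any single
(bin, segment, ky, kz) line is visited — used as the Lipschitz constant in
the proximal-gradient solvers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

from ._fft import cfftn, cifftn
from .sampling import BinAssignment, KSpaceData


@dataclass
class SensingOperator:
    matrix_size: tuple
    coil_sens: np.ndarray  # (n_coils, nx, ny, nz)
    t_index: np.ndarray  # per-readout bin-or-frame index
    segment: np.ndarray
    ky: np.ndarray
    kz: np.ndarray
    n_t: int
    n_seg: int = 4

    def __post_init__(self):
        nx, ny, nz = self.matrix_size
        if self.ky.min() < 0 or self.ky.max() >= ny or self.kz.min() < 0 or self.kz.max() >= nz:
            raise ValueError("sampling pattern index out of range")
        self.n_readouts = self.t_index.size
        self.n_coils = self.coil_sens.shape[0]
        flat = ((self.t_index * self.n_seg + self.segment) * ny + self.ky) * nz + self.kz
        self._flat = flat.astype(np.int64)
        n_lines = self.n_t * self.n_seg * ny * nz
        self._scatter = sparse.csr_matrix(
            (np.ones(self.n_readouts), (self._flat, np.arange(self.n_readouts))),
            shape=(n_lines, self.n_readouts),
        )
        self.counts = np.bincount(self._flat, minlength=n_lines)
        self.max_visits = int(self.counts.max()) if self.n_readouts else 0

    @property
    def x_shape(self):
        return (self.n_t, self.n_seg) + tuple(self.matrix_size)

    @property
    def y_shape(self):
        return (self.n_readouts, self.matrix_size[0], self.n_coils)

    def forward(self, x: np.ndarray) -> np.ndarray:
        """(n_t, n_seg, nx, ny, nz) -> (n_readouts, nx, n_coils)."""
        k = cfftn(self.coil_sens[None, None] * x[:, :, None], axes=(-3, -2, -1))
        lines = k[self.t_index, self.segment, :, :, self.ky, self.kz]
        return np.ascontiguousarray(np.swapaxes(lines, 1, 2))

    def adjoint(self, y: np.ndarray) -> np.ndarray:
        """(n_readouts, nx, n_coils) -> (n_t, n_seg, nx, ny, nz)."""
        nx, ny, nz = self.matrix_size
        yv = np.swapaxes(y, 1, 2).reshape(self.n_readouts, self.n_coils * nx)
        grid = self._scatter @ yv  # (n_lines, n_coils * nx)
        k = grid.reshape(self.n_t, self.n_seg, ny, nz, self.n_coils, nx)
        k = np.ascontiguousarray(np.transpose(k, (0, 1, 4, 5, 2, 3)))
        img = cifftn(k, axes=(-3, -2, -1))
        return np.sum(np.conj(self.coil_sens)[None, None] * img, axis=2)

    def adjoint_dc(self, y: np.ndarray) -> np.ndarray:
        """Density-compensated adjoint (zero-filled recon with visit averaging)."""
        w = 1.0 / np.maximum(self.counts[self._flat], 1)
        return self.adjoint(y * w[:, None, None])

    @property
    def lipschitz(self) -> float:
        """Upper bound on the spectral norm of A^H A."""
        return float(max(self.max_visits, 1))


def build_operator(kspace: KSpaceData, labels: np.ndarray):
    """Operator + measurement vector for readouts with a nonnegative label.

    ``labels`` is a per-readout bin index (cardiac frame or motion bin);
    readouts labeled ``-1`` are excluded. Returns ``(op, y, selected_idx)``.
    """
    labels = np.asarray(labels)
    sel = np.flatnonzero(labels >= 0)
    if sel.size == 0:
        raise ValueError("no readouts selected for reconstruction")
    n_t = int(labels[sel].max()) + 1
    op = SensingOperator(
        matrix_size=tuple(kspace.matrix_size),
        coil_sens=kspace.coil_sens,
        t_index=labels[sel],
        segment=kspace.segment[sel],
        ky=kspace.ky[sel],
        kz=kspace.kz[sel],
        n_t=n_t,
    )
    return op, kspace.samples[sel], sel


def labels_from_assignment(assignment: BinAssignment, dim: str) -> np.ndarray:
    if dim == "cardiac":
        if assignment.cardiac_frame is None:
            raise ValueError("assignment has no cardiac frames")
        return assignment.cardiac_frame
    if dim == "motion_bin":
        if assignment.motion_bin is None:
            raise ValueError("assignment has no motion bins")
        return assignment.motion_bin
    raise ValueError("dim must be 'cardiac' or 'motion_bin'")
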