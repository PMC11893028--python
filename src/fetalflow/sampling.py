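"""Phase-encode scheduling and retrospective binning.

This module owns the acquisition bookkeeping shared by the simulator and the
reconstruction: the pseudo-spiral Cartesian phase-encode schedule, the raw
k-space record (:class:`KSpaceData`), and the three retrospective binning
steps — respiratory gating toward the expiration plateau, cardiac binning
driven by Doppler-ultrasound trigger times, and chronological bulk-motion
binning.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

log = logging.getLogger(__name__)

GOLDEN_FRACTION = 2.0 / (1.0 + np.sqrt(5.0))  # golden-angle fraction of a turn

#: Hadamard sign matrix for four-point velocity encoding. Row = encoding
#: segment, column = velocity component (x, y, z). The velocity-induced phase
#: of segment ``i`` is ``phi0 + (pi / (2 venc)) * sum_j S[i, j] v_j``.
HADAMARD_SIGNS = np.array(
    [[-1, -1, -1], [+1, +1, -1], [+1, -1, +1], [-1, +1, +1]], dtype=float
)


@dataclass
class Trajectory:
    """Ordered phase-encode schedule on the Cartesian (ky, kz) grid."""

    ky: np.ndarray  # (n_readouts,) int
    kz: np.ndarray  # (n_readouts,) int
    segment: np.ndarray  # (n_readouts,) int in {0..3}
    time: np.ndarray  # (n_readouts,) s, strictly increasing
    matrix_size: tuple
    target_acceleration: float
    n_interleaves: int = 1

    def __post_init__(self):
        _, ny, nz = self.matrix_size
        if self.ky.min() < 0 or self.ky.max() >= ny:
            raise ValueError("ky index out of bounds")
        if self.kz.min() < 0 or self.kz.max() >= nz:
            raise ValueError("kz index out of bounds")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("scheduled times must be strictly increasing")

    @property
    def n_readouts(self) -> int:
        return self.ky.size

    def unique_fraction(self) -> float:
        """Fraction of the (ky, kz) grid visited at least once."""
        _, ny, nz = self.matrix_size
        flat = self.ky.astype(np.int64) * nz + self.kz
        return np.unique(flat).size / float(ny * nz)


@dataclass
class KSpaceData:
    """Raw multi-coil k-space with per-readout metadata.

    ``samples`` has shape ``(n_readouts, nx, n_coils)``; one readout is a
    fully sampled kx line at fixed ``(ky, kz, segment)``, which is also the
    granularity of outlier rejection and motion bookkeeping.
    """

    samples: np.ndarray
    time: np.ndarray
    ky: np.ndarray
    kz: np.ndarray
    segment: np.ndarray
    resp: Optional[np.ndarray]
    matrix_size: tuple
    voxel_size: tuple
    venc: float
    n_frames: int
    trigger_times: np.ndarray
    coil_sens: np.ndarray  # (n_coils, nx, ny, nz)
    truth: dict = field(default_factory=dict)
    gated_efficiency: Optional[float] = None

    def __post_init__(self):
        n = self.samples.shape[0]
        for name in ("time", "ky", "kz", "segment"):
            if getattr(self, name).shape[0] != n:
                raise ValueError(f"metadata '{name}' length != number of readouts")
        if self.resp is not None and self.resp.shape[0] != n:
            raise ValueError("respiratory signal length != number of readouts")
        if self.venc <= 0:
            raise ValueError("venc must be positive")

    @property
    def n_readouts(self) -> int:
        return self.samples.shape[0]

    @property
    def n_coils(self) -> int:
        return self.samples.shape[2]

    def subset(self, idx: np.ndarray) -> "KSpaceData":
        """Return a copy restricted to the given readout indices (in order)."""
        truth = dict(self.truth)
        for key in ("shift_mm", "frame", "outlier_mask"):
            if key in truth and np.asarray(truth[key]).shape[:1] == (self.n_readouts,):
                truth[key] = np.asarray(truth[key])[idx]
        return replace(
            self,
            samples=self.samples[idx],
            time=self.time[idx],
            ky=self.ky[idx],
            kz=self.kz[idx],
            segment=self.segment[idx],
            resp=None if self.resp is None else self.resp[idx],
            truth=truth,
        )


@dataclass
class BinAssignment:
    """Per-readout bin labels; ``-1`` marks a rejected readout."""

    cardiac_frame: Optional[np.ndarray] = None
    motion_bin: Optional[np.ndarray] = None
    resp_accept: Optional[np.ndarray] = None

    def merged(self, other: "BinAssignment") -> "BinAssignment":
        return BinAssignment(
            cardiac_frame=self.cardiac_frame if other.cardiac_frame is None else other.cardiac_frame,
            motion_bin=self.motion_bin if other.motion_bin is None else other.motion_bin,
            resp_accept=self.resp_accept if other.resp_accept is None else other.resp_accept,
        )


def _spiral_arm(m, n_steps, ny, nz, turns=3.0, density_power=2.0):
    """Grid points of one outward spiral arm (deduplicated, ordered)."""
    t = np.linspace(0.0, 1.0, n_steps)
    rho = t ** density_power
    phi = 2 * np.pi * (GOLDEN_FRACTION * m + turns * t)
    y = np.clip(np.round(ny / 2 + rho * (ny / 2 - 0.5) * np.cos(phi)), 0, ny - 1)
    z = np.clip(np.round(nz / 2 + rho * (nz / 2 - 0.5) * np.sin(phi)), 0, nz - 1)
    pts = np.stack([y, z], axis=1).astype(int)
    _, first = np.unique(pts[:, 0] * nz + pts[:, 1], return_index=True)
    return pts[np.sort(first)]


def generate_pseudo_spiral_trajectory(
    matrix_size,
    r: float = 4.0,
    n_interleaves: int = 13,
    tr: float = 0.003,
    duration: Optional[float] = None,
) -> Trajectory:
    """Pseudo-spiral Cartesian phase-encode schedule.

    Points lie on the (ky, kz) grid, ordered along outward spiral arms from
    the k-space center; successive interleaves are rotated by the golden
    angle, giving a variable-density pattern with an oversampled center. The
    four Hadamard velocity-encoding segments are interleaved per point
    (segment-innermost). The master point set has ``~ny*nz/r`` distinct
    points; the schedule cycles over the interleaves until ``duration`` is
    filled (one full pass when ``duration`` is None), so that with long scans
    every cardiac frame approaches the master set's undersampling factor
    ``r``.
    """
    _, ny, nz = matrix_size
    if r < 1:
        raise ValueError("acceleration r must be >= 1")
    if ny < 8 or nz < 8:
        raise ValueError("phase-encode matrix must be at least 8x8")

    if r == 1.0:
        # Full sampling: one center-out pass over every grid point.
        yy, zz = np.meshgrid(np.arange(ny), np.arange(nz), indexing="ij")
        ry = yy - ny / 2
        rz = zz - nz / 2
        order = np.lexsort((np.arctan2(rz, ry).ravel(), np.hypot(ry, rz).ravel()))
        arms = [np.stack([yy.ravel()[order], zz.ravel()[order]], axis=1)]
    else:
        target = int(round(ny * nz / r))
        lo, hi = 2, 8 * ny * nz // n_interleaves

        def unique_count(n_steps):
            seen = set()
            for m in range(n_interleaves):
                for p in _spiral_arm(m, n_steps, ny, nz):
                    seen.add((p[0], p[1]))
            return len(seen)

        while hi - lo > 1:
            mid = (lo + hi) // 2
            if unique_count(mid) < target:
                lo = mid
            else:
                hi = mid
        n_steps = hi
        arms = [_spiral_arm(m, n_steps, ny, nz) for m in range(n_interleaves)]
        if min(len(a) for a in arms) < 8:
            raise ValueError(
                "acceleration too high for this grid: fewer than 8 points per interleave"
            )

    # Master sequence: arms in order, 4 encoding segments per point.
    pts = np.concatenate(arms, axis=0)
    master_ky = np.repeat(pts[:, 0], 4)
    master_kz = np.repeat(pts[:, 1], 4)
    master_seg = np.tile(np.arange(4), pts.shape[0])

    n_master = master_ky.size
    if duration is None:
        n_total = n_master
    else:
        n_total = max(4, int(np.floor(duration / tr)))
    reps = int(np.ceil(n_total / n_master))
    idx = np.tile(np.arange(n_master), reps)[:n_total]
    return Trajectory(
        ky=master_ky[idx],
        kz=master_kz[idx],
        segment=master_seg[idx],
        time=np.arange(n_total) * tr,
        matrix_size=tuple(matrix_size),
        target_acceleration=float(r),
        n_interleaves=n_interleaves,
    )


def respiratory_gate(
    kspace: KSpaceData,
    efficiency: float = 0.6,
    plateau_percentile: float = 5.0,
    polarity: str = "low",
) -> KSpaceData:
    """Retain the fraction of readouts nearest the expiration plateau.

    The plateau is operationalized as the ``plateau_percentile`` level of the
    respiratory signal (belt convention: expiration = low signal; set
    ``polarity="high"`` for the opposite convention). Exactly
    ``round(efficiency * n)`` readouts with signal closest to that level are
    retained, ties broken by earlier acquisition time, chronological order
    preserved. Without a respiratory signal the data passes through
    unchanged with a warning.
    """
    if not 0 < efficiency <= 1:
        raise ValueError("efficiency must be in (0, 1]")
    if kspace.resp is None:
        warnings.warn("no respiratory signal available; gating skipped")
        log.warning("respiratory_gate: no signal, passing data through")
        return kspace
    if kspace.gated_efficiency is not None and kspace.gated_efficiency == efficiency:
        return kspace
    resp = kspace.resp
    pct = plateau_percentile if polarity == "low" else 100.0 - plateau_percentile
    plateau = np.percentile(resp, pct)
    dist = np.abs(resp - plateau)
    n_keep = int(round(efficiency * kspace.n_readouts))
    order = np.lexsort((kspace.time, dist))
    keep = np.sort(order[:n_keep])
    out = kspace.subset(keep)
    out.gated_efficiency = efficiency
    log.info(
        "respiratory gating retained %d/%d readouts (%.0f%%)",
        n_keep, kspace.n_readouts, 100.0 * n_keep / kspace.n_readouts,
    )
    return out


def cardiac_frame_of(time, trigger_times, n_frames):
    """Vectorized cardiac binning rule; returns (frame, valid).

    ``frame = floor(n_frames * (t - T_k) / (T_{k+1} - T_k))`` for the
    enclosing trigger pair, clamped to ``n_frames - 1`` at the upper limit.
    ``valid`` is False outside the [first, last] trigger window.
    """
    t = np.asarray(time, dtype=float)
    trig = np.asarray(trigger_times, dtype=float)
    if trig.size < 2:
        raise ValueError("need at least 2 trigger times")
    if np.any(np.diff(trig) <= 0):
        raise ValueError("trigger times must be strictly increasing")
    k = np.clip(np.searchsorted(trig, t, side="right") - 1, 0, trig.size - 2)
    rr = trig[k + 1] - trig[k]
    frame = np.floor(n_frames * (t - trig[k]) / rr).astype(int)
    frame = np.clip(frame, 0, n_frames - 1)
    valid = (t >= trig[0]) & (t <= trig[-1])
    return frame, valid


def bin_cardiac(kspace: KSpaceData, trigger_times, n_frames: int) -> BinAssignment:
    """Assign each readout to one of ``n_frames`` cardiac frames.

    Readouts before the first or after the last trigger are rejected (-1).
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    frame, valid = cardiac_frame_of(kspace.time, trigger_times, n_frames)
    frame = np.where(valid, frame, -1)
    return BinAssignment(cardiac_frame=frame)


def bin_bulk_motion(kspace: KSpaceData, bin_duration: float = 15.0) -> BinAssignment:
    """Chronological bulk-motion bins of ``bin_duration`` seconds.

    A trailing bin spanning less than half a bin duration is merged into its
    predecessor.
    """
    if bin_duration <= 0:
        raise ValueError("bin_duration must be positive")
    if kspace.n_readouts == 0:
        raise ValueError("cannot bin empty k-space data")
    t = kspace.time
    t0 = t.min()
    idx = np.floor((t - t0) / bin_duration).astype(int)
    n_raw = idx.max() + 1
    if n_raw > 1:
        trailing_span = t.max() - t0 - (n_raw - 1) * bin_duration
        if trailing_span < bin_duration / 2:
            idx = np.where(idx == n_raw - 1, n_raw - 2, idx)
    return BinAssignment(motion_bin=idx)
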