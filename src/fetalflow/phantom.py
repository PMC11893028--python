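"""Digital pulsatile-vessel phantom and motion-corrupted acquisition simulator.

The phantom stands in for the fetal great-vessel junction: the ductus
arteriosus (DA) and the aortic isthmus merge at the ductal insertion into the
descending aorta (DAo). Each vessel is a straight cylinder carrying a
parabolic (Poiseuille) velocity profile modulated over the cardiac cycle by a
shared pulsatile waveform; the DAo peak speed is scaled so that the analytic
flux balance ``Q_DA + Q_isthmus = Q_DAo`` holds exactly, which makes the
conservation-of-mass validation statistic zero by construction on the ground
truth.

The simulator produces the raw record a pseudo-spiral Cartesian, four-point
Hadamard velocity-encoded, multi-coil scan would deliver: per-readout kx
lines with timestamps, phase-encode indices, encoding-segment labels and a
respiratory belt value, corrupted by quasi-periodic maternal respiratory
translation and piecewise-constant fetal bulk translations applied as exact
Fourier phase ramps, plus complex white Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
from scipy import ndimage as ndi

from ._fft import cfftn, shift_phase_ramp
from .sampling import HADAMARD_SIGNS, KSpaceData, Trajectory, cardiac_frame_of


@dataclass
class Vessel:
    """Analytic description of one cylindrical vessel segment."""

    name: str
    origin_mm: np.ndarray  # upstream end of the axis segment
    direction: np.ndarray  # unit vector, flow direction
    length_mm: float
    radius_mm: float
    peak_speed: float  # cm/s at the axis, systole

    def analytic_flow(self, waveform_value: float = 1.0) -> float:
        """Poiseuille net flow in mL/min: ``0.6 * v_max * pi * r^2 / 2``."""
        return 0.6 * waveform_value * self.peak_speed * np.pi * self.radius_mm**2 / 2.0


@dataclass
class PhantomConfig:
    matrix_size: tuple = (48, 48, 48)
    voxel_size: tuple = (1.25, 1.25, 1.25)  # mm
    n_frames: int = 10
    n_coils: int = 4
    venc: float = 150.0  # cm/s
    da_peak_speed: float = 60.0  # cm/s
    isthmus_peak_speed: float = 40.0
    da_radius_mm: float = 2.5  # ~5 mm diameter, mid-third-trimester scale
    isthmus_radius_mm: float = 2.5
    dao_radius_mm: float = 3.2
    branch_angle_deg: float = 35.0
    background_fraction: float = 0.2  # static tissue magnitude vs vessel
    phi0: float = 0.1  # rad, constant background phase
    rr_interval: float = 0.42  # s (~143 bpm)
    waveform: Optional[np.ndarray] = None
    texture_seed: int = 7


@dataclass
class PhantomScene:
    matrix_size: tuple
    voxel_size: tuple
    vessel_masks: Dict[str, np.ndarray]
    magnitude_map: np.ndarray
    velocity_field: np.ndarray  # (n_frames, 3, nx, ny, nz) cm/s
    coil_sensitivities: np.ndarray  # (n_coils, nx, ny, nz)
    rr_interval: float
    waveform: np.ndarray
    venc: float
    phi0: float
    vessels: Dict[str, Vessel] = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.velocity_field.shape[0]


def default_waveform(n_frames: int = 10) -> np.ndarray:
    """Pulsatile per-frame scale factors: systolic peak, diastolic baseline."""
    f = np.arange(n_frames)
    w = 0.25 + 0.75 * np.exp(-(((f - 2.5) / 1.4) ** 2))
    return w / w.max()


def _coil_sensitivities(matrix_size, n_coils):
    """Smooth complex birdcage-like sensitivities, sum-of-squares = 1."""
    nx, ny, nz = matrix_size
    x, y, z = np.meshgrid(
        np.linspace(-1, 1, nx), np.linspace(-1, 1, ny), np.linspace(-1, 1, nz),
        indexing="ij",
    )
    sens = np.empty((n_coils, nx, ny, nz), dtype=complex)
    for c in range(n_coils):
        ang = 2 * np.pi * c / n_coils
        cx, cy = 1.3 * np.cos(ang), 1.3 * np.sin(ang)
        mag = np.exp(-((x - cx) ** 2 + (y - cy) ** 2 + 0.3 * z**2) / 1.8)
        phase = 0.5 * (np.cos(ang) * x + np.sin(ang) * y) + 0.1 * c
        sens[c] = mag * np.exp(1j * phase)
    sos = np.sqrt(np.sum(np.abs(sens) ** 2, axis=0))
    return sens / sos[None]


def make_phantom(config: Optional[PhantomConfig] = None, **overrides) -> PhantomScene:
    """Build the branching pulsatile-vessel scene.

    DA and isthmus descend symmetrically at ``branch_angle_deg`` from the
    z-axis and merge at the grid center (the ductal insertion); the DAo
    continues straight down (+z). The DAo peak speed is derived from the
    branch speeds and radii so the analytic flux balance is exact.
    """
    if config is None:
        config = PhantomConfig(**overrides)
    elif overrides:
        raise TypeError("pass either a config or keyword overrides, not both")

    nx, ny, nz = config.matrix_size
    if min(config.matrix_size) < 16:
        raise ValueError("matrix_size must be at least 16 per axis")
    vox = np.asarray(config.voxel_size, dtype=float)
    for r in (config.da_radius_mm, config.isthmus_radius_mm, config.dao_radius_mm):
        if 2 * r / vox.max() < 3.0:
            raise ValueError(
                f"vessel of radius {r} mm is thinner than 3 voxels across"
            )
        if r / vox.max() < 1.5:
            raise ValueError("vessel radii must be at least 1.5 voxels")

    waveform = (
        default_waveform(config.n_frames)
        if config.waveform is None
        else np.asarray(config.waveform, dtype=float)
    )
    if waveform.shape != (config.n_frames,):
        raise ValueError("waveform must have n_frames entries")
    if np.any(waveform < 0):
        raise ValueError("waveform entries must be nonnegative")
    if waveform.max() > 0 and not np.isclose(waveform.max(), 1.0):
        raise ValueError("waveform must be normalized to max 1")

    # conservation by construction
    dao_peak = (
        config.da_radius_mm**2 * config.da_peak_speed
        + config.isthmus_radius_mm**2 * config.isthmus_peak_speed
    ) / config.dao_radius_mm**2
    for v in (config.da_peak_speed, config.isthmus_peak_speed, dao_peak):
        if v >= config.venc:
            raise ValueError("peak speed must stay below venc (no aliasing)")

    fov = np.array(config.matrix_size) * vox
    center = fov / 2.0
    theta = np.deg2rad(config.branch_angle_deg)
    d_da = np.array([np.sin(theta), 0.0, np.cos(theta)])
    d_is = np.array([-np.sin(theta), 0.0, np.cos(theta)])
    d_dao = np.array([0.0, 0.0, 1.0])
    margin = 4.0 * vox.max()
    dao_len = fov[2] / 2.0 - margin
    branch_len = min((fov[2] / 2.0 - margin) / np.cos(theta),
                     (fov[0] / 2.0 - margin) / max(np.sin(theta), 1e-6))

    vessels = {
        "DA": Vessel("DA", center - branch_len * d_da, d_da, branch_len,
                     config.da_radius_mm, config.da_peak_speed),
        "isthmus": Vessel("isthmus", center - branch_len * d_is, d_is, branch_len,
                          config.isthmus_radius_mm, config.isthmus_peak_speed),
        "DAo": Vessel("DAo", center, d_dao, dao_len, config.dao_radius_mm, dao_peak),
    }

    # Voxel-center world coordinates (mm): r = index * voxel. Masks are
    # geometric (center-inside); magnitude and velocity are partial-volume
    # averaged over supersampled sub-voxel points, emulating a scanner's
    # voxel-averaging so that rim voxels carry fractional signal and the
    # discretized flux matches the analytic Poiseuille flux closely.
    base = [np.arange(n) * v for n, v in zip((nx, ny, nz), vox)]
    grid = np.stack(np.meshgrid(*base, indexing="ij"), axis=-1)

    masks = {}
    for name, v in vessels.items():
        rel = grid - v.origin_mm
        ax = rel @ v.direction
        rho = np.linalg.norm(rel - ax[..., None] * v.direction, axis=-1)
        masks[name] = (ax >= 0) & (ax <= v.length_mm) & (rho <= v.radius_mm)
    names = list(vessels)

    ss = 3  # supersampling factor per axis
    profile = np.zeros((nx, ny, nz, 3))
    vessel_frac = np.zeros((nx, ny, nz))
    offs = (np.arange(ss) - (ss - 1) / 2.0) / ss
    for ox in offs:
        for oy in offs:
            for oz in offs:
                pt = np.stack(
                    np.meshgrid(
                        base[0] + ox * vox[0], base[1] + oy * vox[1],
                        base[2] + oz * vox[2], indexing="ij",
                    ),
                    axis=-1,
                )
                speeds = np.zeros((len(names), nx, ny, nz))
                for i, name in enumerate(names):
                    v = vessels[name]
                    rel = pt - v.origin_mm
                    ax = rel @ v.direction
                    rho2 = np.sum((rel - ax[..., None] * v.direction) ** 2, axis=-1)
                    inside = (ax >= 0) & (ax <= v.length_mm)
                    speeds[i] = (
                        v.peak_speed
                        * np.clip(1.0 - rho2 / v.radius_mm**2, 0.0, None)
                        * inside
                    )
                # merging flow: the locally dominant vessel owns the point
                owner = np.argmax(speeds, axis=0)
                speed = np.take_along_axis(speeds, owner[None], axis=0)[0]
                dirs = np.stack([vessels[n].direction for n in names])
                profile += speed[..., None] * dirs[owner]
                vessel_frac += speed > 0
    profile /= ss**3
    vessel_frac /= ss**3

    velocity = np.zeros((config.n_frames, 3, nx, ny, nz))
    for f in range(config.n_frames):
        velocity[f] = waveform[f] * np.moveaxis(profile, -1, 0)

    rng = np.random.default_rng(config.texture_seed)
    texture = ndi.gaussian_filter(rng.normal(size=(nx, ny, nz)), 3.0)
    texture = (texture - texture.min()) / max(np.ptp(texture), 1e-12)
    background = config.background_fraction * (0.5 + texture)
    magnitude = background * (1.0 - vessel_frac) + vessel_frac

    return PhantomScene(
        matrix_size=tuple(config.matrix_size),
        voxel_size=tuple(vox),
        vessel_masks=masks,
        magnitude_map=magnitude,
        velocity_field=velocity,
        coil_sensitivities=_coil_sensitivities(config.matrix_size, config.n_coils),
        rr_interval=config.rr_interval,
        waveform=waveform,
        venc=config.venc,
        phi0=config.phi0,
        vessels=vessels,
    )


@dataclass
class MotionTrace:
    """Maternal respiratory + fetal bulk translation over the scan.

    Respiratory displacement is a quasi-sinusoidal translation along
    ``resp_axis`` that is exactly zero at the expiration plateau (the signal
    minimum by convention). Fetal bulk translation is piecewise constant with
    finitely many change points.
    """

    readout_times: np.ndarray
    respiratory_signal: np.ndarray  # a.u., sampled at readout times
    resp_amplitude_mm: float
    resp_period_s: float
    resp_axis: np.ndarray
    bulk_change_times: np.ndarray  # (m,) s, sorted
    bulk_positions_mm: np.ndarray  # (m + 1, 3), position on each interval

    @staticmethod
    def _resp_shape(t, period):
        # sin^4 gives a flat expiration plateau around signal minimum 0
        return np.sin(np.pi * np.asarray(t, dtype=float) / period) ** 4

    def respiratory_displacement(self, t) -> np.ndarray:
        s = self._resp_shape(t, self.resp_period_s)
        return self.resp_amplitude_mm * s[..., None] * self.resp_axis[None, :]

    def bulk_translation(self, t) -> np.ndarray:
        idx = np.searchsorted(self.bulk_change_times, np.asarray(t, dtype=float),
                              side="right")
        return self.bulk_positions_mm[idx]

    def total_displacement(self, t) -> np.ndarray:
        return self.respiratory_displacement(t) + self.bulk_translation(t)


@dataclass
class MotionConfig:
    resp_amplitude_mm: float = 3.0
    resp_period_s: float = 4.0
    resp_axis: tuple = (0.0, 1.0, 0.0)  # anteroposterior by default
    bulk_max_shift_mm: float = 8.0
    bulk_rate_per_s: float = 1.0 / 45.0  # ~2 events per 90 s scan
    bulk_change_times: Optional[Sequence[float]] = None
    bulk_shifts_mm: Optional[Sequence[Sequence[float]]] = None


def simulate_motion(
    config: MotionConfig, duration: float, readout_times: np.ndarray, seed: int = 0
) -> MotionTrace:
    """Draw (or accept explicitly) the motion realization for one scan."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    axis = np.asarray(config.resp_axis, dtype=float)
    norm = np.linalg.norm(axis)
    axis = axis / norm if norm > 0 else axis

    if config.bulk_change_times is not None:
        times = np.asarray(config.bulk_change_times, dtype=float)
        shifts = np.asarray(config.bulk_shifts_mm, dtype=float)
        if shifts.shape != (times.size, 3):
            raise ValueError("bulk_shifts_mm must be (n_change_points, 3)")
        positions = np.vstack([np.zeros(3), shifts])
    else:
        n_events = rng.poisson(config.bulk_rate_per_s * duration)
        times = np.sort(rng.uniform(0.1 * duration, 0.9 * duration, size=n_events))
        positions = [np.zeros(3)]
        for _ in range(n_events):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            mag = rng.uniform(0.25, 1.0) * config.bulk_max_shift_mm
            positions.append(mag * direction)
        positions = np.asarray(positions)

    signal = MotionTrace._resp_shape(readout_times, config.resp_period_s)
    if config.resp_amplitude_mm == 0:
        signal = np.zeros_like(np.asarray(readout_times, dtype=float))
    return MotionTrace(
        readout_times=np.asarray(readout_times, dtype=float),
        respiratory_signal=signal,
        resp_amplitude_mm=config.resp_amplitude_mm,
        resp_period_s=config.resp_period_s,
        resp_axis=axis,
        bulk_change_times=times,
        bulk_positions_mm=positions,
    )


@dataclass
class TriggerTrain:
    trigger_times: np.ndarray
    mean_hr: float
    jitter_sd: float

    def __post_init__(self):
        if np.any(np.diff(self.trigger_times) <= 0):
            raise ValueError("trigger times must be strictly increasing")


def simulate_triggers(
    mean_hr: float, jitter_sd: float, duration: float, seed: int = 0
) -> TriggerTrain:
    """Doppler-ultrasound-style cardiac trigger times covering [0, duration]."""
    if not 60 <= mean_hr <= 220:
        raise ValueError("mean_hr must be within 60-220 beats/min")
    rr_nominal = 60.0 / mean_hr
    rng = np.random.default_rng(seed)
    times = [0.0]
    while times[-1] <= duration:
        rr = rr_nominal + (rng.normal(0.0, jitter_sd) if jitter_sd > 0 else 0.0)
        while rr <= 0.1 * rr_nominal:  # resample: never emit non-increasing times
            rr = rr_nominal + rng.normal(0.0, jitter_sd)
        times.append(times[-1] + rr)
    return TriggerTrain(np.asarray(times), mean_hr, jitter_sd)


def segment_images(scene: PhantomScene, frame: int) -> np.ndarray:
    """Complex images of the four Hadamard encoding segments for one frame."""
    v = scene.velocity_field[frame]  # (3, nx, ny, nz)
    phase_scale = np.pi / (2.0 * scene.venc)
    imgs = np.empty((4,) + scene.matrix_size, dtype=complex)
    for s in range(4):
        enc = phase_scale * np.tensordot(HADAMARD_SIGNS[s], v, axes=(0, 0))
        imgs[s] = scene.magnitude_map * np.exp(1j * (scene.phi0 + enc))
    return imgs


def simulate_acquisition(
    scene: PhantomScene,
    trajectory: Trajectory,
    motion: Optional[MotionTrace],
    triggers: TriggerTrain,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> KSpaceData:
    """Forward-simulate the motion-corrupted, velocity-encoded acquisition.

    Per readout: the cardiac frame is selected by the same binning rule the
    reconstruction uses; the segment image is synthesized, coil-weighted and
    Fourier transformed; the total translation (respiratory + bulk) at the
    readout time is applied as an exact k-space phase ramp; the fully sampled
    kx line at the readout's (ky, kz) is extracted; complex white Gaussian
    noise of standard deviation ``noise_sd`` per complex sample is added.
    """
    nx, ny, nz = scene.matrix_size
    if tuple(trajectory.matrix_size) != tuple(scene.matrix_size):
        raise ValueError("trajectory matrix does not match the scene")
    sens = scene.coil_sensitivities
    if np.any(~np.isfinite(sens)):
        raise ValueError("NaN/inf in coil sensitivities")
    n_coils = sens.shape[0]
    n_frames = scene.n_frames

    frame, _ = cardiac_frame_of(trajectory.time, triggers.trigger_times, n_frames)

    # Precompute k-space cubes for every (frame, segment, coil).
    kcube = np.empty((n_frames, 4, n_coils, nx, ny, nz), dtype=complex)
    for f in range(n_frames):
        imgs = segment_images(scene, f)
        kcube[f] = cfftn(imgs[:, None] * sens[None], axes=(-3, -2, -1))

    n_ro = trajectory.n_readouts
    t = trajectory.time
    if motion is not None:
        shift_mm = motion.total_displacement(t)
    else:
        shift_mm = np.zeros((n_ro, 3))
    vox = np.asarray(scene.voxel_size)
    shift_vox = shift_mm / vox[None, :]

    kx_freq = np.arange(nx) - nx // 2
    ky_freq = trajectory.ky - ny // 2
    kz_freq = trajectory.kz - nz // 2

    lines = kcube[frame, trajectory.segment, :, :, trajectory.ky, trajectory.kz]
    lines = np.ascontiguousarray(np.swapaxes(lines, 1, 2))  # (n_ro, nx, n_coils)

    ramp_x = np.exp(-2j * np.pi * np.outer(shift_vox[:, 0], kx_freq) / nx)
    ramp_yz = np.exp(
        -2j * np.pi * (ky_freq * shift_vox[:, 1] / ny + kz_freq * shift_vox[:, 2] / nz)
    )
    lines *= (ramp_x * ramp_yz[:, None])[:, :, None]

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        noise = rng.standard_normal((n_ro, nx, n_coils)) + 1j * rng.standard_normal(
            (n_ro, nx, n_coils)
        )
        lines += noise * (noise_sd / np.sqrt(2.0))

    return KSpaceData(
        samples=lines,
        time=t.copy(),
        ky=trajectory.ky.copy(),
        kz=trajectory.kz.copy(),
        segment=trajectory.segment.copy(),
        resp=None if motion is None else motion.respiratory_signal.copy(),
        matrix_size=tuple(scene.matrix_size),
        voxel_size=tuple(scene.voxel_size),
        venc=scene.venc,
        n_frames=n_frames,
        trigger_times=triggers.trigger_times.copy(),
        coil_sens=sens,
        truth={
            "scene": scene,
            "motion": motion,
            "triggers": triggers,
            "shift_mm": shift_mm,
            "frame": frame,
        },
    )
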