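"""Flow validation statistics: net flow through planes, conservation of mass,
and the coefficient of variation of net flow along the descending aorta.

Conservation of mass (CoM) checks the flux balance at the ductal insertion,
``Q_DA + Q_isthmus = Q_DAo``, reported as a symmetric percent difference.
The coefficient of variation (CoV) measures flow consistency: net flow is
evaluated at contours spaced one voxel apart along the vessel centerline and
summarized as population std / mean.

Units: velocities are cm/s, geometry is mm; ``1 cm/s across 1 mm^2`` equals
``0.6 mL/min``, so net flow is ``0.6 * sum(v . n) * cell_area_mm2``.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import skeletonize

FLOW_UNIT = 0.6  # mL/min per (cm/s * mm^2)


@dataclass
class FlowPlane:
    """A square flow-measurement plane orthogonal to the local vessel axis."""

    center_mm: np.ndarray
    normal: np.ndarray  # unit vector
    basis: np.ndarray  # (2, 3) in-plane orthonormal vectors
    extent_mm: float = 20.0
    grid_spacing_mm: float = 0.5

    def __post_init__(self):
        if not np.isclose(np.linalg.norm(self.normal), 1.0, atol=1e-6):
            raise ValueError("plane normal must be a unit vector")

    def grid_points(self) -> np.ndarray:
        """(n, n, 3) mm coordinates of the sampling grid."""
        half = self.extent_mm / 2.0
        offs = np.arange(-half + self.grid_spacing_mm / 2.0, half, self.grid_spacing_mm)
        a, b = np.meshgrid(offs, offs, indexing="ij")
        return (
            self.center_mm[None, None]
            + a[..., None] * self.basis[0][None, None]
            + b[..., None] * self.basis[1][None, None]
        )

    @property
    def cell_area_mm2(self) -> float:
        return self.grid_spacing_mm**2


@dataclass
class CoMResult:
    q_da: float
    q_isthmus: float
    q_dao: float
    percent_difference: float


@dataclass
class CoVResult:
    flows: np.ndarray  # per-contour net flow, mL/min
    cov: float
    n_contours: int
    flagged: bool = False


@dataclass
class FlowReport:
    plane_flows: Dict[str, np.ndarray]  # vessel -> (n_planes, n_frames) mL/min
    com: CoMResult
    cov: CoVResult
    provenance: str = ""


def _local_direction(mask, anchor_mm, voxel_size, radius_mm=5.0):
    """Principal axis of mask voxels within a ball around the anchor."""
    coords = np.argwhere(mask) * voxel_size[None, :]
    d = np.linalg.norm(coords - anchor_mm[None], axis=1)
    for r in (radius_mm, 2 * radius_mm, 4 * radius_mm):
        near = coords[d <= r]
        if near.shape[0] >= 10:
            break
    if near.shape[0] < 4:
        raise ValueError("too few mask voxels near anchor to estimate direction")
    centered = near - near.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    return vt[0], near.mean(axis=0)


def _plane_basis(normal):
    e = np.zeros(3)
    e[np.argmin(np.abs(normal))] = 1.0
    b1 = np.cross(normal, e)
    b1 /= np.linalg.norm(b1)
    b2 = np.cross(normal, b1)
    return np.stack([b1, b2])


def place_planes(
    mask: np.ndarray,
    anchor_mm,
    n_planes: int = 3,
    spacing_mm: float = 1.25,
    extent_mm: float = 20.0,
    voxel_size=(1.25, 1.25, 1.25),
    direction_hint=None,
) -> List[FlowPlane]:
    """Planes orthogonal to the local vessel direction, centered on the axis.

    The local direction is the principal component of mask voxels within a
    5 mm ball of the anchor; its sign follows ``direction_hint`` when given,
    otherwise the dominant component is made positive. Plane centers are
    spaced ``spacing_mm`` apart along the axis around the anchor's projection.
    """
    vox = np.asarray(voxel_size, dtype=float)
    anchor_mm = np.asarray(anchor_mm, dtype=float)
    idx = np.round(anchor_mm / vox).astype(int)
    if np.any(idx < 0) or np.any(idx >= np.asarray(mask.shape)):
        raise ValueError("anchor outside the volume")
    if not mask[tuple(idx)]:
        raise ValueError("anchor must lie inside the vessel mask")
    direction, centroid = _local_direction(mask, anchor_mm, vox)
    if direction_hint is not None:
        hint = np.asarray(direction_hint, dtype=float)
        if np.dot(direction, hint) < 0:
            direction = -direction
    elif direction[np.argmax(np.abs(direction))] < 0:
        direction = -direction
    center0 = centroid + np.dot(anchor_mm - centroid, direction) * direction
    basis = _plane_basis(direction)
    planes = []
    for i in range(n_planes):
        offset = (i - (n_planes - 1) / 2.0) * spacing_mm
        center = center0 + offset * direction
        cidx = np.round(center / vox).astype(int)
        if np.any(cidx < 0) or np.any(cidx >= np.asarray(mask.shape)):
            raise ValueError("vessel too short for the requested planes")
        planes.append(
            FlowPlane(center_mm=center, normal=direction.copy(), basis=basis,
                      extent_mm=extent_mm)
        )
    return planes


def net_flow(
    velocity: np.ndarray,
    plane: FlowPlane,
    mask: Optional[np.ndarray] = None,
    voxel_size=(1.25, 1.25, 1.25),
    contour: Optional[np.ndarray] = None,
    dilate: int = 1,
) -> float:
    """Net flow (mL/min) through the plane's contour for one cardiac frame.

    ``velocity`` is ``(3, nx, ny, nz)`` in cm/s. The contour defaults to the
    vessel mask (dilated by ``dilate`` voxels to capture the profile edge)
    sampled on the plane grid; an explicit boolean ``contour`` on the plane
    grid overrides it. Velocities are sampled by trilinear interpolation and
    signed along the plane normal.
    """
    vox = np.asarray(voxel_size, dtype=float)
    pts = plane.grid_points()
    coords = (pts / vox[None, None]).reshape(-1, 3).T  # (3, n)
    shape = np.asarray(velocity.shape[1:])
    inside = np.all((coords >= -0.5) & (coords <= (shape[:, None] - 0.5)), axis=0)
    if not np.any(inside):
        raise ValueError("plane lies entirely outside the volume")

    if contour is None:
        if mask is None:
            raise ValueError("provide either a vessel mask or an explicit contour")
        m = ndi.binary_dilation(mask, iterations=dilate) if dilate > 0 else mask
        msamp = ndi.map_coordinates(m.astype(float), coords, order=1, mode="constant")
        contour_flat = msamp >= 0.5
    else:
        contour_flat = np.asarray(contour, dtype=bool).reshape(-1)
    contour_flat = contour_flat & inside
    if not np.any(contour_flat):
        return 0.0

    vn = np.zeros(coords.shape[1])
    for comp in range(3):
        vs = ndi.map_coordinates(velocity[comp], coords, order=1, mode="constant")
        vn += vs * plane.normal[comp]
    return FLOW_UNIT * float(vn[contour_flat].sum()) * plane.cell_area_mm2


def conservation_of_mass(q_da: float, q_isthmus: float, q_dao: float) -> float:
    """Percent difference between DA + isthmus inflow and DAo outflow.

    Symmetric definition: ``100 * |L - R| / ((L + R) / 2)`` with
    ``L = Q_DA + Q_isthmus`` and ``R = Q_DAo``; 0 when both sides vanish.
    """
    left = q_da + q_isthmus
    right = q_dao
    if left == 0 and right == 0:
        return 0.0
    denom = (left + right) / 2.0
    if denom == 0:
        warnings.warn("conservation of mass undefined: L + R = 0 with L != R")
        return np.nan
    return 100.0 * abs(left - right) / abs(denom)


_NEIGHBOR_OFFSETS = np.array(
    [o for o in np.ndindex(3, 3, 3) if o != (1, 1, 1)]
) - 1


def centerline(mask: np.ndarray, voxel_size=(1.25, 1.25, 1.25), proximal_axis: int = 2):
    """Ordered centerline points (mm) from 3D skeletonization.

    The skeleton's longest path (double breadth-first search) is extracted
    and ordered so it starts at the end with the smaller coordinate along
    ``proximal_axis``. Every returned point lies inside the mask.
    """
    vox = np.asarray(voxel_size, dtype=float)
    n_comp = ndi.label(mask)[1]
    if n_comp != 1:
        raise ValueError(f"mask must be one connected component (got {n_comp})")
    skel = skeletonize(mask)
    pts = np.argwhere(skel)
    if pts.shape[0] == 0:
        raise ValueError("skeletonization produced no voxels")
    index = {tuple(p): i for i, p in enumerate(pts)}
    adj: List[List[int]] = [[] for _ in range(pts.shape[0])]
    n_edges = 0
    for i, p in enumerate(pts):
        for off in _NEIGHBOR_OFFSETS:
            q = tuple(p + off)
            j = index.get(q)
            if j is not None and j > i:
                adj[i].append(j)
                adj[j].append(i)
                n_edges += 1
    if n_edges >= pts.shape[0]:
        warnings.warn("skeleton contains loops; extracting longest simple path")

    def bfs(start):
        parent = {start: -1}
        queue = deque([start])
        last = start
        while queue:
            u = queue.popleft()
            last = u
            for w in adj[u]:
                if w not in parent:
                    parent[w] = u
                    queue.append(w)
        return last, parent

    a, _ = bfs(0)
    b, parent = bfs(a)
    path = []
    u = b
    while u != -1:
        path.append(u)
        u = parent[u]
    path_pts = pts[path]
    if path_pts[0, proximal_axis] > path_pts[-1, proximal_axis]:
        path_pts = path_pts[::-1]
    return path_pts * vox[None, :]


def _resample_centerline(points_mm, spacing_mm):
    """Keep points at least ``spacing_mm`` apart along the path."""
    kept = [points_mm[0]]
    acc = 0.0
    for prev, cur in zip(points_mm[:-1], points_mm[1:]):
        acc += np.linalg.norm(cur - prev)
        if acc >= spacing_mm:
            kept.append(cur)
            acc = 0.0
    return np.asarray(kept)


def cov_along_vessel(
    velocity: np.ndarray,
    mask: np.ndarray,
    voxel_size=(1.25, 1.25, 1.25),
    trim: int = 2,
    extent_mm: float = 20.0,
    dilate: int = 1,
    per_phase: bool = False,
) -> CoVResult:
    """Coefficient of variation of net flow along the vessel centerline.

    Static contours (the segmentation cross-section) are placed at one voxel
    spacing along the centerline; per-contour net flow is the time mean over
    cardiac frames (or, with ``per_phase``, the CoV is computed per frame and
    averaged). ``trim`` contours are dropped at each end of the span. CoV is
    the population standard deviation over contours divided by the mean.
    """
    vox = np.asarray(voxel_size, dtype=float)
    if velocity.ndim == 4:  # single frame (3, nx, ny, nz)
        velocity = velocity[None]
    line = centerline(mask, vox)
    pts = _resample_centerline(line, float(vox.min()))
    if trim > 0 and pts.shape[0] > 2 * trim + 2:
        pts = pts[trim:-trim]
    if pts.shape[0] < 3:
        raise ValueError("centerline too short: need at least 3 contours")
    # smoothed tangents via central differences
    tangents = np.gradient(pts, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)

    n_frames = velocity.shape[0]
    flows = np.empty((pts.shape[0], n_frames))
    for i, (c, t) in enumerate(zip(pts, tangents)):
        if t[np.argmax(np.abs(t))] < 0:
            t = -t
        plane = FlowPlane(center_mm=c, normal=t, basis=_plane_basis(t),
                          extent_mm=extent_mm)
        for f in range(n_frames):
            flows[i, f] = net_flow(velocity[f], plane, mask, vox, dilate=dilate)

    if per_phase:
        means = flows.mean(axis=0)
        covs = np.where(
            np.abs(means) > 1e-9, flows.std(axis=0) / np.abs(means), np.nan
        )
        cov = float(np.nanmean(covs))
        contour_flows = flows.mean(axis=1)
        flagged = bool(np.any(np.abs(means) < 1e-9))
    else:
        contour_flows = flows.mean(axis=1)
        mean = contour_flows.mean()
        if abs(mean) < 1e-9:
            warnings.warn("mean net flow ~ 0: CoV undefined")
            return CoVResult(contour_flows, np.nan, pts.shape[0], flagged=True)
        cov = float(contour_flows.std() / abs(mean))
        flagged = False
    return CoVResult(contour_flows, cov, pts.shape[0], flagged=flagged)


def compute_flow_report(
    velocity: np.ndarray,
    masks: Dict[str, np.ndarray],
    voxel_size,
    anchors: Optional[Dict[str, np.ndarray]] = None,
    direction_hints: Optional[Dict[str, np.ndarray]] = None,
    n_planes: int = 3,
    spacing_mm: float = 1.25,
    provenance: str = "",
) -> FlowReport:
    """Full validation report: per-plane flows, CoM at the junction, DAo CoV.

    ``masks`` must contain "DA", "isthmus" and "DAo". Anchors default to each
    mask's centroid.
    """
    vox = np.asarray(voxel_size, dtype=float)
    n_frames = velocity.shape[0]
    plane_flows: Dict[str, np.ndarray] = {}
    mean_q = {}
    for name in ("DA", "isthmus", "DAo"):
        mask = masks[name]
        anchor = (
            anchors[name]
            if anchors and name in anchors
            else np.mean(np.argwhere(mask), axis=0) * vox
        )
        hint = direction_hints.get(name) if direction_hints else None
        planes = place_planes(
            mask, anchor, n_planes=n_planes, spacing_mm=spacing_mm,
            voxel_size=vox, direction_hint=hint,
        )
        q = np.empty((len(planes), n_frames))
        for pi, plane in enumerate(planes):
            for f in range(n_frames):
                q[pi, f] = net_flow(velocity[f], plane, mask, vox)
        plane_flows[name] = q
        mean_q[name] = float(q.mean())
    pct = conservation_of_mass(mean_q["DA"], mean_q["isthmus"], mean_q["DAo"])
    com = CoMResult(mean_q["DA"], mean_q["isthmus"], mean_q["DAo"], pct)
    cov = cov_along_vessel(velocity, masks["DAo"], vox)
    return FlowReport(plane_flows=plane_flows, com=com, cov=cov, provenance=provenance)
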