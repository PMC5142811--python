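"""Nucleus detection and tracking by gradient-vector-field flow.

Nuclei are bright blobs; the gradient vector field (GVF) diffuses the
intensity gradient of a smoothed volume into surrounding space so that
every voxel carries a vector pointing (eventually) toward a nucleus center.
Detection advects all voxels along the field and clusters the convergence
points; tracking re-runs the same flow inside a small crop around each
neuron's previous position, frame by frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .core import ImageStack

TRACKED, LOST, MERGED = "tracked", "lost", "merged"


@dataclass
class GVFParams:
    """Parameters of the GVF diffusion.

    ``mu`` is the regularization (diffusion) weight, iterated ``n_iter``
    times with pseudo-time step ``dt``; stability requires
    ``dt * mu <= 1/6`` in 3D.  ``smooth_sigma`` is the Gaussian
    pre-smoothing of the intensity (voxels).
    """

    mu: float = 0.2
    n_iter: int = 80
    dt: float = 0.5
    smooth_sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        if self.dt * self.mu > 1.0 / 6.0 + 1e-12:
            raise ValueError("unstable parameters: need dt * mu <= 1/6 in 3D")


@dataclass
class VectorField:
    """Per-voxel 3-component vector field, components stacked first."""

    components: np.ndarray  # (3, nz, ny, nx)

    def __post_init__(self) -> None:
        self.components = np.asarray(self.components, dtype=float)
        if self.components.ndim != 4 or self.components.shape[0] != 3:
            raise ValueError("field must have shape (3, nz, ny, nx)")
        if not np.all(np.isfinite(self.components)):
            raise ValueError("field must be finite everywhere")

    def magnitude(self) -> np.ndarray:
        return np.sqrt((self.components**2).sum(axis=0))

    def sample(self, positions: np.ndarray) -> np.ndarray:
        """Trilinearly interpolated vectors at (n, 3) subvoxel positions."""
        pos = np.asarray(positions, dtype=float).T  # (3, n)
        return np.stack(
            [
                ndimage.map_coordinates(c, pos, order=1, mode="nearest")
                for c in self.components
            ],
            axis=1,
        )


@dataclass
class NeuronTrack:
    """One neuron's subvoxel center through time with per-frame status."""

    neuron_id: int
    centers: np.ndarray  # (n_frames, 3)
    status: list[str] = field(default_factory=list)
    mask_radius: float = 2.0

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)

    @property
    def n_frames(self) -> int:
        return len(self.centers)

    def tracked_mask(self) -> np.ndarray:
        return np.asarray([s == TRACKED for s in self.status])


def compute_gvf(
    volume: np.ndarray,
    params: GVFParams | None = None,
    voxel_size: tuple[float, float, float] | None = None,
) -> VectorField:
    """Gradient vector field of a (smoothed, range-normalized) volume.

    Iterates ``v <- v + dt * (mu * lap(v) - (v - grad f) * |grad f|^2)``
    where ``f`` is the Gaussian-smoothed intensity scaled to [0, 1]; the
    range normalization makes the field invariant under global intensity
    scaling.  Anisotropic voxels are handled by scaling each gradient
    component by 1/voxel_size.
    """
    params = params or GVFParams()
    f = ndimage.gaussian_filter(np.asarray(volume, dtype=float), params.smooth_sigma)
    rng_ = f.max() - f.min()
    if rng_ > 0:
        f = (f - f.min()) / rng_
    grads = np.gradient(f)
    if voxel_size is not None:
        scale = np.asarray(voxel_size, dtype=float)
        scale = scale / scale.min()
        grads = [g / s for g, s in zip(grads, scale)]
    grad = np.stack(grads)
    g2 = (grad**2).sum(axis=0)
    v = grad.copy()
    for _ in range(params.n_iter):
        lap = np.stack([ndimage.laplace(c, mode="nearest") for c in v])
        v = v + params.dt * (params.mu * lap - (v - grad) * g2)
    return VectorField(components=v)


def advect(
    field: VectorField,
    positions: np.ndarray,
    step: float = 0.5,
    max_steps: int = 200,
    tol: float = 1e-3,
) -> np.ndarray:
    """Advect points along the field with fixed-length steps.

    Each point moves ``step`` voxels in the local field direction until the
    local field magnitude drops below ``tol`` or ``max_steps`` is reached;
    returns the final positions (the convergence points).
    """
    pos = np.asarray(positions, dtype=float).copy()
    upper = np.asarray(field.components.shape[1:], dtype=float) - 1.0
    active = np.arange(len(pos))
    for _ in range(max_steps):
        if len(active) == 0:
            break
        vec = field.sample(pos[active])
        mag = np.linalg.norm(vec, axis=1)
        moving = mag > tol
        if not moving.any():
            break
        idx = active[moving]
        pos[idx] += step * vec[moving] / mag[moving, None]
        np.clip(pos[idx], 0.0, upper, out=pos[idx])
        active = idx
    return pos


def detect_nuclei(
    volume: np.ndarray,
    params: GVFParams | None = None,
    min_basin: int = 30,
    merge_radius: float = 2.0,
    step: float = 0.5,
    max_steps: int = 200,
    tol: float = 1e-3,
    min_intensity_frac: float = 0.1,
    voxel_size: tuple[float, float, float] | None = None,
    full_output: bool = False,
):
    """Find all nucleus centers in a volume by GVF flow.

    Every voxel is advected to its convergence point; convergence points
    within ``merge_radius`` are greedily clustered (largest basin first) and
    clusters with at least ``min_basin`` source voxels are emitted as
    centers (mean of member convergence points, subvoxel).  Clusters whose
    smoothed intensity is below ``min_intensity_frac`` of the volume's
    bright (99.9th percentile) level are rejected: flow can stall on the
    dark saddle lines between nuclei, and a nucleus center must be bright.

    Returns an ``(n, 3)`` array of centers, or ``(centers, clusters)`` with
    the full cluster table (including rejected clusters) if ``full_output``.
    """
    volume = np.asarray(volume, dtype=float)
    field = compute_gvf(volume, params, voxel_size)
    if not field.components.any():  # uniform input: flat field, nothing to find
        empty = np.empty((0, 3))
        return (empty, pd.DataFrame(columns=["z", "y", "x", "basin", "accepted"])) if full_output else empty

    grid = np.stack(np.meshgrid(*[np.arange(s) for s in volume.shape], indexing="ij"))
    start = grid.reshape(3, -1).T.astype(float)
    end = advect(field, start, step=step, max_steps=max_steps, tol=tol)

    # bin endpoints at half-voxel resolution, then cluster bins within
    # merge_radius, seeding greedily from the heaviest bin
    binned = np.round(end * 2.0) / 2.0
    bins, inverse, counts = np.unique(
        binned, axis=0, return_inverse=True, return_counts=True
    )
    order = np.argsort(-counts, kind="stable")
    tree = cKDTree(bins)
    cluster_of_bin = np.full(len(bins), -1, dtype=int)
    seeds: list[np.ndarray] = []
    for b in order:
        if cluster_of_bin[b] >= 0:
            continue
        cid = len(seeds)
        seeds.append(bins[b].astype(float))
        members = tree.query_ball_point(bins[b], merge_radius)
        for m in members:
            if cluster_of_bin[m] < 0:
                cluster_of_bin[m] = cid
    cluster_of_point = cluster_of_bin[inverse]

    n_clusters = len(seeds)
    basin = np.bincount(cluster_of_point, minlength=n_clusters)
    sums = np.zeros((n_clusters, 3))
    np.add.at(sums, cluster_of_point, end)
    centers_all = sums / basin[:, None]
    smoothed = ndimage.gaussian_filter(volume, (params or GVFParams()).smooth_sigma)
    center_intensity = ndimage.map_coordinates(
        smoothed, centers_all.T, order=1, mode="nearest"
    )
    bright = np.percentile(smoothed, 99.9)
    accepted = (basin >= min_basin) & (
        center_intensity >= min_intensity_frac * bright
    )
    centers = centers_all[accepted]
    # deterministic output order: by basin size descending, then coordinates
    order_out = np.lexsort(
        (centers[:, 2], centers[:, 1], centers[:, 0], -basin[accepted])
    )
    centers = centers[order_out]
    if not full_output:
        return centers
    clusters = pd.DataFrame(
        {
            "z": centers_all[:, 0],
            "y": centers_all[:, 1],
            "x": centers_all[:, 2],
            "basin": basin,
            "accepted": accepted,
        }
    )
    return centers, clusters


def _background_threshold(volume: np.ndarray) -> float:
    """Robust background ceiling: median + 5 * 1.4826 * MAD."""
    med = float(np.median(volume))
    mad = float(np.median(np.abs(volume - med)))
    return med + 5.0 * 1.4826 * mad


def track_frame(
    prev_center: np.ndarray,
    next_volume: np.ndarray,
    crop_half_size: tuple[int, int, int] = (3, 7, 7),
    params: GVFParams | None = None,
    max_step: float = 4.0,
    bg_threshold: float | None = None,
    step: float = 0.5,
    max_steps: int = 200,
    tol: float = 1e-3,
) -> tuple[np.ndarray, str]:
    """Follow one neuron into the next frame by local GVF flow.

    The GVF is computed only inside a crop window around the previous
    center; the center is advected to its local sink.  The track is marked
    lost when the sink moved more than ``max_step`` voxels or its local
    intensity fell below the background threshold.
    """
    prev_center = np.asarray(prev_center, dtype=float)
    next_volume = np.asarray(next_volume, dtype=float)
    lo = np.maximum(np.round(prev_center).astype(int) - np.asarray(crop_half_size), 0)
    hi = np.minimum(
        np.round(prev_center).astype(int) + np.asarray(crop_half_size) + 1,
        np.asarray(next_volume.shape),
    )
    if np.any(hi <= lo):
        return prev_center, LOST
    crop = next_volume[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    field = compute_gvf(crop, params)
    local = advect(
        field, (prev_center - lo)[None, :], step=step, max_steps=max_steps, tol=tol
    )[0]
    new_center = local + lo
    displacement = np.linalg.norm(new_center - prev_center)
    if displacement > max_step:
        return prev_center, LOST
    thresh = bg_threshold if bg_threshold is not None else _background_threshold(next_volume)
    smoothed = ndimage.gaussian_filter(crop, (params or GVFParams()).smooth_sigma)
    intensity = ndimage.map_coordinates(
        smoothed, local[:, None], order=1, mode="nearest"
    )[0]
    if intensity < thresh:
        return prev_center, LOST
    return new_center, TRACKED


def track_all(
    stack: ImageStack,
    initial_centers: np.ndarray,
    channel: int | str = "R",
    crop_half_size: tuple[int, int, int] = (3, 7, 7),
    params: GVFParams | None = None,
    max_step: float = 4.0,
    merge_radius: float = 2.0,
    mask_radius: float = 2.0,
    bg_threshold: float | None = None,
) -> list[NeuronTrack]:
    """Track every detected neuron through the whole recording.

    Local flow tracking is repeated frame by frame; lost tracks are not
    re-seeded.  When two tracks come within ``merge_radius`` of each other
    the one with lower mean intensity over the previous 5 frames is flagged
    merged from that frame on.
    """
    initial_centers = np.asarray(initial_centers, dtype=float)
    n_neurons = len(initial_centers)
    n_frames = stack.n_frames
    c = stack.channel_index(channel)
    centers = np.zeros((n_frames, n_neurons, 3))
    centers[0] = initial_centers
    status = np.full((n_frames, n_neurons), TRACKED, dtype=object)

    # rolling record of local intensity for the merge tie-break
    intensity = np.zeros((n_frames, n_neurons))
    vol0 = stack.data[0, :, :, :, c].astype(float)
    sm0 = ndimage.gaussian_filter(vol0, (params or GVFParams()).smooth_sigma)
    intensity[0] = ndimage.map_coordinates(sm0, initial_centers.T, order=1, mode="nearest")

    for t in range(1, n_frames):
        vol = stack.data[t, :, :, :, c].astype(float)
        thresh = bg_threshold if bg_threshold is not None else _background_threshold(vol)
        smoothed = ndimage.gaussian_filter(vol, (params or GVFParams()).smooth_sigma)
        for i in range(n_neurons):
            if status[t - 1, i] != TRACKED:
                centers[t, i] = centers[t - 1, i]
                status[t, i] = status[t - 1, i]
                continue
            new_c, st = track_frame(
                centers[t - 1, i],
                vol,
                crop_half_size=crop_half_size,
                params=params,
                max_step=max_step,
                bg_threshold=thresh,
            )
            centers[t, i] = new_c
            status[t, i] = st
        intensity[t] = ndimage.map_coordinates(
            smoothed, centers[t].T, order=1, mode="nearest"
        )
        # merge handling: flag the lower-contrast member of any close pair
        active = [i for i in range(n_neurons) if status[t, i] == TRACKED]
        if len(active) > 1:
            pts = centers[t, active]
            tree = cKDTree(pts)
            for a_idx, b_idx in tree.query_pairs(merge_radius):
                i, j = active[a_idx], active[b_idx]
                w0 = max(t - 5, 0)
                mi = intensity[w0:t + 1, i].mean()
                mj = intensity[w0:t + 1, j].mean()
                loser = i if mi < mj else j
                status[t, loser] = MERGED

    tracks = []
    for i in range(n_neurons):
        tracks.append(
            NeuronTrack(
                neuron_id=i,
                centers=centers[:, i, :],
                status=list(status[:, i]),
                mask_radius=mask_radius,
            )
        )
    return tracks


def tracks_to_frame(tracks: list[NeuronTrack]) -> pd.DataFrame:
    """Long-format table: neuron_id, frame, z, y, x, status."""
    rows = []
    for tr in tracks:
        for t in range(tr.n_frames):
            rows.append(
                (tr.neuron_id, t, *tr.centers[t], tr.status[t])
            )
    return pd.DataFrame(rows, columns=["neuron_id", "frame", "z", "y", "x", "status"])


def tracks_from_frame(df: pd.DataFrame, mask_radius: float = 2.0) -> list[NeuronTrack]:
    tracks = []
    for nid, grp in df.groupby("neuron_id", sort=True):
        grp = grp.sort_values("frame")
        tracks.append(
            NeuronTrack(
                neuron_id=int(nid),
                centers=grp[["z", "y", "x"]].to_numpy(float),
                status=list(grp["status"]),
                mask_radius=mask_radius,
            )
        )
    return tracks
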