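"""Tract segmentation with waypoint ROIs, outlier removal, pathway masks.

Named pathways are extracted from a connectome by requiring streamlines to
pass through (or terminate in) two waypoint regions. Topological outliers are
then excluded by two sequential criteria: streamlines whose length deviates
from the tract mean by >= n_sd standard deviations, and streamlines whose
mean distance to the tract core (the node-wise mean after resampling every
streamline to a fixed number of equidistant nodes) deviates by >= n_sd
standard deviations of that distance distribution. The pathway mask — the
union of voxels any tract streamline traverses — restricts the
fascicle-evaluation fit for tract-level model comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Connectome, VoxelGrid
from ._voxel import point_to_voxel, streamline_voxels

__all__ = ["WaypointROI", "segment_tract", "remove_outliers", "pathway_mask", "resample_streamline"]


@dataclass(frozen=True)
class WaypointROI:
    """Binary region used to select streamlines.

    mode 'passthrough' keeps streamlines with any point inside the region;
    'endpoint' requires a terminal point inside it.
    """

    mask: np.ndarray
    mode: str = "passthrough"
    label: str = ""

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        if not m.any():
            raise ValueError("waypoint ROI mask is empty")
        if self.mode not in ("passthrough", "endpoint"):
            raise ValueError(f"unknown ROI mode {self.mode!r}")
        object.__setattr__(self, "mask", m)


def _points_inside(points: np.ndarray, mask: np.ndarray, voxel_size: float) -> np.ndarray:
    ijk = point_to_voxel(points, voxel_size)
    dims = np.asarray(mask.shape)
    valid = np.all((ijk >= 0) & (ijk < dims), axis=1)
    inside = np.zeros(len(points), dtype=bool)
    inside[valid] = mask[tuple(ijk[valid].T)]
    return inside


def segment_tract(
    connectome: Connectome,
    roi_a: WaypointROI,
    roi_b: WaypointROI,
    voxel_size: float,
    label: str = "tract",
) -> Connectome:
    """Select the streamlines connecting two waypoint ROIs.

    In passthrough mode a streamline must have at least one point in each
    ROI; in endpoint mode its first point must lie in one ROI and its last in
    the other (either orientation). The two ROIs must share the same mode.
    """
    if roi_a.mode != roi_b.mode:
        raise ValueError(f"ROI mode mismatch: {roi_a.mode!r} vs {roi_b.mode!r}")
    keep = []
    for i, pts in enumerate(connectome.streamlines):
        in_a = _points_inside(pts, roi_a.mask, voxel_size)
        in_b = _points_inside(pts, roi_b.mask, voxel_size)
        if roi_a.mode == "passthrough":
            hit = in_a.any() and in_b.any()
        else:
            hit = (in_a[0] and in_b[-1]) or (in_b[0] and in_a[-1])
        if hit:
            keep.append(i)
    out = connectome.subset(np.asarray(keep, dtype=int))
    out.label = label
    return out


def resample_streamline(points: np.ndarray, n_nodes: int) -> np.ndarray:
    """Resample a polyline to n_nodes equidistant nodes along its arc length."""
    pts = np.asarray(points, dtype=float)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] == 0:
        return np.repeat(pts[:1], n_nodes, axis=0)
    targets = np.linspace(0.0, s[-1], n_nodes)
    out = np.empty((n_nodes, 3))
    for d in range(3):
        out[:, d] = np.interp(targets, s, pts[:, d])
    return out


def remove_outliers(tract: Connectome, n_sd: float = 3.0, n_nodes: int = 100) -> Connectome:
    """Exclude length and position outliers from a tract (single pass).

    Length criterion first: drop streamlines with |length - mean| >= n_sd
    length-sd. Then resample survivors to ``n_nodes`` nodes, orient them
    consistently, form the node-wise mean core, and drop streamlines whose
    mean node-to-core distance is >= n_sd sd of that distance distribution.
    Zero-sd criteria (e.g. identical streamlines) remove nothing.
    """
    if len(tract) < 3:
        raise ValueError("outlier removal needs at least 3 streamlines")
    lengths = tract.lengths()
    sd_len = float(np.std(lengths))
    if sd_len > 0:
        keep_len = np.abs(lengths - lengths.mean()) < n_sd * sd_len
    else:
        keep_len = np.ones(len(tract), dtype=bool)
    survivors = tract.subset(keep_len)
    if len(survivors) == 0:
        return survivors
    resampled = []
    ref = resample_streamline(survivors.streamlines[0], n_nodes)
    for pts in survivors.streamlines:
        r = resample_streamline(pts, n_nodes)
        if np.linalg.norm(r[0] - ref[0]) > np.linalg.norm(r[::-1][0] - ref[0]):
            r = r[::-1]
        resampled.append(r)
    stack = np.stack(resampled)  # (n, n_nodes, 3)
    core = stack.mean(axis=0)
    dist = np.linalg.norm(stack - core[None], axis=2).mean(axis=1)
    sd_d = float(np.std(dist))
    if sd_d > 0:
        keep_pos = np.abs(dist - dist.mean()) < n_sd * sd_d
    else:
        keep_pos = np.ones(len(survivors), dtype=bool)
    out = survivors.subset(keep_pos)
    out.label = tract.label
    return out


def pathway_mask(tracts: list[Connectome], grid: VoxelGrid) -> np.ndarray:
    """Union of voxels traversed by any streamline of any listed tract."""
    if not tracts or all(len(t) == 0 for t in tracts):
        raise ValueError("all tracts are empty")
    mask = np.zeros(grid.dims, dtype=bool)
    dims = grid.dims
    for t in tracts:
        for pts in t:
            for ijk in streamline_voxels(pts, grid.voxel_size):
                if all(0 <= ijk[a] < dims[a] for a in range(3)):
                    mask[ijk] = True
    return mask
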