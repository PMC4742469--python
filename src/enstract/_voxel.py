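"""Streamline voxelization shared by the fascicle-evaluation model and metrics.

The rule is fixed package-wide: a polyline segment is first split at every
voxel-boundary crossing, and each resulting piece is assigned to the voxel
containing its midpoint. Voxels are ``floor(p / voxel_size)``, 0-based.
"""

from __future__ import annotations

import numpy as np

__all__ = ["point_to_voxel", "segment_pieces", "streamline_voxels"]


def point_to_voxel(points: np.ndarray, voxel_size: float) -> np.ndarray:
    """Map mm coordinates to integer voxel indices (half-open intervals)."""
    return np.floor(np.asarray(points, dtype=float) / voxel_size).astype(int)


def segment_pieces(points: np.ndarray, voxel_size: float):
    """Split a polyline at voxel boundaries.

    Yields ``(ijk, tangent, length)`` per piece: the midpoint voxel index
    (3-tuple), the unit tangent of the parent segment, and the piece length in
    mm. Zero-length segments are skipped.
    """
    pts = np.asarray(points, dtype=float)
    for a, b in zip(pts[:-1], pts[1:]):
        d = b - a
        seg_len = float(np.linalg.norm(d))
        if seg_len == 0.0:
            continue
        tangent = d / seg_len
        # boundary-crossing parameters along the segment, per axis
        ts = [0.0, 1.0]
        for ax in range(3):
            if d[ax] == 0.0:
                continue
            lo, hi = sorted((a[ax], b[ax]))
            first = np.ceil(lo / voxel_size)
            last = np.floor(hi / voxel_size)
            for m in np.arange(first, last + 1):
                t = (m * voxel_size - a[ax]) / d[ax]
                if 0.0 < t < 1.0:
                    ts.append(float(t))
        ts = sorted(set(ts))
        for t0, t1 in zip(ts[:-1], ts[1:]):
            if t1 - t0 <= 0:
                continue
            mid = a + d * (0.5 * (t0 + t1))
            ijk = tuple(int(v) for v in np.floor(mid / voxel_size))
            yield ijk, tangent, seg_len * (t1 - t0)


def streamline_voxels(points: np.ndarray, voxel_size: float) -> set[tuple[int, int, int]]:
    """Set of voxels a streamline traverses under the midpoint rule."""
    return {ijk for ijk, _, _ in segment_pieces(points, voxel_size)}
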