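"""Local streamline tracking over a discrete orientation field.

The tracker generates single-parameter candidate connectomes (SPCs). Its
parameterization mirrors common local tractography practice: step size 0.2 mm,
length bounds 10-200 mm, an amplitude stopping criterion of 0.1, whole-mask
uniform seeding, bidirectional growth from the seed, and a curvature bound
expressed as a minimum radius of curvature. The bound is converted to a
per-step angle threshold by treating two successive steps as equal chords on
the circle of minimum radius:

    max_angle = 2 * arcsin(step_size / (2 * R_min))

so R_min = 0.25/0.5/1/2/4 mm at a 0.2 mm step give 47.2/23.1/11.5/5.7/2.9 deg.

Deterministic mode follows the largest-amplitude admissible orientation.
Probabilistic mode draws trial directions uniformly within the angle cone
around the incoming heading and picks one with probability proportional to a
pseudo fiber-orientation-distribution amplitude — the voxel's discrete
orientations smoothed by an axially symmetric von Mises-Fisher kernel of
configurable concentration. Propagation stops when no trial direction
reaches the amplitude stopping criterion. Orientation lookup is
nearest-voxel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import Connectome, OrientationField
from ._voxel import point_to_voxel

__all__ = ["TrackingParams", "radius_to_angle", "track", "clip_to_roi"]


def radius_to_angle(min_radius_curvature: float, step_size: float) -> float:
    """Per-step angle threshold (deg) equivalent to a minimum radius of curvature.

    Two successive steps of length ``step_size`` are treated as equal chords on
    the circle of radius ``min_radius_curvature``; the turning angle between
    them is ``2*arcsin(step/(2R))``.
    """
    if min_radius_curvature <= 0 or step_size <= 0:
        raise ValueError("min_radius_curvature and step_size must be > 0")
    ratio = step_size / (2.0 * min_radius_curvature)
    if ratio > 1.0:
        raise ValueError(
            "step_size exceeds the diameter of the minimum-radius circle "
            f"(step {step_size} mm, radius {min_radius_curvature} mm)"
        )
    return math.degrees(2.0 * math.asin(ratio))


@dataclass
class TrackingParams:
    """Parameter set defining one single-parameter connectome (SPC)."""

    algorithm: str = "probabilistic"  # or "deterministic"
    step_size: float = 0.2  # mm
    min_radius_curvature: float | None = None  # mm; sets max_angle when given
    max_angle: float | None = None  # deg; derived unless given explicitly
    max_length: float = 200.0  # mm
    min_length: float = 10.0  # mm
    amplitude_stop: float = 0.1
    initial_direction: np.ndarray | None = None
    initial_direction_tolerance: float = 20.0  # deg cone around initial_direction
    n_streamlines: int = 1000
    seed: int = 0
    vmf_kappa: float = 20.0  # pseudo-FOD kernel concentration (lobe sd ~ 13 deg)
    n_trials: int = 60  # trial directions per probabilistic step
    attempt_factor: int = 50  # attempt budget = attempt_factor * n_streamlines
    label: str | None = None

    def __post_init__(self) -> None:
        if self.algorithm not in ("deterministic", "probabilistic"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.step_size <= 0:
            raise ValueError("step_size must be > 0")
        if not (0 < self.min_length < self.max_length):
            raise ValueError("need 0 < min_length < max_length")
        if self.min_radius_curvature is not None:
            derived = radius_to_angle(self.min_radius_curvature, self.step_size)
            if self.max_angle is not None and abs(self.max_angle - derived) > 1e-6:
                raise ValueError(
                    "max_angle inconsistent with min_radius_curvature "
                    f"({self.max_angle} vs derived {derived})"
                )
            self.max_angle = derived
        elif self.max_angle is None:
            self.max_angle = 90.0
        if self.label is None:
            if self.min_radius_curvature is not None:
                self.label = f"{self.algorithm}:r{self.min_radius_curvature:g}mm"
            else:
                self.label = f"{self.algorithm}:a{self.max_angle:g}deg"


def _uniform_in_cone(axis: np.ndarray, cos_max: float, n: int,
                     rng: np.random.Generator) -> np.ndarray:
    """n unit vectors uniform over the spherical cap of half-angle acos(cos_max)."""
    w = rng.uniform(cos_max, 1.0, size=n)
    phi = rng.uniform(0.0, 2.0 * math.pi, size=n)
    r = np.sqrt(np.clip(1.0 - w**2, 0.0, None))
    local = np.stack([r * np.cos(phi), r * np.sin(phi), w], axis=1)
    # orthonormal frame with axis as third column
    a = np.array([1.0, 0.0, 0.0]) if abs(axis[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    frame = np.stack([e1, e2, axis], axis=1)
    return local @ frame.T


def _pseudo_fod(cands: np.ndarray, dirs: np.ndarray, amps: np.ndarray,
                kappa: float) -> np.ndarray:
    """Amplitude of the vMF-kernel pseudo-FOD at each candidate direction.

    Each discrete orientation contributes an axially symmetric lobe of peak
    height equal to its amplitude: amp * exp(kappa * (|u.t| - 1)).
    """
    return (amps[None, :] * np.exp(kappa * (np.abs(cands @ dirs.T) - 1.0))).sum(axis=1)


def _grow(
    field: OrientationField,
    pos: np.ndarray,
    direction: np.ndarray,
    params: TrackingParams,
    cos_max: float,
    max_steps: int,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """Propagate one half-streamline; returns the list of points after ``pos``."""
    points: list[np.ndarray] = []
    vs = field.grid.voxel_size
    dims = np.asarray(field.grid.dims)
    d = direction
    for _ in range(max_steps):
        ijk = np.floor(pos / vs).astype(int)
        if np.any(ijk < 0) or np.any(ijk >= dims):
            break
        dirs, amps = field.orientations(ijk)
        if dirs.shape[0] == 0:
            break  # outside the mask
        if params.algorithm == "deterministic":
            dots = dirs @ d
            aligned = np.where(dots[:, None] < 0, -dirs, dirs)
            admissible = (np.abs(dots) >= cos_max - 1e-12) & (amps >= params.amplitude_stop)
            if not np.any(admissible):
                break
            idx = np.flatnonzero(admissible)
            new_d = aligned[idx[np.argmax(amps[idx])]]
        else:
            cands = _uniform_in_cone(d, cos_max, params.n_trials, rng)
            fod = _pseudo_fod(cands, dirs, amps, params.vmf_kappa)
            ok = fod >= params.amplitude_stop
            if not np.any(ok):
                break  # amplitude stopping criterion
            p = np.where(ok, fod, 0.0)
            p = p / p.sum()
            new_d = cands[rng.choice(params.n_trials, p=p)]
        pos = pos + params.step_size * new_d
        points.append(pos.copy())
        d = new_d
    return points


def track(field: OrientationField, params: TrackingParams) -> Connectome:
    """Generate one single-parameter candidate connectome.

    Seeds are drawn uniformly over masked voxels (uniform position within the
    voxel); growth is bidirectional from the seed and the two halves are
    concatenated with the seed-side reversed. Streamlines shorter than
    ``min_length`` are discarded and re-seeded. Raises if the attempt budget
    is exhausted before ``n_streamlines`` are retained.
    """
    voxels = [v for v in field.voxels()
              if np.any(field.orientations(v)[1] >= params.amplitude_stop)]
    if not voxels:
        raise ValueError("no masked voxel passes the amplitude stopping criterion")
    rng = np.random.default_rng(params.seed)
    vs = field.grid.voxel_size
    cos_max = math.cos(math.radians(params.max_angle))
    max_steps = int(math.floor(params.max_length / params.step_size / 2.0))
    cos_init = math.cos(math.radians(params.initial_direction_tolerance))
    init_dir = None
    if params.initial_direction is not None:
        init_dir = np.asarray(params.initial_direction, dtype=float)
        init_dir = init_dir / np.linalg.norm(init_dir)

    kept: list[np.ndarray] = []
    budget = params.attempt_factor * params.n_streamlines
    attempts = 0
    voxel_arr = np.asarray(voxels)
    while len(kept) < params.n_streamlines:
        if attempts >= budget:
            raise RuntimeError(
                f"could not generate {params.n_streamlines} streamlines within "
                f"{budget} attempts ({len(kept)} retained)"
            )
        attempts += 1
        ijk = voxel_arr[rng.integers(len(voxel_arr))]
        seed_pos = (ijk + rng.uniform(0.0, 1.0, size=3)) * vs
        dirs, amps = field.orientations(ijk)
        ok = amps >= params.amplitude_stop
        if not np.any(ok):
            continue
        idx = np.flatnonzero(ok)
        d0 = dirs[idx[rng.integers(len(idx))]].copy()
        if rng.uniform() < 0.5:
            d0 = -d0
        if init_dir is not None and abs(np.dot(d0, init_dir)) < cos_init:
            continue  # seed orientation outside the requested initial cone
        fwd = _grow(field, seed_pos, d0, params, cos_max, max_steps, rng)
        # constrain the seed-side half by the first forward step so the
        # junction angle also respects the curvature bound
        if fwd:
            back_d = -(fwd[0] - seed_pos)
            back_d /= np.linalg.norm(back_d)
        else:
            back_d = -d0
        bwd = _grow(field, seed_pos, back_d, params, cos_max, max_steps, rng)
        pts = np.array(list(reversed(bwd)) + [seed_pos] + fwd)
        if pts.shape[0] < 2:
            continue
        if params.step_size * (pts.shape[0] - 1) < params.min_length:
            continue
        kept.append(pts)
    return Connectome(kept, provenance=params.label, label=params.label)


def clip_to_roi(connectome: Connectome, roi_mask: np.ndarray, voxel_size: float) -> Connectome:
    """Cut streamlines to maximal sub-polylines lying inside an ROI mask.

    Points are assigned to voxels by the floor rule; runs of consecutive
    inside points with at least two points become output streamlines.
    Provenance labels are preserved.
    """
    roi = np.asarray(roi_mask, dtype=bool)
    if not roi.any():
        raise ValueError("ROI mask is empty")
    dims = np.asarray(roi.shape)
    out_lines: list[np.ndarray] = []
    out_prov: list[str] = []
    for pts, prov in zip(connectome.streamlines, connectome.provenance):
        ijk = point_to_voxel(pts, voxel_size)
        valid = np.all((ijk >= 0) & (ijk < dims), axis=1)
        inside = np.zeros(len(pts), dtype=bool)
        inside[valid] = roi[tuple(ijk[valid].T)]
        # split into maximal runs of inside points
        start = None
        for i, flag in enumerate(list(inside) + [False]):
            if flag and start is None:
                start = i
            elif not flag and start is not None:
                if i - start >= 2:
                    out_lines.append(pts[start:i].copy())
                    out_prov.append(prov)
                start = None
    return Connectome(out_lines, out_prov, label=connectome.label + ":clipped")
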