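"""Shared domain containers for diffusion data, orientation fields and connectomes.

Coordinate convention used throughout the package: streamline points are in
millimetres, the phantom affine is the identity scaled by the voxel size, and a
point ``p`` belongs to voxel ``floor(p / voxel_size)`` (0-based, half-open
voxel intervals).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GradientTable",
    "VoxelGrid",
    "OrientationField",
    "DWIDataset",
    "Connectome",
]

_UNIT_TOL = 1e-6


@dataclass(frozen=True)
class GradientTable:
    """Single-shell diffusion gradient scheme.

    Parameters
    ----------
    directions : (N, 3) array
        Unit gradient directions (dimensionless).
    b_value : float
        Diffusion weighting shared by all directions, in s/mm^2.
    """

    directions: np.ndarray
    b_value: float

    def __post_init__(self) -> None:
        dirs = np.atleast_2d(np.asarray(self.directions, dtype=float))
        if dirs.ndim != 2 or dirs.shape[1] != 3:
            raise ValueError("directions must be an (N, 3) array")
        norms = np.linalg.norm(dirs, axis=1)
        if np.any(np.abs(norms - 1.0) > _UNIT_TOL):
            raise ValueError("all gradient directions must be unit vectors")
        if not np.isfinite(self.b_value) or self.b_value <= 0:
            raise ValueError("b_value must be a positive scalar (single shell)")
        object.__setattr__(self, "directions", dirs)

    @property
    def n_directions(self) -> int:
        return self.directions.shape[0]


@dataclass(frozen=True)
class VoxelGrid:
    """Isotropic voxel lattice: integer dims and edge length in mm."""

    dims: tuple[int, int, int]
    voxel_size: float

    def __post_init__(self) -> None:
        dims = tuple(int(d) for d in self.dims)
        if len(dims) != 3 or any(d < 1 for d in dims):
            raise ValueError("dims must be three integers >= 1")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        object.__setattr__(self, "dims", dims)

    @property
    def extent_mm(self) -> np.ndarray:
        return np.asarray(self.dims, dtype=float) * self.voxel_size

    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0] = aff[1, 1] = aff[2, 2] = self.voxel_size
        return aff

    def contains(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(ijk)
        dims = np.asarray(self.dims)
        return np.all((ijk >= 0) & (ijk < dims), axis=1)


class OrientationField:
    """Per-voxel discrete set of fiber orientations with amplitudes.

    This is the quantity the local tracker consumes in place of a continuous
    fiber orientation distribution: each masked voxel carries a short list of
    unit orientations with non-negative amplitudes (interpreted as the signal
    fraction of the corresponding fiber population).
    """

    def __init__(self, grid: VoxelGrid) -> None:
        self.grid = grid
        self._entries: dict[tuple[int, int, int], tuple[np.ndarray, np.ndarray]] = {}

    def add(self, ijk: Sequence[int], orientation: np.ndarray, amplitude: float) -> None:
        ijk = tuple(int(v) for v in ijk)
        if not self.grid.contains(np.asarray(ijk))[0]:
            raise ValueError(f"voxel {ijk} outside grid {self.grid.dims}")
        o = np.asarray(orientation, dtype=float)
        n = np.linalg.norm(o)
        if abs(n - 1.0) > _UNIT_TOL:
            if n == 0:
                raise ValueError("orientation must be a nonzero vector")
            o = o / n
        if amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        dirs, amps = self._entries.get(ijk, (np.empty((0, 3)), np.empty(0)))
        self._entries[ijk] = (
            np.vstack([dirs, o[None, :]]),
            np.append(amps, float(amplitude)),
        )

    def orientations(self, ijk: Sequence[int]) -> tuple[np.ndarray, np.ndarray]:
        """Return (directions, amplitudes) at a voxel; empty arrays outside mask."""
        return self._entries.get(tuple(int(v) for v in ijk), (np.empty((0, 3)), np.empty(0)))

    @property
    def mask(self) -> np.ndarray:
        m = np.zeros(self.grid.dims, dtype=bool)
        for ijk in self._entries:
            m[ijk] = True
        return m

    def voxels(self) -> list[tuple[int, int, int]]:
        return sorted(self._entries)

    def __len__(self) -> int:
        return len(self._entries)


@dataclass
class DWIDataset:
    """One diffusion acquisition repeat: masked 4-D signal plus geometry.

    ``signal`` is voxel-indexed ``(nx, ny, nz, n_directions)``; ``b0`` is the
    (averaged) non-diffusion-weighted volume used as the per-voxel signal
    scale.
    """

    signal: np.ndarray
    b0: np.ndarray
    mask: np.ndarray
    gradients: GradientTable
    grid: VoxelGrid
    repeat_id: int = 1

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.b0 = np.asarray(self.b0, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.signal.shape != (*self.grid.dims, self.gradients.n_directions):
            raise ValueError(
                "signal shape inconsistent with grid dims and n_directions: "
                f"{self.signal.shape} vs {(*self.grid.dims, self.gradients.n_directions)}"
            )
        if self.b0.shape != self.grid.dims or self.mask.shape != self.grid.dims:
            raise ValueError("b0/mask shape inconsistent with grid dims")
        if np.any(self.signal[self.mask] < 0):
            raise ValueError("signal must be >= 0 inside the mask")


class Connectome:
    """A set of streamlines with provenance labels and optional weights.

    Streamlines are (k, 3) float arrays of mm coordinates. ``provenance``
    records which parameter set / algorithm generated each streamline (one
    label per streamline). ``weights``, when present, are the non-negative
    per-streamline contributions assigned by the fascicle-evaluation fit.
    """

    def __init__(
        self,
        streamlines: Iterable[np.ndarray],
        provenance: Sequence[str] | str = "unknown",
        weights: np.ndarray | None = None,
        label: str = "",
    ) -> None:
        self.streamlines = [np.asarray(s, dtype=float).reshape(-1, 3) for s in streamlines]
        if isinstance(provenance, str):
            self.provenance = [provenance] * len(self.streamlines)
        else:
            self.provenance = list(provenance)
        if len(self.provenance) != len(self.streamlines):
            raise ValueError("provenance must align one-to-one with streamlines")
        self.label = label
        self.weights: np.ndarray | None = None
        if weights is not None:
            self.set_weights(weights)

    def set_weights(self, weights: np.ndarray) -> None:
        w = np.asarray(weights, dtype=float).ravel()
        if w.shape[0] != len(self.streamlines):
            raise ValueError(
                f"weights length {w.shape[0]} does not match {len(self.streamlines)} streamlines"
            )
        if np.any(w < 0):
            raise ValueError("weights must be >= 0")
        self.weights = w

    def __len__(self) -> int:
        return len(self.streamlines)

    def __iter__(self):
        return iter(self.streamlines)

    def subset(self, indices: np.ndarray) -> "Connectome":
        indices = np.asarray(indices)
        if indices.dtype == bool:
            indices = np.flatnonzero(indices)
        return Connectome(
            [self.streamlines[i] for i in indices],
            [self.provenance[i] for i in indices],
            None if self.weights is None else self.weights[indices],
            label=self.label,
        )

    def provenance_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for p in self.provenance:
            counts[p] = counts.get(p, 0) + 1
        return counts

    def lengths(self) -> np.ndarray:
        """Arc length of every streamline, in mm."""
        return np.array(
            [np.sum(np.linalg.norm(np.diff(s, axis=0), axis=1)) for s in self.streamlines]
        )
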