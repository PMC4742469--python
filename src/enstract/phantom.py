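"""Synthetic diffusion phantom: ground-truth bundles, orientation fields, signals.

The phantom emulates the structure of a two-repeat, single-shell acquisition:
a 1.5 mm isotropic voxel grid, 96 gradient directions at b = 2000 s/mm^2, and
fiber populations spanning long low-curvature bundles and short high-curvature
(U-shaped) bundles, including crossing-fiber voxels. The forward model is a
stick-and-ball mixture: per voxel

    S(g) = S0 * [ f_iso * exp(-b * d_iso) + sum_k f_k * exp(-b * lambda * (g.t_k)^2) ]

with additive Gaussian noise of fixed standard deviation on each repeat.
Repeats share the noiseless signal and differ only in the noise realization.

Defaults: axial (stick) diffusivity lambda = 1.7e-3 mm^2/s and isotropic
diffusivity d_iso = 3.0e-3 mm^2/s, conventional values for white matter and
free water at b = 2000 s/mm^2; both are configurable. The noise model is
additive Gaussian, not Rician (a Rician generator would be a straightforward
extension point but the accuracy metrics assume equal-variance additive
residuals).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import Connectome, DWIDataset, GradientTable, OrientationField, VoxelGrid
from ._voxel import point_to_voxel, segment_pieces

__all__ = [
    "BundleSpec",
    "make_gradient_table",
    "simulate_signal",
    "make_phantom",
    "mixed_phantom",
    "MixedPhantom",
    "DEFAULT_AXIAL_DIFFUSIVITY",
    "DEFAULT_ISO_DIFFUSIVITY",
]

DEFAULT_AXIAL_DIFFUSIVITY = 1.7e-3  # mm^2/s, stick compartment
DEFAULT_ISO_DIFFUSIVITY = 3.0e-3  # mm^2/s, free-water ball
DEFAULT_STEP_MM = 0.2  # ground-truth centerline sampling, matches the tracker


@dataclass(frozen=True)
class BundleSpec:
    """Geometric description of one fiber bundle.

    shape: 'straight' (line from start to end), 'arc' (minor circular arc of
    the given radius through start and end, bulging toward +n where
    n = z x (end-start)), or 'u_turn' (semicircle whose diameter is the
    start-end chord). radius_of_curvature is in mm (inf for straight).
    signal_fraction is the stick volume fraction this bundle contributes in
    each voxel it occupies.
    """

    shape: str
    start: tuple[float, float, float]
    end: tuple[float, float, float]
    radius_of_curvature: float = math.inf
    n_fibers: int = 10
    signal_fraction: float = 0.5
    label: str = ""

    def __post_init__(self) -> None:
        if self.shape not in ("straight", "arc", "u_turn"):
            raise ValueError(f"unknown bundle shape {self.shape!r}")
        if not (self.radius_of_curvature > 0):
            raise ValueError("radius_of_curvature must be > 0 (inf for straight)")
        if not (0.0 <= self.signal_fraction <= 1.0):
            raise ValueError("signal_fraction must lie in [0, 1]")
        if self.n_fibers < 1:
            raise ValueError("n_fibers must be >= 1")
        if not self.label:
            object.__setattr__(self, "label", f"truth:{self.shape}")


def make_gradient_table(n_directions: int = 96, b_value: float = 2000.0) -> GradientTable:
    """Deterministic single-shell scheme: golden-spiral points on a hemisphere."""
    i = np.arange(n_directions)
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i  # golden angle
    z = (i + 0.5) / n_directions  # upper hemisphere only
    r = np.sqrt(1.0 - z**2)
    dirs = np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)
    return GradientTable(dirs, b_value)


def _centerline(bundle: BundleSpec, step: float) -> np.ndarray:
    s = np.asarray(bundle.start, dtype=float)
    e = np.asarray(bundle.end, dtype=float)
    chord = e - s
    d = np.linalg.norm(chord)
    if d == 0:
        raise ValueError("bundle start and end coincide")
    if bundle.shape == "straight":
        n = max(2, int(round(d / step)) + 1)
        return s + np.linspace(0.0, 1.0, n)[:, None] * chord
    u = chord / d
    n_hat = np.cross([0.0, 0.0, 1.0], u)
    nn = np.linalg.norm(n_hat)
    if nn < 1e-9:
        raise ValueError("arc bundles must not have a chord parallel to z")
    n_hat = n_hat / nn
    if bundle.shape == "u_turn":
        radius = d / 2.0
        center = (s + e) / 2.0
        # semicircle from s to e bulging toward +n_hat
        a0 = math.pi
        a1 = 0.0
    else:  # minor arc through s and e, bulging toward -n_hat
        radius = bundle.radius_of_curvature
        if radius < d / 2.0:
            raise ValueError("arc radius must be >= half the start-end distance")
        h = math.sqrt(radius**2 - (d / 2.0) ** 2)
        center = (s + e) / 2.0 + h * n_hat
        a0 = math.atan2(-h, -d / 2.0)
        a1 = math.atan2(-h, d / 2.0)
    # local frame: x-axis = u, y-axis = n_hat (s at angle a0, e at a1)
    n_pts = max(4, int(round(abs(a1 - a0) * radius / step)) + 1)
    ang = np.linspace(a0, a1, n_pts)
    pts = center[None, :] + radius * (
        np.cos(ang)[:, None] * u[None, :] + np.sin(ang)[:, None] * n_hat[None, :]
    )
    return pts


def _fiber_lines(bundle: BundleSpec, step: float, rng: np.random.Generator,
                 jitter_mm: float = 0.4) -> list[np.ndarray]:
    """n_fibers jittered copies of the centerline (rigid perpendicular offsets)."""
    center = _centerline(bundle, step)
    t0 = center[1] - center[0]
    t0 /= np.linalg.norm(t0)
    # two directions perpendicular to the initial tangent
    p1 = np.cross(t0, [0.0, 0.0, 1.0])
    if np.linalg.norm(p1) < 1e-9:
        p1 = np.cross(t0, [0.0, 1.0, 0.0])
    p1 /= np.linalg.norm(p1)
    p2 = np.cross(t0, p1)
    fibers = [center.copy()]
    for _ in range(bundle.n_fibers - 1):
        off = rng.uniform(-jitter_mm, jitter_mm, size=2)
        fibers.append(center + off[0] * p1 + off[1] * p2)
    return fibers


def simulate_signal(
    field: OrientationField,
    gradients: GradientTable,
    s0: float = 100.0,
    axial_diffusivity: float = DEFAULT_AXIAL_DIFFUSIVITY,
    iso_fraction: float = 0.3,
    iso_diffusivity: float = DEFAULT_ISO_DIFFUSIVITY,
    noise_sd: float = 0.0,
    seed: int = 0,
    repeat_id: int = 1,
) -> DWIDataset:
    """Stick-and-ball forward simulation of one acquisition repeat.

    Orientation amplitudes are taken as stick signal fractions. Noise is
    additive Gaussian with standard deviation ``noise_sd`` on every
    diffusion-weighted measurement; the b0 volume receives noise reduced by
    sqrt(10), emulating an average over ten b=0 acquisitions. Deterministic
    for a fixed ``seed``; signal is clipped at zero.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if len(field) == 0:
        raise ValueError("orientation field has an empty mask")
    grid = field.grid
    G = gradients.directions
    b = gradients.b_value
    signal = np.zeros((*grid.dims, gradients.n_directions))
    b0 = np.zeros(grid.dims)
    mask = np.zeros(grid.dims, dtype=bool)
    ball = iso_fraction * math.exp(-b * iso_diffusivity)
    for ijk in field.voxels():
        dirs, amps = field.orientations(ijk)
        att = ball + (amps[None, :] * np.exp(
            -b * axial_diffusivity * (G @ dirs.T) ** 2
        )).sum(axis=1)
        signal[ijk] = s0 * att
        b0[ijk] = s0
        mask[ijk] = True
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        signal = signal + rng.normal(0.0, noise_sd, size=signal.shape)
        b0 = b0 + rng.normal(0.0, noise_sd / math.sqrt(10.0), size=b0.shape)
    signal[~mask] = 0.0
    b0[~mask] = 0.0
    np.clip(signal, 0.0, None, out=signal)
    return DWIDataset(signal, b0, mask, gradients, grid, repeat_id=repeat_id)


def _build_field(bundles, grid: VoxelGrid, fibers_per_bundle, step: float,
                 orientation_bin_deg: float = 10.0) -> OrientationField:
    """Accumulate per-voxel orientations, binning tangents within each bundle.

    A curved fascicle spans a range of tangents inside a coarse voxel, so one
    voxel may legitimately carry several orientation entries from the same
    bundle: tangents are greedily clustered at ``orientation_bin_deg``
    (sign-aligned, length-weighted means) and the bundle's signal fraction is
    split across clusters in proportion to the fiber length they represent.
    """
    cos_bin = math.cos(math.radians(orientation_bin_deg))
    # per voxel, per bundle: list of [weighted direction sum, total length]
    per_voxel: dict[tuple[int, int, int], dict[int, list[list]]] = {}
    for bi, (bundle, fibers) in enumerate(zip(bundles, fibers_per_bundle)):
        for line in fibers:
            ijks = point_to_voxel(line, grid.voxel_size)
            if np.any(~grid.contains(ijks)):
                raise ValueError(f"bundle {bundle.label!r} does not fit inside the grid")
            for ijk, tangent, length in segment_pieces(line, grid.voxel_size):
                clusters = per_voxel.setdefault(ijk, {}).setdefault(bi, [])
                placed = False
                for c in clusters:
                    mean = c[0] / np.linalg.norm(c[0])
                    d = float(np.dot(mean, tangent))
                    if abs(d) >= cos_bin:
                        c[0] = c[0] + length * (tangent if d >= 0 else -tangent)
                        c[1] += length
                        placed = True
                        break
                if not placed:
                    clusters.append([length * tangent, length])
    field = OrientationField(grid)
    for ijk, slot in per_voxel.items():
        total = sum(bundles[bi].signal_fraction for bi in slot)
        if total > 1.0 + 1e-9:
            raise ValueError(
                f"bundle signal fractions sum to {total:.3f} > 1 in voxel {ijk}"
            )
        for bi, clusters in slot.items():
            lengths = np.array([c[1] for c in clusters])
            shares = lengths / lengths.sum()
            for c, share in zip(clusters, shares):
                field.add(ijk, c[0] / np.linalg.norm(c[0]),
                          bundles[bi].signal_fraction * float(share))
    return field


def make_phantom(
    bundles: list[BundleSpec],
    grid: VoxelGrid,
    gradients: GradientTable,
    noise_sd: float = 0.5,
    seed: int = 0,
    s0: float = 100.0,
    iso_fraction: float = 0.3,
    axial_diffusivity: float = DEFAULT_AXIAL_DIFFUSIVITY,
    step: float = DEFAULT_STEP_MM,
    orientation_bin_deg: float = 10.0,
) -> tuple[DWIDataset, DWIDataset, OrientationField, Connectome]:
    """Build a two-repeat phantom from bundle geometry.

    Returns (repeat 1, repeat 2, orientation field, ground-truth connectome).
    The orientation field is tangent to the bundle centerlines; ground-truth
    streamlines are the jittered fiber lines resampled at the tracking step
    size so curvature analytics are comparable between truth and tracked sets.
    The two repeats share the noiseless signal and differ only in noise.
    """
    if not bundles:
        raise ValueError("at least one bundle is required")
    ss = np.random.SeedSequence(seed)
    geom_seed, noise1, noise2 = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3))
    rng = np.random.default_rng(geom_seed)
    fibers_per_bundle = [_fiber_lines(b, step, rng) for b in bundles]
    field = _build_field(bundles, grid, fibers_per_bundle, step,
                         orientation_bin_deg=orientation_bin_deg)
    truth = Connectome(
        [f for fibers in fibers_per_bundle for f in fibers],
        [b.label for b, fibers in zip(bundles, fibers_per_bundle) for _ in fibers],
        label="ground-truth",
    )
    common = dict(
        s0=s0,
        axial_diffusivity=axial_diffusivity,
        iso_fraction=iso_fraction,
        noise_sd=noise_sd,
    )
    rep1 = simulate_signal(field, gradients, seed=noise1, repeat_id=1, **common)
    rep2 = simulate_signal(field, gradients, seed=noise2, repeat_id=2, **common)
    return rep1, rep2, field, truth


@dataclass
class MixedPhantom:
    """The standard mixed-curvature test phantom with named tract ROIs."""

    repeat1: DWIDataset
    repeat2: DWIDataset
    field: OrientationField
    truth: Connectome
    grid: VoxelGrid
    bundles: list[BundleSpec]
    straight_roi_a: np.ndarray = field(default=None)  # type: ignore[assignment]
    straight_roi_b: np.ndarray = field(default=None)  # type: ignore[assignment]
    u_roi_a: np.ndarray = field(default=None)  # type: ignore[assignment]
    u_roi_b: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def mask(self) -> np.ndarray:
        return self.repeat1.mask


def _endpoint_roi(grid: VoxelGrid, point_mm, radius_vox: int = 1) -> np.ndarray:
    roi = np.zeros(grid.dims, dtype=bool)
    c = point_to_voxel(np.asarray(point_mm)[None, :], grid.voxel_size)[0]
    lo = np.maximum(c - radius_vox, 0)
    hi = np.minimum(c + radius_vox + 1, grid.dims)
    roi[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = True
    return roi


def mixed_phantom(
    seed: int = 0,
    noise_sd: float = 0.5,
    n_directions: int = 96,
    b_value: float = 2000.0,
    n_fibers: int = 10,
) -> MixedPhantom:
    """Standard phantom mixing long straight, crossing, and U-shaped bundles.

    Geometry (1.5 mm isotropic voxels, 20 x 14 x 3 grid):

    * a long bundle along x (22 mm straight core) ending in a curved hook of
      2.5 mm radius — a long-range pathway mixing straight and curved
      sections, like major association fascicles,
    * a second straight bundle along y crossing it (crossing-fiber voxels),
    * a U-shaped bundle of radius 3 mm with short straight legs (high
      curvature, short range, connecting two nearby "gyri").

    Traversing the 3 mm-radius U requires a sustained turn of about 3.8
    degrees per 0.2 mm step, delivered through voxels whose orientation sets
    are tangent clusters about 10 degrees apart; trackers whose per-step
    angle threshold is below that spacing (minimum radius of curvature 2 mm
    or more) cannot follow it, while more lenient bounds can — mirroring the
    short-range/long-range contrast between strict and lenient curvature
    settings.

    The default noise level (sd 0.5 on a b0 signal of 100, i.e. an averaged
    high-SNR acquisition) keeps the cross-validated error dominated by model
    structure rather than measurement noise at this small grid size.
    """
    grid = VoxelGrid((20, 14, 3), 1.5)
    z = 2.25  # middle slice
    straight = BundleSpec("straight", (2.0, 10.6, z), (24.0, 10.6, z),
                          n_fibers=n_fibers, signal_fraction=0.5, label="truth:straight")
    hook = BundleSpec("arc", (24.0, 10.6, z), (26.5, 13.1, z),
                      radius_of_curvature=2.5, n_fibers=n_fibers,
                      signal_fraction=0.5, label="truth:hook")
    crossing = BundleSpec("straight", (8.3, 2.0, z), (8.3, 19.0, z),
                          n_fibers=n_fibers, signal_fraction=0.5, label="truth:crossing")
    u_turn = BundleSpec("u_turn", (19.6, 3.2, z), (25.6, 3.2, z),
                        radius_of_curvature=3.0, n_fibers=n_fibers,
                        signal_fraction=0.5, label="truth:u_turn")
    u_leg_a = BundleSpec("straight", (19.6, 0.7, z), (19.6, 3.2, z),
                         n_fibers=n_fibers, signal_fraction=0.5,
                         label="truth:u_leg_a")
    u_leg_b = BundleSpec("straight", (25.6, 0.7, z), (25.6, 3.2, z),
                         n_fibers=n_fibers, signal_fraction=0.5,
                         label="truth:u_leg_b")
    bundles = [straight, hook, crossing, u_turn, u_leg_a, u_leg_b]
    gradients = make_gradient_table(n_directions, b_value)
    rep1, rep2, fld, truth = make_phantom(bundles, grid, gradients,
                                          noise_sd=noise_sd, seed=seed)
    return MixedPhantom(
        rep1, rep2, fld, truth, grid, bundles,
        straight_roi_a=_endpoint_roi(grid, straight.start),
        straight_roi_b=_endpoint_roi(grid, hook.end),
        u_roi_a=_endpoint_roi(grid, u_leg_a.start, radius_vox=0),
        u_roi_b=_endpoint_roi(grid, u_leg_b.start, radius_vox=0),
    )
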