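"""Connectome accuracy and coverage statistics.

Model accuracy is measured by cross-validation against a second, independent
acquisition repeat. Per voxel, over the N gradient directions:

    M_rmse = sqrt( sum_i (m(theta_i) - S2(theta_i))^2 / N )   model error
    D_rmse = sqrt( sum_i (S1(theta_i) - S2(theta_i))^2 / N )  test-retest error
    R_rmse = M_rmse / D_rmse                                  relative error

R_rmse = 1 means the model predicts the held-out repeat as accurately as the
data's own test-retest reliability; the theoretical floor for an ideal
predictor under equal-variance additive noise is 1/sqrt(2) ~ 0.707. All RMSEs
are computed on demeaned signals by default, consistent with the fitted
quantity (set ``demeaned=False`` for raw signals). The headline summary is
the median of per-voxel R_rmse.

When no second repeat exists, a non-cross-validated fallback scores the
prediction against the fitting repeat itself; such reports are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Connectome, DWIDataset
from .life import DesignMatrix, build_design_matrix, demean_signal, fit_nnls, predict, optimized_connectome
from ._voxel import streamline_voxels

__all__ = [
    "AccuracyReport",
    "model_rmse",
    "data_rmse",
    "r_rmse",
    "single_repeat_rmse",
    "coverage",
    "density_histogram",
    "compare_models",
    "evaluate_on_mask",
]

VoxelMap = dict[tuple[int, int, int], float]


@dataclass
class AccuracyReport:
    """Per-voxel accuracy and global statistics for one connectome model."""

    per_voxel_m_rmse: VoxelMap
    per_voxel_d_rmse: VoxelMap
    per_voxel_r_rmse: VoxelMap
    median_r_rmse: float
    coverage: float
    n_supported: int
    density_histogram: dict[int, int]
    model_label: str = ""
    n_excluded_voxels: int = 0  # D_rmse == 0 voxels dropped from the ratio
    cross_validated: bool = True


def _per_voxel_rmse(a: np.ndarray, b: np.ndarray, voxels: list, n_dirs: int) -> VoxelMap:
    res = (a - b).reshape(len(voxels), n_dirs)
    vals = np.sqrt(np.mean(res**2, axis=1))
    return {v: float(x) for v, x in zip(voxels, vals)}


def _demeaned_vector(ds: DWIDataset, fit_mask: np.ndarray, demeaned: bool):
    fit_mask = np.asarray(fit_mask, dtype=bool)
    voxels = [tuple(v) for v in np.argwhere(fit_mask)]
    parts = []
    for v in voxels:
        s = ds.signal[v]
        parts.append(s - s.mean() if demeaned else s)
    return (np.concatenate(parts) if parts else np.empty(0)), voxels


def model_rmse(
    prediction: np.ndarray,
    held_out: DWIDataset,
    fit_mask: np.ndarray,
    demeaned: bool = True,
) -> VoxelMap:
    """Per-voxel RMSE between a model prediction and the held-out repeat."""
    y2, voxels = _demeaned_vector(held_out, fit_mask, demeaned)
    prediction = np.asarray(prediction, dtype=float).ravel()
    if prediction.shape[0] != y2.shape[0]:
        raise ValueError(
            f"prediction length {prediction.shape[0]} does not match {y2.shape[0]} rows"
        )
    return _per_voxel_rmse(prediction, y2, voxels, held_out.gradients.n_directions)


def data_rmse(
    repeat1: DWIDataset,
    repeat2: DWIDataset,
    fit_mask: np.ndarray,
    demeaned: bool = True,
) -> VoxelMap:
    """Per-voxel test-retest RMSE between two acquisition repeats."""
    if repeat1.gradients.n_directions != repeat2.gradients.n_directions or not np.allclose(
        repeat1.gradients.directions, repeat2.gradients.directions
    ):
        raise ValueError("repeats have mismatched gradient tables")
    y1, voxels = _demeaned_vector(repeat1, fit_mask, demeaned)
    y2, _ = _demeaned_vector(repeat2, fit_mask, demeaned)
    return _per_voxel_rmse(y1, y2, voxels, repeat1.gradients.n_directions)


def r_rmse(m_rmse: VoxelMap, d_rmse: VoxelMap) -> tuple[VoxelMap, float, int]:
    """Per-voxel ratio M_rmse/D_rmse plus the median across voxels.

    Voxels with zero test-retest error are excluded; returns the per-voxel
    map, the median, and the excluded-voxel count. Raises if every voxel is
    excluded.
    """
    if set(m_rmse) != set(d_rmse):
        raise ValueError("M_rmse and D_rmse cover different voxel sets")
    ratios: VoxelMap = {}
    excluded = 0
    for v, m in m_rmse.items():
        d = d_rmse[v]
        if d == 0:
            excluded += 1
            continue
        ratios[v] = m / d
    if not ratios:
        raise ValueError("all voxels have zero test-retest error; R_rmse undefined")
    return ratios, float(np.median(list(ratios.values()))), excluded


def single_repeat_rmse(
    prediction: np.ndarray,
    repeat1: DWIDataset,
    fit_mask: np.ndarray,
    demeaned: bool = True,
) -> VoxelMap:
    """Non-cross-validated RMSE against the fitting repeat itself."""
    return model_rmse(prediction, repeat1, fit_mask, demeaned=demeaned)


def coverage(connectome: Connectome, mask: np.ndarray, voxel_size: float) -> float:
    """Fraction of mask voxels traversed by at least one streamline."""
    mask = np.asarray(mask, dtype=bool)
    n_mask = int(mask.sum())
    if n_mask == 0:
        raise ValueError("empty mask")
    covered: set[tuple[int, int, int]] = set()
    dims = mask.shape
    for pts in connectome:
        for ijk in streamline_voxels(pts, voxel_size):
            if all(0 <= ijk[a] < dims[a] for a in range(3)) and mask[ijk]:
                covered.add(ijk)
    return len(covered) / n_mask


def density_histogram(
    connectome: Connectome, mask: np.ndarray, voxel_size: float
) -> dict[int, int]:
    """Histogram over mask voxels of per-voxel distinct-streamline counts."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    dims = mask.shape
    counts = np.zeros(dims, dtype=int)
    for pts in connectome:
        for ijk in streamline_voxels(pts, voxel_size):
            if all(0 <= ijk[a] < dims[a] for a in range(3)) and mask[ijk]:
                counts[ijk] += 1
    vals, tallies = np.unique(counts[mask], return_counts=True)
    return {int(v): int(t) for v, t in zip(vals, tallies)}


def compare_models(
    report_a: AccuracyReport, report_b: AccuracyReport, bins: int = 30
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Joint per-voxel histogram of (R_rmse_a, R_rmse_b) and P(a better).

    Returns (hist2d, x_edges, y_edges, fraction of voxels with a < b).
    """
    va = report_a.per_voxel_r_rmse
    vb = report_b.per_voxel_r_rmse
    if set(va) != set(vb):
        raise ValueError("reports cover different voxel sets")
    keys = sorted(va)
    a = np.array([va[k] for k in keys])
    b = np.array([vb[k] for k in keys])
    lo, hi = float(min(a.min(), b.min())), float(max(a.max(), b.max()))
    if lo == hi:
        hi = lo + 1e-9
    hist, xe, ye = np.histogram2d(a, b, bins=bins, range=[[lo, hi], [lo, hi]])
    return hist, xe, ye, float(np.mean(a < b))


def evaluate_on_mask(
    connectome: Connectome,
    repeat1: DWIDataset,
    repeat2: DWIDataset | None,
    fit_mask: np.ndarray,
    coverage_mask: np.ndarray | None = None,
    axial_diffusivity: float | None = None,
    tolerance: float = 1e-6,
    max_iterations: int = 500,
    label: str = "",
    demeaned: bool = True,
) -> tuple[AccuracyReport, Connectome, "FitHandle"]:
    """Fit a candidate connectome on a mask and score it end to end.

    Builds the design matrix on ``repeat1`` restricted to ``fit_mask``, fits
    non-negative weights, and scores the prediction against ``repeat2``
    (cross-validated) or against ``repeat1`` when no second repeat is given
    (flagged non-cross-validated). Returns the accuracy report, the optimized
    connectome, and a handle bundling the design matrix and fit.
    """
    kwargs = {}
    if axial_diffusivity is not None:
        kwargs["axial_diffusivity"] = axial_diffusivity
    matrix = build_design_matrix(connectome, repeat1, fit_mask, **kwargs)
    y1, _ = demean_signal(repeat1, fit_mask)
    if not demeaned:
        y1, _ = _demeaned_vector(repeat1, fit_mask, demeaned=False)
    fit = fit_nnls(matrix, y1, tolerance=tolerance, max_iterations=max_iterations)
    pred = predict(matrix, fit.weights[matrix.column_streamlines])
    opt = optimized_connectome(connectome, fit)
    cross = repeat2 is not None
    scoring = repeat2 if cross else repeat1
    m = model_rmse(pred, scoring, fit_mask, demeaned=demeaned)
    if cross:
        d = data_rmse(repeat1, repeat2, fit_mask, demeaned=demeaned)
    else:
        d = {v: 1.0 for v in m}  # ratio degenerates to raw RMSE
    ratios, med, excluded = r_rmse(m, d)
    cov_mask = coverage_mask if coverage_mask is not None else repeat1.mask
    vs = repeat1.grid.voxel_size
    report = AccuracyReport(
        per_voxel_m_rmse=m,
        per_voxel_d_rmse=d,
        per_voxel_r_rmse=ratios,
        median_r_rmse=med,
        coverage=coverage(opt, cov_mask, vs),
        n_supported=len(opt),
        density_histogram=density_histogram(opt, cov_mask, vs),
        model_label=label or connectome.label,
        n_excluded_voxels=excluded,
        cross_validated=cross,
    )
    return report, opt, FitHandle(matrix, fit, pred)


@dataclass
class FitHandle:
    """Design matrix, fit result and prediction from one evaluation run."""

    matrix: DesignMatrix
    fit: "object"
    prediction: np.ndarray
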