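"""Linear fascicle evaluation: sparse design matrix and non-negative fit.

The model predicts the demeaned diffusion-weighted signal in every voxel of a
fit mask as a non-negative weighted sum of per-streamline contributions. A
streamline's contribution in a voxel it traverses is the single-stick Gaussian
attenuation of each within-voxel segment,

    s0 * exp(-b * lambda * (g . t)^2)

scaled by the segment length in mm, summed over segments, and demeaned across
gradient directions (so every column block sums to zero per voxel, matching
the demeaned signal it predicts). Segments are assigned to voxels by the
midpoint rule after splitting at voxel boundaries.

Weights are found by non-negative least squares, minimized with a projected
gradient method using Barzilai-Borwein step lengths (SBB-style) safeguarded by
a monotone backtracking line search; the iteration starts at w = 0 and stops
on a relative objective decrease below tolerance. Streamlines with strictly
positive weight form the optimized connectome.

A scikit-learn-compatible estimator (:class:`NonNegativeLinearRegression`)
exposes the same solver for generic design matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .core import Connectome, DWIDataset
from ._voxel import segment_pieces
from .phantom import DEFAULT_AXIAL_DIFFUSIVITY

__all__ = [
    "DesignMatrix",
    "FitResult",
    "demean_signal",
    "build_design_matrix",
    "fit_nnls",
    "predict",
    "optimized_connectome",
    "NonNegativeLinearRegression",
]

WEIGHT_FLUSH = 1e-12  # weights at or below this are treated as exactly zero


@dataclass
class DesignMatrix:
    """Sparse linear model: rows are (voxel, direction) pairs, columns streamlines."""

    matrix: sp.csc_matrix
    voxels: list[tuple[int, int, int]]  # fit-mask voxels in row-block order
    n_directions: int
    column_streamlines: np.ndarray  # index into the source connectome
    column_provenance: list[str]
    n_dropped: int  # streamlines intersecting no fit-mask voxel
    n_candidates: int = 0  # size of the source candidate connectome

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def row_index(self) -> list[tuple[tuple[int, int, int], int]]:
        return [(v, i) for v in self.voxels for i in range(self.n_directions)]


@dataclass
class FitResult:
    weights: np.ndarray  # per-candidate-streamline, >= 0
    objective_trajectory: np.ndarray  # non-increasing
    n_iterations: int
    converged: bool
    tolerance: float


def demean_signal(dataset: DWIDataset, fit_mask: np.ndarray) -> tuple[np.ndarray, list]:
    """Per-voxel demeaned diffusion-weighted signal, ordered voxel-major.

    Subtracts the across-direction mean within each fit-mask voxel. Returns
    the stacked vector and the ordered voxel list defining the row blocks.
    """
    fit_mask = np.asarray(fit_mask, dtype=bool)
    if np.any(fit_mask & ~dataset.mask):
        raise ValueError("fit_mask must be a subset of the dataset mask")
    voxels = [tuple(v) for v in np.argwhere(fit_mask)]
    if any(dataset.b0[v] == 0 for v in voxels):
        raise ValueError("fit mask contains voxels with zero b0 signal")
    parts = []
    for v in voxels:
        s = dataset.signal[v]
        parts.append(s - s.mean())
    return np.concatenate(parts) if parts else np.empty(0), voxels


def build_design_matrix(
    connectome: Connectome,
    dataset: DWIDataset,
    fit_mask: np.ndarray,
    axial_diffusivity: float = DEFAULT_AXIAL_DIFFUSIVITY,
    s0: float | None = None,
) -> DesignMatrix:
    """Assemble the sparse streamline-to-signal design matrix.

    ``s0=None`` uses each voxel's measured mean b0 as the signal scale
    (set ``s0=1.0`` for unit tests). Streamlines that intersect no fit-mask
    voxel are dropped from the columns; their count is recorded.
    """
    if len(connectome) == 0:
        raise ValueError("empty candidate connectome")
    fit_mask = np.asarray(fit_mask, dtype=bool)
    voxels = [tuple(v) for v in np.argwhere(fit_mask)]
    vox_row = {v: i for i, v in enumerate(voxels)}
    G = dataset.gradients.directions
    b = dataset.gradients.b_value
    N = dataset.gradients.n_directions
    vs = dataset.grid.voxel_size

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    kept_idx: list[int] = []
    kept_prov: list[str] = []
    n_dropped = 0
    for si, pts in enumerate(connectome.streamlines):
        contrib: dict[int, np.ndarray] = {}
        for ijk, tangent, length in segment_pieces(pts, vs):
            r = vox_row.get(ijk)
            if r is None:
                continue
            profile = length * np.exp(-b * axial_diffusivity * (G @ tangent) ** 2)
            if r in contrib:
                contrib[r] += profile
            else:
                contrib[r] = profile
        if not contrib:
            n_dropped += 1
            continue
        ci = len(kept_idx)
        kept_idx.append(si)
        kept_prov.append(connectome.provenance[si])
        for r, profile in contrib.items():
            scale = s0 if s0 is not None else dataset.b0[voxels[r]]
            block = scale * (profile - profile.mean())
            rows.append(r * N + np.arange(N))
            cols.append(np.full(N, ci))
            vals.append(block)
    if not kept_idx:
        raise ValueError("no candidate streamline intersects the fit mask")
    M = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(len(voxels) * N, len(kept_idx)),
    ).tocsc()
    return DesignMatrix(M, voxels, N, np.asarray(kept_idx), kept_prov, n_dropped,
                        n_candidates=len(connectome))


def _sbb(M, y: np.ndarray, tolerance: float, max_iterations: int):
    """Projected-gradient NNLS with Barzilai-Borwein steps and monotone safeguard.

    Minimizes 0.5*||y - M w||^2 over w >= 0 from w = 0. The BB step length is
    backtracked (halving) until the objective does not increase, so the
    recorded trajectory is non-increasing by construction.
    """
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite entries in the target vector")
    data = M.data if sp.issparse(M) else M
    if not np.all(np.isfinite(data)):
        raise ValueError("non-finite entries in the design matrix")
    n = M.shape[1]
    w = np.zeros(n)
    r = -y  # residual M w - y
    f = 0.5 * float(r @ r)
    g = M.T @ r
    traj = [f]
    converged = False
    step = None
    prev_w = None
    prev_g = None
    it = 0
    for it in range(1, max_iterations + 1):
        if step is None:
            Mg = M @ g
            denom = float(Mg @ Mg)
            step = float(g @ g) / denom if denom > 0 else 1.0
        # backtracking on the projected BB step
        t = step
        for _ in range(60):
            w_new = np.maximum(w - t * g, 0.0)
            r_new = M @ w_new - y
            f_new = 0.5 * float(r_new @ r_new)
            if f_new <= f:
                break
            t *= 0.5
        else:
            w_new, f_new = w, f
        prev_w, prev_g = w, g
        w, f_prev = w_new, f
        f = f_new
        r = M @ w - y
        g = M.T @ r
        traj.append(f)
        if f_prev - f <= tolerance * max(f_prev, 1e-30):
            converged = True
            break
        s_vec = w - prev_w
        q_vec = g - prev_g
        sq = float(s_vec @ q_vec)
        step = float(s_vec @ s_vec) / sq if sq > 1e-30 else None
    w[w <= WEIGHT_FLUSH] = 0.0
    return w, np.asarray(traj), it, converged


def fit_nnls(
    matrix: DesignMatrix,
    y: np.ndarray,
    tolerance: float = 1e-6,
    max_iterations: int = 500,
) -> FitResult:
    """Fit non-negative streamline weights to a demeaned signal vector.

    Returns weights aligned with the *candidate* connectome that built the
    design matrix (dropped columns get weight 0).
    """
    y = np.asarray(y, dtype=float).ravel()
    if y.shape[0] != matrix.shape[0]:
        raise ValueError(f"row mismatch: y has {y.shape[0]}, matrix {matrix.shape[0]}")
    w_cols, traj, n_iter, converged = _sbb(matrix.matrix, y, tolerance, max_iterations)
    n = matrix.n_candidates or (int(matrix.column_streamlines.max()) + 1)
    weights = np.zeros(n)
    weights[matrix.column_streamlines] = w_cols
    return FitResult(weights, traj, n_iter, converged, tolerance)


def predict(matrix: DesignMatrix, weights: np.ndarray) -> np.ndarray:
    """Model prediction M @ w over the design-matrix rows."""
    w = np.asarray(weights, dtype=float).ravel()
    if np.any(w < 0):
        raise ValueError("weights must be >= 0")
    if w.shape[0] == matrix.shape[1]:
        w_cols = w
    else:
        w_cols = w[matrix.column_streamlines]
    return matrix.matrix @ w_cols


def optimized_connectome(connectome: Connectome, fit: FitResult) -> Connectome:
    """Streamlines with strictly positive weight, weights attached."""
    w = fit.weights
    if w.shape[0] != len(connectome):
        raise ValueError(
            f"weight vector length {w.shape[0]} does not match connectome size {len(connectome)}"
        )
    keep = w > 0
    out = connectome.subset(keep)
    out.set_weights(w[keep])
    out.label = (connectome.label + ":optimized") if connectome.label else "optimized"
    return out


class NonNegativeLinearRegression(BaseEstimator, RegressorMixin):
    """Least squares with non-negativity constraints, SBB projected gradient.

    Parameters
    ----------
    tolerance : float
        Relative objective-decrease stopping criterion.
    max_iterations : int
        Iteration cap.

    Attributes
    ----------
    coef_ : ndarray of shape (n_features,)
        Fitted non-negative coefficients.
    n_iter_ : int
    converged_ : bool
    objective_trajectory_ : ndarray, non-increasing.
    """

    def __init__(self, tolerance: float = 1e-6, max_iterations: int = 500):
        self.tolerance = tolerance
        self.max_iterations = max_iterations

    def fit(self, X, y):
        y = np.asarray(y, dtype=float).ravel()
        if not sp.issparse(X):
            X = np.asarray(X, dtype=float)
            if X.ndim != 2:
                raise ValueError("X must be 2-D")
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y have inconsistent numbers of rows")
        coef, traj, n_iter, converged = _sbb(X, y, self.tolerance, self.max_iterations)
        self.coef_ = coef
        self.objective_trajectory_ = traj
        self.n_iter_ = n_iter
        self.converged_ = converged
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        return X @ self.coef_
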