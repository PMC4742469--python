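"""Fascicle-evaluation model: demeaning, design matrix, non-negative fit."""

import itertools

import numpy as np
import pytest
import scipy.optimize
from sklearn.base import clone

from enstract.core import Connectome, DWIDataset, VoxelGrid
from enstract.life import (
    NonNegativeLinearRegression,
    build_design_matrix,
    demean_signal,
    fit_nnls,
    optimized_connectome,
    predict,
)
from enstract.phantom import DEFAULT_AXIAL_DIFFUSIVITY, make_gradient_table, mixed_phantom


def flat_dataset(dims=(4, 4, 1), n_dirs=24, s0=100.0, fill=50.0):
    grid = VoxelGrid(dims, 1.5)
    g = make_gradient_table(n_dirs)
    signal = np.full((*dims, n_dirs), fill)
    b0 = np.full(dims, s0)
    mask = np.ones(dims, dtype=bool)
    return DWIDataset(signal, b0, mask, g, grid)


def active_set_nnls_objective(M, y):
    """Exhaustive nonnegative LS over all active sets (independent oracle)."""
    best = 0.5 * float(y @ y)
    n = M.shape[1]
    for k in range(1, n + 1):
        for subset in itertools.combinations(range(n), k):
            sub = M[:, subset]
            w, *_ = np.linalg.lstsq(sub, y, rcond=None)
            if np.all(w >= -1e-12):
                r = sub @ w - y
                best = min(best, 0.5 * float(r @ r))
    return best


class TestDemeanSignal:
    def test_constant_signal_demeans_to_zero(self):
        ds = flat_dataset()
        y, voxels = demean_signal(ds, ds.mask)
        assert len(voxels) == 16
        np.testing.assert_allclose(y, 0.0, atol=1e-12)

    def test_per_voxel_sums_vanish(self, rng):
        ds = flat_dataset()
        ds.signal = rng.uniform(10, 90, size=ds.signal.shape)
        y, voxels = demean_signal(ds, ds.mask)
        blocks = y.reshape(len(voxels), ds.gradients.n_directions)
        np.testing.assert_allclose(blocks.sum(axis=1), 0.0, atol=1e-9)

    def test_zero_b0_voxel_raises(self):
        ds = flat_dataset()
        ds.b0[0, 0, 0] = 0.0
        with pytest.raises(ValueError, match="b0"):
            demean_signal(ds, ds.mask)

    def test_mask_subset_enforced(self):
        ds = flat_dataset()
        ds.mask[0, 0, 0] = False
        with pytest.raises(ValueError, match="subset"):
            demean_signal(ds, np.ones(ds.grid.dims, bool))


class TestDesignMatrix:
    def test_single_stick_column_closed_form(self):
        """One streamline along z in one voxel: demeaned stick profile x length."""
        ds = flat_dataset(dims=(1, 1, 2))
        pts = np.array([[0.75, 0.75, 0.2], [0.75, 0.75, 1.3]])  # 1.1 mm inside voxel 0
        M = build_design_matrix(Connectome([pts]), ds, ds.mask, s0=1.0)
        G = ds.gradients.directions
        profile = 1.1 * np.exp(-ds.gradients.b_value * DEFAULT_AXIAL_DIFFUSIVITY * G[:, 2] ** 2)
        expected = profile - profile.mean()
        col = M.matrix.toarray()[: ds.gradients.n_directions, 0]
        np.testing.assert_allclose(col, expected, rtol=1e-9, atol=1e-12)

    def test_antipodal_tangent_gives_identical_column(self):
        ds = flat_dataset(dims=(1, 1, 2))
        up = np.array([[0.75, 0.75, 0.2], [0.75, 0.75, 1.3]])
        down = up[::-1]
        Ma = build_design_matrix(Connectome([up]), ds, ds.mask, s0=1.0)
        Mb = build_design_matrix(Connectome([down]), ds, ds.mask, s0=1.0)
        np.testing.assert_allclose(Ma.matrix.toarray(), Mb.matrix.toarray(), atol=1e-12)

    def test_parallel_duplicates_give_identical_columns(self):
        ds = flat_dataset(dims=(2, 1, 1))
        pts = np.array([[0.2, 0.75, 0.75], [2.8, 0.75, 0.75]])
        M = build_design_matrix(Connectome([pts, pts.copy()]), ds, ds.mask, s0=1.0)
        dense = M.matrix.toarray()
        np.testing.assert_allclose(dense[:, 0], dense[:, 1], atol=1e-12)

    def test_columns_demean_per_voxel_and_none_zero(self, phantom):
        conn = Connectome(phantom.truth.streamlines[:6], provenance="t")
        M = build_design_matrix(conn, phantom.repeat1, phantom.mask)
        dense = M.matrix.toarray()
        n = M.n_directions
        blocks = dense.reshape(len(M.voxels), n, dense.shape[1])
        np.testing.assert_allclose(blocks.sum(axis=1), 0.0, atol=1e-7)
        assert np.all(np.abs(dense).sum(axis=0) > 0)

    def test_outside_streamlines_dropped_or_rejected(self):
        ds = flat_dataset(dims=(2, 2, 1))
        inside = np.array([[0.2, 0.75, 0.75], [2.5, 0.75, 0.75]])
        outside = inside + np.array([100.0, 0.0, 0.0])
        M = build_design_matrix(Connectome([inside, outside]), ds, ds.mask, s0=1.0)
        assert M.n_dropped == 1
        assert M.shape[1] == 1
        with pytest.raises(ValueError, match="intersect"):
            build_design_matrix(Connectome([outside]), ds, ds.mask, s0=1.0)


class TestFitNNLS:
    def small_system(self, rng, n_cols=4, n_rows=40):
        M = rng.normal(size=(n_rows, n_cols))
        y = rng.normal(size=n_rows)
        return M, y

    def test_zero_target_gives_zero_weights(self):
        ds = flat_dataset(dims=(1, 1, 2))
        pts = np.array([[0.75, 0.75, 0.2], [0.75, 0.75, 1.3]])
        M = build_design_matrix(Connectome([pts]), ds, ds.mask, s0=1.0)
        fit = fit_nnls(M, np.zeros(M.shape[0]))
        np.testing.assert_array_equal(fit.weights, 0.0)
        assert fit.objective_trajectory[-1] == 0.0

    def test_single_column_exact_recovery(self):
        ds = flat_dataset(dims=(1, 1, 2))
        pts = np.array([[0.75, 0.75, 0.2], [0.75, 0.75, 1.3]])
        M = build_design_matrix(Connectome([pts]), ds, ds.mask, s0=1.0)
        y = 2.0 * M.matrix.toarray()[:, 0]
        fit = fit_nnls(M, y, tolerance=1e-12, max_iterations=2000)
        assert fit.weights[0] == pytest.approx(2.0, rel=1e-6)

    def test_crossing_voxel_weight_recovery(self):
        """Two orthogonal sticks with weights (1.0, 0.5) recovered within 1%."""
        ds = flat_dataset(dims=(2, 2, 1), n_dirs=48)
        sx = np.array([[0.2, 0.75, 0.75], [2.8, 0.75, 0.75]])
        sy = np.array([[0.75, 0.2, 0.75], [0.75, 2.8, 0.75]])
        M = build_design_matrix(Connectome([sx, sy]), ds, ds.mask, s0=1.0)
        w_true = np.array([1.0, 0.5])
        y = predict(M, w_true)
        fit = fit_nnls(M, y, tolerance=1e-12, max_iterations=2000)
        np.testing.assert_allclose(fit.weights, w_true, rtol=0.01)

    def test_objective_trajectory_non_increasing(self, rng):
        from enstract.life import _sbb

        for _ in range(20):
            M, y = self.small_system(rng)
            _, traj, _, _ = _sbb(M, y, 1e-10, 1000)
            assert np.all(np.diff(traj) <= 1e-12)

    def test_matches_active_set_oracle(self, rng):
        from enstract.life import _sbb

        for _ in range(30):
            n = int(rng.integers(2, 7))
            M, y = self.small_system(rng, n_cols=n)
            _, traj, _, _ = _sbb(M, y, 1e-12, 5000)
            assert traj[-1] == pytest.approx(active_set_nnls_objective(M, y), abs=1e-6)

    def test_column_permutation_permutes_weights(self, rng):
        from enstract.life import _sbb

        M, y = self.small_system(rng, n_cols=5)
        perm = rng.permutation(5)
        w, *_ = _sbb(M, y, 1e-12, 5000)
        wp, *_ = _sbb(M[:, perm], y, 1e-12, 5000)
        np.testing.assert_allclose(wp, w[perm], atol=1e-6)

    def test_non_finite_inputs_raise(self):
        from enstract.life import _sbb

        M = np.ones((4, 2))
        with pytest.raises(ValueError, match="non-finite"):
            _sbb(M, np.array([1.0, np.nan, 0.0, 0.0]), 1e-6, 10)
        M[0, 0] = np.inf
        with pytest.raises(ValueError, match="non-finite"):
            _sbb(M, np.zeros(4), 1e-6, 10)


class TestOptimizedConnectome:
    def three_streamline_setup(self):
        ds = flat_dataset(dims=(3, 1, 1))
        lines = [
            np.array([[0.2 + 1.5 * i, 0.75, 0.75], [1.2 + 1.5 * i, 0.75, 0.75]])
            for i in range(3)
        ]
        conn = Connectome(lines, provenance=["a", "b", "c"])
        M = build_design_matrix(conn, ds, ds.mask, s0=1.0)
        return conn, M

    def test_strictly_positive_weights_define_support(self):
        from enstract.life import FitResult

        conn, _ = self.three_streamline_setup()
        fit = FitResult(np.array([0.0, 0.3, 0.0]), np.array([1.0]), 1, True, 1e-6)
        opt = optimized_connectome(conn, fit)
        assert len(opt) == 1
        assert opt.provenance == ["b"]
        assert opt.weights[0] == 0.3
        empty = optimized_connectome(conn, FitResult(np.zeros(3), np.array([1.0]), 1, True, 1e-6))
        assert len(empty) == 0

    def test_zero_weight_columns_do_not_change_prediction(self):
        conn, M = self.three_streamline_setup()
        w = np.array([0.0, 0.7, 0.2])
        full = predict(M, w)
        # prediction from the optimized subset only
        opt = conn.subset(w > 0)
        ds = flat_dataset(dims=(3, 1, 1))
        Mo = build_design_matrix(opt, ds, ds.mask, s0=1.0)
        reduced = predict(Mo, w[w > 0])
        np.testing.assert_allclose(full, reduced, atol=1e-9)

    def test_predict_validates_weights(self):
        _, M = self.three_streamline_setup()
        np.testing.assert_array_equal(predict(M, np.zeros(3)), 0.0)
        with pytest.raises(ValueError, match=">= 0"):
            predict(M, np.array([-1.0, 0.0, 0.0]))

    def test_length_mismatch_raises(self):
        from enstract.life import FitResult

        conn, _ = self.three_streamline_setup()
        with pytest.raises(ValueError, match="match"):
            optimized_connectome(conn, FitResult(np.zeros(2), np.array([1.0]), 1, True, 1e-6))


class TestSklearnEstimator:
    def test_matches_scipy_nnls(self, rng):
        for _ in range(10):
            M = rng.normal(size=(30, 5))
            y = rng.normal(size=30)
            est = NonNegativeLinearRegression(tolerance=1e-12, max_iterations=5000)
            est.fit(M, y)
            ref, _ = scipy.optimize.nnls(M, y)
            np.testing.assert_allclose(est.coef_, ref, atol=1e-6)
            assert np.all(est.coef_ >= 0)

    def test_sklearn_protocol(self, rng):
        M = rng.normal(size=(20, 3))
        y = rng.normal(size=20)
        est = NonNegativeLinearRegression(max_iterations=200)
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()
        est.set_params(tolerance=1e-8).fit(M, y)
        assert est.predict(M).shape == (20,)
        assert np.all(np.diff(est.objective_trajectory_) <= 1e-12)
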