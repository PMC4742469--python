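"""Accuracy ratios, coverage and density statistics."""

import math

import numpy as np
import pytest

from enstract.core import Connectome, DWIDataset, VoxelGrid
from enstract.metrics import (
    compare_models,
    coverage,
    data_rmse,
    density_histogram,
    model_rmse,
    r_rmse,
    single_repeat_rmse,
)
from enstract.phantom import make_gradient_table


def dataset_from_signal(signal, b0=100.0):
    signal = np.asarray(signal, dtype=float)
    dims = signal.shape[:3]
    grid = VoxelGrid(dims, 1.5)
    g = make_gradient_table(signal.shape[3])
    return DWIDataset(signal, np.full(dims, b0), np.ones(dims, bool),
                      g, grid)


class TestModelRmse:
    def test_perfect_prediction_is_zero(self, rng):
        sig = rng.uniform(10, 90, size=(2, 2, 1, 12))
        ds = dataset_from_signal(sig)
        demeaned = (sig - sig.mean(axis=3, keepdims=True)).reshape(-1)
        m = model_rmse(demeaned, ds, ds.mask)
        assert all(v == pytest.approx(0.0, abs=1e-12) for v in m.values())

    def test_hand_arithmetic_two_directions(self):
        """Residuals (3, 4) over N=2 give sqrt(25/2)."""
        sig = np.zeros((1, 1, 1, 2))
        sig[0, 0, 0] = [10.0, 20.0]
        ds = dataset_from_signal(sig)
        prediction = np.array([10.0 + 3.0, 20.0 + 4.0])
        m = model_rmse(prediction, ds, ds.mask, demeaned=False)
        assert m[(0, 0, 0)] == pytest.approx(math.sqrt(25.0 / 2.0))

    def test_zero_prediction_gives_signal_rms(self, rng):
        sig = rng.uniform(10, 90, size=(1, 1, 1, 16))
        ds = dataset_from_signal(sig)
        m = model_rmse(np.zeros(16), ds, ds.mask, demeaned=False)
        assert m[(0, 0, 0)] == pytest.approx(np.sqrt(np.mean(sig**2)))

    def test_dimension_mismatch_raises(self):
        ds = dataset_from_signal(np.ones((1, 1, 1, 8)))
        with pytest.raises(ValueError, match="match"):
            model_rmse(np.zeros(5), ds, ds.mask)


class TestDataRmse:
    def test_identical_repeats_and_symmetry(self, rng):
        sig = rng.uniform(10, 90, size=(2, 1, 1, 12))
        a = dataset_from_signal(sig)
        b = dataset_from_signal(sig + rng.normal(0, 1, size=sig.shape))
        assert all(v == 0 for v in data_rmse(a, a, a.mask).values())
        ab = data_rmse(a, b, a.mask)
        ba = data_rmse(b, a, a.mask)
        for v in ab:
            assert ab[v] == pytest.approx(ba[v])

    def test_iid_noise_gives_sigma_sqrt2(self, rng):
        sigma = 3.0
        base = rng.uniform(20, 80, size=(10, 10, 1, 96))
        a = dataset_from_signal(base + rng.normal(0, sigma, base.shape))
        b = dataset_from_signal(base + rng.normal(0, sigma, base.shape))
        d = data_rmse(a, b, a.mask, demeaned=False)
        assert np.mean(list(d.values())) == pytest.approx(sigma * math.sqrt(2), rel=0.05)

    def test_mismatched_gradients_raise(self):
        sig = np.ones((1, 1, 1, 8))
        a = dataset_from_signal(sig)
        b = DWIDataset(np.ones((1, 1, 1, 6)), np.full((1, 1, 1), 100.0),
                       np.ones((1, 1, 1), bool), make_gradient_table(6), a.grid)
        with pytest.raises(ValueError, match="gradient"):
            data_rmse(a, b, a.mask)


class TestRRmse:
    def test_equal_errors_give_unity(self):
        m = {(0, 0, 0): 2.0, (1, 0, 0): 5.0}
        ratios, med, excl = r_rmse(m, dict(m))
        assert all(v == 1.0 for v in ratios.values())
        assert med == 1.0 and excl == 0

    def test_zero_model_error_gives_zero(self):
        ratios, med, _ = r_rmse({(0, 0, 0): 0.0}, {(0, 0, 0): 3.0})
        assert med == 0.0

    def test_zero_reliability_voxels_excluded(self):
        m = {(0, 0, 0): 1.0, (1, 0, 0): 1.0}
        d = {(0, 0, 0): 2.0, (1, 0, 0): 0.0}
        ratios, _, excl = r_rmse(m, d)
        assert excl == 1 and (1, 0, 0) not in ratios
        with pytest.raises(ValueError, match="undefined"):
            r_rmse({(0, 0, 0): 1.0}, {(0, 0, 0): 0.0})

    def test_scale_invariance(self, rng):
        base = rng.uniform(20, 80, size=(3, 3, 1, 24))
        n1 = rng.normal(0, 2, base.shape)
        n2 = rng.normal(0, 2, base.shape)
        pred = (base - base.mean(3, keepdims=True)).reshape(-1)
        for s in (1.0, 7.5):
            a = dataset_from_signal(s * (base + n1))
            b = dataset_from_signal(s * (base + n2))
            m = model_rmse(s * pred, b, a.mask)
            d = data_rmse(a, b, a.mask)
            _, med, _ = r_rmse(m, d)
            if s == 1.0:
                ref = med
        assert med == pytest.approx(ref, rel=1e-9)

    def test_ideal_predictor_floor(self, rng):
        """The perfect-mean predictor converges to R_rmse = 1/sqrt(2)."""
        base = rng.uniform(20, 80, size=(25, 40, 1, 96))
        sigma = 3.0
        a = dataset_from_signal(base + rng.normal(0, sigma, base.shape))
        b = dataset_from_signal(base + rng.normal(0, sigma, base.shape))
        pred = (base - base.mean(3, keepdims=True)).reshape(-1)
        m = model_rmse(pred, b, a.mask)
        d = data_rmse(a, b, a.mask)
        ratios, _, _ = r_rmse(m, d)
        assert np.mean(list(ratios.values())) == pytest.approx(1 / math.sqrt(2), abs=0.01)

    def test_agrees_with_naive_loop_oracle(self, rng):
        sig1 = rng.uniform(10, 90, size=(2, 2, 1, 6))
        sig2 = rng.uniform(10, 90, size=(2, 2, 1, 6))
        pred = rng.normal(size=2 * 2 * 1 * 6)
        a, b = dataset_from_signal(sig1), dataset_from_signal(sig2)
        m = model_rmse(pred, b, a.mask)
        d = data_rmse(a, b, a.mask)
        p = pred.reshape(2, 2, 1, 6)
        for idx in np.ndindex(2, 2, 1):
            s1 = sig1[idx] - sig1[idx].mean()
            s2 = sig2[idx] - sig2[idx].mean()
            m_ref = math.sqrt(sum((p[idx][i] - s2[i]) ** 2 for i in range(6)) / 6)
            d_ref = math.sqrt(sum((s1[i] - s2[i]) ** 2 for i in range(6)) / 6)
            assert m[idx] == pytest.approx(m_ref, abs=1e-12)
            assert d[idx] == pytest.approx(d_ref, abs=1e-12)


class TestSingleRepeatRmse:
    def test_equals_model_rmse_on_same_repeat(self, rng):
        sig = rng.uniform(10, 90, size=(2, 1, 1, 8))
        ds = dataset_from_signal(sig)
        pred = rng.normal(size=16)
        a = single_repeat_rmse(pred, ds, ds.mask)
        b = model_rmse(pred, ds, ds.mask)
        assert a == b

    def test_perfect_prediction(self, rng):
        sig = rng.uniform(10, 90, size=(1, 1, 1, 8))
        ds = dataset_from_signal(sig)
        pred = (sig - sig.mean(3, keepdims=True)).reshape(-1)
        assert single_repeat_rmse(pred, ds, ds.mask)[(0, 0, 0)] == pytest.approx(0, abs=1e-12)


def h_line(y, z, x0=0.2, x1=14.8):
    return np.array([[x0, y, z], [x1, y, z]])


class TestCoverageAndDensity:
    mask = np.ones((10, 1, 1), dtype=bool)

    def test_full_and_empty_coverage(self):
        full = Connectome([h_line(0.75, 0.75)])
        assert coverage(full, self.mask, 1.5) == 1.0
        assert coverage(Connectome([]), self.mask, 1.5) == 0.0
        with pytest.raises(ValueError, match="empty mask"):
            coverage(full, np.zeros((2, 1, 1), bool), 1.5)

    def test_union_monotonicity(self):
        a = Connectome([h_line(0.75, 0.75, 0.2, 5.0)])
        b = Connectome([h_line(0.75, 0.75, 8.0, 14.8)])
        from enstract.ensemble import combine

        cov_ab = coverage(combine([a, b]), self.mask, 1.5)
        assert cov_ab >= max(coverage(a, self.mask, 1.5), coverage(b, self.mask, 1.5))

    def test_density_tally_and_double_counting(self):
        # one streamline through the first 5 voxels of a 10-voxel tube
        conn = Connectome([h_line(0.75, 0.75, 0.2, 7.3)])
        tally = density_histogram(conn, self.mask, 1.5)
        assert tally == {0: 5, 1: 5}
        weighted = sum(count * n for count, n in tally.items())
        from enstract._voxel import streamline_voxels

        assert weighted == sum(len(streamline_voxels(s, 1.5)) for s in conn)


class TestCompareModels:
    def make_report(self, values):
        from enstract.metrics import AccuracyReport

        return AccuracyReport({}, {}, dict(values), float(np.median(list(values.values()))),
                              0.0, 0, {}, model_label="x")

    def test_identical_reports_on_diagonal(self):
        vals = {(i, 0, 0): 0.8 + 0.01 * i for i in range(10)}
        a = self.make_report(vals)
        hist, xe, ye, frac = compare_models(a, self.make_report(dict(vals)))
        assert frac == 0.0
        # all mass in diagonal bins
        ix = np.digitize([v for v in vals.values()], xe) - 1
        assert hist.sum() == 10

    def test_uniform_shift_gives_full_fraction(self):
        vals = {(i, 0, 0): 0.8 + 0.01 * i for i in range(10)}
        shifted = {k: v + 0.1 for k, v in vals.items()}
        *_, frac = compare_models(self.make_report(vals), self.make_report(shifted))
        assert frac == 1.0

    def test_voxel_set_mismatch_raises(self):
        a = self.make_report({(0, 0, 0): 1.0})
        b = self.make_report({(1, 0, 0): 1.0})
        with pytest.raises(ValueError, match="voxel"):
            compare_models(a, b)
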