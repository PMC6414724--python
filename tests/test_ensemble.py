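import numpy as np
import pandas as pd
import pytest

from enmtransfer.ensemble import (
    EnsembleENM,
    ModelSpec,
    RegistryError,
    SingleModelFit,
    StratificationError,
    build_combined,
    build_ensemble,
    fit_regional_climate,
    fit_single,
    project_direct,
    split_sample,
)
from enmtransfer.raster import ConfigurationError, RasterGrid


class TestSplitSample:
    def test_stratified_counts(self):
        y = np.r_[np.ones(30), np.zeros(70)]
        parts = split_sample(y, n_replicates=5, train_fraction=0.7, seed=1)
        for train, test in parts:
            assert len(test) == 30
            assert y[test].sum() == 9  # round(0.3 * 30)
            assert len(np.intersect1d(train, test)) == 0
            assert len(np.union1d(train, test)) == 100

    def test_deterministic(self):
        y = np.r_[np.ones(20), np.zeros(20)]
        a = split_sample(y, 3, 0.7, seed=5)
        b = split_sample(y, 3, 0.7, seed=5)
        for (ta, sa), (tb, sb) in zip(a, b):
            np.testing.assert_array_equal(ta, tb)
            np.testing.assert_array_equal(sa, sb)

    def test_single_class_rejected(self):
        with pytest.raises(StratificationError):
            split_sample(np.ones(10), 3, 0.7, seed=1)


def _point_data(n=200, seed=0, separable=False, noise_only=False):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, 2))
    if separable:
        y = (X[:, 0] > 0).astype(int)
    elif noise_only:
        y = rng.integers(0, 2, n)
    else:
        p = 1 / (1 + np.exp(-1.5 * X[:, 0]))
        y = (rng.random(n) < p).astype(int)
    return X, y


class TestFitSingle:
    def test_separable_data_perfect_auc(self):
        X, y = _point_data(separable=True)
        train = np.arange(140)
        test = np.arange(140, 200)
        fit = fit_single(X, y, train, test, "glm", 0, seed=1)
        assert fit.holdout_auc == 1.0

    def test_pure_noise_auc_band(self):
        # mean holdout AUC over 30 replicates stays in the permutation-null band
        X, y = _point_data(noise_only=True, seed=3)
        parts = split_sample(y, 30, 0.7, seed=3)
        aucs = [
            fit_single(X, y, tr, te, "glm", i, seed=3).holdout_auc
            for i, (tr, te) in enumerate(parts)
        ]
        assert 0.35 <= np.mean(aucs) <= 0.65

    def test_seed_repeatability(self):
        X, y = _point_data(seed=5)
        train, test = split_sample(y, 1, 0.7, seed=5)[0]
        a = fit_single(X, y, train, test, "rf", 0, seed=9)
        b = fit_single(X, y, train, test, "rf", 0, seed=9)
        assert a.holdout_auc == b.holdout_auc

    def test_unregistered_algorithm(self):
        X, y = _point_data()
        with pytest.raises(RegistryError):
            fit_single(X, y, np.arange(100), np.arange(100, 200), "maxent", 0, 1)


class _ConstantModel:
    """Test double predicting a fixed value for every row."""

    def __init__(self, value):
        self.value = value

    def predict_proba(self, X):
        p = np.full(len(X), self.value)
        return np.column_stack([1 - p, p])


def _member(auc_val, pred_value):
    return SingleModelFit(
        algorithm="const", replicate=0, estimator=_ConstantModel(pred_value),
        holdout_auc=auc_val, train_idx=np.arange(1), test_idx=np.arange(1, 2),
    )


class TestBuildEnsemble:
    def test_threshold_excludes_weak_members(self):
        res = build_ensemble([_member(0.9, 0.5), _member(0.6, 0.9)], threshold=0.65)
        assert [m.holdout_auc for m in res.included] == [0.9]
        assert not res.fallback

    def test_equal_weights_give_arithmetic_mean(self):
        res = build_ensemble([_member(0.8, 0.2), _member(0.8, 0.6)])
        X = np.zeros((3, 1))
        np.testing.assert_allclose(res.predict(X), 0.4)

    def test_weighted_mean_arithmetic(self):
        # AUC weights 0.8 and 0.7 on predictions 0.5 and 0.65
        res = build_ensemble([_member(0.8, 0.5), _member(0.7, 0.65)])
        expected = (0.8 * 0.5 + 0.7 * 0.65) / 1.5
        np.testing.assert_allclose(res.predict(np.zeros((1, 1))), expected)
        assert expected == pytest.approx(0.57)

    def test_fallback_to_best_member(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="enmtransfer.ensemble"):
            res = build_ensemble([_member(0.5, 0.1), _member(0.55, 0.9)])
        assert res.fallback
        assert [m.holdout_auc for m in res.included] == [0.55]
        assert any("falling back" in r.message for r in caplog.records)

    def test_empty_members_rejected(self):
        with pytest.raises(ConfigurationError):
            build_ensemble([])

    def test_convexity_of_predictions(self):
        members = [_member(0.7, 0.2), _member(0.8, 0.5), _member(0.9, 0.9)]
        res = build_ensemble(members)
        pred = res.predict(np.zeros((5, 1)))
        assert np.all(pred >= 0.2 - 1e-12) and np.all(pred <= 0.9 + 1e-12)


def _occ_from_grid(suit: RasterGrid, n=200, seed=0):
    rng = np.random.default_rng(seed)
    flat = rng.choice(suit.values.size, size=n, replace=False)
    r, c = np.divmod(flat, suit.n_cols)
    xs, ys = suit.cell_centers()
    p = suit.values[r, c]
    return pd.DataFrame(
        {
            "species_id": "S", "x": xs[c], "y": ys[r],
            "detected": (rng.random(n) < p).astype(int),
            "epoch": "t0", "protocol": "calibration",
        }
    )


def _gradient_grid(n=30, cell=100.0):
    vals = np.tile(np.linspace(-2, 2, n), (n, 1))
    return RasterGrid(vals, cell, (0.0, cell * n))


class TestEnsembleENM:
    def test_at_most_three_predictors(self, flat_grid):
        stack = {f"p{i}": flat_grid for i in range(4)}
        with pytest.raises(ConfigurationError):
            EnsembleENM(pd.DataFrame(), stack)

    def test_member_accounting(self):
        grid = _gradient_grid()
        suit = grid.with_values(1 / (1 + np.exp(-grid.values)))
        occ = _occ_from_grid(suit, seed=1)
        spec = ModelSpec(algorithms=("glm", "gbm"), n_replicates=4)
        res = EnsembleENM(occ, {"z": grid}, spec).fit(seed=2)
        assert len(res.members) + len(res.fold_skips) == 4 * 2

    def test_predict_map_constant_stack(self):
        grid = _gradient_grid()
        suit = grid.with_values(1 / (1 + np.exp(-grid.values)))
        occ = _occ_from_grid(suit, seed=3)
        spec = ModelSpec(algorithms=("glm",), n_replicates=3)
        res = EnsembleENM(occ, {"z": grid}, spec).fit(seed=3)
        const = grid.with_values(np.full(grid.values.shape, 0.7))
        out = res.predict_map({"z": const})
        assert np.ptp(out.values) < 1e-12

    def test_single_member_ensemble_identity(self):
        grid = _gradient_grid()
        suit = grid.with_values(1 / (1 + np.exp(-grid.values)))
        occ = _occ_from_grid(suit, seed=4)
        spec = ModelSpec(algorithms=("glm",), n_replicates=1)
        res = EnsembleENM(occ, {"z": grid}, spec).fit(seed=4)
        assert len(res.included) == 1
        member_map = res.included[0].predict(grid.values.reshape(-1, 1))
        ens_map = res.predict_map({"z": grid})
        np.testing.assert_allclose(
            ens_map.values.ravel(), member_map, atol=1e-12
        )

    def test_missing_layer_in_predict(self):
        grid = _gradient_grid()
        suit = grid.with_values(1 / (1 + np.exp(-grid.values)))
        occ = _occ_from_grid(suit, seed=5)
        res = EnsembleENM(occ, {"z": grid}, ModelSpec(algorithms=("glm",), n_replicates=2)).fit(1)
        with pytest.raises(KeyError):
            res.predict_map({"other": grid})

    def test_summary_mentions_members(self):
        grid = _gradient_grid()
        suit = grid.with_values(1 / (1 + np.exp(-grid.values)))
        occ = _occ_from_grid(suit, seed=6)
        res = EnsembleENM(occ, {"z": grid}, ModelSpec(algorithms=("glm",), n_replicates=2)).fit(1)
        text = res.summary()
        assert "Members fitted" in text and "glm" in text


class TestCombined:
    def test_arity_bounds(self):
        grid = _gradient_grid()
        with pytest.raises(ConfigurationError):
            build_combined({"a": grid}, pd.DataFrame())
        with pytest.raises(ConfigurationError):
            build_combined({f"m{i}": grid for i in range(4)}, pd.DataFrame())

    def test_identical_inputs_rank_equal_prediction(self):
        grid = _gradient_grid()
        suit = grid.with_values(1 / (1 + np.exp(-grid.values)))
        occ = _occ_from_grid(suit, seed=7)
        spec = ModelSpec(algorithms=("glm",), n_replicates=3)
        res = build_combined({"a": suit, "b": suit.copy()}, occ, spec, seed=7)
        out = res.predict_map({"a": suit, "b": suit.copy()})
        from scipy.stats import spearmanr

        rho = spearmanr(out.values.ravel(), suit.values.ravel()).statistic
        assert rho > 0.999

    def test_informative_input_dominates_linear_member(self):
        grid = _gradient_grid()
        suit = grid.with_values(1 / (1 + np.exp(-2 * grid.values)))
        noise = grid.with_values(
            np.random.default_rng(8).random(grid.values.shape)
        )
        occ = _occ_from_grid(suit, n=400, seed=8)
        spec = ModelSpec(algorithms=("glm",), n_replicates=5)
        res = build_combined({"signal": suit, "noise": noise}, occ, spec, seed=8)
        coefs = [m.estimator.coef_[0] for m in res.members]
        mean_coef = np.mean(coefs, axis=0)
        assert abs(mean_coef[0]) > 3 * abs(mean_coef[1])


class TestHierarchical:
    def _regional_setup(self, seed=9):
        grid = _gradient_grid(n=20, cell=10_000.0)
        suit = grid.with_values(1 / (1 + np.exp(-grid.values)))
        occ = _occ_from_grid(suit, n=300, seed=seed)
        spec = ModelSpec(algorithms=("glm",), n_replicates=3)
        res = fit_regional_climate(occ, {"z": grid}, spec, seed=seed)
        return grid, res

    def test_roundtrip_on_regional_grid(self):
        grid, res = self._regional_setup()
        direct = project_direct(res, {"z": grid})
        native = res.predict_map({"z": grid})
        np.testing.assert_allclose(direct.values, native.values)

    def test_monotone_transport(self):
        grid, res = self._regional_setup()
        fine = RasterGrid(
            np.tile(np.linspace(-1.5, 1.5, 40), (40, 1)), 230.0, (0.0, 9200.0)
        )
        proj = project_direct(res, {"z": fine})
        row = proj.values[0]
        # regional response increases in z, so a z-ordered row stays ordered
        assert (np.diff(row) >= -1e-9).all() or (np.diff(row) <= 1e-9).all()
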