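"""Scaler, hyperparameter tuning, ε-SVR training and persistence.

The training contract is checked against an independent dense quadratic
program: the ε-SVR dual solved with a generic convex optimizer (SLSQP) on a
tiny problem, with the bias recovered from the KKT conditions of the free
support vectors.
"""

import dataclasses

import numpy as np
import pytest
from scipy.optimize import minimize

from polarccs.data_model import AdductRecord, PropertyDataset, random_split
from polarccs.svr import (
    DEFAULT_FEATURES,
    DegenerateFeatureError,
    HyperParams,
    ModelFormatError,
    _cv_fold_indices,
    _cv_score_arrays,
    fit_minmax_scaler,
    grid_points,
    load_model,
    predict_ccs,
    save_model,
    train_svr,
    tune_hyperparameters,
)
from polarccs.synthetic import default_twim_config, generate_dataset
from polarccs.evaluation import mean_relative_error

from conftest import SINGLE_POINT_GRID, make_record


def _dataset_from_xy(x, y, feature="polarizability"):
    """1-feature dataset (m/z held harmless at a constant-free ramp)."""
    recs = []
    for i, (xi, yi) in enumerate(zip(x, y)):
        recs.append(AdductRecord(f"p{i}", "M-H", mz=100.0 + i, ccs=float(yi),
                                 polarizability=float(xi)))
    return PropertyDataset(records=recs)


def svr_dual_qp_oracle(X, y, C, gamma, epsilon):
    """Solve the ε-SVR dual as a dense QP with SLSQP.

    maximize  -1/2 (a-a*)' K (a-a*) - eps * sum(a+a*) + y'(a-a*)
    s.t.      0 <= a, a* <= C,  sum(a - a*) = 0
    Returns a prediction function.
    """
    X = np.atleast_2d(X)
    n = len(y)
    d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1)
    K = np.exp(-gamma * d2)

    def objective(z):
        beta = z[:n] - z[n:]
        return 0.5 * beta @ K @ beta + epsilon * z.sum() - y @ beta

    def grad(z):
        beta = z[:n] - z[n:]
        Kb = K @ beta
        return np.concatenate([Kb + epsilon - y, -Kb + epsilon + y])

    cons = {"type": "eq", "fun": lambda z: z[:n].sum() - z[n:].sum(),
            "jac": lambda z: np.concatenate([np.ones(n), -np.ones(n)])}
    res = minimize(objective, np.zeros(2 * n), jac=grad, method="SLSQP",
                   bounds=[(0.0, C)] * (2 * n), constraints=[cons],
                   options={"maxiter": 2000, "ftol": 1e-14})
    assert res.success
    beta = res.x[:n] - res.x[n:]
    # bias from KKT on free SVs: y_i - K_i beta = b + eps (a free) / -eps (a* free)
    tol = 1e-8 * C
    free_pos = (res.x[:n] > tol) & (res.x[:n] < C - tol)
    free_neg = (res.x[n:] > tol) & (res.x[n:] < C - tol)
    resid = y - K @ beta
    b_candidates = np.concatenate([resid[free_pos] - epsilon, resid[free_neg] + epsilon])
    b = float(np.mean(b_candidates)) if len(b_candidates) else 0.0

    def predict(Xq):
        Xq = np.atleast_2d(Xq)
        d2q = ((Xq[:, None, :] - X[None, :, :]) ** 2).sum(-1)
        return np.exp(-gamma * d2q) @ beta + b

    return predict


class TestScaler:
    def test_endpoints_and_linear_interpolation(self):
        ds = _dataset_from_xy([10.0, 30.0, 90.0], [100.0, 120.0, 140.0])
        scaler = fit_minmax_scaler(ds, ["polarizability"])
        scaled = scaler.transform(np.array([[10.0], [30.0], [90.0]])).ravel()
        assert scaled == pytest.approx([0.0, 0.25, 1.0])

    def test_constant_feature_errors(self):
        ds = _dataset_from_xy([5.0, 5.0, 5.0], [100.0, 110.0, 120.0])
        with pytest.raises(DegenerateFeatureError, match="polarizability"):
            fit_minmax_scaler(ds, ["polarizability"])

    def test_features_scaled_independently_and_order_invariant(self, twim_dataset):
        scaler = fit_minmax_scaler(twim_dataset, ["polarizability", "mz"])
        shuffled = PropertyDataset(
            records=[twim_dataset[i] for i in np.random.default_rng(0).permutation(len(twim_dataset))])
        scaler2 = fit_minmax_scaler(shuffled, ["polarizability", "mz"])
        assert scaler.mins == scaler2.mins and scaler.maxs == scaler2.maxs
        X = twim_dataset.feature_matrix(["polarizability", "mz"])
        S = scaler.transform(X)
        assert S.min(axis=0) == pytest.approx([0.0, 0.0], abs=1e-15)
        assert S.max(axis=0) == pytest.approx([1.0, 1.0], abs=1e-15)


class TestTuning:
    def test_default_grid_has_45_points_in_documented_order(self):
        points = grid_points()
        assert len(points) == 45
        assert points[0] == HyperParams("rbf", 100.0, 0.01, 0.01)
        assert points[1].epsilon == 0.1  # epsilon varies fastest
        assert points[-1] == HyperParams("rbf", 1_000_000.0, 1.0, 1.0)

    def test_single_point_grid_returned_without_cv(self, toy_dataset):
        hp = tune_hyperparameters(toy_dataset, grid=SINGLE_POINT_GRID, seed=0)
        assert hp == HyperParams("rbf", 1000.0, 0.1, 0.1)

    def test_selected_point_attains_exhaustive_minimum(self, twim_dataset):
        """CV-selection oracle: re-score all 45 combinations independently
        with the same fold assignment; the selected point's CV MRE equals
        the exhaustive minimum, and ties go to the first grid point."""
        train, _ = random_split(twim_dataset, 40, 0, seed=2)
        best, table = tune_hyperparameters(train, folds=5, seed=3, return_details=True)
        X = train.feature_matrix(DEFAULT_FEATURES)
        y = train.ccs_values()
        folds = _cv_fold_indices(len(y), 5, seed=3)
        rescored = [
            _cv_score_arrays(X, y, hp, folds, tuple(DEFAULT_FEATURES), max_iter=50_000)
            for hp in grid_points()
        ]
        min_score = min(rescored)
        chosen = [s for hp, s in table if hp == best][0]
        assert chosen == pytest.approx(min_score, rel=1e-12)
        first_min_index = int(np.argmin(rescored))
        assert grid_points()[first_min_index] == best

    def test_too_few_records_for_folds_errors(self):
        ds = _dataset_from_xy([1.0, 2.0, 3.0], [10.0, 20.0, 30.0])
        with pytest.raises(ValueError, match="folds"):
            tune_hyperparameters(ds, folds=5, seed=0)


class TestTraining:
    def test_wide_tube_keeps_training_residuals_inside(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([10.0, 10.4, 9.8, 10.2])
        ds = _dataset_from_xy(x, y)
        hp = HyperParams(C=1000.0, gamma=0.5, epsilon=1.0)  # tube wider than spread
        model = train_svr(ds, hp, features=["polarizability"])
        pred = predict_ccs(model, ds)["predicted_ccs"].to_numpy()
        assert np.all(np.abs(pred - y) <= hp.epsilon + 1e-9)

    @pytest.mark.parametrize("C,gamma,epsilon", [
        (500.0, 0.7, 0.05),
        (1000.0, 2.0, 0.01),
        (100.0, 0.3, 0.3),
    ])
    def test_matches_independent_dense_qp(self, C, gamma, epsilon):
        """Predictions agree with the SLSQP dual solution to <= 1e-6 relative."""
        x = np.array([1.0, 2.0, 3.5, 5.0])
        y = np.array([100.0, 104.0, 101.0, 108.0])
        ds = _dataset_from_xy(x, y)
        hp = HyperParams(C=C, gamma=gamma, epsilon=epsilon)
        model = train_svr(ds, hp, features=["polarizability"], tol=1e-9)
        # oracle works on the same scaled coordinates the model uses
        Xs = model.scaler.transform(x[:, None])
        oracle = svr_dual_qp_oracle(Xs, y, C, gamma, epsilon)
        probe = np.linspace(1.0, 5.0, 9)[:, None]
        ours = model.decision_function(model.scaler.transform(probe))
        ref = oracle(model.scaler.transform(probe))
        assert ours == pytest.approx(ref, rel=1e-6)

    def test_duplicated_training_set_same_function(self):
        x = np.array([1.0, 2.0, 3.5, 5.0, 6.5])
        y = np.array([100.0, 104.0, 101.0, 108.0, 103.0])
        ds = _dataset_from_xy(x, y)
        dup = PropertyDataset(records=[
            dataclasses.replace(r, compound_id=f"{r.compound_id}{tag}")
            for tag in ("a", "b") for r in ds])
        # C far above any active dual so the box constraint is slack and
        # duplication cannot change the optimum
        hp = HyperParams(C=10_000_000.0, gamma=0.5, epsilon=0.1)
        m1 = train_svr(ds, hp, features=["polarizability"], tol=1e-9)
        m2 = train_svr(dup, hp, features=["polarizability"], tol=1e-9)
        probe = np.linspace(1.0, 6.5, 12)[:, None]
        p1 = m1.decision_function(m1.scaler.transform(probe))
        p2 = m2.decision_function(m2.scaler.transform(probe))
        assert p1 == pytest.approx(p2, rel=1e-6)

    def test_dual_coefficients_bounded_by_C(self, twim_dataset):
        train, _ = random_split(twim_dataset, 50, 0, seed=1)
        hp = HyperParams(C=1000.0, gamma=0.1, epsilon=0.1)
        model = train_svr(train, hp)
        assert np.all(np.abs(model.dual_coefficients) <= hp.C * (1 + 1e-12))


class TestPrediction:
    def test_feature_order_invariance(self, twim_dataset):
        train, test = random_split(twim_dataset, 60, 20, seed=5)
        hp = HyperParams(C=1000.0, gamma=0.1, epsilon=0.1)
        m_pm = train_svr(train, hp, features=["polarizability", "mz"])
        m_mp = train_svr(train, hp, features=["mz", "polarizability"])
        p1 = predict_ccs(m_pm, test)["predicted_ccs"].to_numpy()
        p2 = predict_ccs(m_mp, test)["predicted_ccs"].to_numpy()
        assert p1 == pytest.approx(p2, rel=1e-9)

    def test_permuting_records_permutes_output(self, twim_dataset):
        train, test = random_split(twim_dataset, 60, 20, seed=5)
        model = train_svr(train, HyperParams())
        perm = np.random.default_rng(3).permutation(len(test))
        permuted = PropertyDataset(records=[test[i] for i in perm])
        out = predict_ccs(model, test)
        out_perm = predict_ccs(model, permuted)
        assert list(out_perm["compound_id"]) == [out["compound_id"][i] for i in perm]
        assert out_perm["predicted_ccs"].to_numpy() == pytest.approx(
            out["predicted_ccs"].to_numpy()[perm])

    def test_extrapolation_flagged_not_refused(self, twim_dataset):
        train, _ = random_split(twim_dataset, 40, 0, seed=8)
        model = train_svr(train, HyperParams())
        far = PropertyDataset(records=[make_record(0, "M-H", mz=5000.0, polarizability=200.0)])
        out = predict_ccs(model, far)
        assert bool(out["extrapolated"][0])
        assert np.isfinite(out["predicted_ccs"][0])

    def test_monotone_in_polarizability_at_median_mz(self, twim_dataset):
        """Mean predicted CCS is nondecreasing in polarizability with m/z
        held at its training median (probe grid inside the training range)."""
        train, _ = random_split(twim_dataset, 70, 0, seed=4)
        hp = tune_hyperparameters(train, seed=4)
        model = train_svr(train, hp)
        P = train.feature_matrix(["polarizability"]).ravel()
        mz_med = float(np.median(train.feature_matrix(["mz"])))
        probe = np.column_stack([np.linspace(P.min(), P.max(), 15),
                                 np.full(15, mz_med)])
        pred = model.decision_function(model.scaler.transform(probe))
        assert np.all(np.diff(pred) > -1e-6)

    def test_missing_feature_names_record(self, twim_dataset):
        train, _ = random_split(twim_dataset, 40, 0, seed=8)
        model = train_svr(train, HyperParams(), features=["polarizability", "vdw_volume"])
        bare = PropertyDataset(records=[AdductRecord("no-volume", "M+H", 100, 150, 12)])
        with pytest.raises(Exception, match="no-volume"):
            predict_ccs(model, bare)

    def test_end_to_end_mre_below_noise_ceiling(self, twim_dataset):
        """70-train/18-test on synthetic defaults: test MRE under 5%."""
        train, test = random_split(twim_dataset, 70, 18, seed=1)
        hp = tune_hyperparameters(train, seed=1)
        model = train_svr(train, hp)
        pred = predict_ccs(model, test)["predicted_ccs"].to_numpy()
        assert mean_relative_error(pred, test.ccs_values()) < 5.0


class TestAdductVsNeutralFeature:
    def test_adduct_polarizability_feature_not_worse(self, twim_dataset):
        """With the sodium offset active the adduct-form polarizability
        carries the CCS signal directly; the neutral-form feature misplaces
        every sodium adduct by the offset, so as a single feature it cannot
        beat the adduct form on mean MRE over repeated splits."""
        errs = {"polarizability": [], "polarizability_neutral": []}
        for seed in range(6):
            train, test = random_split(twim_dataset, 70, 18, seed=20 + seed)
            for feat in errs:
                model = train_svr(train, HyperParams(C=10_000.0, gamma=0.1, epsilon=0.1),
                                  features=[feat])
                pred = predict_ccs(model, test)["predicted_ccs"].to_numpy()
                errs[feat].append(mean_relative_error(pred, test.ccs_values()))
        assert np.mean(errs["polarizability"]) <= np.mean(errs["polarizability_neutral"]) + 1e-9


class TestPersistence:
    def test_save_load_round_trip_preserves_predictions(self, twim_dataset, tmp_path):
        train, test = random_split(twim_dataset, 50, 30, seed=6)
        model = train_svr(train, HyperParams(C=1000.0, gamma=0.1, epsilon=0.1))
        path = tmp_path / "model.json"
        save_model(model, path)
        back = load_model(path)
        p1 = predict_ccs(model, test)["predicted_ccs"].to_numpy()
        p2 = predict_ccs(back, test)["predicted_ccs"].to_numpy()
        assert p2 == pytest.approx(p1, rel=1e-9)
        assert back.features == model.features

    def test_wrong_version_tag_rejected(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text('{"version": "other-format-9"}')
        with pytest.raises(ModelFormatError, match="version"):
            load_model(path)

    def test_not_json_rejected(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text("not json at all")
        with pytest.raises(ModelFormatError):
            load_model(path)
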