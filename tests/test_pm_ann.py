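"""Screening, L-M network training, gridded prediction, validation metrics."""

import numpy as np
import pytest

from paqikit import (
    AnnModel,
    predict_grid,
    stepwise_select,
    train_lm,
    validate,
)
from paqikit.pm_ann import _Diverged, _fit_lm, _forward, _pack, _unpack


# ---------------------------------------------------------------------------
# validation metrics


def test_validate_identity_and_hand_example():
    m = validate([10, 20, 30], [10, 20, 30])
    assert m["r"] == pytest.approx(1.0)
    assert m["ape"] == pytest.approx(0.0)
    m = validate([110, 220, 330], [100, 200, 300])
    assert m["r"] == pytest.approx(1.0)
    assert m["ape"] == pytest.approx(10.0)


def test_validate_anticorrelation_and_errors():
    obs = np.array([10.0, 20.0, 30.0])
    assert validate(-obs + 100, obs)["r"] == pytest.approx(-1.0)
    with pytest.raises(ValueError, match="zero"):
        validate([1.0, 2.0], [0.0, 2.0])
    with pytest.raises(ValueError, match="variance"):
        validate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
    with pytest.raises(ValueError):
        validate([1.0], [1.0])


# ---------------------------------------------------------------------------
# L-M core


def test_noiseless_linear_target_fits_perfectly(station_table_factory):
    rng = np.random.default_rng(0)
    X = rng.normal(size=(200, 4))
    y = 80 + X @ [5.0, -3.0, 2.0, 1.0]
    table = station_table_factory(X, y)
    model, report = train_lm(
        table, layer_sizes=[4, 1, 1], n_runs=3, seed=1, max_iter=300, patience=None
    )
    r = report.runs.iloc[report.best_run]["r"]
    assert r >= 0.999


def test_no_hidden_layer_matches_ols_on_training_split(station_table_factory):
    rng = np.random.default_rng(1)
    X = rng.normal(size=(200, 3))
    y = 80 + X @ [3.0, -2.0, 1.0] + rng.normal(0, 2.0, 200)
    table = station_table_factory(X, y)
    model, report = train_lm(
        table, layer_sizes=[3, 1], n_runs=2, seed=0, max_iter=500,
        tol=1e-14, patience=None,
    )
    slope, intercept = model.linear_coefficients()
    tr = model.meta["train_rows"]
    A = np.column_stack([np.ones(len(tr)), table.X()[tr]])
    coef = np.linalg.lstsq(A, table.y()[tr], rcond=None)[0]
    assert np.abs(slope - coef[1:]).max() < 1e-6
    assert abs(intercept - coef[0]) < 1e-6


def test_training_is_deterministic_under_fixed_seed(small_stations):
    m1, r1 = train_lm(small_stations, n_runs=4, seed=9, max_iter=60)
    m2, r2 = train_lm(small_stations, n_runs=4, seed=9, max_iter=60)
    assert all(np.array_equal(a, b) for a, b in zip(m1.weights, m2.weights))
    assert all(np.array_equal(a, b) for a, b in zip(m1.biases, m2.biases))
    assert r1.runs.equals(r2.runs)


def test_accepted_lm_steps_never_increase_training_sse(small_stations):
    _, report = train_lm(small_stations, n_runs=3, seed=2, max_iter=80)
    traj = report.loss_trajectory
    assert len(traj) >= 2
    assert all(b <= a for a, b in zip(traj, traj[1:]))


def test_standardization_round_trip(small_stations):
    model, _ = train_lm(small_stations, n_runs=2, seed=0, max_iter=30)
    X = small_stations.X()
    back = model.standardize(X) * model.input_scale + model.input_center
    assert np.allclose(back, X, atol=1e-10)


def test_recovery_improves_with_iteration_budget(station_table_factory):
    # noiseless nonlinear target: training error shrinks as max_iter grows
    rng = np.random.default_rng(3)
    X = rng.normal(size=(150, 2))
    y = 50 + 10 * np.tanh(X[:, 0]) + 5 * X[:, 1] ** 2
    table = station_table_factory(X, y)
    sses = []
    for max_iter in (3, 30, 300):
        _, report = train_lm(
            table, layer_sizes=[2, 6, 1], n_runs=2, seed=5,
            max_iter=max_iter, patience=None,
        )
        sses.append(report.loss_trajectory[-1])
    assert sses[0] > sses[1] > sses[2]


def test_divergence_reported_with_last_damping():
    # a target that is NaN poisons every step
    X = np.zeros((30, 1))
    y = np.full(30, np.nan)
    rng = np.random.default_rng(0)
    with pytest.raises(_Diverged):
        _fit_lm(X, y, [1, 1], rng, max_iter=10, tol=0.0)


def test_pack_unpack_round_trip():
    rng = np.random.default_rng(4)
    sizes = [3, 5, 2, 1]
    weights = [rng.normal(size=(a, b)) for a, b in zip(sizes, sizes[1:])]
    biases = [rng.normal(size=b) for b in sizes[1:]]
    w2, b2 = _unpack(_pack(weights, biases), sizes)
    assert all(np.array_equal(a, b) for a, b in zip(weights, w2))
    assert all(np.array_equal(a, b) for a, b in zip(biases, b2))


def test_jacobian_matches_finite_differences():
    from paqikit.pm_ann import _jacobian

    rng = np.random.default_rng(5)
    sizes = [2, 3, 1]
    X = rng.normal(size=(7, 2))
    weights = [rng.normal(size=(a, b)) for a, b in zip(sizes, sizes[1:])]
    biases = [rng.normal(size=b) for b in sizes[1:]]
    theta = _pack(weights, biases)
    acts = _forward(X, weights, biases)
    J = _jacobian(acts, weights)
    eps = 1e-6
    for k in range(theta.size):
        up, dn = theta.copy(), theta.copy()
        up[k] += eps
        dn[k] -= eps
        wu, bu = _unpack(up, sizes)
        wd, bd = _unpack(dn, sizes)
        num = (_forward(X, wu, bu)[-1][:, 0] - _forward(X, wd, bd)[-1][:, 0]) / (2 * eps)
        assert np.allclose(J[:, k], num, atol=1e-5)


# ---------------------------------------------------------------------------
# model serialization and gridded prediction


def test_model_json_round_trip(tmp_path, small_stations):
    model, _ = train_lm(small_stations, n_runs=2, seed=0, max_iter=30)
    path = tmp_path / "model.json"
    model.to_json(path)
    back = AnnModel.from_json(path)
    X = small_stations.X()
    assert np.allclose(back.predict(X), model.predict(X))
    assert back.predictor_names == model.predictor_names


def test_predict_grid_constant_input_identity(small_stations, small_fields):
    model, _ = train_lm(small_stations, n_runs=2, seed=1, max_iter=60)
    row = small_stations.X()[5]
    fields = {
        name: small_fields[name].with_values(
            np.full(small_fields[name].shape, row[k]), name=name
        )
        for k, name in enumerate(model.predictor_names)
    }
    out = predict_grid(model, fields)
    fitted = model.predict(row[None, :])[0]
    assert np.allclose(out.values, max(fitted, 0.0))


def test_predict_grid_mask_propagation_and_missing_predictor(small_stations, small_fields):
    model, _ = train_lm(small_stations, n_runs=2, seed=1, max_iter=30)
    fields = dict(small_fields)
    dead = fields["AOT"].with_values(fields["AOT"].values)
    dead.mask = np.zeros(dead.shape, bool)
    fields["AOT"] = dead
    out = predict_grid(model, fields)
    assert not out.mask.any()
    with pytest.raises(KeyError, match="AOT"):
        predict_grid(model, {k: v for k, v in small_fields.items() if k != "AOT"})


# ---------------------------------------------------------------------------
# stepwise screening


def test_stepwise_recovers_true_sparse_support(station_table_factory):
    rng = np.random.default_rng(10)
    n = 500
    X = rng.normal(size=(n, 6))
    y = 60 + 5 * X[:, 1] - 4 * X[:, 4] + rng.normal(0, 1.0, n)
    table = station_table_factory(X, y, names=[f"c{j}" for j in range(6)])
    # strict entry level keeps the expected number of false entries near zero
    report = stepwise_select(
        table, [f"c{j}" for j in range(6)], alpha_enter=0.01, alpha_remove=0.02
    )
    assert sorted(report.selected) == ["c1", "c4"]


def test_stepwise_single_strong_candidate(station_table_factory):
    rng = np.random.default_rng(11)
    n = 200
    X = rng.normal(size=(n, 2))
    y = 30 + 8 * X[:, 0] + rng.normal(0, 0.5, n)
    table = station_table_factory(X, y, names=["a", "b"])
    report = stepwise_select(table, ["a", "b"])
    assert report.selected == ["a"]


def test_stepwise_null_target_selects_nothing_usually(station_table_factory):
    n = 500
    empty = 0
    n_seeds = 100
    for seed in range(n_seeds):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 6))
        y = rng.normal(size=n) + 50
        table = station_table_factory(X, y, names=[f"c{j}" for j in range(6)])
        report = stepwise_select(
            table, [f"c{j}" for j in range(6)], alpha_enter=0.001, alpha_remove=0.002
        )
        empty += not report.selected
    assert empty >= 0.95 * n_seeds


def test_stepwise_drops_constant_candidate(station_table_factory):
    rng = np.random.default_rng(12)
    X = np.column_stack([rng.normal(size=100), np.full(100, 3.0), rng.normal(size=100)])
    y = 20 + 4 * X[:, 0] + rng.normal(0, 0.5, 100)
    table = station_table_factory(X, y, names=["a", "const", "b"])
    with pytest.warns(UserWarning, match="constant"):
        report = stepwise_select(table, ["a", "const", "b"])
    assert "const" not in report.candidates
    assert report.selected == ["a"]


def test_stepwise_skips_collinear_entry(station_table_factory):
    rng = np.random.default_rng(13)
    a = rng.normal(size=300)
    X = np.column_stack([a, 2 * a, rng.normal(size=300)])
    y = 10 + 3 * a + rng.normal(0, 0.3, 300)
    table = station_table_factory(X, y, names=["a", "a2", "b"])
    report = stepwise_select(table, ["a", "a2", "b"])
    # one of the two collinear twins enters, never both
    assert len({"a", "a2"} & set(report.selected)) == 1
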