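"""Dataset splitting, GPR training, VI selection and evaluation tests."""

import numpy as np
import pandas as pd
import pytest

from crownchl.hybrid_inversion import (
    GPRModel,
    evaluate,
    iterative_vi_selection,
    predict_traits,
    split_dataset,
    train_gpr,
)

# ------------------------------------------------------------------- split


def test_split_sizes_small():
    train, val = split_dataset(10, seed=0)
    assert len(train) == 7 and len(val) == 3


def test_split_sizes_lut_scale():
    train, val = split_dataset(20160, seed=1)
    assert len(train) == 14112 and len(val) == 6048


def test_split_deterministic_and_exhaustive():
    t1, v1 = split_dataset(101, seed=9)
    t2, v2 = split_dataset(101, seed=9)
    np.testing.assert_array_equal(t1, t2)
    np.testing.assert_array_equal(v1, v2)
    assert len(np.intersect1d(t1, v1)) == 0
    assert len(np.union1d(t1, v1)) == 101


def test_split_rejects_bad_inputs():
    with pytest.raises(ValueError):
        split_dataset(100, ratio=1.5)
    with pytest.raises(ValueError):
        split_dataset(5)


# ---------------------------------------------------------------- evaluate


def test_evaluate_perfect_prediction():
    obs = np.array([1.0, 2.0, 3.0])
    m = evaluate(obs, obs)
    assert (m.r2, m.rmse, m.nrmse) == (1.0, 0.0, 0.0)


def test_evaluate_nrmse_consistency():
    """mean(observed)=56.05 with rmse=6.86 gives nrmse=12.24%."""
    rng = np.random.default_rng(0)
    obs = rng.normal(56.05, 8.0, 4000)
    obs += 56.05 - obs.mean()  # pin the mean exactly
    pred = obs + 6.86  # constant offset: rmse = 6.86 exactly
    m = evaluate(obs, pred)
    assert m.rmse == pytest.approx(6.86)
    assert m.nrmse == pytest.approx(6.86 / 56.05 * 100.0)
    assert m.nrmse == pytest.approx(12.24, abs=0.01)


def test_evaluate_constant_prediction_r2_zero():
    obs = np.array([1.0, 2.0, 3.0, 4.0])
    assert evaluate(obs, np.full(4, 2.5)).r2 == 0.0


def test_evaluate_rejects_degenerate_inputs():
    with pytest.raises(ZeroDivisionError):
        evaluate([-1.0, 1.0], [0.0, 0.0])
    with pytest.raises(ValueError):
        evaluate([1.0], [1.0])


# ------------------------------------------------------------------- GPR


def test_gpr_learns_linear_function():
    rng = np.random.default_rng(3)
    x = rng.uniform(0, 1, 150)[:, None]
    y = 30.0 + 40.0 * x[:, 0]
    model = train_gpr(x[:100], y[:100], seed=1, n_restarts=1)
    m = evaluate(y[100:], model.predict(x[100:]))
    assert m.r2 >= 0.99


def test_gpr_handles_duplicate_rows():
    x = np.repeat(np.linspace(0, 1, 15), 3)[:, None]
    y = np.repeat(np.linspace(10, 20, 15), 3)
    model = train_gpr(x, y, seed=0, n_restarts=1)
    assert np.isfinite(model.predict(x)).all()


def test_gpr_interpolates_training_rows():
    rng = np.random.default_rng(5)
    x = rng.uniform(0, 1, (60, 2))
    y = 5.0 * x[:, 0] + 2.0 * x[:, 1]
    model = train_gpr(x, y, seed=2, n_restarts=1)
    pred, std = model.predict(x, return_std=True)
    noise = np.sqrt(np.exp(model.gpr.kernel_.theta[-1])) * model.y_std
    assert np.all(np.abs(pred - y) <= 2.0 * noise + 1e-3)


def test_gpr_rejects_bad_inputs():
    x = np.linspace(0, 1, 30)[:, None]
    y = np.linspace(0, 1, 30)
    with pytest.raises(ValueError):
        train_gpr(x[:10], y[:10], seed=0)  # too few rows
    xx = x.copy()
    xx[0, 0] = np.nan
    with pytest.raises(ValueError):
        train_gpr(xx, y, seed=0)


def test_gpr_subsampling_is_seeded():
    rng = np.random.default_rng(1)
    x = rng.uniform(0, 1, (200, 1))
    y = x[:, 0] * 10
    m1 = train_gpr(x, y, seed=4, max_train=50, n_restarts=1)
    m2 = train_gpr(x, y, seed=4, max_train=50, n_restarts=1)
    grid = np.linspace(0, 1, 11)[:, None]
    np.testing.assert_allclose(m1.predict(grid), m2.predict(grid))


def test_gpr_model_roundtrip(tmp_path):
    rng = np.random.default_rng(7)
    x = rng.uniform(0, 1, (40, 1))
    y = 3 * x[:, 0] + 1
    model = train_gpr(x, y, seed=0, n_restarts=1, feature_names=["NDVI"])
    path = tmp_path / "model.pkl"
    sidecar = tmp_path / "model.json"
    model.save(path, sidecar=sidecar)
    loaded = GPRModel.load(path)
    grid = np.linspace(0, 1, 9)[:, None]
    np.testing.assert_allclose(loaded.predict(grid), model.predict(grid))
    assert sidecar.exists()


# --------------------------------------------------------------- selection


def _toy_vi_table(n=300, seed=0):
    rng = np.random.default_rng(seed)
    table = pd.DataFrame(
        {f"vi{i}": rng.uniform(0, 1, n) for i in range(4)}
    )
    return table


def test_selection_stops_at_one_when_first_vi_suffices():
    table = _toy_vi_table()
    target = 50.0 * table["vi0"] + 10.0
    sel = iterative_vi_selection(
        list(table.columns), table, target, seed=0, max_train=150, n_restarts=1
    )
    assert sel.chosen == ["vi0"]
    assert sel.step_rmse[0] == min(sel.step_rmse) or sel.step_rmse[0] <= min(sel.step_rmse) * 1.01


def test_selection_respects_k_max():
    table = _toy_vi_table(seed=2)
    rng = np.random.default_rng(1)
    target = 20 * table["vi0"] + 10 * table["vi1"] + 5 * table["vi2"] + rng.normal(0, 0.1, len(table))
    sel = iterative_vi_selection(
        list(table.columns), table, target, seed=0, k_max=2, max_train=150, n_restarts=1
    )
    assert sel.n_chosen <= 2
    assert len(sel.step_rmse) == 2


def test_selection_chosen_is_prefix():
    table = _toy_vi_table(seed=5)
    target = 10 * table["vi0"] - 4 * table["vi3"]
    sel = iterative_vi_selection(
        list(table.columns), table, target, seed=3, max_train=150, n_restarts=1
    )
    assert sel.chosen == sel.ranked_vis[: sel.n_chosen]


def test_selection_rejects_empty_ranking():
    with pytest.raises(ValueError):
        iterative_vi_selection([], _toy_vi_table(), np.zeros(300))


# ----------------------------------------------------------------- traits


def _tiny_models():
    rng = np.random.default_rng(0)
    x = rng.uniform(0, 1, (40, 1))
    m_lcc = train_gpr(x, 50 + 10 * x[:, 0], seed=0, n_restarts=1, feature_names=["NDVI-RE"])
    m_lai = train_gpr(x, 2 + 3 * x[:, 0], seed=0, n_restarts=1, feature_names=["NDVI"])
    return m_lcc, m_lai


def test_predict_traits_ccc_is_exact_product():
    m_lcc, m_lai = _tiny_models()
    table = pd.DataFrame({"NDVI-RE": [0.2, 0.5], "NDVI": [0.6, 0.7]})
    out = predict_traits(m_lcc, m_lai, table)
    np.testing.assert_array_equal(out["ccc"], out["lcc"] * out["lai"])


def test_predict_traits_missing_feature_column():
    m_lcc, m_lai = _tiny_models()
    with pytest.raises(KeyError, match="NDVI"):
        predict_traits(m_lcc, m_lai, pd.DataFrame({"NDVI-RE": [0.2]}))


def test_predict_traits_nan_rows_flagged_others_proceed():
    m_lcc, m_lai = _tiny_models()
    table = pd.DataFrame({"NDVI-RE": [0.2, np.nan], "NDVI": [0.6, 0.7]})
    out = predict_traits(m_lcc, m_lai, table)
    assert np.isfinite(out.loc[0, "lcc"])
    assert np.isnan(out.loc[1, "lcc"])
    assert out.loc[1, "error"] != ""
    assert out.loc[0, "error"] == ""


def test_lut_parameter_recovery_bar(reduced_lut, selection):
    """70/30 split with the selected VI set recovers cab with R^2 >= 0.7."""
    from crownchl.spectral_indices import BAND_NAMES, compute_all

    vis = compute_all(reduced_lut[list(BAND_NAMES)])
    y = reduced_lut["cab"].to_numpy()
    tr, va = split_dataset(len(y), seed=11)
    X = vis[selection.chosen].to_numpy()
    ok = np.isfinite(X).all(axis=1)
    model = train_gpr(
        X[tr[ok[tr]]],
        y[tr[ok[tr]]],
        seed=1,
        max_train=1000,
        n_restarts=1,
        feature_names=selection.chosen,
    )
    m = evaluate(y[va[ok[va]]], model.predict(X[va[ok[va]]]))
    assert m.r2 >= 0.7


def test_predict_traits_product_contract_literal():
    """lcc=50, lai=3 implies ccc=150 in the output table."""
    out = pd.DataFrame({"tree_id": [1], "lcc": [50.0], "lai": [3.0]})
    out["ccc"] = out["lcc"] * out["lai"]
    assert out.loc[0, "ccc"] == 150.0
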