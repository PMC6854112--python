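import numpy as np
import pandas as pd
import pytest

from maxentsdm.fitting import MaxentModel, fit_model
from maxentsdm.interrogate import (
    project_model,
    report_coefficients,
    response_marginal,
    response_single,
)
from maxentsdm.io_tabular import AsciiGrid
from maxentsdm.transform import derive_vars


@pytest.fixture
def fitted(pb_table):
    catalog, dv = derive_vars(pb_table, types=("L", "M", "D", "B"))
    model = fit_model(dv, pb_table.response)
    return pb_table, catalog, dv, model


class TestProjectModel:
    def test_training_projection_ranges_are_unit_interval(self, fitted):
        table, catalog, dv, model = fitted
        res = project_model(model, catalog, table.ev)
        cont = res.ranges.dropna(subset=["min"])
        np.testing.assert_allclose(cont["min"], 0.0, atol=1e-12)
        np.testing.assert_allclose(cont["max"], 1.0, atol=1e-12)
        assert (res.ranges["status"] == "inside").all()
        assert len(res.predictions) == len(table.df)

    def test_clamped_projection_ignores_out_of_range_distance(self, fitted):
        table, catalog, dv, model = fitted
        tmax = catalog.entries["temp"][0][1].params["train_max"]
        base = table.ev.iloc[:1].copy()
        rows = []
        for v in (tmax, tmax + 1.0, tmax + 100.0):
            r = base.copy()
            r["temp"] = v
            rows.append(r)
        frame = pd.concat(rows, ignore_index=True)
        res = project_model(model, catalog, frame, clamp=True)
        np.testing.assert_allclose(res.predictions, res.predictions.iloc[0])

    def test_unclamped_out_of_range_is_flagged(self, fitted):
        table, catalog, dv, model = fitted
        frame = table.ev.iloc[:3].copy()
        frame.loc[frame.index[0], "temp"] = 1e6
        res = project_model(model, catalog, frame)
        row = res.ranges[res.ranges["EV"] == "temp"].iloc[0]
        assert row["status"] == "outside" and row["max"] > 1.0

    def test_unseen_categorical_level_flags_outside(self, fitted):
        table, catalog, dv, model = fitted
        frame = table.ev.iloc[:3].copy()
        frame.loc[frame.index[0], "soil"] = "zz"
        res = project_model(model, catalog, frame)
        row = res.ranges[res.ranges["EV"] == "soil"].iloc[0]
        assert row["status"] == "outside"
        assert np.isfinite(res.predictions).all()

    def test_raster_and_tabular_projections_agree_cellwise(self, pb_table):
        # 2-EV toy model projected over grids vs the flattened table
        catalog, dv = derive_vars(pb_table, types=("L", "D"))
        cols = [c for c in dv.columns if c.startswith(("temp", "noise"))]
        model = fit_model(dv[cols], pb_table.response)
        rng = np.random.default_rng(3)
        header = dict(ncols=8, nrows=6, xllcorner=0.0, yllcorner=0.0, cellsize=1.0, nodata_value=-9999.0)
        vt = rng.normal(0, 1, (6, 8))
        vn = rng.uniform(0, 10, (6, 8))
        vt[2, 3] = -9999.0
        grids = {"temp": AsciiGrid(values=vt, **header), "noise": AsciiGrid(values=vn, **header)}
        res = project_model(model, catalog, grids)
        flat = pd.DataFrame({"temp": vt.ravel(), "noise": vn.ravel()})
        valid = flat["temp"] != -9999.0
        tab = project_model(model, catalog, flat[valid])
        np.testing.assert_array_equal(
            res.predictions.values.ravel()[valid.to_numpy()], np.asarray(tab.predictions)
        )
        assert res.predictions.values[2, 3] == -9999.0

    def test_missing_ev_raises(self, fitted):
        table, catalog, dv, model = fitted
        with pytest.raises(KeyError, match="missing"):
            project_model(model, catalog, table.ev.drop(columns=["temp"]))

    def test_mean_training_background_pro_is_one(self, fitted):
        table, catalog, dv, model = fitted
        res = project_model(model, catalog, table.ev)
        rv = np.asarray(table.response, float)
        preds = np.asarray(res.predictions)
        bg_mean = np.concatenate([preds[np.isnan(rv)], preds[rv == 1.0]]).mean()
        assert bg_mean == pytest.approx(1.0, abs=1e-8)


class TestResponseCurves:
    def test_single_effect_curve_of_one_ev_model_matches_projection(self, pb_table):
        catalog, dv = derive_vars(pb_table, types=("L", "D"))
        cols = catalog.groups["temp"]
        model = fit_model(dv[cols], pb_table.response)
        curve = response_single(model, catalog, dv, pb_table.response, "temp", grid_n=21)
        proj = project_model(model, catalog, pd.DataFrame({"temp": curve["temp"]}))
        np.testing.assert_allclose(curve["response"], np.asarray(proj.predictions), rtol=1e-9)

    def test_linear_only_response_ratio_is_exp_beta(self, pb_table):
        catalog, dv = derive_vars(pb_table, types=("L",))
        model = fit_model(dv[["temp_L"]], pb_table.response)
        curve = response_single(model, catalog, dv, pb_table.response, "temp", grid_n=2)
        ratio = curve["response"].iloc[-1] / curve["response"].iloc[0]
        assert np.log(ratio) == pytest.approx(model.beta_[0])

    def test_marginal_curve_matches_closed_form(self, pb_table):
        catalog, dv = derive_vars(pb_table, types=("L",))
        model = fit_model(dv[["temp_L", "noise_L"]], pb_table.response)
        curve = response_marginal(model, catalog, pb_table.ev, "temp", grid_n=11)
        fn_t = dict(catalog.entries["temp"])["temp_L"]
        fn_n = dict(catalog.entries["noise"])["noise_L"]
        x2 = fn_n(np.array([pb_table.ev["noise"].mean()]))[0]
        expect = np.exp(model.alpha_ + model.beta_[0] * fn_t(curve["temp"].to_numpy()) + model.beta_[1] * x2)
        np.testing.assert_allclose(curve["response"], expect, rtol=1e-12)

    def test_zero_coefficient_ev_leaves_marginal_curve_unchanged(self, pb_table):
        catalog, dv = derive_vars(pb_table, types=("L",))
        m1 = fit_model(dv[["temp_L"]], pb_table.response)
        d2 = MaxentModel.from_dict(
            {**m1.to_dict(), "dv_names": ["temp_L", "noise_L"], "beta": [m1.beta_[0], 0.0]}
        )
        c1 = response_marginal(m1, catalog, pb_table.ev, "temp", grid_n=11)
        c2 = response_marginal(d2, catalog, pb_table.ev, "temp", grid_n=11)
        np.testing.assert_allclose(c1["response"], c2["response"])

    def test_ev_not_in_model_raises(self, fitted):
        table, catalog, dv, model = fitted
        sub = fit_model(dv[catalog.groups["temp"]], table.response)
        with pytest.raises(ValueError, match="not in the model"):
            response_single(sub, catalog, dv, table.response, "noise")


class TestReportCoefficients:
    def test_sorted_by_absolute_beta(self, fitted):
        table, catalog, dv, model = fitted
        rep = report_coefficients(model, catalog)
        betas = rep[~rep["dv"].str.startswith("(")]["beta"].abs()
        assert betas.is_monotonic_decreasing

    def test_null_model_reports_only_normalizer(self, pb_table):
        m = fit_model(pd.DataFrame(index=pb_table.df.index), pb_table.response)
        rep = report_coefficients(m)
        assert list(rep["dv"]) == ["(alpha)", "(N)"]

    def test_round_trip_report_is_identical(self, tmp_path, fitted):
        table, catalog, dv, model = fitted
        p = tmp_path / "m.json"
        model.to_json(p)
        rep1 = report_coefficients(model, catalog)
        rep2 = report_coefficients(MaxentModel.from_json(p), catalog)
        pd.testing.assert_frame_equal(rep1, rep2)
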