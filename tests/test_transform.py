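import numpy as np
import pandas as pd
import pytest
import scipy.stats

from maxentsdm.synthetic import Effect, EVSpec, SyntheticSpec, generate
from maxentsdm.transform import (
    DegenerateEVError,
    DerivedVariables,
    DVCatalog,
    binary_dvs,
    derive_vars,
    deviation_dv,
    linear_dv,
    local_maxima,
    spline_dvs,
    zero_skewness_dv,
)


class TestLinear:
    def test_endpoints_and_midpoint(self):
        fn = linear_dv(np.array([2.0, 6.0, 10.0]), "ev")
        assert fn(np.array([2.0]))[0] == 0.0
        assert fn(np.array([10.0]))[0] == 1.0
        assert fn(np.array([6.0]))[0] == 0.5

    def test_extrapolation_is_not_clamped(self):
        fn = linear_dv(np.array([2.0, 10.0]), "ev")
        assert fn(np.array([12.0]))[0] == pytest.approx(1.25)

    def test_constant_ev_raises(self):
        with pytest.raises(DegenerateEVError):
            linear_dv(np.full(5, 3.0), "ev")


class TestZeroSkewness:
    def test_symmetric_sample_reduces_to_linear_rescale(self):
        fn = zero_skewness_dv(np.array([1.0, 2.0, 3.0]), "ev")
        np.testing.assert_allclose(fn(np.array([1.0, 2.0, 3.0])), [0.0, 0.5, 1.0])

    @pytest.mark.parametrize("sign", [1.0, -1.0], ids=["right-skewed", "left-skewed"])
    def test_lognormal_sample_skewness_vanishes(self, rng, sign):
        x = sign * rng.lognormal(0.0, 1.0, 500)
        fn = zero_skewness_dv(x, "ev")
        # independent skewness implementation as the oracle
        assert abs(scipy.stats.skew(fn(x))) < 1e-6

    def test_monotonicity_preserved(self, rng):
        x = rng.lognormal(0.0, 0.8, 200)
        fn = zero_skewness_dv(x, "ev")
        order = np.argsort(x)[::-1]
        out = fn(x[order])
        assert np.all(np.diff(out) <= 0)

    def test_training_column_spans_unit_interval(self, rng):
        x = rng.lognormal(0.0, 1.0, 300)
        y = zero_skewness_dv(x, "ev")(x)
        assert y.min() == pytest.approx(0.0, abs=1e-12)
        assert y.max() == pytest.approx(1.0, abs=1e-12)


class TestDeviation:
    def test_zero_at_optimum_for_every_exponent(self):
        x = np.linspace(0, 10, 11)
        for name, fn in deviation_dv(x, 6.0, "ev"):
            assert fn(np.array([6.0]))[0] == 0.0

    def test_hand_computed_squared_deviation(self):
        x = np.arange(11, dtype=float)
        dvs = dict(deviation_dv(x, 6.0, "ev"))
        d2 = dvs["ev_D2"]
        assert d2(np.array([0.0]))[0] == pytest.approx(1.0)
        assert d2(np.array([10.0]))[0] == pytest.approx(16.0 / 36.0)

    def test_names_encode_exponent(self):
        names = [n for n, _ in deviation_dv(np.arange(5.0), 2.0, "slope")]
        assert names == ["slope_D05", "slope_D1", "slope_D2"]

    def test_undefined_optimum_falls_back_to_median(self):
        x = np.arange(7.0)
        with pytest.warns(UserWarning, match="median"):
            dvs = deviation_dv(x, None, "ev")
        assert dvs[0][1].params["optimum"] == 3.0


class TestSplines:
    def test_local_maximum_retention_rule(self):
        assert list(local_maxima([0.01, 0.03, 0.02, 0.04, 0.01])) == [1, 3]
        assert list(local_maxima([0.05, 0.01, 0.02])) == [0, 2]
        assert list(local_maxima([0.01])) == [0]

    def test_hinge_endpoints_after_rescale(self, pb_table):
        rv = pb_table.response
        x = np.asarray(pb_table.ev["temp"], float)
        dvs = spline_dvs(x, rv, "HF", "temp", n_knots=5)
        assert dvs, "at least one hinge DV retained"
        for _, fn in dvs:
            k = fn.params["knot"]
            assert fn(np.array([k]))[0] == 0.0
            assert fn(np.array([x.max()]))[0] == pytest.approx(1.0)

    def test_threshold_knot_recovers_true_step(self):
        """With a single true threshold response, the retained T knot
        nearest the step achieves the maximum D-squared of the scan."""
        spec = SyntheticSpec(
            n_background=2000,
            n_presence=300,
            evs=[EVSpec("ev1", "continuous", ("uniform", 0.0, 1.0))],
            true_model=[Effect("ev1", "threshold", 2.0, {"knot": 0.5})],
            seed=101,
            with_coords=False,
        )
        table, _ = generate(spec)
        rv = table.response
        x = np.asarray(table.ev["ev1"], float)
        from maxentsdm.fitting import fit_model
        from maxentsdm.transform import TransformFn

        # oracle: exhaustive one-DV D-squared scan over the same knot grid
        lo, hi = x.min(), x.max()
        knots = lo + (hi - lo) * np.arange(1, 21) / 21
        scan = []
        for k in knots:
            col = (x > k).astype(float)
            scan.append(fit_model(pd.DataFrame({"t": col}), rv).dsq_)
        best_knot = knots[int(np.argmax(scan))]
        grid_step = knots[1] - knots[0]
        assert abs(best_knot - 0.5) <= grid_step  # scan peak brackets the step

        retained = spline_dvs(x, rv, "T", "ev1", n_knots=20)
        kept_knots = [fn.params["knot"] for _, fn in retained]
        assert any(np.isclose(k, best_knot) for k in kept_knots)

    def test_too_few_distinct_values_yields_no_dvs(self):
        with pytest.warns(UserWarning, match="fewer than 3"):
            out = spline_dvs(np.array([1.0, 1.0, 2.0, 2.0]), np.array([1.0, 1, np.nan, np.nan]), "HF")
        assert out == []


class TestBinary:
    def test_one_hot_encoding(self):
        dvs = binary_dvs(np.array(["a", "b", "c", "b"], dtype=object), "lc")
        row = np.array(["b"], dtype=object)
        encoded = [fn(row)[0] for _, fn in dvs]
        assert encoded == [0.0, 1.0, 0.0]

    def test_unseen_level_maps_to_all_zeros(self):
        dvs = binary_dvs(np.array(["a", "b", "c"], dtype=object), "lc")
        row = np.array(["d"], dtype=object)
        assert all(fn(row)[0] == 0.0 for _, fn in dvs)

    def test_indicator_column_sums_match_level_counts(self, rng):
        levels = rng.choice(np.array(["a", "b", "c", "d"], dtype=object), 200)
        dvs = binary_dvs(levels, "lc")
        direct = pd.Series(levels).value_counts()
        for name, fn in dvs:
            lev = fn.params["level"]
            assert fn(levels).sum() == direct[lev]

    def test_single_level_warns_and_yields_nothing(self):
        with pytest.warns(UserWarning, match="single level"):
            assert binary_dvs(np.array(["a", "a"], dtype=object), "lc") == []


class TestDeriveVars:
    def test_linear_only_yields_one_named_dv(self, pb_table):
        catalog, dv = derive_vars(pb_table, types=("L",))
        assert catalog.groups["temp"] == ["temp_L"]
        assert list(dv.columns) == ["temp_L", "noise_L"]

    def test_categorical_level_count(self, pb_table):
        catalog, dv = derive_vars(pb_table, types=("B",))
        assert len(catalog.groups["soil"]) == 3

    def test_all_training_dvs_span_unit_interval(self, pb_table):
        catalog, dv = derive_vars(pb_table, types=("L", "M", "D", "HF", "HR", "T", "B"))
        for ev, fns in catalog.entries.items():
            for name, fn in fns:
                col = dv[name]
                if fn.type_tag in ("T", "B"):
                    assert set(np.unique(col)) <= {0.0, 1.0}
                else:
                    assert col.min() == pytest.approx(0.0, abs=1e-12)
                    assert col.max() == pytest.approx(1.0, abs=1e-12)

    def test_empty_type_set_raises(self, pb_table):
        with pytest.raises(ValueError):
            derive_vars(pb_table, types=())

    def test_serialized_catalog_reproduces_training_columns(self, tmp_path, pb_table):
        catalog, dv = derive_vars(pb_table, types=("L", "M", "D", "B"))
        p = tmp_path / "catalog.json"
        catalog.to_json(p)
        catalog2 = DVCatalog.from_json(p)
        dv2 = catalog2.transform(pb_table.ev)
        pd.testing.assert_frame_equal(dv, dv2)

    def test_monotone_types_preserve_or_invert_order(self, rng):
        x = np.sort(rng.lognormal(0, 1, 50))
        df = pd.DataFrame({"RV": [1.0] * 5 + [np.nan] * 45, "ev": x})
        from maxentsdm.io_tabular import OccurrenceTable

        table = OccurrenceTable(df, categorical=set())
        catalog, dv = derive_vars(table, types=("L", "M", "HF", "HR", "T"))
        for name, fn in catalog.entries["ev"]:
            diffs = np.diff(dv[name])
            if fn.type_tag == "HR":
                assert np.all(diffs <= 0)
            else:
                assert np.all(diffs >= 0)
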