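import io

import numpy as np
import pandas as pd
import pytest
import scipy.special

from maxentsdm.fitting import fit_model
from maxentsdm.selection import (
    TRAIL_COLUMNS,
    choose_model,
    nested_f_test,
    select_dv_for_ev,
    select_ev,
    write_trail,
)
from maxentsdm.synthetic import Effect, EVSpec, SyntheticSpec, generate
from maxentsdm.transform import derive_vars


def f_sf_oracle(F, d1, d2):
    """Upper-tail F probability via the regularized incomplete beta
    function (independent of scipy.stats.f)."""
    return scipy.special.betainc(d2 / 2.0, d1 / 2.0, d2 / (d2 + d1 * F))


class TestNestedFTest:
    def test_no_added_deviance_gives_f_zero_p_one(self):
        F, df_e, df_u, p = nested_f_test(0.02, 0.02, 3, 2, 1000)
        assert F == 0.0 and p == 1.0

    def test_df_accounting_matches_audit_convention(self):
        """With n = 16,420 background locations, a one-DV model has
        df_u = 16,417 and a 20-DV model has df_u = 16,398."""
        _, df_e, df_u, _ = nested_f_test(0.012, 0.0, 1, 0, 16420)
        assert (df_e, df_u) == (1, 16417)
        _, df_e, df_u, _ = nested_f_test(0.031, 0.03, 20, 19, 16420)
        assert (df_e, df_u) == (1, 16398)

    def test_p_values_match_incomplete_beta_oracle(self, rng):
        for _ in range(1000):
            dsq_ref = rng.uniform(0, 0.5)
            dsq_full = dsq_ref + rng.uniform(0, 0.4)
            m_ref = int(rng.integers(0, 5))
            m_full = m_ref + int(rng.integers(1, 6))
            n = int(rng.integers(m_full + 10, 20000))
            F, df_e, df_u, p = nested_f_test(dsq_full, dsq_ref, m_full, m_ref, n)
            assert abs(p - f_sf_oracle(F, df_e, df_u)) < 1e-10

    def test_saturated_model_gives_zero_p(self):
        F, _, _, p = nested_f_test(1.0, 0.5, 2, 1, 100)
        assert np.isinf(F) and p == 0.0

    def test_nonpositive_df_u_raises(self):
        with pytest.raises(ValueError, match="df"):
            nested_f_test(0.5, 0.1, 10, 5, 11)


@pytest.fixture
def selection_data():
    spec = SyntheticSpec(
        n_background=1500,
        n_presence=200,
        evs=[
            EVSpec("good", "continuous", ("uniform", 0.0, 1.0)),
            EVSpec("dud", "continuous", ("normal", 0.0, 1.0)),
        ],
        true_model=[Effect("good", "hinge", 3.0, {"knot": 0.4, "scale": 0.6})],
        seed=21,
        with_coords=False,
    )
    table, _ = generate(spec)
    catalog, dv = derive_vars(table, types=("L", "M", "D", "HF"))
    return table, catalog, dv


class TestSelectDVForEV:
    def test_true_hinge_dv_selected_first(self, selection_data):
        table, catalog, dv = selection_data
        results = select_dv_for_ev(catalog, dv, table.response)
        first = results["good"].trail.iloc[0]
        # oracle: exhaustive one-DV D-squared scan over the same candidates
        scan = {
            name: fit_model(dv[[name]], table.response).dsq_
            for name in catalog.groups["good"]
        }
        assert first["variables"] == max(scan, key=scan.get)
        assert results["good"].selected

    def test_uninformative_ev_is_dropped(self, selection_data):
        table, catalog, dv = selection_data
        results = select_dv_for_ev(catalog, dv, table.response)
        assert results["dud"].selected == {}
        # and its trail shows why: best candidate failed the threshold
        assert results["dud"].trail.iloc[0]["p"] >= 0.01

    def test_empty_candidate_list_gives_empty_trail(self, selection_data):
        table, catalog, dv = selection_data

        class EmptyCatalog:
            groups = {"ghost": []}

        res = select_dv_for_ev(EmptyCatalog(), dv, table.response)
        assert res["ghost"].selected == {} and len(res["ghost"].trail) == 0


class TestSelectEV:
    def test_trail_rows_sorted_by_p_within_round(self, selection_data):
        table, catalog, dv = selection_data
        stage1 = select_dv_for_ev(catalog, dv, table.response)
        sets = {ev: r.selected[ev] for ev, r in stage1.items() if r.selected}
        sets["dud"] = ["dud_L"]  # force a competitor to create a full round
        res = select_ev(sets, dv, table.response)
        assert list(res.trail.columns) == TRAIL_COLUMNS
        for _, grp in res.trail.groupby("round"):
            assert grp["p"].is_monotonic_increasing

    def test_accepted_path_never_loses_deviance(self, selection_data):
        table, catalog, dv = selection_data
        sets = {"good": catalog.groups["good"], "dud": ["dud_L", "dud_M"]}
        res = select_ev(sets, dv, table.response)
        accepted = res.trail.groupby("round").first()
        assert accepted["Dsq"].is_monotonic_increasing

    def test_insignificant_single_candidate_keeps_null_model(self, selection_data):
        table, catalog, dv = selection_data
        res = select_ev({"dud": ["dud_L"]}, dv, table.response)
        assert res.selected == {}
        assert res.final_model.m_ == 0 and res.final_model.dsq_ == 0.0
        assert len(res.trail) == 1

    def test_duplicated_ev_is_never_retained_twice(self, selection_data):
        """A copy of an already-included EV adds no orthogonal deviance,
        so subset selection never keeps both."""
        table, catalog, dv = selection_data
        dv2 = dv.copy()
        copies = {}
        for name in catalog.groups["good"]:
            dv2[f"copy_{name}"] = dv[name]
            copies.setdefault("goodcopy", []).append(f"copy_{name}")
        sets = {"good": catalog.groups["good"], "goodcopy": copies["goodcopy"]}
        res = select_ev(sets, dv2, table.response)
        assert set(res.selected) != {"good", "goodcopy"}

    def test_formula_start_forces_ev_into_base_model(self, selection_data):
        table, catalog, dv = selection_data
        sets = {"good": catalog.groups["good"], "dud": ["dud_L"]}
        res = select_ev(sets, dv, table.response, formula_start=["dud"])
        assert "dud" in res.selected

    def test_formula_start_unknown_ev_raises(self, selection_data):
        table, catalog, dv = selection_data
        with pytest.raises(ValueError, match="unknown"):
            select_ev({"good": ["good_L"]}, dv, table.response, formula_start=["nope"])

    def test_interaction_candidates_are_products(self, selection_data):
        table, catalog, dv = selection_data
        sets = {"good": ["good_L"], "dud": ["dud_L"]}
        res = select_ev(
            sets, dv, table.response, alpha=0.9, interaction=True
        )
        inter = [u for u in res.selected if ":" in u]
        if inter:  # when accepted, interaction DVs are rescaled products
            names = res.selected[inter[0]]
            assert all(":" in n for n in names)

    def test_trail_is_byte_identical_across_reruns(self, tmp_path, selection_data):
        table, catalog, dv = selection_data
        sets = {"good": catalog.groups["good"], "dud": ["dud_L", "dud_M"]}
        paths = []
        for i in range(2):
            res = select_ev(sets, dv, table.response)
            p = tmp_path / f"trail{i}.csv"
            write_trail(res.trail, p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]


class TestChooseModel:
    def test_formula_reproduces_trail_dsq(self, selection_data):
        table, catalog, dv = selection_data
        stage1 = select_dv_for_ev(catalog, dv, table.response)
        sets = {ev: r.selected[ev] for ev, r in stage1.items() if r.selected}
        res = select_ev(sets, dv, table.response)
        evs = [ev for ev in res.selected]
        m = choose_model(sets, dv, table.response, evs)
        assert m.dsq_ == pytest.approx(res.final_model.dsq_)
        np.testing.assert_allclose(m.beta_, res.final_model.beta_)

    def test_empty_formula_is_null_model(self, selection_data):
        table, catalog, dv = selection_data
        m = choose_model({"good": ["good_L"]}, dv, table.response, [])
        assert m.m_ == 0 and m.dsq_ == 0.0

    def test_unknown_ev_raises(self, selection_data):
        table, catalog, dv = selection_data
        with pytest.raises(ValueError, match="not among"):
            choose_model({"good": ["good_L"]}, dv, table.response, ["ghost"])
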