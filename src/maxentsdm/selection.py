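"""Two-stage forward subset selection of derived variables.

Model selection proceeds by forward stepwise inclusion with a nested-model
significance test at each step.  Comparing a richer model (m_full DVs,
fraction of deviance explained Dsq_full) with a nested simpler one gives

    F = ((Dsq_full - Dsq_ref) / df_e) / ((1 - Dsq_full) / df_u)

with df_e = m_full - m_ref (DVs added) and df_u = n - m_full - 2 degrees
of freedom for the unexplained deviance, where n is the number of
background locations used in fitting (total rows for presence-absence
regression).  The candidate with the smallest p-value is accepted when
p < alpha, and selection stops otherwise.

Selection runs in two stages.  First, within each EV, individual DVs are
selected — EVs with no significant DV are dropped.  Second, across EVs,
each EV's selected DV set enters as an indivisible unit whose added
degrees of freedom equal the number of DVs it contributes.  Because the
test demands deviance orthogonal to what is already explained, two highly
correlated EVs are never both retained.  Every comparison is recorded in a
trail table (round, variables, m, Dsq, F, df_e, df_u, p) for audit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .fitting import MaxentModel, fit_model, is_background

__all__ = [
    "nested_f_test",
    "SelectionResult",
    "select_dv_for_ev",
    "select_ev",
    "choose_model",
    "interaction_units",
    "TRAIL_COLUMNS",
]

TRAIL_COLUMNS = ["round", "variables", "m", "Dsq", "F", "df_e", "df_u", "p"]


def nested_f_test(dsq_full, dsq_ref, m_full, m_ref, n):
    """F-test of a nested model comparison on the D-squared scale.

    Returns (F, df_e, df_u, p).  ``n`` is the number of background rows
    used in fitting (presences included in the background) for
    maximum-entropy models, or the number of observations for logistic
    regression.
    """
    if m_full <= m_ref:
        raise ValueError("full model must have more DVs than the reference")
    df_e = int(m_full - m_ref)
    df_u = int(n - m_full - 2)
    if df_u <= 0:
        raise ValueError(f"non-positive unexplained df: n={n}, m={m_full}")
    if dsq_full >= 1.0:
        return np.inf, df_e, df_u, 0.0
    F = ((dsq_full - dsq_ref) / df_e) / ((1.0 - dsq_full) / df_u)
    F = max(F, 0.0)
    p = float(stats.f.sf(F, df_e, df_u))
    return float(F), df_e, df_u, p


def _test_n(model: MaxentModel, rv) -> int:
    if model.algorithm == "maxent":
        return model.n_background_
    return int(len(np.asarray(rv)))


@dataclass
class SelectionResult:
    """Outcome of a forward-selection stage."""

    selected: dict[str, list[str]]  # EV -> chosen DV names
    trail: pd.DataFrame  # TRAIL_COLUMNS
    final_model: MaxentModel


def _forward_select(dv_df, rv, units, alpha, algorithm, bg_weight):
    """Generic forward selection over indivisible candidate units.

    ``units`` is an ordered dict unit_name -> list of DV column names.
    Ranking within a round is by p ascending, then F descending, then
    input order; the best candidate is accepted when p < alpha.
    """
    chosen: list[str] = []
    chosen_cols: list[str] = []
    remaining = list(units)
    trail_rows = []
    base_model = fit_model(dv_df[chosen_cols], rv, algorithm=algorithm, bg_weight=bg_weight)
    base_dsq = base_model.dsq_
    round_no = 0
    while remaining:
        round_no += 1
        rows = []
        for order, unit in enumerate(remaining):
            cols = chosen_cols + units[unit]
            model = fit_model(dv_df[cols], rv, algorithm=algorithm, bg_weight=bg_weight)
            F, df_e, df_u, p = nested_f_test(
                model.dsq_, base_dsq, len(cols), len(chosen_cols), _test_n(model, rv)
            )
            rows.append(
                {
                    "round": round_no,
                    "variables": " + ".join(chosen + [unit]),
                    "m": len(cols),
                    "Dsq": model.dsq_,
                    "F": F,
                    "df_e": df_e,
                    "df_u": df_u,
                    "p": p,
                    "_unit": unit,
                    "_order": order,
                    "_model": model,
                }
            )
        rows.sort(key=lambda r: (r["p"], -r["F"], r["_order"]))
        trail_rows.extend(rows)
        best = rows[0]
        if best["p"] < alpha:
            chosen.append(best["_unit"])
            chosen_cols.extend(units[best["_unit"]])
            remaining.remove(best["_unit"])
            base_model = best["_model"]
            base_dsq = base_model.dsq_
        else:
            break
    trail = pd.DataFrame(trail_rows, columns=TRAIL_COLUMNS + ["_unit", "_order", "_model"])
    trail = trail[TRAIL_COLUMNS].reset_index(drop=True)
    return chosen, chosen_cols, trail, base_model


def select_dv_for_ev(
    catalog,
    dv_df: pd.DataFrame,
    rv,
    alpha: float = 0.01,
    algorithm: str = "maxent",
    bg_weight: float = 100.0,
) -> dict[str, SelectionResult]:
    """Stage one: forward DV selection separately within each EV.

    Returns a mapping EV -> SelectionResult; EVs whose selection is empty
    (no DV reaching p < alpha) have an empty ``selected`` entry and are
    dropped from further modelling.
    """
    out = {}
    for ev, names in catalog.groups.items():
        units = {name: [name] for name in names}
        chosen, cols, trail, model = _forward_select(
            dv_df, rv, units, alpha, algorithm, bg_weight
        )
        out[ev] = SelectionResult({ev: cols} if cols else {}, trail, model)
    return out


def interaction_units(selected: dict[str, list[str]], dv_df: pd.DataFrame):
    """Candidate product units between pairs of selected EVs.

    Product DVs are rescaled to [0, 1] after multiplication and named
    ``ev1:ev2_dv1.dv2``; each EV pair forms one indivisible unit.
    """
    evs = list(selected)
    units = {}
    cols = {}
    for i in range(len(evs)):
        for j in range(i + 1, len(evs)):
            a, b = evs[i], evs[j]
            unit = f"{a}:{b}"
            names = []
            for da in selected[a]:
                for db in selected[b]:
                    prod = dv_df[da].to_numpy() * dv_df[db].to_numpy()
                    lo, hi = prod.min(), prod.max()
                    if hi == lo:
                        continue
                    name = f"{a}:{b}_{da.split('_', 1)[1]}.{db.split('_', 1)[1]}"
                    cols[name] = (prod - lo) / (hi - lo)
                    names.append(name)
            if names:
                units[unit] = names
    return units, pd.DataFrame(cols, index=dv_df.index)


def select_ev(
    selected_dv_sets: dict[str, list[str]],
    dv_df: pd.DataFrame,
    rv,
    alpha: float = 0.01,
    interaction: bool = False,
    formula_start=None,
    algorithm: str = "maxent",
    bg_weight: float = 100.0,
) -> SelectionResult:
    """Stage two: forward selection over whole per-EV DV sets.

    ``formula_start`` names EVs unconditionally included in the base model.
    With ``interaction=True``, after main-effect selection terminates,
    products of DV pairs between selected EVs are tested as further
    candidate units.
    """
    units = {ev: list(names) for ev, names in selected_dv_sets.items() if names}
    if not units:
        raise ValueError("no EV has a nonempty selected DV set")
    start_cols: list[str] = []
    start_evs: list[str] = []
    if formula_start:
        for ev in formula_start:
            if ev not in units:
                raise ValueError(f"formula_start EV {ev!r} unknown or empty")
            start_evs.append(ev)
            start_cols.extend(units.pop(ev))

    if start_cols:
        # selection proceeds on top of the unconditional base model
        chosen, cols, trail, model = _forward_select_from(
            dv_df, rv, units, alpha, algorithm, bg_weight, start_evs, start_cols
        )
    else:
        chosen, cols, trail, model = _forward_select(dv_df, rv, units, alpha, algorithm, bg_weight)
        chosen = list(chosen)

    all_chosen_evs = start_evs + [ev for ev in chosen if ":" not in ev]
    sel = {ev: selected_dv_sets[ev] for ev in all_chosen_evs}
    frame = dv_df

    if interaction and len(all_chosen_evs) >= 2:
        iunits, icols = interaction_units(sel, dv_df)
        if iunits:
            frame = pd.concat([dv_df, icols], axis=1)
            ichosen, icols_sel, itrail, imodel = _forward_select_from(
                frame, rv, iunits, alpha, algorithm, bg_weight,
                all_chosen_evs, [c for ev in all_chosen_evs for c in sel[ev]],
                start_round=int(trail["round"].max() or 0),
            )
            if len(itrail):
                trail = pd.concat([trail, itrail], ignore_index=True)
            for unit in ichosen:
                sel[unit] = iunits[unit]
            model = imodel

    final_cols = [c for ev in sel for c in sel[ev]]
    final = fit_model(frame[final_cols], rv, algorithm=algorithm, bg_weight=bg_weight)
    return SelectionResult(sel, trail, final)


def _forward_select_from(
    dv_df, rv, units, alpha, algorithm, bg_weight, start_units, start_cols, start_round=0
):
    """Forward selection with a non-null base model already in place."""
    chosen = list(start_units)
    chosen_cols = list(start_cols)
    remaining = list(units)
    trail_rows = []
    base_model = fit_model(dv_df[chosen_cols], rv, algorithm=algorithm, bg_weight=bg_weight)
    base_dsq = base_model.dsq_
    round_no = start_round
    accepted = []
    while remaining:
        round_no += 1
        rows = []
        for order, unit in enumerate(remaining):
            cols = chosen_cols + units[unit]
            model = fit_model(dv_df[cols], rv, algorithm=algorithm, bg_weight=bg_weight)
            F, df_e, df_u, p = nested_f_test(
                model.dsq_, base_dsq, len(cols), len(chosen_cols), _test_n(model, rv)
            )
            rows.append(
                {
                    "round": round_no,
                    "variables": " + ".join(chosen + [unit]),
                    "m": len(cols),
                    "Dsq": model.dsq_,
                    "F": F,
                    "df_e": df_e,
                    "df_u": df_u,
                    "p": p,
                    "_unit": unit,
                    "_order": order,
                    "_model": model,
                }
            )
        rows.sort(key=lambda r: (r["p"], -r["F"], r["_order"]))
        trail_rows.extend(rows)
        best = rows[0]
        if best["p"] < alpha:
            chosen.append(best["_unit"])
            accepted.append(best["_unit"])
            chosen_cols.extend(units[best["_unit"]])
            remaining.remove(best["_unit"])
            base_model = best["_model"]
            base_dsq = base_model.dsq_
        else:
            break
    trail = pd.DataFrame(trail_rows, columns=TRAIL_COLUMNS + ["_unit", "_order", "_model"])
    trail = trail[TRAIL_COLUMNS].reset_index(drop=True)
    return accepted, chosen_cols, trail, base_model


def choose_model(
    selected_dv_sets: dict[str, list[str]],
    dv_df: pd.DataFrame,
    rv,
    formula: list[str],
    algorithm: str = "maxent",
    bg_weight: float = 100.0,
) -> MaxentModel:
    """Fit the model containing exactly the selected DVs of the named EVs."""
    cols = []
    for ev in formula:
        if ev not in selected_dv_sets:
            raise ValueError(f"EV {ev!r} not among the selected DV sets")
        cols.extend(selected_dv_sets[ev])
    return fit_model(dv_df[cols], rv, algorithm=algorithm, bg_weight=bg_weight)


def write_trail(trail: pd.DataFrame, path):
    """Write a selection trail CSV in the audit-table column layout."""
    trail[TRAIL_COLUMNS].to_csv(path, index=False)
    return path
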