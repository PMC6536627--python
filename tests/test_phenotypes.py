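"""Pooling, outlier removal, Type III ANOVA, Welch contrasts, fCORT."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from stresspattern import (
    PhenoSimConfig,
    anova2_type3,
    body_weight_change,
    fcort_analysis,
    phenotype_anova_table,
    pool_groups,
    remove_outliers,
    simulate_fcort_timecourse,
    simulate_phenotypes,
    welch_t,
)


def tiny_table():
    return pd.DataFrame(
        {
            "animal_id": ["a1", "a2", "a3", "a4"],
            "strain": ["B"] * 4,
            "treatment": ["NH", "CMS", "NH-R", "CMS-R"],
            "body_weight_start_g": [18.2, 22.0, 19.0, 20.0],
            "body_weight_end_g": [20.5, 21.0, 19.0, 22.5],
        }
    )


# --- pooling & body weight ------------------------------------------------

def test_pooling_splits_treatments_evenly():
    pooled = pool_groups(tiny_table())
    assert (pooled["pooled_group"] == "CMSgroup").sum() == 2
    assert (pooled["pooled_group"] == "NHgroup").sum() == 2


def test_unknown_treatment_rejected():
    t = tiny_table()
    t.loc[0, "treatment"] = "SHAM"
    with pytest.raises(ValueError, match="SHAM"):
        pool_groups(t)


def test_body_weight_change_arithmetic():
    change = body_weight_change(tiny_table())
    assert change["a1"] == pytest.approx(2.3)
    assert change["a2"] == pytest.approx(-1.0)
    assert change["a3"] == 0.0


def test_missing_weight_excluded_with_warning():
    t = tiny_table()
    t.loc[3, "body_weight_end_g"] = np.nan
    with pytest.warns(UserWarning, match="1 animals"):
        change = body_weight_change(t)
    assert len(change) == 3


# --- outlier removal ------------------------------------------------------

def test_all_equal_group_untouched():
    kept, removed = remove_outliers([5.0] * 6, ["g"] * 6)
    assert len(kept) == 6 and removed.empty


def test_hand_computed_two_sd_exceedance():
    values = [0.0] * 9 + [10.0]
    kept, removed = remove_outliers(values, ["g"] * 10)
    assert removed.tolist() == [10.0]
    assert len(kept) == 9


def test_small_groups_never_trimmed():
    kept, removed = remove_outliers([0.0, 100.0], ["g", "g"])
    assert removed.empty


@given(
    st.lists(st.floats(-100, 100, allow_nan=False), min_size=3, max_size=30)
)
def test_removed_points_exceed_criterion_kept_points_do_not(values):
    s = pd.Series(values)
    mu, sd = s.mean(), s.std(ddof=1)
    kept, removed = remove_outliers(s, ["g"] * len(s))
    if sd == 0:
        assert removed.empty
        return
    assert ((removed - mu).abs() > 2 * sd).all()
    assert ((kept - mu).abs() <= 2 * sd).all()


# --- ANOVA ----------------------------------------------------------------

def balanced_two_way_oracle(y, a, b):
    """Textbook balanced two-way decomposition from cell/marginal means."""
    df = pd.DataFrame({"y": y, "a": a, "b": b})
    grand = df["y"].mean()
    ss_a = sum(len(g) * (g["y"].mean() - grand) ** 2 for _, g in df.groupby("a"))
    ss_b = sum(len(g) * (g["y"].mean() - grand) ** 2 for _, g in df.groupby("b"))
    ss_cells = sum(len(g) * (g["y"].mean() - grand) ** 2 for _, g in df.groupby(["a", "b"]))
    ss_ab = ss_cells - ss_a - ss_b
    ss_tot = ((df["y"] - grand) ** 2).sum()
    return ss_a, ss_b, ss_ab, ss_tot - ss_cells, ss_tot


def test_balanced_design_matches_classical_decomposition():
    rng = np.random.default_rng(21)
    a = np.repeat(["a1", "a2"], 6)
    b = np.tile(np.repeat(["b1", "b2"], 3), 2)
    y = rng.normal(0, 1, 12) + np.where(a == "a2", 1.5, 0) + np.where(b == "b2", -0.8, 0)
    res = anova2_type3(y, a, b)
    ss_a, ss_b, ss_ab, ss_res, ss_tot = balanced_two_way_oracle(y, a, b)
    assert res.loc["A", "sum_sq"] == pytest.approx(ss_a, abs=1e-8)
    assert res.loc["B", "sum_sq"] == pytest.approx(ss_b, abs=1e-8)
    assert res.loc["A:B", "sum_sq"] == pytest.approx(ss_ab, abs=1e-8)
    assert res.loc["Residual", "sum_sq"] == pytest.approx(ss_res, abs=1e-8)
    # classical decomposition sums to the corrected total under balance
    assert res["sum_sq"].sum() == pytest.approx(ss_tot, abs=1e-8)
    assert res.loc["A", "eta_sq"] == pytest.approx(ss_a / ss_tot, abs=1e-10)


def test_constant_response_degenerates_cleanly():
    res = anova2_type3([3.0] * 8, ["a1", "a2"] * 4, ["b1"] * 4 + ["b2"] * 4)
    assert (res["sum_sq"] == 0).all()
    assert (res["p"].dropna() == 1.0).all() or (res["p"] == 1.0).all()


def test_factor_with_equal_cell_means_has_zero_ss():
    # factor B identical across its levels within each A level: SS_B = 0
    a = np.repeat(["a1", "a2"], 4)
    b = np.tile(["b1", "b1", "b2", "b2"], 2)
    y = np.array([1.0, 3.0, 1.0, 3.0, 5.0, 7.0, 5.0, 7.0])
    res = anova2_type3(y, a, b)
    assert res.loc["B", "sum_sq"] == pytest.approx(0.0, abs=1e-10)
    assert res.loc["A:B", "sum_sq"] == pytest.approx(0.0, abs=1e-10)


def test_empty_cell_raises_named_error():
    a = ["a1", "a1", "a2", "a2"]
    b = ["b1", "b2", "b1", "b1"]
    with pytest.raises(ValueError, match="a2.*b2"):
        anova2_type3([1.0, 2.0, 3.0, 4.0], a, b)


def test_eta_squared_in_unit_interval_on_unbalanced_data():
    rng = np.random.default_rng(5)
    n = 40
    a = rng.choice(["a1", "a2", "a3"], n)
    b = rng.choice(["b1", "b2"], n)
    # guarantee non-empty cells
    a[:6] = ["a1", "a1", "a2", "a2", "a3", "a3"]
    b[:6] = ["b1", "b2", "b1", "b2", "b1", "b2"]
    y = rng.normal(0, 1, n)
    res = anova2_type3(y, a, b)
    assert ((res["eta_sq"] >= 0) & (res["eta_sq"] <= 1)).all()


# --- Welch ----------------------------------------------------------------

def welch_oracle(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    return t, df


def test_welch_identical_groups():
    r = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert r.t == 0.0 and r.p == pytest.approx(1.0)


def test_welch_antisymmetry():
    a, b = [1.0, 2.0, 5.0], [2.0, 3.0, 4.0, 9.0]
    r1, r2 = welch_t(a, b), welch_t(b, a)
    assert r1.t == pytest.approx(-r2.t)
    assert r1.p == pytest.approx(r2.p)


def test_welch_matches_textbook_formula():
    a, b = [1.0, 2.0, 3.0], [2.0, 3.0, 4.0]
    r = welch_t(a, b)
    t, df = welch_oracle(a, b)
    assert abs(r.t - t) < 1e-10
    assert abs(r.df - df) < 1e-10
    assert r.df <= len(a) + len(b) - 2


def test_welch_scale_and_shift_invariance():
    rng = np.random.default_rng(3)
    a, b = rng.normal(0, 1, 8), rng.normal(1, 2, 6)
    r = welch_t(a, b)
    assert welch_t(a + 7, b + 7).t == pytest.approx(r.t)
    assert welch_t(a * 3, b * 3).t == pytest.approx(r.t)


def test_welch_zero_variance_distinct_means():
    with pytest.warns(UserWarning):
        r = welch_t([1.0, 1.0], [2.0, 2.0])
    assert r.p == 0.0


# --- fCORT ----------------------------------------------------------------

def test_all_unit_concentrations_give_zero_ss():
    table = pd.DataFrame(
        {
            "animal_id": [f"f{i}" for i in range(12)],
            "strain": ["B", "N", "D"] * 4,
            "week": [0, 0, 0, 0, 0, 0, 1, 1, 1, 1, 1, 1],
            "fcort": 1.0,
        }
    )
    res = fcort_analysis(table)
    assert (res["sum_sq"] == 0).all()


def test_nonpositive_concentration_rejected():
    table = pd.DataFrame(
        {"animal_id": ["f1"], "strain": ["B"], "week": [0], "fcort": [0.0]}
    )
    with pytest.raises(ValueError, match="non-positive"):
        fcort_analysis(table)


def test_planted_habituation_yields_strong_week_effect():
    cfg = PhenoSimConfig(
        seed=14, group_sizes={"NH": 0, "NH-R": 0, "CMS": 30, "CMS-R": 30}
    )
    table = simulate_fcort_timecourse(cfg)
    res = fcort_analysis(table)
    assert res.loc["week", "p"] < 0.001


def test_identical_trajectories_give_near_zero_strain_ss():
    """Permutation-style check: strain labels carry no signal when
    trajectories are identical, so its SS is a small share of the total."""
    cfg = PhenoSimConfig(
        seed=15,
        fcort_baseline={"B": (1.8, 0.2), "N": (1.8, 0.2), "D": (1.8, 0.2)},
        group_sizes={"NH": 0, "NH-R": 0, "CMS": 40, "CMS-R": 40},
    )
    table = simulate_fcort_timecourse(cfg)
    res = fcort_analysis(table)
    assert res.loc["strain", "eta_sq"] < 0.02
    assert res.loc["strain", "p"] > 0.001


def test_full_phenotype_anova_table_runs():
    table = simulate_phenotypes(PhenoSimConfig(seed=1))
    res = phenotype_anova_table(table)
    assert set(res["measure"]) == {
        "body_weight_change_g", "adrenal_mg", "thymus_mg",
        "heart_mg", "brain_g", "plasma_cort_ng_ml",
    }
    heart = res[(res.measure == "heart_mg") & (res.term == "treatment")]
    assert float(heart["p"].iloc[0]) < 0.05  # planted 10.4 mg deficit detected
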