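"""Incidence tables, chi-squared comparisons, the intra-line fixed model."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from wstripe.pheno import (
    chi_square_by_category,
    fit_ws_fixed_model,
    flag_outliers,
    incidence_table,
    lsmeans_tukey,
)

# the study's per-line category counts (pHu+: 685 birds, pHu-: 664)
LINE_COUNTS = {
    "pHu+": {"NORM": 234, "MOD": 289, "SEV": 162},
    "pHu-": {"NORM": 431, "MOD": 206, "SEV": 27},
}


def counts_frame() -> pd.DataFrame:
    rows = []
    for line, by_cat in LINE_COUNTS.items():
        for cat, n in by_cat.items():
            rows += [{"id": f"{line}-{cat}-{i}", "WS": cat, "line": line, "sex": "M"}
                     for i in range(n)]
    return pd.DataFrame(rows)


def test_overall_incidence_from_per_line_counts():
    inc = incidence_table(counts_frame())
    overall = inc.iloc[-1]
    assert overall["n"] == 1349
    assert round(overall["MOD_pct"], 1) == 36.7
    assert round(overall["SEV_pct"], 1) == 14.0
    assert round(overall["affected_pct"], 1) == 50.7


def test_per_line_incidence():
    inc = incidence_table(counts_frame(), by=["line"])
    plus = inc[inc["line"] == "pHu+"].iloc[0]
    assert plus["MOD_pct"] == pytest.approx(100 * 289 / 685)


def test_all_norm_input():
    tab = pd.DataFrame({"id": range(10), "WS": ["NORM"] * 10})
    inc = incidence_table(tab)
    assert inc.iloc[-1]["NORM_pct"] == 100.0
    assert inc.iloc[-1]["MOD_pct"] == 0.0 and inc.iloc[-1]["SEV_pct"] == 0.0


def test_incidence_invariances():
    tab = counts_frame()
    base = incidence_table(tab, by=["line"])
    shuffled = incidence_table(tab.sample(frac=1, random_state=1), by=["line"])
    pd.testing.assert_frame_equal(
        base.reset_index(drop=True), shuffled.reset_index(drop=True)
    )
    with_extra = incidence_table(tab.assign(BW=1.0), by=["line"])
    pd.testing.assert_frame_equal(base, with_extra)


def test_numeric_ws_codes_accepted():
    tab = pd.DataFrame({"id": range(4), "WS": [1, 2, 3, 2]})
    inc = incidence_table(tab)
    assert inc.iloc[-1]["MOD_n"] == 2


# ------------------------------------------------------------ chi-squared


def test_chi_square_zero_for_identical_proportions():
    tab = pd.DataFrame(
        {
            "id": range(200),
            "WS": (["MOD"] * 20 + ["NORM"] * 80) * 2,
            "line": ["A"] * 100 + ["B"] * 100,
        }
    )
    res = chi_square_by_category(tab, groups=["line"])
    mod = res[(res.category == "MOD") & (res.comparison == "overall")].iloc[0]
    assert mod["statistic"] == pytest.approx(0.0, abs=1e-12)


def test_chi_square_matches_closed_form_2x2():
    """(a,b;c,d) = (10,90;20,80): X² = n(ad−bc)²/((a+b)(c+d)(a+c)(b+d)) = 3.9216."""
    tab = pd.DataFrame(
        {
            "id": range(200),
            "WS": ["MOD"] * 10 + ["NORM"] * 90 + ["MOD"] * 20 + ["NORM"] * 80,
            "line": ["A"] * 100 + ["B"] * 100,
        }
    )
    res = chi_square_by_category(tab, groups=["line"])
    mod = res[(res.category == "MOD") & (res.comparison == "overall")].iloc[0]
    n, a, b, c, d = 200, 10, 90, 20, 80
    hand = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
    assert mod["statistic"] == pytest.approx(hand, rel=1e-12)
    assert mod["statistic"] == pytest.approx(3.9216, abs=1e-4)
    assert mod["df"] == 1


def test_chi_square_df_for_four_groups():
    rng = np.random.default_rng(2)
    tab = pd.DataFrame(
        {
            "id": range(400),
            "WS": rng.choice(["NORM", "MOD", "SEV"], 400),
            "line": np.repeat(["A", "B"], 200),
            "sex": np.tile(["M", "F"], 200),
        }
    )
    res = chi_square_by_category(tab)
    assert (res[res.comparison == "overall"]["df"] == 3).all()
    # 6 pairwise comparisons of 4 groups per category
    assert (res.comparison != "overall").sum() == 3 * 6


# ------------------------------------------------- fixed model + LSMeans


def _simulated_fixed_data(seed=0, n=2000, ws_effect=0.0):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "hatch": rng.integers(1, 5, n),
            "sex": rng.choice(["M", "F"], n),
            "line": rng.choice(["pHu+", "pHu-"], n),
            "WS": rng.choice(["NORM", "MOD", "SEV"], n, p=[0.5, 0.36, 0.14]),
        }
    )
    df["y"] = (
        rng.normal(0, 1, n)
        + df["hatch"] * 0.3
        + (df["sex"] == "F") * 0.5
        + (df["line"] == "pHu+") * 1.0
        + df["WS"].map({"NORM": 0.0, "MOD": ws_effect, "SEV": 2 * ws_effect})
    )
    return df


def test_zero_ws_effect_contrasts_center_on_zero():
    fit = fit_ws_fixed_model(_simulated_fixed_data(seed=5, ws_effect=0.0), "y")
    ls = lsmeans_tukey(fit)
    for line, sub in ls.groupby("line"):
        means = sub["lsmean"].to_numpy()
        ses = sub["se"].to_numpy()
        diffs = np.subtract.outer(means, means)
        sed = np.sqrt(np.add.outer(ses**2, ses**2))
        assert np.abs(diffs / sed).max() < 4.0
        assert (sub["letters"] == sub["letters"].iloc[0]).all()


def test_nonzero_ws_effect_detected():
    fit = fit_ws_fixed_model(_simulated_fixed_data(seed=5, ws_effect=0.6), "y")
    ls = lsmeans_tukey(fit)
    for _, sub in ls.groupby("line"):
        assert sub["letters"].nunique() == 3  # all categories separated


def test_single_level_factors_reduce_to_one_way_anova():
    rng = np.random.default_rng(8)
    df = pd.DataFrame(
        {
            "hatch": 1,
            "sex": "M",
            "line": "pHu+",
            "WS": rng.choice(["NORM", "MOD", "SEV"], 300),
        }
    )
    df["y"] = rng.normal(0, 1, 300) + df["WS"].map({"NORM": 0, "MOD": 1, "SEV": 2})
    fit = fit_ws_fixed_model(df, "y")
    ls = lsmeans_tukey(fit).set_index("WS")["lsmean"]
    group_means = df.groupby("WS")["y"].mean()
    for ws in group_means.index:
        assert ls[ws] == pytest.approx(group_means[ws], abs=1e-10)


def test_fitted_plus_residuals_reproduce_y():
    df = _simulated_fixed_data(seed=1, n=500)
    fit = fit_ws_fixed_model(df, "y")
    res = fit.result
    np.testing.assert_allclose(
        res.fittedvalues + res.resid, fit.data["_y"], atol=1e-10
    )


def test_log_transform_applied():
    df = _simulated_fixed_data(seed=2, n=300)
    df["DL"] = np.exp(df["y"])
    fit = fit_ws_fixed_model(df, "DL", transform="log")
    np.testing.assert_allclose(fit.data["_y"], np.log(df.dropna()["DL"]), atol=1e-12)


def test_rank_deficiency_beyond_nesting_is_hard_error():
    df = _simulated_fixed_data(seed=3, n=400)
    df["sex"] = np.where(df["hatch"] <= 2, "M", "F")  # sex aliased with hatch
    with pytest.raises(ValueError, match="rank-deficient"):
        fit_ws_fixed_model(df, "y")


def test_balanced_design_lsmeans_equal_cell_means():
    rng = np.random.default_rng(3)
    n = 240
    df = pd.DataFrame(
        {
            "hatch": np.tile([1, 1, 2, 2], 60),
            "sex": np.tile(["M", "F"], 120),
            "line": np.repeat(["A", "B"], 120),
            "WS": np.tile(np.repeat(["NORM", "MOD", "SEV"], 40), 2),
        }
    )
    df["y"] = rng.normal(0, 1, n) + df["WS"].map({"NORM": 0, "MOD": 1, "SEV": 2})
    ls = lsmeans_tukey(fit_ws_fixed_model(df, "y"))
    cell = df.groupby(["line", "WS"])["y"].mean()
    for _, row in ls.iterrows():
        assert row["lsmean"] == pytest.approx(cell[(row["line"], row["WS"])], abs=1e-10)


def test_two_group_tukey_equals_t_test():
    rng = np.random.default_rng(4)
    df = pd.DataFrame(
        {
            "hatch": 1,
            "sex": "M",
            "line": "A",
            "WS": rng.choice(["NORM", "MOD"], 120),
        }
    )
    df["y"] = rng.normal(0, 1, 120) + (df["WS"] == "MOD") * 0.4
    fit = fit_ws_fixed_model(df, "y")
    ls = lsmeans_tukey(fit)
    pw = ls.attrs["pairwise"]
    t = stats.ttest_ind(
        df.loc[df.WS == "NORM", "y"], df.loc[df.WS == "MOD", "y"]
    )
    assert pw["p_tukey"].iloc[0] == pytest.approx(t.pvalue, rel=1e-6)


def test_lsmeans_match_prediction_grid_average_unbalanced():
    df = _simulated_fixed_data(seed=7, n=700)
    fit = fit_ws_fixed_model(df, "y")
    ls = lsmeans_tukey(fit)
    res = fit.result
    for _, row in ls.iterrows():
        grid = pd.DataFrame(
            [
                {"hatch": h, "sex": s, "line": row["line"], "WS": row["WS"]}
                for h in fit.hatch_levels
                for s in fit.sex_levels
            ]
        )
        brute = res.predict(grid).mean()
        assert row["lsmean"] == pytest.approx(brute, abs=1e-8)


def test_constant_shift_moves_every_lsmean_equally():
    df = _simulated_fixed_data(seed=9, n=600)
    base = lsmeans_tukey(fit_ws_fixed_model(df, "y"))
    shifted = lsmeans_tukey(fit_ws_fixed_model(df.assign(y=df["y"] + 7.5), "y"))
    np.testing.assert_allclose(shifted["lsmean"], base["lsmean"] + 7.5, atol=1e-8)
    assert (shifted["letters"] == base["letters"]).all()


def test_outlier_flagging_is_conservative():
    s = pd.Series(np.concatenate([np.random.default_rng(0).normal(0, 1, 200), [50.0]]))
    mask = flag_outliers(s, k=5)
    assert mask.iloc[-1]
    assert mask.iloc[:-1].sum() == 0
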