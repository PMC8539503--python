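"""Filters, marker classification rules, crosstabs, multinomial ORs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dietnet.association import (
    MarkerRules,
    apply_filters,
    classify_markers,
    crosstab_summary,
    multinomial_or,
)


# ---------------------------------------------------------------- filters
def test_energy_filter_boundaries():
    tab = pd.DataFrame({"energy_kcal": [450.0, 500.0, 2000.0, 4000.0, 4001.0]})
    kept, log = apply_filters(tab)
    assert kept["energy_kcal"].tolist() == [500.0, 2000.0, 4000.0]
    assert log["energy_out_of_range"] == 2


def test_incomplete_rows_removed_and_logged():
    tab = pd.DataFrame({"energy_kcal": [1000.0, 1500.0], "sex": ["male", None]})
    kept, log = apply_filters(tab)
    assert len(kept) == 1
    assert log["incomplete_record"] == 1
    assert log["retained"] == 1


def test_clean_table_zero_exclusions():
    tab = pd.DataFrame({"energy_kcal": [600.0, 3500.0], "sex": ["male", "female"]})
    kept, log = apply_filters(tab)
    assert len(kept) == 2
    assert log["energy_out_of_range"] == 0
    assert log["incomplete_record"] == 0


# ----------------------------------------------------------- marker rules
@pytest.mark.parametrize(
    "sbp,dbp,treated,expected",
    [
        (118, 78, "no", "normal"),
        (118, 80, "no", "elevated"),
        (125, 70, "no", "elevated"),
        (139.5, 89.5, "no", "elevated"),
        (141, 70, "no", "hypertension"),
        (120, 91, "no", "hypertension"),
        (110, 70, "yes", "hypertension"),
    ],
)
def test_bp_classification(sbp, dbp, treated, expected):
    tab = pd.DataFrame({"sbp": [sbp], "dbp": [dbp], "bp_treated": [treated]})
    out = classify_markers(tab)
    assert out["bp_group"].iloc[0] == expected


@pytest.mark.parametrize(
    "chol,expected",
    [(4.0, "optimal"), (4.65, "optimal"), (4.66, "normal"), (5.0, "normal"),
     (5.19, "borderline"), (6.21, "borderline"), (6.22, "high"), (6.3, "high")],
)
def test_cholesterol_classification(chol, expected):
    out = classify_markers(pd.DataFrame({"total_chol": [chol]}))
    assert out["chol_group"].iloc[0] == expected


def test_glucose_self_report_dominates_numeric():
    tab = pd.DataFrame({"glucose": [5.0, 5.0, 6.2],
                        "glucose_treated": ["yes", "no", "no"]})
    out = classify_markers(tab)
    assert out["glucose_group"].tolist() == [
        "prediabetes_diabetes", "normal", "prediabetes_diabetes"]


@pytest.mark.parametrize("gfr,expected",
                         [(95, "normal"), (90, "normal"), (89.9, "mild"),
                          (60, "mild"), (59.9, "moderate")])
def test_gfr_classification(gfr, expected):
    out = classify_markers(pd.DataFrame({"gfr": [gfr]}))
    assert out["gfr_group"].iloc[0] == expected


def test_contradictory_bp_row_flagged_invalid():
    tab = pd.DataFrame({"sbp": [-5.0, 80.0], "dbp": [70.0, 120.0],
                        "bp_treated": ["no", "no"]})
    out = classify_markers(tab)
    assert out["bp_group"].isna().all()


@settings(max_examples=200, deadline=None)
@given(
    sbp=st.floats(80, 220), dbp=st.floats(40, 130),
    chol=st.floats(2.0, 10.0), glu=st.floats(3.0, 15.0), gfr=st.floats(5.0, 150.0),
    bp_flag=st.booleans(), glu_flag=st.booleans(),
)
def test_every_valid_row_gets_exactly_one_category_per_marker(
        sbp, dbp, chol, glu, gfr, bp_flag, glu_flag):
    if dbp > sbp:
        sbp, dbp = dbp, sbp
    tab = pd.DataFrame({
        "sbp": [sbp], "dbp": [dbp], "bp_treated": ["yes" if bp_flag else "no"],
        "total_chol": [chol], "glucose": [glu],
        "glucose_treated": ["yes" if glu_flag else "no"], "gfr": [gfr],
    })
    out = classify_markers(tab)
    assert out["bp_group"].iloc[0] in ("normal", "elevated", "hypertension")
    assert out["chol_group"].iloc[0] in ("optimal", "normal", "borderline", "high")
    assert out["glucose_group"].iloc[0] in ("normal", "prediabetes_diabetes")
    assert out["gfr_group"].iloc[0] in ("normal", "mild", "moderate")


# --------------------------------------------------------------- crosstab
def reconstruct(counts: dict[tuple[str, str], int]) -> pd.DataFrame:
    rows = []
    for (r, c), k in counts.items():
        rows += [(r, c)] * k
    return pd.DataFrame(rows, columns=["row", "col"])


def test_column_percentages_match_printed_style():
    tab = reconstruct({("male", "normal"): 4513, ("female", "normal"): 2158})
    res = crosstab_summary(tab, "row", "col")
    assert res["percent"].loc["male", "normal"] == 67.7
    assert res["percent"].loc["female", "normal"] == 32.3


def test_identical_rows_give_chi2_zero():
    tab = reconstruct({("a", "x"): 50, ("a", "y"): 50, ("b", "x"): 50, ("b", "y"): 50})
    res = crosstab_summary(tab, "row", "col")
    assert res["statistic"] == pytest.approx(0.0, abs=1e-10)
    assert res["p"] == pytest.approx(1.0)


def test_percentages_sum_to_100_per_column():
    rng = np.random.default_rng(0)
    tab = pd.DataFrame({
        "row": rng.choice(["a", "b", "c"], 500),
        "col": rng.choice(["x", "y"], 500),
    })
    res = crosstab_summary(tab, "row", "col")
    assert np.allclose(res["percent"].sum(axis=0), 100.0, atol=0.1)


def test_continuous_row_uses_t_or_anova():
    rng = np.random.default_rng(1)
    tab = pd.DataFrame({
        "age": np.r_[rng.normal(50, 5, 300), rng.normal(55, 5, 300)],
        "grp": ["a"] * 300 + ["b"] * 300,
    })
    res = crosstab_summary(tab, "age", "grp")
    assert res["test"] == "t"
    assert res["p"] < 0.001
    tab3 = pd.DataFrame({
        "age": rng.normal(50, 5, 300),
        "grp": rng.choice(["a", "b", "c"], 300),
    })
    assert crosstab_summary(tab3, "age", "grp")["test"] == "anova"


# ---------------------------------------------------------- multinomial OR
def test_saturated_2x2_matches_cross_product_ratio():
    rows = ([("exposed", "case")] * 40 + [("exposed", "control")] * 60 +
            [("unexposed", "case")] * 20 + [("unexposed", "control")] * 80)
    tab = pd.DataFrame(rows, columns=["exposure", "outcome"])
    ors = multinomial_or(tab, "outcome", "control", {"exposure": "unexposed"})
    assert len(ors) == 1
    assert ors["OR"].iloc[0] == pytest.approx(40 * 80 / (60 * 20), abs=1e-2)
    assert ors["ci_lower"].iloc[0] <= ors["OR"].iloc[0] <= ors["ci_upper"].iloc[0]


def test_null_predictor_ci_covers_one_in_most_seeds():
    covered = 0
    for seed in range(20):
        rng = np.random.default_rng(seed)
        n = 5000
        tab = pd.DataFrame({
            "exp": rng.choice(["no", "yes"], n),
            "out": rng.choice(["ref", "case"], n),
        })
        ors = multinomial_or(tab, "out", "ref", {"exp": "no"})
        covered += ors["ci_lower"].iloc[0] <= 1.0 <= ors["ci_upper"].iloc[0]
    assert covered >= 18


def test_three_level_outcome_matches_stratified_cross_products():
    counts = {("yes", "ref"): 70, ("yes", "m1"): 50, ("yes", "m2"): 30,
              ("no", "ref"): 90, ("no", "m1"): 40, ("no", "m2"): 20}
    rows = []
    for (e, o), k in counts.items():
        rows += [(e, o)] * k
    tab = pd.DataFrame(rows, columns=["exp", "out"])
    ors = multinomial_or(tab, "out", "ref", {"exp": "no"})
    expected_m1 = (50 / 70) / (40 / 90)
    expected_m2 = (30 / 70) / (20 / 90)
    got = {r["outcome_level"]: r["OR"] for _, r in ors.iterrows()}
    assert got["m1"] == pytest.approx(expected_m1, abs=1e-2)
    assert got["m2"] == pytest.approx(expected_m2, abs=1e-2)


def test_rank_deficient_design_is_reported():
    rng = np.random.default_rng(3)
    n = 200
    a = rng.choice(["p", "q"], n)
    tab = pd.DataFrame({"a": a, "b": a, "out": rng.choice(["x", "y"], n)})
    with pytest.raises(ValueError, match="collinear"):
        multinomial_or(tab, "out", "x", {"a": "p", "b": "p"})


def test_missing_reference_level_is_an_error():
    tab = pd.DataFrame({"exp": ["yes"] * 10, "out": ["a"] * 5 + ["b"] * 5})
    with pytest.raises(ValueError, match="reference"):
        multinomial_or(tab, "out", "a", {"exp": "no"})
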