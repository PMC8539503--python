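"""Cohort filters, comorbidity-marker classification, descriptive
comparisons, and multinomial-logistic odds ratios.

Marker categories follow standard clinical guideline cutoffs:

* blood pressure (mmHg): normal (DBP < 80 and SBP < 120), elevated
  (DBP 80–89 or SBP 120–139), hypertension (DBP ≥ 90 or SBP ≥ 140, or
  antihypertensive treatment / self-reported hypertension) — flags
  dominate numeric thresholds, and precedence runs hypertension >
  elevated > normal;
* total cholesterol (mmol/L): < 4.66 optimal, [4.66, 5.19) normal,
  [5.19, 6.22) borderline, ≥ 6.22 high (half-open intervals close the
  guideline's rounding gaps);
* fasting glucose (mmol/L): normal < 6.11 without treatment or
  self-report, otherwise the combined prediabetes + diabetes group;
* GFR (mL/min/1.73 m²): ≥ 90 normal, 60–89 mildly impaired, < 60
  moderately impaired;
* BMI (kg/m²): < 23, 23–24.9, ≥ 25 (East-Asian cutoffs).

Rows reporting implausible total energy (< 500 or > 4000 kcal/day,
boundaries retained) or incomplete records are excluded before any
modeling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = ["MarkerRules", "apply_filters", "classify_markers",
           "crosstab_summary", "multinomial_or"]


@dataclass(frozen=True)
class MarkerRules:
    energy_min: float = 500.0
    energy_max: float = 4000.0
    sbp_elevated: float = 120.0
    sbp_hypertension: float = 140.0
    dbp_elevated: float = 80.0
    dbp_hypertension: float = 90.0
    chol_cuts: tuple[float, float, float] = (4.66, 5.19, 6.22)
    chol_labels: tuple[str, ...] = ("optimal", "normal", "borderline", "high")
    glucose_cut: float = 6.11
    gfr_cuts: tuple[float, float] = (60.0, 90.0)
    bmi_cuts: tuple[float, float] = (23.0, 25.0)


DEFAULT_RULES = MarkerRules()


def apply_filters(table: pd.DataFrame, rules: MarkerRules = DEFAULT_RULES,
                  required: list[str] | None = None
                  ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Energy-plausibility and completeness filters.

    Exclusion is strict: exactly 500 or 4000 kcal is retained. Returns
    the filtered table and a per-reason exclusion log.
    """
    if "energy_kcal" not in table.columns:
        raise ValueError("missing 'energy_kcal' column")
    required = required if required is not None else list(table.columns)
    log: dict[str, int] = {}
    energy = pd.to_numeric(table["energy_kcal"], errors="coerce")
    bad_energy = (energy < rules.energy_min) | (energy > rules.energy_max)
    bad_energy |= energy.isna()
    log["energy_out_of_range"] = int(bad_energy.sum())
    kept = table.loc[~bad_energy]
    incomplete = kept[required].isna().any(axis=1)
    log["incomplete_record"] = int(incomplete.sum())
    kept = kept.loc[~incomplete]
    log["retained"] = len(kept)
    return kept, log


def _classify_bp(sbp, dbp, treated) -> np.ndarray:
    invalid = (sbp <= 0) | (dbp <= 0) | (dbp > sbp)
    hyper = treated | (dbp >= 90) | (sbp >= 140)
    elevated = ~hyper & (((dbp >= 80) & (dbp < 90)) | ((sbp >= 120) & (sbp < 140)))
    out = np.where(hyper, "hypertension", np.where(elevated, "elevated", "normal"))
    return np.where(invalid, None, out)


def classify_markers(table: pd.DataFrame, rules: MarkerRules = DEFAULT_RULES,
                     overwrite: bool = True) -> pd.DataFrame:
    """Assign one category per comorbidity marker from raw measures.

    Treatment / self-report flags dominate the numeric thresholds for
    blood pressure and glucose. Physiologically contradictory rows
    (non-positive pressures, DBP > SBP) are flagged by a missing
    category. Columns already categorized are passed through when the
    raw measures are absent.
    """
    out = table.copy()

    def flag(col):
        if col in out.columns:
            return out[col].astype(str).str.lower().isin(["yes", "true", "1"]).to_numpy()
        return np.zeros(len(out), dtype=bool)

    if {"sbp", "dbp"} <= set(out.columns) and (overwrite or "bp_group" not in out):
        sbp = pd.to_numeric(out["sbp"]).to_numpy()
        dbp = pd.to_numeric(out["dbp"]).to_numpy()
        cat = _classify_bp(sbp, dbp, flag("bp_treated"))
        out["bp_group"] = pd.array(cat, dtype=object)
        out.loc[out["sbp"].isna() | out["dbp"].isna(), "bp_group"] = None

    if "total_chol" in out.columns and (overwrite or "chol_group" not in out):
        chol = pd.to_numeric(out["total_chol"])
        c1, c2, c3 = rules.chol_cuts
        lab = np.select(
            [chol < c1, chol < c2, chol < c3, chol >= c3],
            list(rules.chol_labels), default=None)
        lab = np.where(chol.isna(), None, lab)
        out["chol_group"] = pd.array(lab, dtype=object)

    if "glucose" in out.columns and (overwrite or "glucose_group" not in out):
        glu = pd.to_numeric(out["glucose"])
        high = flag("glucose_treated") | (glu >= rules.glucose_cut).to_numpy()
        lab = np.where(high, "prediabetes_diabetes", "normal")
        out["glucose_group"] = pd.array(np.where(glu.isna(), None, lab), dtype=object)

    if "gfr" in out.columns and (overwrite or "gfr_group" not in out):
        gfr = pd.to_numeric(out["gfr"])
        lo, hi = rules.gfr_cuts
        lab = np.select([gfr >= hi, gfr >= lo, gfr < lo],
                        ["normal", "mild", "moderate"], default=None)
        out["gfr_group"] = pd.array(np.where(gfr.isna() | (gfr <= 0), None, lab),
                                    dtype=object)

    if "bmi" in out.columns and (overwrite or "bmi_group" not in out):
        bmi = pd.to_numeric(out["bmi"])
        lo, hi = rules.bmi_cuts
        lab = np.select([bmi < lo, bmi < hi, bmi >= hi],
                        ["<23", "23-24.9", ">=25"], default=None)
        out["bmi_group"] = pd.array(np.where(bmi.isna() | (bmi <= 0), None, lab),
                                    dtype=object)
    return out


def crosstab_summary(table: pd.DataFrame, row_factor: str, col_factor: str,
                     row_levels: list[str] | None = None,
                     col_levels: list[str] | None = None) -> dict:
    """Counts with column percentages and a chi-square test, or group
    means ± SD with ANOVA / t-test when the row variable is continuous.

    Percentages are 100·n_kl / column total, rounded to one decimal, as
    descriptive cohort tables print them.
    """
    data = table[[row_factor, col_factor]].dropna()
    col = data[col_factor].astype(str)
    if col_levels:
        col = pd.Categorical(col, categories=col_levels)

    if pd.api.types.is_numeric_dtype(data[row_factor]):
        groups = [g.to_numpy(dtype=float)
                  for _, g in data.groupby(col, observed=True)[row_factor]]
        means = data.groupby(col, observed=True)[row_factor].agg(["mean", "std", "count"])
        if len(groups) == 2:
            stat, p = stats.ttest_ind(*groups, equal_var=True)
            test = "t"
        else:
            stat, p = stats.f_oneway(*groups)
            test = "anova"
        return {"kind": "continuous", "summary": means, "test": test,
                "statistic": float(stat), "p": float(p)}

    row = data[row_factor].astype(str)
    if row_levels:
        row = pd.Categorical(row, categories=row_levels)
    counts = pd.crosstab(row, col, dropna=False)
    pct = (100.0 * counts / counts.sum(axis=0)).round(1)
    nonzero = counts.loc[counts.sum(axis=1) > 0, counts.sum(axis=0) > 0]
    if nonzero.shape[0] > 1 and nonzero.shape[1] > 1:
        chi2, p, _, _ = stats.chi2_contingency(nonzero)
    else:
        chi2, p = 0.0, 1.0
    return {"kind": "categorical", "counts": counts, "percent": pct,
            "test": "chi2", "statistic": float(chi2), "p": float(p)}


def _dummy_design(table: pd.DataFrame, predictors: dict[str, str]) -> pd.DataFrame:
    """Reference-coded indicator design with intercept; ``predictors``
    maps column -> reference level."""
    cols = {}
    for var, ref in predictors.items():
        levels = [lv for lv in pd.unique(table[var].astype(str)) if lv != ref]
        if ref not in set(table[var].astype(str)):
            raise ValueError(f"reference level {ref!r} not observed in {var!r}")
        for lv in sorted(levels):
            cols[f"{var}[{lv}]"] = (table[var].astype(str) == lv).astype(float)
    X = pd.DataFrame(cols, index=table.index)
    X.insert(0, "const", 1.0)
    return X


def multinomial_or(table: pd.DataFrame, outcome: str, outcome_ref: str,
                   predictors: dict[str, str], maxiter: int = 200) -> pd.DataFrame:
    """Adjusted odds ratios from one multinomial logistic model.

    All predictors enter jointly (mutual adjustment). Returns a tidy
    table with one row per (outcome level vs reference) × (predictor
    level vs reference): OR = exp(β̂), Wald 95% CI = exp(β̂ ± 1.96·SE),
    and the Wald p-value.
    """
    use = table[[outcome, *predictors]].dropna()
    levels = [outcome_ref] + sorted(lv for lv in use[outcome].astype(str).unique()
                                    if lv != outcome_ref)
    if outcome_ref not in set(use[outcome].astype(str)):
        raise ValueError(f"reference level {outcome_ref!r} not observed in {outcome!r}")
    endog = pd.Categorical(use[outcome].astype(str), categories=levels).codes
    X = _dummy_design(use, predictors)

    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ValueError(f"rank-deficient design for outcome {outcome!r}: "
                         f"{X.shape[1] - rank} collinear column(s) among {list(X.columns)}")

    model = sm.MNLogit(endog, X)
    try:
        res = model.fit(method="newton", maxiter=maxiter, disp=0)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"multinomial fit failed for outcome {outcome!r}; "
                         f"possible separation") from exc
    if not res.mle_retvals.get("converged", True):
        # Newton can stall on thin outcome categories; retry with BFGS
        res = model.fit(method="bfgs", maxiter=5 * maxiter, disp=0)
    if not res.mle_retvals.get("converged", True):
        bad = X.columns[np.abs(res.params.to_numpy()).max(axis=1) > 15].tolist()
        raise ValueError(f"multinomial fit for outcome {outcome!r} did not converge; "
                         f"possible separation in predictors {bad}")

    rows = []
    params, bses, pvals = res.params, res.bse, res.pvalues
    for k, lev in enumerate(levels[1:]):
        for name in X.columns:
            if name == "const":
                continue
            beta = float(params.loc[name, k])
            se = float(bses.loc[name, k])
            var, pred_level = name[:-1].split("[", 1)
            rows.append({
                "outcome_level": lev,
                "predictor": var,
                "level": pred_level,
                "OR": float(np.exp(beta)),
                "ci_lower": float(np.exp(beta - 1.96 * se)),
                "ci_upper": float(np.exp(beta + 1.96 * se)),
                "p": float(pvals.loc[name, k]),
            })
    return pd.DataFrame(rows)
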