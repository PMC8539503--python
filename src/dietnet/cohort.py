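"""Seeded synthetic cohorts with planted ground truth.

The generator emulates the structure of a health-screening cohort table:

* 16 food-group intakes (g/day), drawn as ``exp`` of a multivariate
  normal on the log scale whose precision matrix is the planted
  Gaussian-graphical-model ground truth;
* demographic categoricals (age group, sex, marital status, education,
  employment, income, smoking, drinking, exercise, BMI group) sampled
  from a categorical Markov random field by Gibbs sampling, so that the
  planted pairwise potentials are the true conditional-dependence edges;
* comorbidity-marker categories (blood pressure, total cholesterol,
  fasting glucose, GFR) drawn from multinomial logits on the
  demographics, then back-filled with raw clinical measures lying inside
  the drawn category's numeric window so the classification rules can be
  exercised and checked;
* total energy as a fixed positive linear combination of intakes plus
  Gaussian noise, so the kcal plausibility filter has something to do;
* optional missing-completely-at-random cells (sentinel ``NA`` on disk).

Identical ``(config, seed)`` always yields a byte-identical table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from dietnet._mrf import MRFNode, MixedMRF

__all__ = [
    "FOOD_GROUPS",
    "DEMO_LEVELS",
    "MARKER_LEVELS",
    "CohortSchema",
    "DEFAULT_SCHEMA",
    "OutcomeModel",
    "SimConfig",
    "PlantedTruth",
    "default_config",
    "generate_cohort",
    "planted_truth",
    "read_cohort",
    "write_cohort",
]

FOOD_GROUPS: tuple[str, ...] = (
    "cereals_grains",
    "potatoes_starches",
    "sugars_sweets",
    "legumes",
    "seeds_nuts",
    "vegetables",
    "mushrooms",
    "fruits",
    "meat_poultry",
    "eggs",
    "fish_shellfish",
    "seaweeds",
    "milk_dairy",
    "oils_fats",
    "beverages",
    "seasonings",
)

DEMO_LEVELS: dict[str, tuple[str, ...]] = {
    "age_group": ("<50", "50-54", "55-59", ">=60"),
    "sex": ("male", "female"),
    "marital": ("married", "others"),
    "education": ("<high school", "high school", ">=college"),
    "employment": ("employed", "unemployed"),
    "income": ("<2M", "2-4M", ">=4M"),
    "smoking": ("never", "past", "current"),
    "drinking": ("never", "past", "current"),
    "exercise": ("yes", "no"),
    "bmi_group": ("<23", "23-24.9", ">=25"),
}

MARKER_LEVELS: dict[str, tuple[str, ...]] = {
    "bp_group": ("normal", "elevated", "hypertension"),
    "chol_group": ("optimal", "normal", "borderline", "high"),
    "glucose_group": ("normal", "prediabetes_diabetes"),
    "gfr_group": ("normal", "mild", "moderate"),
}

_FLAG_LEVELS = ("no", "yes")

MISSING_SENTINEL = "NA"

# kcal per gram, by food group (coarse energy densities)
_ENERGY_DENSITY = np.array(
    [1.6, 0.9, 3.9, 1.5, 5.0, 0.3, 0.3, 0.6, 2.5, 1.5, 1.3, 0.4, 0.6, 9.0, 0.4, 1.0]
)


@dataclass(frozen=True)
class CohortSchema:
    """Declared column types: level tuples for categoricals, ``None``
    for continuous columns."""

    columns: dict[str, tuple[str, ...] | None]

    def categorical(self) -> dict[str, tuple[str, ...]]:
        return {c: lv for c, lv in self.columns.items() if lv is not None}

    def continuous(self) -> list[str]:
        return [c for c, lv in self.columns.items() if lv is None]

    def validate(self, table: pd.DataFrame) -> None:
        dupes = table.columns[table.columns.duplicated()].tolist()
        if dupes:
            raise ValueError(f"duplicate column names: {dupes}")
        for col, levels in self.columns.items():
            if col not in table.columns:
                raise ValueError(f"missing column {col!r}")
            s = table[col]
            if levels is None:
                pd.to_numeric(s.dropna())  # raises on non-numeric
            else:
                observed = s.dropna().astype(str)
                unknown = ~observed.isin(levels)
                if unknown.any():
                    row = observed.index[unknown][0]
                    raise ValueError(
                        f"unknown category {observed.loc[row]!r} in column {col!r} at row {row}"
                    )


def _default_schema() -> CohortSchema:
    cols: dict[str, tuple[str, ...] | None] = {}
    for name, levels in DEMO_LEVELS.items():
        cols[name] = levels
    for f in FOOD_GROUPS:
        cols[f] = None
    cols["energy_kcal"] = None
    for c in ("sbp", "dbp", "total_chol", "glucose", "gfr"):
        cols[c] = None
    cols["bp_treated"] = _FLAG_LEVELS
    cols["glucose_treated"] = _FLAG_LEVELS
    for name, levels in MARKER_LEVELS.items():
        cols[name] = levels
    return CohortSchema(cols)


DEFAULT_SCHEMA = _default_schema()


@dataclass(frozen=True)
class OutcomeModel:
    """Multinomial logit for one comorbidity marker.

    ``coefs[var]`` is an ``(n_levels(var), n_levels(marker))`` block; the
    logit of marker level ``k`` for a participant adds
    ``coefs[var][level(var), k]`` for every predictor variable.
    """

    levels: tuple[str, ...]
    intercepts: np.ndarray
    coefs: dict[str, np.ndarray] = field(default_factory=dict)

    def logits(self, demo: pd.DataFrame) -> np.ndarray:
        n = len(demo)
        out = np.tile(np.asarray(self.intercepts, dtype=float), (n, 1))
        for var, block in self.coefs.items():
            block = np.asarray(block, dtype=float)
            idx = pd.Categorical(demo[var], categories=DEMO_LEVELS[var]).codes
            if (idx < 0).any():
                raise ValueError(f"unknown level in predictor {var!r}")
            out += block[idx]
        return out


@dataclass(frozen=True)
class SimConfig:
    n_participants: int
    food_precision: np.ndarray
    food_log_means: np.ndarray
    demo_spec: MixedMRF
    outcome_coefs: dict[str, OutcomeModel]
    energy_coefs: np.ndarray
    energy_noise_sd: float
    missing_rate: float
    seed: int
    gibbs_burn_in: int = 500
    gibbs_thin: int = 10

    def __post_init__(self):
        p = len(FOOD_GROUPS)
        prec = np.asarray(self.food_precision, dtype=float)
        if prec.shape != (p, p):
            raise ValueError(f"food_precision must be {p}x{p}")
        if not np.allclose(prec, prec.T):
            raise ValueError("food_precision must be symmetric")
        if np.linalg.eigvalsh(prec).min() <= 0:
            raise ValueError("food_precision is not positive definite")
        if len(np.asarray(self.food_log_means)) != p:
            raise ValueError(f"food_log_means must have length {p}")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.n_participants < 1:
            raise ValueError("n_participants must be positive")
        for node in self.demo_spec.nodes:
            if node.kind != "categorical":
                raise ValueError("demo_spec may contain categorical nodes only")


@dataclass(frozen=True)
class PlantedTruth:
    food_partial_corr: np.ndarray
    demo_edges: set[frozenset[str]]
    outcome_coefs: dict[str, OutcomeModel]


def _partial_corr_from_precision(omega: np.ndarray) -> np.ndarray:
    omega = np.asarray(omega, dtype=float)
    if np.linalg.eigvalsh(omega).min() <= 0:
        raise ValueError("precision matrix is not positive definite")
    d = np.sqrt(np.diag(omega))
    rho = -omega / np.outer(d, d)
    np.fill_diagonal(rho, 1.0)
    return rho


def default_config(n_participants: int = 2000, seed: int = 0,
                   missing_rate: float = 0.01) -> SimConfig:
    """Study-condition defaults for the synthetic cohort.

    The planted food network carries five partial-correlation edges on
    disjoint pairs (0.6 down to 0.3), echoing the magnitudes a screening
    cohort's strongest food-pair dependencies show; log-scale marginal
    SDs are ~0.5 around medians taken from typical East-Asian FFQ
    intake levels. Demographic potentials plant the sex–smoking,
    age–employment, marital–income, sex–employment and education–income
    dependencies; marker logits make blood pressure, glucose, GFR and
    cholesterol depend on age, sex, smoking and BMI.
    """
    p = len(FOOD_GROUPS)
    idx = {f: i for i, f in enumerate(FOOD_GROUPS)}
    base = np.eye(p)
    planted = [
        ("sugars_sweets", "oils_fats", 0.6),
        ("seasonings", "vegetables", 0.42),
        ("potatoes_starches", "cereals_grains", 0.33),
        ("fish_shellfish", "seaweeds", 0.32),
        ("milk_dairy", "fruits", 0.30),
    ]
    for a, b, rho in planted:
        base[idx[a], idx[b]] = base[idx[b], idx[a]] = -rho
    # weak ring backbone so the food network is connected, as observed
    # food networks are; keeps the matrix diagonally dominant (PD)
    for i in range(p):
        j = (i + 1) % p
        if base[i, j] == 0.0:
            base[i, j] = base[j, i] = -0.12
    food_precision = base / 0.25  # marginal log-scale SD ~ 0.5

    median_intake = np.array(
        [560.0, 43.0, 4.7, 58.0, 5.6, 305.0, 9.0, 220.0, 59.0, 18.0,
         38.0, 2.2, 108.0, 3.6, 71.0, 17.0]
    )
    food_log_means = np.log(median_intake)

    nodes = [MRFNode(name, "categorical", levels) for name, levels in DEMO_LEVELS.items()]
    ni = {n.name: k for k, n in enumerate(nodes)}
    intercepts = {
        ni["age_group"]: np.array([0.6, 0.2, 0.0, 0.1]),
        ni["sex"]: np.array([0.6, 0.0]),
        ni["marital"]: np.array([1.8, 0.0]),
        ni["education"]: np.array([-1.0, 0.0, 0.3]),
        ni["employment"]: np.array([2.4, 0.0]),
        ni["income"]: np.array([-0.4, 0.2, 0.2]),
        ni["smoking"]: np.array([1.0, 0.0, -0.4]),
        ni["drinking"]: np.array([0.3, -1.2, 0.6]),
        ni["exercise"]: np.array([0.0, 0.2]),
        ni["bmi_group"]: np.array([0.6, 0.0, 0.05]),
    }
    couplings = {
        # males smoke (past/current) far more than females
        (ni["sex"], ni["smoking"]): np.array([[0.0, 1.3, 1.2], [1.0, 0.0, 0.0]]),
        # employment drops in the oldest group
        (ni["age_group"], ni["employment"]): np.array(
            [[0.6, 0.0], [0.5, 0.0], [0.3, 0.0], [0.0, 0.7]]
        ),
        # married participants report higher income
        (ni["marital"], ni["income"]): np.array([[0.0, 0.4, 0.7], [0.5, 0.1, 0.0]]),
        # female employment rate lower
        (ni["sex"], ni["employment"]): np.array([[0.7, 0.0], [0.0, 0.5]]),
        # education tracks income
        (ni["education"], ni["income"]): np.array(
            [[0.6, 0.1, 0.0], [0.1, 0.3, 0.1], [0.0, 0.2, 0.5]]
        ),
    }
    demo_spec = MixedMRF(nodes=nodes, couplings=couplings, intercepts=intercepts)

    age_trend = lambda w: np.outer(np.array([0.0, 0.4, 0.7, 1.0]), w)  # noqa: E731
    outcome_coefs = {
        "bp_group": OutcomeModel(
            levels=MARKER_LEVELS["bp_group"],
            intercepts=np.array([0.3, 0.4, -0.6]),
            coefs={
                "age_group": age_trend(np.array([0.0, 0.4, 1.4])),
                "sex": np.array([[0.0, 0.3, 0.0], [0.0, 0.0, 0.4]]),
                "bmi_group": np.array([[0.0, 0.0, 0.0], [0.0, 0.2, 0.3], [0.0, 0.3, 0.6]]),
            },
        ),
        "chol_group": OutcomeModel(
            levels=MARKER_LEVELS["chol_group"],
            intercepts=np.array([0.4, 0.7, 0.8, -0.3]),
            coefs={
                "age_group": age_trend(np.array([0.0, 0.2, 0.4, 0.7])),
                "smoking": np.array(
                    [[0.0, 0.0, 0.0, 0.0], [0.0, 0.0, 0.1, 0.2], [0.0, 0.0, 0.2, 0.5]]
                ),
            },
        ),
        "glucose_group": OutcomeModel(
            levels=MARKER_LEVELS["glucose_group"],
            intercepts=np.array([2.2, 0.0]),
            coefs={
                "age_group": age_trend(np.array([0.0, 1.0])),
                "smoking": np.array([[0.0, 0.0], [0.0, 0.5], [0.0, 0.5]]),
            },
        ),
        "gfr_group": OutcomeModel(
            levels=MARKER_LEVELS["gfr_group"],
            intercepts=np.array([0.0, 1.1, -2.8]),
            coefs={
                "age_group": age_trend(np.array([0.0, 0.3, 2.2])),
                "sex": np.array([[0.0, 0.0, 0.2], [0.0, 0.1, 0.0]]),
            },
        ),
    }

    return SimConfig(
        n_participants=n_participants,
        food_precision=food_precision,
        food_log_means=food_log_means,
        demo_spec=demo_spec,
        outcome_coefs=outcome_coefs,
        energy_coefs=_ENERGY_DENSITY.copy(),
        energy_noise_sd=120.0,
        missing_rate=missing_rate,
        seed=seed,
    )


# numeric windows per marker category used to back-fill raw measures
_RAW_WINDOWS = {
    "chol_group": {"optimal": (3.2, 4.60), "normal": (4.70, 5.15),
                   "borderline": (5.22, 6.18), "high": (6.25, 8.5)},
    "glucose": {"normal": (4.2, 6.0), "high": (6.2, 10.0)},
    "gfr_group": {"normal": (90.0, 130.0), "mild": (60.0, 89.5), "moderate": (25.0, 59.5)},
}


def _fill_raw_markers(table: pd.DataFrame, rng: np.random.Generator) -> None:
    n = len(table)

    def uni(lo, hi, mask):
        vals = rng.uniform(lo, hi, size=n)
        return vals, mask

    # blood pressure: draw SBP/DBP inside the drawn category's window;
    # for hypertension, half of the rows qualify via treatment/self-report
    sbp = np.empty(n)
    dbp = np.empty(n)
    treated = np.zeros(n, dtype=bool)
    grp = table["bp_group"].to_numpy()
    normal = grp == "normal"
    elevated = grp == "elevated"
    hyper = grp == "hypertension"
    sbp[normal] = rng.uniform(95, 119, size=n)[normal]
    dbp[normal] = rng.uniform(60, 78, size=n)[normal]
    sbp[elevated] = rng.uniform(121, 138, size=n)[elevated]
    dbp[elevated] = rng.uniform(62, 88, size=n)[elevated]
    via_flag = hyper & (rng.uniform(size=n) < 0.5)
    via_number = hyper & ~via_flag
    treated[via_flag] = True
    sbp[via_flag] = rng.uniform(115, 150, size=n)[via_flag]
    dbp[via_flag] = rng.uniform(65, 92, size=n)[via_flag]
    sbp[via_number] = rng.uniform(141, 185, size=n)[via_number]
    dbp[via_number] = rng.uniform(70, 108, size=n)[via_number]
    table["sbp"] = np.round(sbp, 1)
    table["dbp"] = np.round(dbp, 1)
    table["bp_treated"] = np.where(treated, "yes", "no")

    chol = np.empty(n)
    for cat, (lo, hi) in _RAW_WINDOWS["chol_group"].items():
        m = table["chol_group"].to_numpy() == cat
        chol[m] = rng.uniform(lo, hi, size=n)[m]
    table["total_chol"] = np.round(chol, 2)

    glu = np.empty(n)
    gtreated = np.zeros(n, dtype=bool)
    gnorm = table["glucose_group"].to_numpy() == "normal"
    ghigh = ~gnorm
    glu[gnorm] = rng.uniform(*_RAW_WINDOWS["glucose"]["normal"], size=n)[gnorm]
    gflag = ghigh & (rng.uniform(size=n) < 0.5)
    gnum = ghigh & ~gflag
    gtreated[gflag] = True
    glu[gflag] = rng.uniform(4.8, 6.0, size=n)[gflag]
    glu[gnum] = rng.uniform(*_RAW_WINDOWS["glucose"]["high"], size=n)[gnum]
    table["glucose"] = np.round(glu, 2)
    table["glucose_treated"] = np.where(gtreated, "yes", "no")

    gfr = np.empty(n)
    for cat, (lo, hi) in _RAW_WINDOWS["gfr_group"].items():
        m = table["gfr_group"].to_numpy() == cat
        gfr[m] = rng.uniform(lo, hi, size=n)[m]
    table["gfr"] = np.round(gfr, 1)


def generate_cohort(config: SimConfig) -> pd.DataFrame:
    """Generate one synthetic cohort table; deterministic in (config, seed)."""
    rng = np.random.default_rng(config.seed)
    n = config.n_participants

    # demographics by Gibbs sampling from the planted categorical MRF
    demo = config.demo_spec.sample(
        n, rng, burn_in=config.gibbs_burn_in, thin=config.gibbs_thin
    )
    table = pd.DataFrame(demo)

    # food intakes: exp of MVN with the planted precision matrix
    cov = np.linalg.inv(np.asarray(config.food_precision, dtype=float))
    logs = rng.multivariate_normal(
        np.asarray(config.food_log_means, dtype=float), cov, size=n, method="cholesky"
    )
    intakes = np.exp(logs)
    for k, f in enumerate(FOOD_GROUPS):
        table[f] = np.round(intakes[:, k], 2)

    # energy = positive linear map of intakes + noise
    energy = intakes @ np.asarray(config.energy_coefs, dtype=float)
    energy = energy + rng.normal(0.0, config.energy_noise_sd, size=n)
    table["energy_kcal"] = np.round(energy, 1)

    # marker categories from multinomial logits on demographics
    for marker, model in config.outcome_coefs.items():
        logits = model.logits(table)
        g = rng.gumbel(size=logits.shape)
        draw = np.argmax(logits + g, axis=1)
        table[marker] = np.asarray(model.levels, dtype=object)[draw]

    _fill_raw_markers(table, rng)

    if config.missing_rate > 0:
        mask = rng.uniform(size=table.shape) < config.missing_rate
        table = table.mask(pd.DataFrame(mask, index=table.index, columns=table.columns))

    # fix column order to the declared schema
    table = table[[c for c in DEFAULT_SCHEMA.columns if c in table.columns]]
    table.index.name = "participant"
    return table


def planted_truth(config: SimConfig) -> PlantedTruth:
    """Return the ground-truth structures the generator used."""
    return PlantedTruth(
        food_partial_corr=_partial_corr_from_precision(config.food_precision),
        demo_edges=config.demo_spec.edges(),
        outcome_coefs=dict(config.outcome_coefs),
    )


def write_cohort(table: pd.DataFrame, path) -> None:
    table.to_csv(path, na_rep=MISSING_SENTINEL, index=True)


def read_cohort(path, schema: CohortSchema | None = None) -> pd.DataFrame:
    """Read a cohort CSV and validate it against the schema.

    Unknown categorical labels raise a :class:`ValueError` naming the
    column, row and offending value; an empty file raises "no rows".
    """
    schema = schema or DEFAULT_SCHEMA
    try:
        table = pd.read_csv(path, na_values=[MISSING_SENTINEL], keep_default_na=False,
                            index_col=0)
    except pd.errors.EmptyDataError:
        raise ValueError(f"no rows in cohort file {path}") from None
    if len(table) == 0:
        raise ValueError(f"no rows in cohort file {path}")
    present = {c: lv for c, lv in schema.columns.items() if c in table.columns}
    CohortSchema(present).validate(table)
    for col, levels in present.items():
        if levels is None:
            table[col] = pd.to_numeric(table[col])
    return table
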