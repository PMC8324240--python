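"""Synthetic two-sex cohort generator with a known ground-truth hazard.

Each individual i carries a constant (exponential) stroke hazard

    h_i = base_hazard * r_area(i) * exp(beta' z_i + gamma * 1[SBP_i > 160 and age_i > 65])

where ``z_i`` are standardized covariates, ``r_area`` are area-level
multipliers log-spaced to span ``area_hazard_spread`` (geometric mean 1),
and ``gamma`` is a log-hazard increment for an elderly-hypertensive
subgroup that a linear risk model cannot represent.  The observed record is
the usual competing minimum of the event time ``~ Exp(h_i)``, an
independent stroke-free dropout time ``~ Exp(early_censor_rate)``, and
administrative censoring at ``admin_horizon`` years.

Because hazards are constant in time, the true absolute risk over a
horizon ``t`` is closed-form, ``p_i = 1 - exp(-t * h_i)``, and every
downstream stage can be tested against a recoverable truth.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import truncnorm

from .config import GeneratorConfig
from .exceptions import SchemaError

#: Thresholds defining the nonlinear (elderly hypertensive) subgroup.
SUBGROUP_SBP_THRESHOLD = 160.0
SUBGROUP_AGE_THRESHOLD = 65.0

#: Seed of the fixed scramble assigning hazard multipliers to area codes.
#: Area codes are arbitrary administrative labels, so risk is deliberately
#: non-monotone in the code; the assignment is part of the simulated world
#: and does not vary with the cohort seed.
_AREA_SCRAMBLE_SEED = 20170

CONTINUOUS_FIELDS = ("age", "sbp")
BINARY_FIELDS = ("bp_treatment", "current_smoker", "diabetes", "chd", "urban")


def area_multipliers(config: GeneratorConfig) -> np.ndarray:
    """Hazard multiplier for each area code 1..n_areas.

    Multipliers are log-spaced with max/min equal to ``area_hazard_spread``
    and geometric mean 1, then assigned to codes by a fixed permutation.
    """
    n = config.n_areas
    if n == 1:
        return np.ones(1)
    log_spread = np.log(config.area_hazard_spread)
    levels = np.exp((np.arange(n) / (n - 1) - 0.5) * log_spread)
    perm = np.random.default_rng(_AREA_SCRAMBLE_SEED).permutation(n)
    return levels[perm]


def noise_feature_names(config: GeneratorConfig) -> list[str]:
    return [f"x{i + 1:02d}" for i in range(config.n_noise_features)]


def _standardized_design(cohort: pd.DataFrame, config: GeneratorConfig) -> pd.DataFrame:
    """Covariates on the scale the generator's beta vector refers to."""
    z = pd.DataFrame(index=cohort.index)
    z["age_z"] = (cohort["age"] - config.age_mean) / config.age_sd
    z["sbp_z"] = (cohort["sbp"] - config.sbp_mean) / config.sbp_sd
    for name in BINARY_FIELDS:
        z[name] = cohort[name].astype(float)
    for name in noise_feature_names(config):
        if name in cohort.columns:
            z[name] = cohort[name]
    return z


def subgroup_indicator(cohort: pd.DataFrame) -> np.ndarray:
    """The nonlinear-hazard subgroup: SBP > 160 mmHg and age > 65 years."""
    return (
        (cohort["sbp"].to_numpy() > SUBGROUP_SBP_THRESHOLD)
        & (cohort["age"].to_numpy() > SUBGROUP_AGE_THRESHOLD)
    ).astype(float)


def individual_hazard(cohort: pd.DataFrame, config: GeneratorConfig) -> np.ndarray:
    """Ground-truth constant hazard h_i (events / person-year) per row."""
    z = _standardized_design(cohort, config)
    lp = np.zeros(len(cohort))
    for name, coef in config.beta.items():
        if name not in z.columns:
            raise SchemaError(f"beta refers to unknown covariate {name!r}")
        lp += coef * z[name].to_numpy()
    lp += config.gamma_nonlinear * subgroup_indicator(cohort)
    mult = area_multipliers(config)[cohort["area"].to_numpy() - 1]
    return config.base_hazard * mult * np.exp(lp)


def true_risk(
    cohort: pd.DataFrame, config: GeneratorConfig, horizon: float | None = None
) -> np.ndarray:
    """Closed-form true absolute risk 1 - exp(-horizon * h_i).

    ``horizon`` defaults to the administrative horizon (9 years).  Pure
    function of the covariates; accepts a one-row frame for a single
    individual.
    """
    if horizon is None:
        horizon = config.admin_horizon
    return -np.expm1(-horizon * individual_hazard(cohort, config))


def truth_design(cohort: pd.DataFrame, config: GeneratorConfig) -> pd.DataFrame:
    """The generator's own (correctly specified) log-hazard design matrix.

    Standardized covariates, the nonlinear-subgroup indicator, and area
    indicators (first code dropped).  A Cox fit on this design estimates
    exactly the generator's coefficients, so it is the design to use for
    parameter-recovery checks.
    """
    z = _standardized_design(cohort, config)
    z = z.drop(columns=["urban"], errors="ignore")
    z["subgroup"] = subgroup_indicator(cohort)
    area = cohort["area"].to_numpy()
    for k in range(2, config.n_areas + 1):
        z[f"area_{k}"] = (area == k).astype(float)
    return z


def generate_cohort(config: GeneratorConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a cohort and its ground truth.

    Returns
    -------
    cohort : DataFrame
        One row per individual: id, sex, age, area, sbp, bp_treatment,
        current_smoker, diabetes, chd, noise features, event, time,
        censor_reason.
    truth : DataFrame
        Parallel frame keyed by id with the constant hazard and the true
        horizon risk.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_individuals

    female = rng.random(n) < config.prop_female
    sex = np.where(female, "F", "M")

    lo, hi = config.age_range
    a = (lo - config.age_mean) / config.age_sd
    b = (hi - config.age_mean) / config.age_sd
    age = truncnorm.rvs(
        a, b, loc=config.age_mean, scale=config.age_sd, size=n, random_state=rng
    )

    area = rng.integers(1, config.n_areas + 1, size=n)
    # recorded urbanicity: areas in the upper half of baseline hazard.
    # Correlated with (but far from exhausting) the area-level risk, like
    # urban/rural recruitment-site labels in real cohorts.
    mult = area_multipliers(config)
    urban = (mult[area - 1] > np.median(mult)).astype(int)

    sbp = (
        config.sbp_mean
        + config.sbp_age_slope * (age - config.age_mean)
        + rng.normal(0.0, config.sbp_resid_sd, size=n)
    )
    sbp = np.clip(sbp, 80.0, None)

    p_treat = expit(
        logit(config.bp_treatment_prev) + 0.04 * (sbp - config.sbp_mean)
    )
    bp_treatment = (rng.random(n) < p_treat).astype(int)
    smoking_prev = np.where(female, config.smoking_prev_female, config.smoking_prev_male)
    current_smoker = (rng.random(n) < smoking_prev).astype(int)
    diabetes = (rng.random(n) < config.diabetes_prev).astype(int)
    chd = (rng.random(n) < config.chd_prev).astype(int)

    cohort = pd.DataFrame(
        {
            "id": np.arange(n, dtype=np.int64),
            "sex": sex,
            "age": age,
            "area": area,
            "sbp": sbp,
            "bp_treatment": bp_treatment,
            "current_smoker": current_smoker,
            "diabetes": diabetes,
            "chd": chd,
            "urban": urban,
        }
    )
    for name in noise_feature_names(config):
        cohort[name] = rng.normal(0.0, 1.0, size=n)

    hazard = individual_hazard(cohort, config)
    t_event = rng.exponential(1.0 / hazard)
    if config.early_censor_rate > 0:
        t_early = rng.exponential(1.0 / config.early_censor_rate, size=n)
    else:
        t_early = np.full(n, np.inf)
    t_admin = config.admin_horizon

    time = np.minimum(np.minimum(t_event, t_early), t_admin)
    event = t_event <= time
    reason = np.where(event, "event", np.where(t_early < t_admin, "early", "administrative"))
    cohort["event"] = event.astype(int)
    cohort["time"] = time
    cohort["censor_reason"] = reason

    truth = pd.DataFrame(
        {
            "id": cohort["id"],
            "hazard": hazard,
            "true_risk": -np.expm1(-config.admin_horizon * hazard),
        }
    )
    return cohort, truth


def summarize_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Risk-factor distribution per sex and stroke status.

    One column per (sex, status) group present in the cohort — up to four:
    men/women with and without stroke — containing means of continuous
    fields and prevalences (as fractions) of binary fields.  The
    "no stroke" groups include early-censored stroke-free individuals.
    Empty groups are simply absent.
    """
    if cohort.empty:
        raise SchemaError("cannot summarize an empty cohort")
    columns = {}
    for sex in ("M", "F"):
        for status, label in ((1, "stroke"), (0, "no_stroke")):
            grp = cohort[(cohort["sex"] == sex) & (cohort["event"] == status)]
            if grp.empty:
                continue
            stats: dict[str, float] = {"n": float(len(grp))}
            for f in CONTINUOUS_FIELDS:
                stats[f"{f}_mean"] = grp[f].mean()
            for f in BINARY_FIELDS:
                stats[f"{f}_prev"] = grp[f].mean()
            columns[f"{sex}_{label}"] = stats
    return pd.DataFrame(columns)


def save_cohort(cohort: pd.DataFrame, truth: pd.DataFrame, cohort_path, truth_path) -> None:
    cohort.to_csv(cohort_path, index=False)
    truth.to_csv(truth_path, index=False)


def load_cohort(cohort_path, truth_path=None):
    cohort = pd.read_csv(cohort_path)
    required = {"id", "sex", "event", "time", "censor_reason"}
    missing = required - set(cohort.columns)
    if missing:
        raise SchemaError(f"cohort file missing columns: {sorted(missing)}")
    if truth_path is None:
        return cohort
    return cohort, pd.read_csv(truth_path)
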