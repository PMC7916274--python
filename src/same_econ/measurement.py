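"""Derivation of analysis variables from raw person-wave survey records.

Raw records (one row per respondent per wave) carry demographics, smoking
history, household poverty indicators, anthropometrics, drinking frequency and
per-service health care use / spending. This module turns them, fully
deterministically, into the derived covariates of the analysis:

* a 5-level smoking status (never / current light / current heavy /
  former who quit < 5 years ago / former who quit >= 5 years ago), where
  "light" vs "heavy" splits current smokers at a smoking index
  (cigarettes per day x years smoked) of 200;
* a household poverty flag (at least two of four deprivation indicators);
* BMI class against the Chinese normal range 18.5-23.9 kg/m^2;
* a drinker flag (more than once a month);
* medical-care CPI deflation of nominal expenditures to constant 2015 dollars;
* the fixed-order design matrix used by every downstream model, including the
  eight smoking-status x age-group interaction columns IT1-IT8.

The design-matrix layout is a frozen contract: every fitted model, prediction
and counterfactual replay indexes columns by :data:`DESIGN_COLUMNS`.
"""

from __future__ import annotations

import numbers

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, InvalidArgumentError, InvalidRecordError

SMOKING_LEVELS = (
    "never",
    "current_light",
    "current_heavy",
    "former_quit_lt5",
    "former_quit_ge5",
)

AGE_GROUPS = ("45_54", "55_64", "65_plus")

BMI_CLASSES = ("normal", "underweight", "overweight")

#: Smoking index at and above which a current smoker is classified heavy.
SMOKING_INDEX_HEAVY_THRESHOLD = 200.0

#: Years since quitting below which a former smoker counts as a recent quitter.
QUIT_YEARS_THRESHOLD = 5.0

#: Chinese normal BMI range, kg/m^2 (inclusive on both ends).
BMI_NORMAL_RANGE = (18.5, 23.9)

# Non-reference smoking levels in the order the interaction block uses:
# IT1/IT2 = current light x (55-64, 65+), IT3/IT4 = current heavy x (...),
# IT5/IT6 = former quit<5yr, IT7/IT8 = former quit>=5yr.
_SMOKING_DUMMY_ORDER = (
    "current_light",
    "current_heavy",
    "former_quit_lt5",
    "former_quit_ge5",
)
_AGE_DUMMY_ORDER = ("55_64", "65_plus")

SMOKING_DUMMY_COLUMNS = tuple(f"smk_{lvl}" for lvl in _SMOKING_DUMMY_ORDER)
INTERACTION_COLUMNS = tuple(f"it{k}" for k in range(1, 9))

#: Canonical design-matrix column order. Reference cell: never smoker, female,
#: age 45-54, rural, primary education or below, unpartnered, not poor,
#: uninsured, west region, normal BMI, never drinker.
DESIGN_COLUMNS = (
    ("const",)
    + SMOKING_DUMMY_COLUMNS
    + (
        "male",
        "age_55_64",
        "age_65_plus",
        "urban",
        "edu_middle_or_above",
        "partnered",
        "poverty",
        "insured",
        "region_middle",
        "region_east",
        "bmi_underweight",
        "bmi_overweight",
        "drinker",
    )
    + INTERACTION_COLUMNS
)

#: Columns zeroed by the never-smoker counterfactual.
SMOKING_DESIGN_COLUMNS = SMOKING_DUMMY_COLUMNS + INTERACTION_COLUMNS

#: Raw input columns expected in a person-wave CSV.
RECORD_COLUMNS = (
    "person_id",
    "wave_year",
    "sex",
    "age",
    "residency",
    "education",
    "marital",
    "insurance",
    "region",
    "cooking_fuel_traditional",
    "toilet_not_flushable",
    "no_running_water",
    "asset_count",
    "weight_kg",
    "height_m",
    "drink_freq_per_month",
    "ever_smoked_100",
    "currently_smokes",
    "cigs_per_day",
    "years_smoked",
    "years_since_quit",
    "used_outpatient_1m",
    "outpatient_exp_1m",
    "used_inpatient_12m",
    "inpatient_exp_12m",
    "used_selfmed_1m",
    "selfmed_exp_1m",
    "sampling_weight",
)

SERVICES = ("outpatient", "inpatient", "selfmed")

#: (use flag column, expenditure column) per service type in the raw records.
SERVICE_COLUMNS = {
    "outpatient": ("used_outpatient_1m", "outpatient_exp_1m"),
    "inpatient": ("used_inpatient_12m", "inpatient_exp_12m"),
    "selfmed": ("used_selfmed_1m", "selfmed_exp_1m"),
}

#: Months covered by the recall window of each service question.
RECALL_MONTHS = {"outpatient": 1, "inpatient": 12, "selfmed": 1}


def _require_nonnegative(name: str, value) -> float:
    if not isinstance(value, numbers.Real) or not np.isfinite(value):
        raise InvalidArgumentError(f"{name} must be a finite number, got {value!r}")
    if value < 0:
        raise InvalidArgumentError(f"{name} must be >= 0, got {value!r}")
    return float(value)


def smoking_index(cigs_per_day, years_smoked) -> float:
    """Cigarettes smoked per day times years of smoking."""
    c = _require_nonnegative("cigs_per_day", cigs_per_day)
    y = _require_nonnegative("years_smoked", years_smoked)
    return c * y


def classify_smoking_status(
    ever_smoked_100: bool,
    currently_smokes: bool,
    cigs_per_day: float,
    years_smoked: float,
    years_since_quit: float,
) -> str:
    """Assign one of the five smoking-status levels.

    Never smokers are those who never reached 100 lifetime cigarettes.
    Current smokers split at a smoking index of 200 (index exactly 200 is
    classified heavy so the partition is total). Former smokers split at
    5 years since quitting.
    """
    if not ever_smoked_100:
        if currently_smokes:
            raise InvalidRecordError(
                "currently_smokes=True requires ever_smoked_100=True"
            )
        return "never"
    if currently_smokes:
        idx = smoking_index(cigs_per_day, years_smoked)
        if idx < SMOKING_INDEX_HEAVY_THRESHOLD:
            return "current_light"
        return "current_heavy"
    ysq = _require_nonnegative("years_since_quit", years_since_quit)
    if ysq < QUIT_YEARS_THRESHOLD:
        return "former_quit_lt5"
    return "former_quit_ge5"


def classify_poverty(
    cooking_fuel_traditional: bool,
    toilet_not_flushable: bool,
    no_running_water: bool,
    asset_count: int,
) -> bool:
    """Household poverty: at least two of four deprivation indicators.

    The indicators are traditional cooking fuel, a non-flushable toilet, no
    running water, and owning fewer than two assets from the household list.
    """
    if asset_count < 0:
        raise InvalidArgumentError(f"asset_count must be >= 0, got {asset_count!r}")
    n = (
        int(bool(cooking_fuel_traditional))
        + int(bool(toilet_not_flushable))
        + int(bool(no_running_water))
        + int(asset_count < 2)
    )
    return n >= 2


def classify_bmi(weight_kg: float, height_m: float) -> str:
    """BMI class against the Chinese normal range 18.5-23.9 kg/m^2."""
    if not (
        isinstance(weight_kg, numbers.Real)
        and isinstance(height_m, numbers.Real)
        and np.isfinite(weight_kg)
        and np.isfinite(height_m)
        and weight_kg > 0
        and height_m > 0
    ):
        raise InvalidArgumentError(
            f"weight and height must be positive, got {weight_kg!r}, {height_m!r}"
        )
    bmi = weight_kg / height_m**2
    lo, hi = BMI_NORMAL_RANGE
    if bmi < lo:
        return "underweight"
    if bmi > hi:
        return "overweight"
    return "normal"


def classify_drinker(drink_freq_per_month: float) -> bool:
    """Drinker: any alcoholic beverage strictly more than once a month."""
    f = _require_nonnegative("drink_freq_per_month", drink_freq_per_month)
    return f > 1.0


def classify_age_group(age: float) -> str:
    if age < 45:
        raise InvalidArgumentError(f"age {age!r} below the 45+ eligibility floor")
    if age < 55:
        return "45_54"
    if age < 65:
        return "55_64"
    return "65_plus"


def adjust_to_2015(amount, year, cpi_medical, fx_rate=1.0):
    """Deflate a nominal amount to constant 2015 dollars.

    ``cpi_medical`` maps calendar year to the medical-care CPI level; the
    amount is scaled by ``cpi[2015] / cpi[year]`` and divided by the
    currency-per-dollar rate ``fx_rate``. Works elementwise on arrays.
    """
    cpi = {int(k): float(v) for k, v in dict(cpi_medical).items()}
    year = int(year)
    if year not in cpi or 2015 not in cpi:
        raise ConfigurationError(
            f"cpi_medical must contain {year} and 2015; has {sorted(cpi)}"
        )
    if not fx_rate > 0:
        raise ConfigurationError(f"fx_rate must be > 0, got {fx_rate!r}")
    return np.asarray(amount, dtype=float) * (cpi[2015] / cpi[year]) / fx_rate


# ---------------------------------------------------------------------------
# Table-level derivation


def derive_covariates(records: pd.DataFrame, min_age: float = 45.0):
    """Derive analysis covariates for every eligible person-wave.

    Returns ``(covariates, dropped)`` where ``covariates`` carries the derived
    categorical fields plus pass-through identifiers, outcomes and weights,
    and ``dropped`` counts excluded records by reason (currently the under-age
    exclusion; missing fields raise instead, upstream completeness is assumed
    for the synthetic panels this package generates).
    """
    df = records.copy()
    dropped = {"age_below_min": int((df["age"] < min_age).sum())}
    df = df[df["age"] >= min_age].copy()

    smoking = [
        classify_smoking_status(e, c, n, y, q)
        for e, c, n, y, q in zip(
            df["ever_smoked_100"].astype(bool),
            df["currently_smokes"].astype(bool),
            df["cigs_per_day"],
            df["years_smoked"],
            df["years_since_quit"],
        )
    ]
    out = pd.DataFrame(
        {
            "person_id": df["person_id"].to_numpy(),
            "wave_year": df["wave_year"].astype(int).to_numpy(),
            "smoking_status": pd.Categorical(smoking, categories=SMOKING_LEVELS),
            "sex": df["sex"].to_numpy(),
            "age_group": pd.Categorical(
                [classify_age_group(a) for a in df["age"]], categories=AGE_GROUPS
            ),
            "residency": df["residency"].to_numpy(),
            "education": df["education"].to_numpy(),
            "marital": df["marital"].to_numpy(),
            "poverty": [
                classify_poverty(f, t, w, a)
                for f, t, w, a in zip(
                    df["cooking_fuel_traditional"],
                    df["toilet_not_flushable"],
                    df["no_running_water"],
                    df["asset_count"],
                )
            ],
            "insurance": df["insurance"].to_numpy(),
            "region": df["region"].to_numpy(),
            "bmi_class": pd.Categorical(
                [classify_bmi(w, h) for w, h in zip(df["weight_kg"], df["height_m"])],
                categories=BMI_CLASSES,
            ),
            "drinker": [classify_drinker(f) for f in df["drink_freq_per_month"]],
            "sampling_weight": df["sampling_weight"].astype(float).to_numpy(),
        },
        index=df.index,
    )
    for service, (use_col, exp_col) in SERVICE_COLUMNS.items():
        out[f"use_{service}"] = df[use_col].astype(bool).to_numpy()
        out[f"exp_{service}"] = df[exp_col].astype(float).to_numpy()
    return out.reset_index(drop=True), dropped


def deflate_expenditures(
    covariates: pd.DataFrame, cpi_medical, fx_rate: float = 1.0
) -> pd.DataFrame:
    """Deflate the per-service expenditure columns to 2015 dollars, by wave."""
    out = covariates.copy()
    for service in SERVICES:
        col = f"exp_{service}"
        out[col] = [
            float(adjust_to_2015(a, y, cpi_medical, fx_rate))
            for a, y in zip(out[col], out["wave_year"])
        ]
    return out


def build_design_row(cov: dict) -> np.ndarray:
    """Encode one derived-covariate mapping as a design vector.

    See :func:`build_design_matrix` for the table-level version; the layout is
    :data:`DESIGN_COLUMNS`.
    """
    frame = pd.DataFrame([cov])
    return build_design_matrix(frame).iloc[0].to_numpy()


def build_design_matrix(covariates: pd.DataFrame) -> pd.DataFrame:
    """Indicator-code derived covariates in the canonical column order.

    Reference levels (never smoker, female, 45-54, rural, primary or below,
    unpartnered, not poor, uninsured, west, normal BMI, never drinker) are
    absorbed into the constant. The interaction block holds the eight products
    of the four non-reference smoking levels with the two non-reference age
    groups, in the fixed order IT1..IT8.
    """
    n = len(covariates)
    X = pd.DataFrame(
        np.zeros((n, len(DESIGN_COLUMNS))),
        columns=list(DESIGN_COLUMNS),
        index=covariates.index,
    )
    X["const"] = 1.0
    smoking = np.asarray(covariates["smoking_status"].astype(str))
    age = np.asarray(covariates["age_group"].astype(str))
    for lvl in _SMOKING_DUMMY_ORDER:
        X[f"smk_{lvl}"] = (smoking == lvl).astype(float)
    X["male"] = (np.asarray(covariates["sex"]) == "male").astype(float)
    X["age_55_64"] = (age == "55_64").astype(float)
    X["age_65_plus"] = (age == "65_plus").astype(float)
    X["urban"] = (np.asarray(covariates["residency"]) == "urban").astype(float)
    X["edu_middle_or_above"] = (
        np.asarray(covariates["education"]) == "middle_or_above"
    ).astype(float)
    X["partnered"] = (np.asarray(covariates["marital"]) == "partnered").astype(float)
    X["poverty"] = np.asarray(covariates["poverty"]).astype(float)
    X["insured"] = (np.asarray(covariates["insurance"]) == "yes").astype(float)
    region = np.asarray(covariates["region"])
    X["region_middle"] = (region == "middle").astype(float)
    X["region_east"] = (region == "east").astype(float)
    bmi = np.asarray(covariates["bmi_class"].astype(str))
    X["bmi_underweight"] = (bmi == "underweight").astype(float)
    X["bmi_overweight"] = (bmi == "overweight").astype(float)
    X["drinker"] = np.asarray(covariates["drinker"]).astype(float)
    k = 0
    for lvl in _SMOKING_DUMMY_ORDER:
        for ag in _AGE_DUMMY_ORDER:
            k += 1
            X[f"it{k}"] = X[f"smk_{lvl}"] * X[f"age_{ag}"]
    return X
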