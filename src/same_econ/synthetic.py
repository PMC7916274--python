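"""Synthetic balanced 3-wave panel generator with known ground truth.

The restricted survey the analysis was designed for cannot be redistributed,
so this module generates panels with the same statistical structure the
estimators assume: time-invariant covariates, a 5-level smoking status with
slow drift toward quitting across waves, individual normal random intercepts,
and two-part outcomes (Bernoulli use x conditional lognormal cost) for three
service types. Every generating parameter is known, so parameter recovery and
end-to-end attributable-fraction recovery can be tested exactly.

Default generating coefficients follow the magnitudes of the published
six-equation fit (use-equation coefficients are logs of the reported adjusted
odds ratios; cost-equation coefficients are the reported semi-elasticities),
and default covariate prevalences follow the published baseline-wave weighted
descriptives. Random-intercept and residual scales are not published; the
defaults are typical magnitudes for log health-expenditure panel data (see
docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from . import measurement as ms
from .exceptions import ConfigurationError

# ---------------------------------------------------------------------------
# Default generating parameters (design-column keyed, canonical order).


def _gamma(aor_by_col: dict) -> dict:
    """Use-equation coefficients from adjusted odds ratios (log scale)."""
    return {k: float(np.log(v)) for k, v in aor_by_col.items()}


# Use equations: adjusted odds ratios (constant = baseline odds).
_USE_AOR = {
    "outpatient": {
        "const": 0.433,
        "smk_current_light": 0.907, "smk_current_heavy": 0.740,
        "smk_former_quit_lt5": 1.421, "smk_former_quit_ge5": 1.574,
        "male": 0.742, "age_55_64": 0.998, "age_65_plus": 1.106,
        "urban": 1.015, "edu_middle_or_above": 0.883, "partnered": 0.984,
        "poverty": 1.035, "insured": 1.322,
        "region_middle": 0.672, "region_east": 0.480,
        "bmi_underweight": 1.125, "bmi_overweight": 0.979, "drinker": 0.876,
        "it1": 1.053, "it2": 1.024, "it3": 1.200, "it4": 1.206,
        "it5": 1.043, "it6": 0.83, "it7": 0.798, "it8": 1.093,
    },
    "inpatient": {
        "const": 0.0738,
        "smk_current_light": 1.082, "smk_current_heavy": 0.875,
        "smk_former_quit_lt5": 1.728, "smk_former_quit_ge5": 1.138,
        "male": 0.975, "age_55_64": 1.395, "age_65_plus": 1.940,
        "urban": 1.122, "edu_middle_or_above": 0.963, "partnered": 0.883,
        "poverty": 1.000, "insured": 1.595,
        "region_middle": 0.712, "region_east": 0.530,
        "bmi_underweight": 1.217, "bmi_overweight": 1.202, "drinker": 0.649,
        "it1": 1.194, "it2": 0.991, "it3": 0.898, "it4": 1.019,
        "it5": 1.348, "it6": 1.381, "it7": 1.452, "it8": 1.728,
    },
    "selfmed": {
        "const": 0.624,
        "smk_current_light": 1.028, "smk_current_heavy": 1.097,
        "smk_former_quit_lt5": 1.287, "smk_former_quit_ge5": 1.582,
        "male": 0.801, "age_55_64": 1.255, "age_65_plus": 1.238,
        "urban": 1.160, "edu_middle_or_above": 1.099, "partnered": 1.075,
        "poverty": 1.140, "insured": 1.408,
        "region_middle": 0.598, "region_east": 0.595,
        "bmi_underweight": 0.903, "bmi_overweight": 1.305, "drinker": 0.953,
        "it1": 1.058, "it2": 1.055, "it3": 0.973, "it4": 1.105,
        "it5": 0.989, "it6": 0.835, "it7": 0.945, "it8": 1.039,
    },
}

# Cost equations: semi-elasticities on the log-dollar scale.
_COST_BETA = {
    "outpatient": {
        "const": 5.072,
        "smk_current_light": -0.0298, "smk_current_heavy": 0.103,
        "smk_former_quit_lt5": 0.886, "smk_former_quit_ge5": 0.137,
        "male": -0.0903, "age_55_64": 0.159, "age_65_plus": 0.352,
        "urban": 0.148, "edu_middle_or_above": 0.222, "partnered": 0.154,
        "poverty": -0.0394, "insured": -0.0147,
        "region_middle": -0.118, "region_east": 0.0495,
        "bmi_underweight": 0.172, "bmi_overweight": 0.122, "drinker": -0.305,
        "it1": 0.335, "it2": -0.0807, "it3": -0.173, "it4": -0.148,
        "it5": -0.190, "it6": -0.405, "it7": 0.217, "it8": 0.190,
    },
    "inpatient": {
        "const": 7.887,
        "smk_current_light": -0.0593, "smk_current_heavy": 0.0579,
        "smk_former_quit_lt5": 0.445, "smk_former_quit_ge5": 0.518,
        "male": 0.157, "age_55_64": 0.0952, "age_65_plus": 0.0862,
        "urban": 0.283, "edu_middle_or_above": 0.146, "partnered": 0.143,
        "poverty": -0.127, "insured": 0.0573,
        "region_middle": 0.0241, "region_east": 0.360,
        "bmi_underweight": 0.0970, "bmi_overweight": 0.133, "drinker": -0.156,
        "it1": 0.0171, "it2": -0.126, "it3": -0.178, "it4": -0.0289,
        "it5": 0.0139, "it6": 0.0948, "it7": -0.543, "it8": -0.223,
    },
    "selfmed": {
        "const": 4.057,
        "smk_current_light": -0.0250, "smk_current_heavy": -0.181,
        "smk_former_quit_lt5": 0.206, "smk_former_quit_ge5": 0.0456,
        "male": -0.0818, "age_55_64": 0.156, "age_65_plus": 0.270,
        "urban": 0.135, "edu_middle_or_above": 0.125, "partnered": 0.117,
        "poverty": 0.0162, "insured": 0.0464,
        "region_middle": -0.225, "region_east": -0.274,
        "bmi_underweight": 0.0881, "bmi_overweight": 0.0771, "drinker": -0.243,
        "it1": -0.0320, "it2": -0.130, "it3": 0.0992, "it4": 0.136,
        "it5": 0.102, "it6": 0.113, "it7": 0.162, "it8": 0.322,
    },
}


def default_true_params() -> dict:
    """Per-service generating parameters for the two equations."""
    return {
        service: {
            "gamma": _gamma(_USE_AOR[service]),
            "beta": dict(_COST_BETA[service]),
            "sigma_alpha_logit": 0.8,
            "sigma_alpha_cost": 0.7,
            "sigma_u_cost": 1.2,
        }
        for service in ms.SERVICES
    }


def default_prevalences() -> dict:
    """Baseline-wave covariate distribution (published weighted descriptives)."""
    return {
        # quit<5yr 3.90% / quit>=5yr 2.94% at baseline, per the text
        "smoking_status": {
            "never": 0.6440, "current_light": 0.0410, "current_heavy": 0.2437,
            "former_quit_lt5": 0.0390, "former_quit_ge5": 0.0294,
        },
        "male": 0.4456,
        "age_group": {"45_54": 0.3934, "55_64": 0.3750, "65_plus": 0.2316},
        "urban": 0.4248,
        "edu_middle_or_above": 0.3488,
        "partnered": 0.8930,
        "insured": 0.9420,
        "region": {"west": 0.2955, "middle": 0.2786, "east": 0.4259},
        "bmi_class": {"normal": 0.4940, "underweight": 0.0611, "overweight": 0.4449},
        "drinker": 0.2434,
        "poverty": 0.2235,
    }


@dataclass
class SimConfig:
    """Generating configuration for a balanced multi-wave panel.

    ``transition_quit`` is the per-wave probability a current smoker quits
    (entering the quit<5yr state); ``transition_age_out`` the per-wave
    probability a quit<5yr former smoker crosses the 5-year mark. Both echo
    the published drift toward more quitters across waves; the rates
    themselves are generator defaults, not published values.

    ``intercept_corr`` correlates the use- and cost-equation random
    intercepts (default independent). ``inflate_by_wave`` emits nominal
    wave-year costs (multiplying by cpi[wave]/cpi[2015]) so the deflation
    step can be exercised; the default generates constant 2015 dollars.
    """

    n_individuals: int = 2000
    wave_years: tuple = (2011, 2013, 2015)
    covariate_prevalences: dict = field(default_factory=default_prevalences)
    true_params: dict = field(default_factory=default_true_params)
    transition_quit: float = 0.06
    transition_age_out: float = 0.5
    intercept_corr: float = 0.0
    inflate_by_wave: bool = False
    cpi_medical: dict = field(
        default_factory=lambda: {2011: 0.926, 2013: 0.956, 2015: 1.0}
    )
    seed: int = 0

    def validate(self) -> None:
        prev = self.covariate_prevalences
        flat = []
        for v in prev.values():
            flat.extend(v.values() if isinstance(v, dict) else [v])
        if not all(0.0 <= p <= 1.0 for p in flat):
            raise ConfigurationError("prevalences must lie in [0, 1]")
        for name, cats in (
            ("smoking_status", prev["smoking_status"]),
            ("age_group", prev["age_group"]),
            ("region", prev["region"]),
            ("bmi_class", prev["bmi_class"]),
        ):
            # published rounded shares can miss 1 by a few tenths of a percent;
            # draws renormalize
            if abs(sum(cats.values()) - 1.0) > 1e-2:
                raise ConfigurationError(f"{name} prevalences must sum to 1")
        for service, p in self.true_params.items():
            for key in ("sigma_alpha_logit", "sigma_alpha_cost", "sigma_u_cost"):
                if p[key] < 0:
                    raise ConfigurationError(f"{service}.{key} must be >= 0")
        if not -1.0 <= self.intercept_corr <= 1.0:
            raise ConfigurationError("intercept_corr must lie in [-1, 1]")


@dataclass
class TruthBundle:
    """Ground truth accompanying a simulated panel.

    ``alpha_use``/``alpha_cost`` map service -> per-person random intercepts
    (arrays over the person index), and ``true_saf`` maps service -> the
    attributable fraction implied by the generating model on the realized
    population (expected costs conditioned on the drawn covariates and
    intercepts, with the residual integrated out analytically).
    """

    config: SimConfig
    person_ids: np.ndarray
    alpha_use: dict
    alpha_cost: dict
    design: pd.DataFrame
    true_saf: dict = field(default_factory=dict)


def _draw_cat(rng, levels_probs: dict, n: int) -> np.ndarray:
    levels = list(levels_probs)
    p = np.array([levels_probs[k] for k in levels], dtype=float)
    p = p / p.sum()
    return rng.choice(levels, size=n, p=p)


# Raw-field backfill templates so classification reproduces the intended level.
_SMOKING_RAW = {
    "never": dict(ever=False, cur=False, cigs=0.0, yrs=0.0, quit=0.0),
    "current_light": dict(ever=True, cur=True, cigs=5.0, yrs=10.0, quit=0.0),
    "current_heavy": dict(ever=True, cur=True, cigs=20.0, yrs=30.0, quit=0.0),
    "former_quit_lt5": dict(ever=True, cur=False, cigs=0.0, yrs=15.0, quit=2.0),
    "former_quit_ge5": dict(ever=True, cur=False, cigs=0.0, yrs=15.0, quit=10.0),
}
_BMI_RAW = {"normal": (60.0, 1.70), "underweight": (45.0, 1.70), "overweight": (80.0, 1.70)}


def simulate_panel(config: SimConfig):
    """Generate a balanced panel and its :class:`TruthBundle`.

    Covariates other than age and smoking status are time-invariant; age
    advances with the calendar and smoking status follows an absorbing-ish
    Markov chain (never stays never, current smokers may quit, recent
    quitters age into long-term quitters). Outcomes per service: a Bernoulli
    use flag with probability ``expit(x'gamma + alpha_i)`` and, given use, a
    cost ``exp(x'beta + alpha'_i + u)`` with normal residual u.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = int(config.n_individuals)
    prev = config.covariate_prevalences
    waves = [int(w) for w in config.wave_years]

    # --- person-level draws
    male = rng.random(n) < prev["male"]
    age_group0 = _draw_cat(rng, prev["age_group"], n)
    base_age = np.where(
        age_group0 == "45_54",
        rng.uniform(45, 55, n),
        np.where(age_group0 == "55_64", rng.uniform(55, 65, n), rng.uniform(65, 80, n)),
    )
    urban = rng.random(n) < prev["urban"]
    edu = rng.random(n) < prev["edu_middle_or_above"]
    partnered = rng.random(n) < prev["partnered"]
    insured = rng.random(n) < prev["insured"]
    region = _draw_cat(rng, prev["region"], n)
    bmi_class = _draw_cat(rng, prev["bmi_class"], n)
    drinker = rng.random(n) < prev["drinker"]
    poverty = rng.random(n) < prev["poverty"]

    smoking0 = _draw_cat(rng, prev["smoking_status"], n)

    alpha_use, alpha_cost = {}, {}
    rho = config.intercept_corr
    for service in ms.SERVICES:
        p = config.true_params[service]
        z1 = rng.standard_normal(n)
        z2 = rng.standard_normal(n)
        alpha_use[service] = p["sigma_alpha_logit"] * z1
        alpha_cost[service] = p["sigma_alpha_cost"] * (
            rho * z1 + np.sqrt(max(0.0, 1.0 - rho**2)) * z2
        )

    # --- wave-level smoking dynamics
    smoking_by_wave = [smoking0]
    cur = smoking0.copy()
    for _ in waves[1:]:
        nxt = cur.copy()
        is_current = np.isin(cur, ["current_light", "current_heavy"])
        quits = is_current & (rng.random(n) < config.transition_quit)
        nxt[quits] = "former_quit_lt5"
        ages_out = (cur == "former_quit_lt5") & (rng.random(n) < config.transition_age_out)
        nxt[ages_out] = "former_quit_ge5"
        cur = nxt
        smoking_by_wave.append(cur)

    # --- assemble person-wave records
    rows = []
    design_blocks = []
    person_ids = np.array([f"p{i:06d}" for i in range(n)])
    for w_idx, wave in enumerate(waves):
        age = base_age + (wave - waves[0])
        smoking = smoking_by_wave[w_idx]
        cov = pd.DataFrame(
            {
                "smoking_status": pd.Categorical(smoking, categories=ms.SMOKING_LEVELS),
                "age_group": pd.Categorical(
                    [ms.classify_age_group(a) for a in age], categories=ms.AGE_GROUPS
                ),
                "sex": np.where(male, "male", "female"),
                "residency": np.where(urban, "urban", "rural"),
                "education": np.where(edu, "middle_or_above", "primary_or_below"),
                "marital": np.where(partnered, "partnered", "unpartnered"),
                "poverty": poverty,
                "insurance": np.where(insured, "yes", "no"),
                "region": region,
                "bmi_class": pd.Categorical(bmi_class, categories=ms.BMI_CLASSES),
                "drinker": drinker,
            }
        )
        X = ms.build_design_matrix(cov)
        design_blocks.append(X)

        rec = pd.DataFrame(
            {
                "person_id": person_ids,
                "wave_year": wave,
                "sex": cov["sex"],
                "age": np.round(age, 1),
                "residency": cov["residency"],
                "education": cov["education"],
                "marital": cov["marital"],
                "insurance": cov["insurance"],
                "region": region,
                # two deprivation flags iff poor; one otherwise-harmless flag if not
                "cooking_fuel_traditional": poverty,
                "toilet_not_flushable": poverty,
                "no_running_water": False,
                "asset_count": 4,
                "weight_kg": np.array([_BMI_RAW[b][0] for b in bmi_class]),
                "height_m": np.array([_BMI_RAW[b][1] for b in bmi_class]),
                "drink_freq_per_month": np.where(drinker, 4.0, 0.0),
                "ever_smoked_100": np.array(
                    [_SMOKING_RAW[s]["ever"] for s in smoking]
                ),
                "currently_smokes": np.array([_SMOKING_RAW[s]["cur"] for s in smoking]),
                "cigs_per_day": np.array([_SMOKING_RAW[s]["cigs"] for s in smoking]),
                "years_smoked": np.array([_SMOKING_RAW[s]["yrs"] for s in smoking]),
                "years_since_quit": np.array([_SMOKING_RAW[s]["quit"] for s in smoking]),
                "sampling_weight": np.round(np.exp(rng.normal(0.0, 0.25, n)), 4),
            }
        )

        Xv = X.to_numpy()
        for service in ms.SERVICES:
            p = config.true_params[service]
            gamma = np.array([p["gamma"][c] for c in ms.DESIGN_COLUMNS])
            beta = np.array([p["beta"][c] for c in ms.DESIGN_COLUMNS])
            eta_use = Xv @ gamma + alpha_use[service]
            use = rng.random(n) < expit(eta_use)
            log_cost = (
                Xv @ beta
                + alpha_cost[service]
                + p["sigma_u_cost"] * rng.standard_normal(n)
            )
            cost = np.where(use, np.exp(log_cost), 0.0)
            if config.inflate_by_wave:
                cost = cost * (config.cpi_medical[wave] / config.cpi_medical[2015])
            use_col, exp_col = ms.SERVICE_COLUMNS[service]
            rec[use_col] = use
            rec[exp_col] = np.round(cost, 6)
        rows.append(rec)

    panel = pd.concat(rows, ignore_index=True)
    panel = panel.sort_values(["person_id", "wave_year"], kind="stable").reset_index(
        drop=True
    )
    design = pd.concat(design_blocks, ignore_index=True)

    truth = TruthBundle(
        config=config,
        person_ids=person_ids,
        alpha_use=alpha_use,
        alpha_cost=alpha_cost,
        design=design,
    )
    truth.true_saf = {s: true_saf(truth, s) for s in ms.SERVICES}
    return panel, truth


def _expected_costs(truth: TruthBundle, service: str, design: pd.DataFrame):
    """Per person-wave expected cost under the generating model.

    Conditions on the realized random intercepts and integrates the lognormal
    residual analytically: E[cost] = expit(x'g + a_i) * exp(x'b + a'_i + s_u^2/2).
    """
    cfg = truth.config
    p = cfg.true_params[service]
    n = len(truth.alpha_use[service])
    n_waves = len(design) // n
    gamma = np.array([p["gamma"][c] for c in ms.DESIGN_COLUMNS])
    beta = np.array([p["beta"][c] for c in ms.DESIGN_COLUMNS])
    Xv = design.to_numpy()
    a_use = np.tile(truth.alpha_use[service], n_waves)
    a_cost = np.tile(truth.alpha_cost[service], n_waves)
    p_use = expit(Xv @ gamma + a_use)
    cond = np.exp(Xv @ beta + a_cost + 0.5 * p["sigma_u_cost"] ** 2)
    return p_use * cond


def true_saf(truth: TruthBundle, service: str) -> float:
    """Attributable fraction implied by the generating model for one service.

    Replays every person-wave with the smoking dummies and their age
    interactions zeroed and takes 1 - hypothetical/factual on expected costs.
    """
    design = truth.design
    cf = design.copy()
    cf[list(ms.SMOKING_DESIGN_COLUMNS)] = 0.0
    factual = _expected_costs(truth, service, design).sum()
    hypothetical = _expected_costs(truth, service, cf).sum()
    if factual == 0:
        return 0.0
    return float(1.0 - hypothetical / factual)
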