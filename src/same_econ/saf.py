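"""Counterfactual prediction and the smoking-attributable fraction.

The two fitted equations are combined into an expected cost per person-wave:

    E[cost | x] = Pr(use | x) * E[cost | use, x]

The use probability comes from the random-intercept logit, either averaged
over the estimated intercept distribution (population-average, the default)
or evaluated at intercept zero. The conditional cost is the exponentiated
linear predictor of the log-cost equation times a retransformation factor:
Duan's smearing estimate (default) or the lognormal normal-theory factor
``exp((sigma_alpha'^2 + sigma_u'^2) / 2)``.

The never-smoker counterfactual zeroes the four smoking dummies and the
eight smoking-by-age interaction columns of the design (covering current
and former smokers alike) and replays the identical fitted equations. The
smoking-attributable fraction for a stratum and service is

    SAF = (factual total - hypothetical total) / factual total.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit, roots_hermite

from .exceptions import FitFailureError, SchemaError
from .measurement import SMOKING_DESIGN_COLUMNS
from .models import REFit

RETRANSFORMS = ("smearing", "normal_theory")
INTEGRATIONS = ("population_average", "zero_intercept")

_PA_NODES = 31  # Gauss-Hermite nodes for the population-average probability


def _check_design(fit: REFit, rows: pd.DataFrame) -> None:
    if tuple(rows.columns) != tuple(fit.design_columns):
        raise SchemaError(
            "design columns do not match the fit: "
            f"{list(rows.columns)[:4]}... vs {list(fit.design_columns)[:4]}..."
        )


def population_average_probability(eta: np.ndarray, sigma_alpha: float) -> np.ndarray:
    """E_alpha[expit(eta + alpha)] for alpha ~ N(0, sigma_alpha^2)."""
    if sigma_alpha <= 0:
        return expit(eta)
    x, w = roots_hermite(_PA_NODES)
    nodes = np.sqrt(2.0) * sigma_alpha * x
    return (expit(eta[:, None] + nodes[None, :]) @ w) / np.sqrt(np.pi)


def retransformation_factor(cost_fit: REFit, retransform: str = "smearing") -> float:
    """Back-transformation factor for predictions from the log-cost equation."""
    if retransform == "smearing":
        if cost_fit.smearing_factor is None:
            raise SchemaError("cost fit carries no smearing factor")
        return float(cost_fit.smearing_factor)
    if retransform == "normal_theory":
        return float(np.exp(0.5 * (cost_fit.sigma_alpha**2 + cost_fit.sigma_u**2)))
    raise SchemaError(f"unknown retransform {retransform!r}; use one of {RETRANSFORMS}")


def predict_two_part(
    use_fit: REFit,
    cost_fit: REFit,
    rows: pd.DataFrame,
    retransform: str = "smearing",
    integration: str = "population_average",
    scenario: str = "factual",
) -> pd.DataFrame:
    """Expected cost per design row from the two fitted equations.

    Returns a table with columns ``p_use``, ``cond_cost``, ``expected_cost``
    and ``scenario``, row-aligned with ``rows``.
    """
    if integration not in INTEGRATIONS:
        raise SchemaError(
            f"unknown integration {integration!r}; use one of {INTEGRATIONS}"
        )
    for fit in (use_fit, cost_fit):
        if not fit.converged:
            raise FitFailureError("prediction requires converged fits")
    _check_design(use_fit, rows)
    _check_design(cost_fit, rows)
    Xv = rows.to_numpy(dtype=float)
    eta_use = Xv @ use_fit.coef_array()
    if integration == "population_average":
        p_use = population_average_probability(eta_use, use_fit.sigma_alpha)
    else:
        p_use = expit(eta_use)
    factor = retransformation_factor(cost_fit, retransform)
    cond_cost = np.exp(Xv @ cost_fit.coef_array()) * factor
    return pd.DataFrame(
        {
            "p_use": p_use,
            "cond_cost": cond_cost,
            "expected_cost": p_use * cond_cost,
            "scenario": scenario,
        },
        index=rows.index,
    )


def make_counterfactual(rows: pd.DataFrame) -> pd.DataFrame:
    """Never-smoker replay design: smoking and interaction columns zeroed."""
    missing = [c for c in SMOKING_DESIGN_COLUMNS if c not in rows.columns]
    if missing:
        raise SchemaError(f"design lacks smoking columns {missing}")
    out = rows.copy()
    out[list(SMOKING_DESIGN_COLUMNS)] = 0.0
    return out


def compute_saf(
    factual: pd.DataFrame,
    hypothetical: pd.DataFrame,
    strata: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Attributable fractions by service and stratum.

    ``factual`` and ``hypothetical`` are row-aligned tables with columns
    ``service`` and ``expected_cost`` (one row per person-wave per service).
    ``strata`` optionally supplies label columns (e.g. sex, residency) aligned
    on the same rows; an ``all`` stratum is always produced, and an
    ``overall`` service row pools the three services within each stratum.
    """
    if len(factual) != len(hypothetical):
        raise SchemaError("factual and hypothetical tables are not row-aligned")
    if not np.array_equal(
        factual["service"].to_numpy(), hypothetical["service"].to_numpy()
    ):
        raise SchemaError("service labels differ between scenarios")

    base = pd.DataFrame(
        {
            "service": factual["service"].to_numpy(),
            "factual": factual["expected_cost"].to_numpy(),
            "hypothetical": hypothetical["expected_cost"].to_numpy(),
        }
    )
    groupings = {"all": pd.Series("all", index=base.index)}
    if strata is not None:
        if len(strata) != len(factual):
            raise SchemaError("strata not row-aligned with predictions")
        for col in strata.columns:
            groupings[col] = pd.Series(strata[col].to_numpy(), index=base.index)

    out_rows = []
    for dim, labels in groupings.items():
        for label, chunk in base.groupby(labels, observed=True):
            per_service = chunk.groupby("service", observed=True)[
                ["factual", "hypothetical"]
            ].sum()
            pooled = per_service.sum()
            per_service.loc["overall"] = pooled
            for service, row in per_service.iterrows():
                f, h = float(row["factual"]), float(row["hypothetical"])
                if f == 0:
                    raise ZeroDivisionError(
                        f"factual total is zero for {service}/{label}; SAF undefined"
                    )
                out_rows.append(
                    {
                        "service": service,
                        "stratum_dim": dim,
                        "stratum": str(label),
                        "factual_total": f,
                        "hypothetical_total": h,
                        "saf": (f - h) / f,
                    }
                )
    return pd.DataFrame(out_rows)
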