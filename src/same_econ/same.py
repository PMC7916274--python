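"""National aggregation: from attributable fractions to attributable dollars.

Survey means (average price and utilization per service, within each
service's recall window) are scaled to an annual national total health
expenditure (THE) per service:

    THE_outpatient = PV * QV * 12 * POP       (1-month recall, annualized)
    THE_inpatient  = PH * QH * POP            (12-month recall)
    THE_selfmed    = PM * QM * 12 * POP       (1-month recall, annualized)

Self-reported survey spending understates actual spending, so the prices
entering THE are first multiplied by a calibration factor: the official
all-ages national health expenditure times the 45+ age-group share, divided
by the survey-implied national total. The smoking-attributable medical
expenditure (SAME) per service is then THE times that service's
smoking-attributable fraction, and the overall SAME is the sum over services.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigurationError, DegenerateOutcomeError, SchemaError
from .measurement import SERVICES, SERVICE_COLUMNS


@dataclass
class NationalParams:
    """National scaling inputs for the expenditure aggregation.

    PV/QV: average spend per outpatient visit and average visits per person
    per month; PH/QH: the same for inpatient episodes per 12 months; PM:
    average monthly self-medication spend among those with positive spend;
    QM: share with positive monthly self-medication spend. POP is the 45+
    population; ``official_the_all_ages`` the official all-ages national
    health expenditure and ``share_45plus`` the 45+ share of it.
    """

    PV: float
    QV: float
    PH: float
    QH: float
    PM: float
    QM: float
    POP: float
    official_the_all_ages: float
    share_45plus: float = 0.5999
    n_smokers_45plus: float | None = None
    n_smokers_by_service: dict | None = None

    def __post_init__(self):
        for name in ("PV", "QV", "PH", "QH", "PM", "QM", "POP"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        for name in ("QM", "share_45plus"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "NationalParams":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        try:
            return cls(**payload)
        except TypeError as exc:
            raise ConfigurationError(f"bad national-params file {path}: {exc}") from exc

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def estimate_service_params(panel: pd.DataFrame):
    """Survey estimates of (PV, QV, PH, QH, PM, QM) from a person-wave table.

    Expenditures must already be in 2015 dollars. Use flags stand in for
    visit counts within each recall window, so PV/PH are mean spend per
    using person and QV/QH the per-person use rates.
    """
    use_o, exp_o = SERVICE_COLUMNS["outpatient"]
    use_i, exp_i = SERVICE_COLUMNS["inpatient"]
    use_s, exp_s = SERVICE_COLUMNS["selfmed"]
    users_o = panel[panel[use_o].astype(bool)]
    users_i = panel[panel[use_i].astype(bool)]
    pos_s = panel[panel[exp_s] > 0]
    if len(pos_s) == 0:
        raise DegenerateOutcomeError("no positive self-medication spend in panel")
    PV = float(users_o[exp_o].mean()) if len(users_o) else 0.0
    QV = float(panel[use_o].astype(float).mean())
    PH = float(users_i[exp_i].mean()) if len(users_i) else 0.0
    QH = float(panel[use_i].astype(float).mean())
    PM = float(pos_s[exp_s].mean())
    QM = float((panel[exp_s] > 0).mean())
    return PV, QV, PH, QH, PM, QM


def survey_national_estimate(params: NationalParams) -> float:
    """Survey-implied annual national expenditure (the SAF-free total)."""
    return float(
        params.PV * params.QV * 12.0 * params.POP
        + params.PH * params.QH * params.POP
        + params.PM * params.QM * 12.0 * params.POP
    )


def calibration_factor(
    survey_national_estimate: float,
    official_the_all_ages: float,
    share_45plus: float,
    invert: bool = False,
) -> float:
    """Ratio scaling survey-based averages to official expenditure levels.

    Default direction: (official all-ages THE x 45+ share) / survey estimate,
    so a survey undercount yields a factor above one that inflates PV, PH and
    PM. ``invert`` flips the ratio for sensitivity analysis.
    """
    if survey_national_estimate <= 0:
        raise ZeroDivisionError("survey national estimate must be positive")
    if official_the_all_ages <= 0 or share_45plus <= 0:
        raise ConfigurationError("official THE and 45+ share must be positive")
    factor = official_the_all_ages * share_45plus / survey_national_estimate
    return 1.0 / factor if invert else factor


_THE_FORMULA = {
    # service -> (price attr, quantity attr, annualization multiplier)
    "outpatient": ("PV", "QV", 12.0),
    "inpatient": ("PH", "QH", 1.0),
    "selfmed": ("PM", "QM", 12.0),
}


def compute_same(
    saf: pd.DataFrame,
    params: NationalParams,
    factor: float = 1.0,
    stratum: str = "all",
) -> pd.DataFrame:
    """Smoking-attributable expenditure per service for one stratum.

    ``saf`` is a :func:`same_econ.saf.compute_saf` table; the three service
    rows of ``stratum`` are required. Returns per-service and overall rows
    with the calibrated total expenditure (``the``), ``same = the * saf``,
    the calibration factor, and per-smoker amounts when smoker counts are
    configured.
    """
    sub = saf[saf["stratum"] == stratum]
    rows = []
    same_total = 0.0
    the_total = 0.0
    for service in SERVICES:
        cell = sub[sub["service"] == service]
        if len(cell) != 1:
            raise SchemaError(f"SAF table lacks a unique {service} row for {stratum!r}")
        saf_s = float(cell["saf"].iloc[0])
        price, qty, months = _THE_FORMULA[service]
        the = factor * getattr(params, price) * getattr(params, qty) * months * params.POP
        same = the * saf_s
        the_total += the
        same_total += same
        rows.append(
            {
                "service": service,
                "stratum": stratum,
                "saf": saf_s,
                "the_estimate": the,
                "same": same,
                "calibration_factor": factor,
                "per_smoker": _per_smoker_for(params, service, same),
            }
        )
    rows.append(
        {
            "service": "overall",
            "stratum": stratum,
            "saf": same_total / the_total if the_total else 0.0,
            "the_estimate": the_total,
            "same": same_total,
            "calibration_factor": factor,
            "per_smoker": _per_smoker_for(params, "overall", same_total),
        }
    )
    return pd.DataFrame(rows)


def _per_smoker_for(params: NationalParams, service: str, same: float):
    by_service = params.n_smokers_by_service or {}
    n = by_service.get(service)
    if n is None and service == "overall":
        n = params.n_smokers_45plus
    if n is None:
        return np.nan
    return per_smoker_same(same, n)


def per_smoker_same(same_total: float, n_smokers: float) -> float:
    """Attributable expenditure per smoker."""
    if n_smokers <= 0:
        raise ZeroDivisionError("smoker count must be positive")
    return float(same_total) / float(n_smokers)
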