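"""End-to-end orchestration: panel -> covariates -> six fits -> SAF -> SAME.

A run either simulates a synthetic panel or reads a person-wave CSV, derives
the analysis covariates and design matrix, fits the use and cost equations
for each of the three service types, replays the never-smoker counterfactual
to obtain attributable fractions overall and by stratum, and (when national
parameters are configured) scales them to national attributable expenditure.
Every artifact is written to the output directory together with a manifest
(config, seed, record counts, stage status) sufficient to reproduce the run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import measurement as ms
from . import models, saf as saf_mod, same as same_mod, synthetic
from .exceptions import ConfigurationError, InvalidArgumentError

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Fully serializable configuration of one pipeline run."""

    panel_csv: str | None = None  # read this CSV if set, else simulate
    sim: dict = field(default_factory=dict)  # SimConfig overrides
    deflation: dict | None = None  # {"cpi_medical": {...}, "fx_rate": ..}
    quadrature_nodes: int = 15
    tolerance: float = 1e-6
    max_iterations: int = 200
    retransform: str = "smearing"
    integration: str = "population_average"
    strata: tuple = ("sex", "residency")
    national_params: str | None = None  # YAML path; SAME skipped if absent
    seed: int = 0
    out_dir: str = "results"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(payload) - known
        if bad:
            raise ConfigurationError(f"unknown run-config keys: {sorted(bad)}")
        cfg = cls(**payload)
        cfg.strata = tuple(cfg.strata)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["strata"] = list(self.strata)
        return d


def weighted_descriptives(covariates: pd.DataFrame) -> pd.DataFrame:
    """Sampling-weighted category shares per wave, in percent.

    One row per (wave, variable, level); weights are the survey sampling
    weights, used here and only here (model fits are unweighted).
    """
    w = covariates["sampling_weight"].to_numpy(dtype=float)
    if np.any(w <= 0) or not np.all(np.isfinite(w)):
        raise InvalidArgumentError("sampling weights must be positive and finite")
    cat_cols = (
        "smoking_status",
        "sex",
        "age_group",
        "residency",
        "education",
        "marital",
        "poverty",
        "insurance",
        "region",
        "bmi_class",
        "drinker",
    )
    rows = []
    for wave, chunk in covariates.groupby("wave_year"):
        total = chunk["sampling_weight"].sum()
        for col in cat_cols:
            shares = chunk.groupby(col, observed=False)["sampling_weight"].sum() / total
            for level, share in shares.items():
                rows.append(
                    {
                        "wave_year": int(wave),
                        "variable": col,
                        "level": str(level),
                        "percent": 100.0 * float(share),
                    }
                )
    return pd.DataFrame(rows)


def fit_service_models(design: pd.DataFrame, covariates: pd.DataFrame, config: RunConfig):
    """Fit the use logit and the positive-cost GLS for every service."""
    groups = covariates["person_id"].to_numpy()
    fits = {}
    for service in ms.SERVICES:
        use = covariates[f"use_{service}"].to_numpy(dtype=float)
        fits[f"use_{service}"] = models.fit_re_logit(
            design,
            use,
            groups,
            quadrature_nodes=config.quadrature_nodes,
            tolerance=config.tolerance,
            max_iterations=config.max_iterations,
        )
        pos = covariates[f"exp_{service}"].to_numpy(dtype=float) > 0
        fits[f"cost_{service}"] = models.fit_re_gls(
            design[pos],
            covariates.loc[pos, f"exp_{service}"].to_numpy(dtype=float),
            groups[pos],
        )
        logger.info(
            "%s: use n=%d, cost n=%d (sigma_alpha %.3f / %.3f)",
            service,
            fits[f"use_{service}"].n_obs,
            fits[f"cost_{service}"].n_obs,
            fits[f"use_{service}"].sigma_alpha,
            fits[f"cost_{service}"].sigma_alpha,
        )
    return fits


def compute_saf_tables(design, covariates, fits, config: RunConfig) -> pd.DataFrame:
    """Factual vs never-smoker replay, stacked over services, with strata."""
    cf_design = saf_mod.make_counterfactual(design)
    strata_cols = [c for c in config.strata if c in covariates.columns]
    fact_parts, hyp_parts, strata_parts = [], [], []
    for service in ms.SERVICES:
        use_fit, cost_fit = fits[f"use_{service}"], fits[f"cost_{service}"]
        fact = saf_mod.predict_two_part(
            use_fit, cost_fit, design, config.retransform, config.integration,
            scenario="factual",
        )
        hyp = saf_mod.predict_two_part(
            use_fit, cost_fit, cf_design, config.retransform, config.integration,
            scenario="hypothetical",
        )
        fact["service"] = service
        hyp["service"] = service
        fact_parts.append(fact)
        hyp_parts.append(hyp)
        strata_parts.append(covariates[strata_cols].reset_index(drop=True))
    factual = pd.concat(fact_parts, ignore_index=True)
    hypothetical = pd.concat(hyp_parts, ignore_index=True)
    strata = pd.concat(strata_parts, ignore_index=True) if strata_cols else None
    return saf_mod.compute_saf(factual, hypothetical, strata)


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage and write the artifact directory.

    Returns the output directory; see the manifest it contains for stage
    status and record counts.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "stages": {},
        "counts": {},
    }

    truth = None
    if config.panel_csv:
        panel = pd.read_csv(config.panel_csv)
    else:
        sim_cfg = synthetic.SimConfig(**{"seed": config.seed, **config.sim})
        panel, truth = synthetic.simulate_panel(sim_cfg)
    panel.to_csv(out / "panel.csv", index=False)
    manifest["stages"]["panel"] = "ok"
    manifest["counts"]["person_waves"] = int(len(panel))

    covariates, dropped = ms.derive_covariates(panel)
    if config.deflation:
        covariates = ms.deflate_expenditures(
            covariates,
            config.deflation["cpi_medical"],
            config.deflation.get("fx_rate", 1.0),
        )
    manifest["counts"].update(dropped)
    design = ms.build_design_matrix(covariates)
    design.to_csv(out / "design.csv", index=False)
    manifest["stages"]["measurement"] = "ok"

    descr = weighted_descriptives(covariates)
    descr.to_csv(out / "descriptives.csv", index=False)

    fits_dir = out / "fits"
    fits_dir.mkdir(exist_ok=True)
    fits = fit_service_models(design, covariates, config)
    for name, fit in fits.items():
        fit.to_json(fits_dir / f"{name}.json")
    manifest["stages"]["fit"] = "ok"
    manifest["counts"]["positive_cost_obs"] = {
        s: int(fits[f"cost_{s}"].n_obs) for s in ms.SERVICES
    }

    saf_table = compute_saf_tables(design, covariates, fits, config)
    saf_table.to_csv(out / "saf.csv", index=False)
    manifest["stages"]["saf"] = "ok"

    if truth is not None:
        with open(out / "truth.json", "w") as fh:
            json.dump(
                {"true_saf": truth.true_saf, "seed": config.seed}, fh, indent=2
            )

    if config.national_params:
        params = same_mod.NationalParams.from_yaml(config.national_params)
        survey_est = same_mod.survey_national_estimate(params)
        factor = same_mod.calibration_factor(
            survey_est, params.official_the_all_ages, params.share_45plus
        )
        same_table = same_mod.compute_same(saf_table, params, factor)
        same_table.to_csv(out / "same.csv", index=False)
        manifest["stages"]["same"] = "ok"
    else:
        manifest["stages"]["same"] = "skipped (no national params)"

    manifest["config_hash"] = hashlib.sha256(
        json.dumps(manifest["config"], sort_keys=True).encode()
    ).hexdigest()[:16]
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return out
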