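import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from same_econ import measurement as ms
from same_econ import models, synthetic

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_panel():
    """Default-configuration panel at n=2000 with its ground truth."""
    cfg = synthetic.SimConfig(n_individuals=2000, seed=1)
    panel, truth = synthetic.simulate_panel(cfg)
    return cfg, panel, truth


@pytest.fixture(scope="session")
def default_design(default_panel):
    _, panel, _ = default_panel
    cov, _ = ms.derive_covariates(panel)
    return cov, ms.build_design_matrix(cov)


@pytest.fixture(scope="session")
def outpatient_fits(default_design):
    """Use-logit and cost-GLS fits for the outpatient service."""
    cov, design = default_design
    groups = cov["person_id"].to_numpy()
    use_fit = models.fit_re_logit(
        design, cov["use_outpatient"].to_numpy(float), groups
    )
    pos = cov["exp_outpatient"].to_numpy(float) > 0
    cost_fit = models.fit_re_gls(
        design[pos], cov.loc[pos, "exp_outpatient"].to_numpy(float), groups[pos]
    )
    return use_fit, cost_fit


def make_record(**overrides):
    """A single internally consistent person-wave record."""
    base = dict(
        person_id="p0",
        wave_year=2011,
        sex="female",
        age=50.0,
        residency="rural",
        education="primary_or_below",
        marital="unpartnered",
        insurance="no",
        region="west",
        cooking_fuel_traditional=False,
        toilet_not_flushable=False,
        no_running_water=False,
        asset_count=4,
        weight_kg=60.0,
        height_m=1.70,
        drink_freq_per_month=0.0,
        ever_smoked_100=False,
        currently_smokes=False,
        cigs_per_day=0.0,
        years_smoked=0.0,
        years_since_quit=0.0,
        used_outpatient_1m=False,
        outpatient_exp_1m=0.0,
        used_inpatient_12m=False,
        inpatient_exp_12m=0.0,
        used_selfmed_1m=False,
        selfmed_exp_1m=0.0,
        sampling_weight=1.0,
    )
    base.update(overrides)
    return base


@pytest.fixture
def record_frame():
    def _make(records):
        return pd.DataFrame([make_record(**r) for r in records])

    return _make


def zero_effect_sim_config(n=2000, seed=0, sigma_alpha=0.0):
    """Generating model with no covariate effects beyond the intercepts."""
    params = synthetic.default_true_params()
    for service in params:
        for block in ("gamma", "beta"):
            for key in params[service][block]:
                if key != "const":
                    params[service][block][key] = 0.0
        params[service]["sigma_alpha_logit"] = sigma_alpha
        params[service]["sigma_alpha_cost"] = sigma_alpha
    return synthetic.SimConfig(n_individuals=n, seed=seed, true_params=params)


def zero_smoking_sim_config(n=2000, seed=0):
    """Generating model whose smoking and interaction effects are all zero."""
    params = synthetic.default_true_params()
    for service in params:
        for block in ("gamma", "beta"):
            for key in ms.SMOKING_DESIGN_COLUMNS:
                params[service][block][key] = 0.0
    return synthetic.SimConfig(n_individuals=n, seed=seed, true_params=params)
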