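import numpy as np
import pandas as pd
import pytest

from gxemed import regression
from gxemed.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Study-sized cohort (n=187) with missingness, plus generator truth."""
    cohort, truth = simulate_cohort(SimulationConfig(seed=42))
    return cohort, truth


@pytest.fixture(scope="session")
def complete_cohort():
    """A larger complete cohort (no missingness) with analysis-scale
    outcomes and the true latent care factor as the environment score."""
    cfg = SimulationConfig(n_subjects=2000, seed=7, missing_rates={})
    cohort, truth = simulate_cohort(cfg)
    cohort = cohort.copy()
    cohort["care_quality"] = truth["care_latent"]
    cohort = regression.transform_outcomes(cohort)
    return cohort, truth


def make_analysis_cohort(n, seed, **config_kwargs):
    """Complete cohort on the analysis scale with the true care factor."""
    config_kwargs.setdefault("missing_rates", {})
    cfg = SimulationConfig(n_subjects=n, seed=seed, **config_kwargs)
    cohort, truth = simulate_cohort(cfg)
    cohort = cohort.copy()
    cohort["care_quality"] = truth["care_latent"]
    return regression.transform_outcomes(cohort), truth
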