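import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

import rintx

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """A small but structured cohort: 60 donors, 400 genes, all regions."""
    cfg = rintx.SimulationConfig(n_donors=60, genes=400, seed=42)
    donors, samples = rintx.generate_cohort(cfg)
    matrices, ground_truth = rintx.generate_expression(donors, samples, cfg)
    return cfg, donors, samples, matrices, ground_truth


@pytest.fixture(scope="session")
def block_design():
    """Planted-module design: 5 orthogonal blocks of 50 genes + 250 noise."""
    cfg = rintx.SimulationConfig(
        n_donors=80, genes=500, n_modules=5, module_size=50,
        frac_rin_genes=0.0, frac_de_genes=0.0, frac_sex_genes=0.0,
        n_dense_factors=0, region_effect_sd=0.0, depth_normalize=False, seed=7,
    )
    donors, samples = rintx.generate_cohort(cfg)
    matrices, ground_truth = rintx.generate_expression(donors, samples, cfg)
    return cfg, donors, samples, matrices, ground_truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
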