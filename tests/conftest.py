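import numpy as np
import pytest

from mvqtl import simstudy
from mvqtl.qtltests import TestSpec
from mvqtl.scan import LocusEncoding


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def study_design():
    """The fixed study design: n=300, F2 genotype, 5-level block covariate
    (treatment-coded columns)."""
    n = 300
    covariate = simstudy.covariate_blocks(n)
    cov_cols = (covariate[:, None] == np.arange(2, 6)[None, :]).astype(float)
    return n, covariate, cov_cols


def make_sim_spec(test, scenario_label, seed, with_var_covs=None):
    """One simulated experiment under a canonical scenario, wrapped as a
    TestSpec ready for any of the eight tests."""
    scenario = simstudy.get_scenario(scenario_label)
    n = scenario.n
    covariate = simstudy.covariate_blocks(n)
    cov_cols = (covariate[:, None] == np.arange(2, 6)[None, :]).astype(float)
    rng = np.random.default_rng(seed)
    q = simstudy.simulate_genotypes(n, rng)
    y = simstudy.simulate_phenotype(q, covariate, scenario, rng)
    if with_var_covs is None:
        with_var_covs = test.startswith("dglm")
    return TestSpec(
        test_name=test,
        phenotype=y,
        locus=LocusEncoding(a=q, d=(q == 0).astype(float), hard_calls=q.astype(int)),
        mean_covariates=cov_cols,
        variance_covariates=cov_cols if with_var_covs else None,
        cross_type="f2",
    )
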