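import numpy as np
import pytest

from chdopt.economics import EconomicParameters, endstate_values
from chdopt.risk_update import LikelihoodTable, estimate_likelihoods
from chdopt.synthetic import CohortSpec, build_risk_distribution, generate_cohort


@pytest.fixture(scope="session")
def base_params():
    return EconomicParameters()


@pytest.fixture(scope="session")
def base_endstates(base_params):
    return endstate_values(base_params)


@pytest.fixture(scope="session")
def default_cohort():
    """Source-cohort-scale synthetic cohort used across estimation tests."""
    return generate_cohort(CohortSpec(seed=0))


@pytest.fixture(scope="session")
def model_inputs(default_cohort):
    """(lik_trs, lik_grs, risk_distribution) estimated from the default cohort."""
    lik_trs = estimate_likelihoods(default_cohort, "trs", 10)
    lik_grs = estimate_likelihoods(default_cohort, "grs", 10)
    dist = build_risk_distribution("beta", (1.5, 27.0))
    return lik_trs, lik_grs, dist


@pytest.fixture(scope="session")
def two_bin_tests():
    """Symmetric two-bin TRS/GRS toys with likelihood ratios 4 and 1/4."""
    trs = LikelihoodTable(
        test_name="trs",
        bin_edges=np.array([-np.inf, 0.0, np.inf]),
        p_result_given_chd=np.array([0.2, 0.8]),
        p_result_given_no_chd=np.array([0.8, 0.2]),
    )
    grs = LikelihoodTable(
        test_name="grs",
        bin_edges=np.array([-np.inf, 0.0, np.inf]),
        p_result_given_chd=np.array([0.3, 0.7]),
        p_result_given_no_chd=np.array([0.7, 0.3]),
    )
    return trs, grs
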