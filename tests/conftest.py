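import numpy as np
import pytest

from denovostat.simulate import make_rate_table, pcms_like_config, simulate_trio_cohort


@pytest.fixture(scope="session")
def pcms_config():
    return pcms_like_config(seed=1)


@pytest.fixture(scope="session")
def pcms_rates(pcms_config):
    return make_rate_table(pcms_config, np.random.default_rng(1))


@pytest.fixture(scope="session")
def pcms_cohort(pcms_config, pcms_rates):
    """One frozen pCMS-like synthetic cohort (118 case / 750 control trios)."""
    return simulate_trio_cohort(pcms_config, pcms_rates, np.random.default_rng(11))


@pytest.fixture(scope="session")
def small_rates():
    """Tiny rate table for fast exact/oracle checks."""
    from denovostat.io import MutationRateTable

    return MutationRateTable(
        genes=np.array(["A", "B", "C"], dtype=object),
        mu_total=np.array([1e-5, 1e-5, 1e-5]),
        mu_lgd=np.array([2e-6, 2e-6, 2e-6]),
        mu_misd=np.array([3e-6, 3e-6, 3e-6]),
    )
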