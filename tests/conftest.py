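import numpy as np
import pytest
from hypothesis import settings

from stochmet import preset, three_stage_params, three_stage_pmf

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def table1():
    return preset("table1")


@pytest.fixture(scope="session")
def table1_enzyme_pmf(table1):
    return three_stage_pmf(three_stage_params(table1))


@pytest.fixture(scope="session")
def downscaled_rc():
    """Small, fast-mixing network used for oracle comparisons.

    n_s = 30 with all stationary means below ~5 so the full
    five-species master equation fits a tractable state-space box, and
    relaxation times of seconds so simulated histograms converge quickly.
    """
    from stochmet import RateConstants
    return RateConstants(
        n_s=30, k_1=1.0 / 6.0, k_m1=15.0, k_cat=1.0, k_rev=0.05, k_c=0.15,
        k_tx=0.12, k_tl=0.25, k_on=0.02, k_off=0.02, k_deg=1.0, delta=0.005,
    )


def random_rate_constants(rng):
    """Log-uniform random valid rate constants for property tests."""
    from stochmet import RateConstants

    def lu(lo, hi):
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    return RateConstants(
        n_s=int(rng.integers(1, 10000)),
        k_1=lu(1e-4, 10.0), k_m1=lu(1e-2, 1e4), k_cat=lu(1e-3, 1e3),
        k_rev=lu(1e-6, 1.0), k_c=lu(1e-4, 10.0), k_tx=lu(1e-4, 1.0),
        k_tl=lu(1e-3, 10.0), k_on=lu(1e-6, 1.0), k_off=lu(1e-6, 1.0),
        k_deg=lu(1e-3, 10.0), delta=lu(1e-5, 1e-2),
    )
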