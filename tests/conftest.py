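import numpy as np
import pytest

from aerotox.grids import make_size_grid
from aerotox.synthesis import simulate_campaign

#: documented seed of the packaged winter campaign used across the suite
WINTER_SEED = 1


@pytest.fixture(scope="session")
def grid():
    """The default 8-1000 nm, 16 bins/decade measurement grid."""
    return make_size_grid(8, 1000, 16)


@pytest.fixture(scope="session")
def wide_grid():
    """A grid wide enough that lognormal modes are numerically unbounded."""
    return make_size_grid(1, 10000, 32)


@pytest.fixture(scope="session")
def winter():
    """The packaged seeded 16-day winter campaign (10-min cadence)."""
    return simulate_campaign(seed=WINTER_SEED)


@pytest.fixture(scope="session")
def winter_daily(winter):
    from aerotox.pipeline import daily_table

    return daily_table(
        winter.pnsd,
        winter.grid,
        covariates_10min=winter.covariates_10min,
        daily_covariates=winter.daily_covariates,
    )
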