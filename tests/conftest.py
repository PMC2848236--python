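import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# The four-carbon worked example: observed relative intensities carrying
# 13C natural-abundance contamination, and the values the sequential
# correction recovers from them (to the precision they are quoted at).
TABLE1_OBSERVED = np.array([0.956, 1.01, 3.33e-2, 3.70e-4, 1.38e-6])
TABLE1_CORRECTED_2DP = np.array([1.00, 1.00, 0.00, 0.00, 0.00])
TABLE1_NA = 0.01109
TABLE1_CMAX = 4


@pytest.fixture
def table1_observed():
    return TABLE1_OBSERVED.copy()


@pytest.fixture
def four_carbon_table():
    from nacorr import build_binomial_table

    return build_binomial_table(TABLE1_CMAX, TABLE1_NA)
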