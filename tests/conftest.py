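import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import gestwin as gw

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def base():
    """The calibrated default Gompertz baseline."""
    return gw.default_baseline()


@pytest.fixture(scope="session")
def m1_truth_spec():
    """A fully pinned one-constant-class generating model (known truth)."""
    lc = gw.LocusClass("constant", gamma=2.0, maf=0.05, count=2)
    return gw.ModelSpec("m1_truth", (lc,), (frozenset(),))


@pytest.fixture(scope="session")
def m1_reference(m1_truth_spec):
    """Reference quantile table generated under the known M1-style truth."""
    rng = np.random.default_rng(42)
    cohort = gw.simulate_pair_cohort(m1_truth_spec, 35_541, rng, engine="iterative")
    return gw.conditional_quantile_table(cohort, rng=rng)
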