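import numpy as np
import pytest

from rtrunc.distributions import FamilySpec
from rtrunc.estimation import TruncatedSample
from rtrunc.simulation import Scenario, draw_truncated_sample


@pytest.fixture
def rng():
    return np.random.default_rng(20140203)


@pytest.fixture
def toy_sample():
    """Three cases with visible truncation; hand-checkable."""
    return TruncatedSample(x=[1.0, 2.0, 3.0], t=[2.0, 3.0, 4.0])


@pytest.fixture
def untruncated_sample(rng):
    """Exponential draws with truncation times far beyond every onset."""
    x = rng.exponential(scale=20.0, size=80)
    return TruncatedSample(x=x, t=np.full(80, 1e9))


@pytest.fixture(scope="session")
def lymphoma_like_sample():
    """Synthetic 64-case sample near the anti-TNF lymphoma application:
    Weibull onset (lam=0.00468, beta=1.49) observed through uniform
    truncation with t* around 529 weeks."""
    spec = FamilySpec("weibull", (0.00468, 1.49))
    scenario = Scenario(spec=spec, p=0.979, n=64, n_reps=1, seed=529)
    return draw_truncated_sample(scenario)


def weibull_sample(n=200, lam=0.05, beta=2.0, p=0.8, seed=11):
    spec = FamilySpec("weibull", (lam, beta))
    return draw_truncated_sample(Scenario(spec=spec, p=p, n=n, n_reps=1, seed=seed))
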