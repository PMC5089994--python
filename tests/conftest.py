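import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def oracle_category_probs(theta, alpha, beta, tau, weight=1.0):
    """Brute-force adjacent-logit oracle: exponentiate cumulative log-odds, normalize.

    Written as an explicit loop, independent of the vectorized implementation.
    """
    logw = [0.0]
    for t in tau:
        logw.append(logw[-1] + alpha * theta - (beta + weight * t))
    w = np.exp(np.asarray(logw))
    return w / w.sum()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2026)
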