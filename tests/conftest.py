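import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_segments(rng, H=2, T_h=4, k=1, coupled_mu=False):
    """Random per-segment data and prior moments for oracle comparisons."""
    from nhdbn.regression import PriorMoments, SegmentData

    segments, moments = [], []
    for _ in range(H):
        X = np.column_stack([np.ones(T_h), rng.standard_normal((T_h, k))])
        y = rng.standard_normal(T_h)
        mu = rng.standard_normal(k + 1) if coupled_mu else np.zeros(k + 1)
        A = rng.standard_normal((k + 1, k + 1))
        Sigma = A @ A.T + 0.5 * np.eye(k + 1)
        segments.append(SegmentData(y=y, X=X))
        moments.append(PriorMoments(mu=mu, Sigma=Sigma))
    return segments, moments


@pytest.fixture
def small_matrix():
    """A deterministic 4-node expression matrix with T+1 = 13 time points."""
    from nhdbn.regression import ExpressionMatrix

    g = np.random.default_rng(7)
    return ExpressionMatrix(
        values=g.standard_normal((4, 13)),
        node_names=("A", "B", "C", "D"),
    )
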