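import numpy as np
import pytest

from abcdp import DistanceSpec, KernelSpec
from abcdp.simulators import THETA_STAR, mixture_stream, sample_mixture_data


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_mixture_problem():
    """A small, fully materialized mixture-benchmark stream.

    Observed data (N=100) drawn at the ground-truth mixing proportions, a
    50-pair public stream with n=100 points per pseudo-dataset, and the raw
    MMD distances — shared by engine and bound tests.
    """
    from abcdp.engine import stream_distances

    rng = np.random.default_rng(777)
    observed = sample_mixture_data(THETA_STAR, 100, rng)
    spec = DistanceSpec(kind="mmd", kernel=KernelSpec(bandwidth=1.0))
    thetas, rho = stream_distances(observed, mixture_stream(50, 100, rng), spec)
    return {"observed": observed, "spec": spec, "thetas": thetas, "rho": rho}
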