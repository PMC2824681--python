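import numpy as np
import pytest

from gxesim import EnvironmentDistribution, PopulationSpec


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def two_point_env():
    """Exposure 0 or 1 with equal probability."""
    return EnvironmentDistribution.discrete_dist([0.0, 1.0], [0.5, 0.5])


@pytest.fixture
def std_normal_env():
    return EnvironmentDistribution.normal_dist(0.0, 1.0)


def make_spec(model="AM", n=1000, m=0.1, rr31=3.0, w=0.5, env_or=1.5,
              freqs=(0.25, 0.5, 0.25), env=None, **kw):
    if env is None:
        env = EnvironmentDistribution.normal_dist(0.0, 1.0)
    return PopulationSpec(
        n_individuals=n,
        genotype_freqs=(freqs,),
        env_dists=(env,),
        disease_freq=m,
        model=model,
        rr31=rr31,
        w=w,
        env_or=env_or,
        **kw,
    )


@pytest.fixture
def make_population_spec():
    return make_spec
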