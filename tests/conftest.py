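import numpy as np
import pytest

from deafsim.model_core import AgentPopulation


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def build_population(
    male,
    genotypes=None,
    env_deaf=None,
    knows_sign=None,
    social_position=0.0,
):
    """Hand-rolled small population; genotypes as 'AA'/'Aa'/'aa' strings."""
    n = len(male)
    genotypes = genotypes or ["AA"] * n
    a1 = np.array([1 if g[0] == "a" else 0 for g in genotypes], dtype=np.uint8)
    a2 = np.array([1 if g[1] == "a" else 0 for g in genotypes], dtype=np.uint8)
    return AgentPopulation(
        male=np.asarray(male, dtype=bool),
        allele1=a1,
        allele2=a2,
        env_deaf=np.asarray(env_deaf if env_deaf is not None else [False] * n, dtype=bool),
        knows_sign=np.asarray(knows_sign if knows_sign is not None else [False] * n, dtype=bool),
        social_position=np.full(n, social_position, dtype=float),
    )


@pytest.fixture
def make_population():
    return build_population
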