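import math

import pytest

from parsnet import (
    ChainConfig,
    GeneratorParams,
    build_network,
    generate_network,
    toy_fixtures,
)

# Desk-scale chain settings for toy networks; production defaults
# (B=10^4, burn-in 10^7, S=10^4) are far beyond what the fixtures need.
TOY_CHAIN = dict(batch_size=50, burn_in_steps=2_000, n_samples=20_000)

T1_P = (1 + math.exp(-1)) / (2 + math.exp(-1))  # exact P(r1)=P(r2) on t1
T1_DISJOINT_P = (1 + math.exp(-2)) / (2 + math.exp(-2))


@pytest.fixture(scope="session")
def fixtures():
    return toy_fixtures()


@pytest.fixture(scope="session")
def t1(fixtures):
    return fixtures["t1"].network


@pytest.fixture(scope="session")
def shared_chain(fixtures):
    return fixtures["shared_chain"].network


@pytest.fixture(scope="session")
def forced_net(fixtures):
    return fixtures["forced"].network


def small_generated_params(seed: int) -> GeneratorParams:
    """A generator setting whose networks stay inside the enumeration cap."""
    return GeneratorParams(
        n_metabolites=24,
        n_reactions=14,
        metabolites_per_reaction=(2, 3),
        n_enzymes=10,
        promiscuous_fraction=0.4,
        reactions_per_promiscuous_enzyme=(2, 3),
        metabolite_sharing_bias=2.0,
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_generated():
    return generate_network(small_generated_params(0))


@pytest.fixture(scope="session")
def mono_only():
    """Single mono-functional enzyme: degenerate sampling space."""
    return build_network({"r1": {"A", "B"}}, {"e1": {"r1"}})


def toy_config(seed: int = 1, **overrides) -> ChainConfig:
    kwargs = {**TOY_CHAIN, "lam": 1.0, "seed": seed}
    kwargs.update(overrides)
    return ChainConfig(**kwargs)
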