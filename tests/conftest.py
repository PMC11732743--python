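import numpy as np
import pytest

from socialdrift import social
from socialdrift.sampling import SamplingScheme, SchemeKind, draw_sample


def rng_for(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def small_population(
    n_groups=6,
    mating=social.MONOGAMY,
    n_loci=5,
    seed=7,
    ticks=0,
    pool=None,
    life=None,
):
    """A small, genetics-enabled population for rule-level tests."""
    r = np.random.default_rng(seed)
    if pool is None:
        pool = social.make_founder_pool(n_loci, r, pool_genes=60)
    life = life or social.LifeHistory()
    pop = social.init_population(n_groups, mating, life, pool, r)
    for _ in range(ticks):
        social.advance_tick(pop, r)
    return pop, r


@pytest.fixture(scope="session")
def social_battery():
    """Scaled-down study battery shared by the acceptance tests.

    For each mating system: 20 independent 50-group simulations run for
    50,000 ticks with 100 microsatellite loci (mutation-drift equilibrium
    is reached within ~20,000 ticks at these sizes).  Returns the final
    populations keyed by mating-system label.
    """
    out = {}
    for label, mating in [
        ("monogamy", social.MONOGAMY),
        ("polygynandry", social.POLYGYNANDRY),
        ("polygyny", social.POLYGYNY),
    ]:
        pops = []
        for rep in range(20):
            r = np.random.default_rng(50_000 + rep)
            pool = social.make_founder_pool(100, r)
            pop = social.init_population(50, mating, social.LifeHistory(), pool, r)
            rec = social.run(pop, 50_000, 10_000, r)
            assert not rec.extinct
            pops.append((pop, rec))
        out[label] = pops
    return out


def battery_sample(pop, rng, n=20, n_loci=100, pool_size=30):
    """The study's random-pool sample from a final population state."""
    ds = draw_sample(
        pop, SamplingScheme(SchemeKind.RANDOM_POOL, n, pool_size=pool_size), rng
    )
    if n_loci < ds.n_loci:
        ds = ds.subset(loci=np.arange(n_loci))
    return ds
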