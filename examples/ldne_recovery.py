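"""LD-based contemporary Ne: recovery of a known truth, then social bias.

Part 1 estimates Ne from linkage disequilibrium in samples from an ideal
Wright-Fisher population of known size (N = 50): the method recovers the
truth.  Part 2 applies the same estimator to a socially structured
population whose census is an order of magnitude larger than anything the
estimates suggest.
"""

import numpy as np

from socialdrift import (
    LDNeConfig,
    LifeHistory,
    MONOGAMY,
    WFConfig,
    estimate_ne,
    init_population,
    make_founder_pool,
    run_social,
    run_wf,
)
from socialdrift.sampling import SamplingScheme, SchemeKind, draw_sample

rng = np.random.default_rng(3)

# --- part 1: ideal Wright-Fisher population, true N = 50 ----------------
nes = []
for _ in range(40):
    cfg = WFConfig(ploidy=2, n_individuals=50, n_loci=20, mu=2.5e-3,
                   init="equilibrium", n_generations=120)
    est = estimate_ne(run_wf(cfg, rng))
    if np.isfinite(est.ne_point):
        nes.append(est.ne_point)
print(f"ideal WF, true N=50:  median Ne = {np.median(nes):.1f} "
      f"({len(nes)} finite estimates of 40)")

# --- part 2: socially structured population -----------------------------
pool = make_founder_pool(20, rng)
pop = init_population(50, MONOGAMY, LifeHistory(), pool, rng)
run_social(pop, 30_000, 30_000, rng)
scheme = SamplingScheme(SchemeKind.RANDOM_POOL, 50, pool_size=30)
vals = []
for _ in range(5):
    est = estimate_ne(draw_sample(pop, scheme, rng),
                      LDNeConfig(mating_model="monogamy"))
    if np.isfinite(est.ne_point):
        vals.append(est.ne_point)
print(f"social monogamy:      mean Ne = {np.mean(vals):.0f}  "
      f"(census {pop.census()}, RS individuals {pop.n_rs()})")
print(
    "\nThe first line shows the estimator is sound on its home ground; the "
    "second shows\nthat under social structure the LD signal reflects the "
    "small breeding pool, not\nthe census, so Ne estimates sit far below "
    "the number of living individuals."
)
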