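"""Spurious expansion signals from the heterozygosity test.

Generates stationary coalescent microsatellite datasets (theta = 2,
40 genes, 100 loci) — populations that never changed size — and runs the
mutation-drift-equilibrium test on each.  A perfectly calibrated test
would flag about 5% of datasets in either direction; instead a
substantial fraction shows a significant heterozygosity deficit, read as
(spurious) population expansion.
"""

import numpy as np

from socialdrift import MsatConfig, aggregate_proportions, simulate_msat_dataset
from socialdrift import test_dataset as equilibrium_test

rng = np.random.default_rng(42)
verdicts = []
for rep in range(15):
    ds = simulate_msat_dataset(MsatConfig(theta=2.0, n_loci=100, n_genes=40),
                               rng, ploidy=2)
    res = equilibrium_test(ds, rng)
    verdicts.append(res.verdict)
    print(f"dataset {rep + 1:2d}: H-deficit p = {res.p_deficit:6.4f}  "
          f"H-excess p = {res.p_excess:6.4f}  -> {res.verdict}")

print()
print(aggregate_proportions(verdicts).round(3))
print(
    "\nEvery dataset comes from a constant-size, random-mating population; "
    "every\n'expansion' row is a false signal produced by the test's "
    "conditional null at\nmoderate diversity."
)
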