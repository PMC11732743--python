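"""Forward-in-time Wright-Fisher simulator of one panmictic population with
SMM microsatellites.

Two configurations mirror the panmictic reference scenarios: 2000 haploid
individuals, and 1000 diploid dioecious individuals (500 males, 500 females)
with random mating.  Generations are non-overlapping and population size and
sex counts are exactly constant.  Each transmitted allele mutates by +-1 with
probability mu per locus per generation, so the scaled mutation parameter is
theta = 2*N*mu (haploid) or 4*N*mu (diploid).

Initialization modes:

``monomorphic``
    all alleles start at state 0; run 20N generations (the default run
    length) to guarantee mutation-drift equilibrium from scratch.
``equilibrium``
    every locus is initialized from a coalescent SMM sample of the whole
    population at the matched theta, which is already stationary; a short
    forward burn-in (200 generations) then imposes the forward process's
    fine-scale pedigree structure.  This is the fast mode used by the
    scaled-down experiment presets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .coalescent import MsatConfig, simulate_msat_dataset
from .dataset import GenotypeDataset

__all__ = ["WFConfig", "run_wf"]

_FAST_BURNIN = 200  # generations after an equilibrium (coalescent) start


@dataclass
class WFConfig:
    """Wright-Fisher run configuration.

    sex_ratio applies to diploids only, as (n_males, n_females); counts must
    sum to n_individuals.  n_generations=None picks 20N for a monomorphic
    start or the fixed fast burn-in for an equilibrium start.
    """

    ploidy: int
    n_individuals: int
    n_loci: int
    mu: float
    sex_ratio: tuple[int, int] | None = None
    n_generations: int | None = None
    init: str = "monomorphic"

    def __post_init__(self):
        if self.ploidy not in (1, 2):
            raise ValueError("ploidy must be 1 or 2")
        if self.n_individuals < 2:
            raise ValueError("n_individuals must be >= 2")
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError("mu must be in [0, 1]")
        if self.init not in ("monomorphic", "equilibrium"):
            raise ValueError("init must be 'monomorphic' or 'equilibrium'")
        if self.ploidy == 2:
            if self.sex_ratio is None:
                half = self.n_individuals // 2
                self.sex_ratio = (half, self.n_individuals - half)
            if sum(self.sex_ratio) != self.n_individuals:
                raise ValueError("sex_ratio must sum to n_individuals")

    @property
    def theta(self) -> float:
        return 2.0 * self.ploidy * self.n_individuals * self.mu

    def generations(self) -> int:
        if self.n_generations is not None:
            return int(self.n_generations)
        if self.init == "equilibrium":
            return _FAST_BURNIN
        return 20 * self.n_individuals


def _mutate(states: np.ndarray, mu: float, rng: np.random.Generator) -> None:
    if mu <= 0.0:
        return
    mask = rng.random(states.shape) < mu
    n = int(mask.sum())
    if n:
        states[mask] += rng.integers(0, 2, size=n) * 2 - 1


def run_wf(config: WFConfig, rng: np.random.Generator) -> GenotypeDataset:
    """Run the forward simulation and return the full final population."""
    N, L = config.n_individuals, config.n_loci
    if config.init == "equilibrium":
        ds = simulate_msat_dataset(
            MsatConfig(theta=config.theta, n_loci=L, n_genes=N * config.ploidy),
            rng,
            ploidy=config.ploidy,
        )
        geno = np.ascontiguousarray(ds.genotypes, dtype=np.int64)
    else:
        geno = np.zeros((N, L, config.ploidy), dtype=np.int64)

    gens = config.generations()
    if config.ploidy == 1:
        states = geno[:, :, 0]
        for _ in range(gens):
            parents = rng.integers(0, N, size=N)
            states = states[parents].copy()
            _mutate(states, config.mu, rng)
        geno = states[:, :, None]
    else:
        n_m, n_f = config.sex_ratio
        for _ in range(gens):
            dads = rng.integers(0, n_m, size=N)
            moms = n_m + rng.integers(0, n_f, size=N)
            pat = np.take_along_axis(
                geno[dads], rng.integers(0, 2, size=(N, L))[:, :, None], axis=2
            )[:, :, 0]
            mat = np.take_along_axis(
                geno[moms], rng.integers(0, 2, size=(N, L))[:, :, None], axis=2
            )[:, :, 0]
            _mutate(pat, config.mu, rng)
            _mutate(mat, config.mu, rng)
            geno = np.stack([pat, mat], axis=2)
    return GenotypeDataset(geno)
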