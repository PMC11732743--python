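"""Individual-based forward simulator of a socially structured population.

The population is a fully connected network of social groups (structure, but
no space).  Each group is a small age-structured aggregation of kin: a fixed
complement of reproductive-status (RS) males and females defined by the
mating system's sex ratio (1:1 monogamy, 2:2 polygynandry, 1:10 polygyny)
plus their descendants.  Females are philopatric; males disperse to fill RS
vacancies in other groups.  There is no carrying capacity or density
regulation: census size is an emergent balance between the birth stream of
the RS females and the lifespan distribution.

One tick (a quarter of the modeled species' year) applies, in order:
aging, mortality, reproduction, vacancy filling (migration / philopatric
replacement), and colonization of vanished groups.

Demographic rules
-----------------
* lifespan drawn at birth from Poisson(lifespan_mean) rejected above
  lifespan_max; death when age exceeds the draw.
* newborns die with probability ``infant_mortality`` before weaning
  (applied at birth; weaning age is one tick).
* each RS female at or above reproductive age, and at least
  ``birth_interval`` ticks past her previous reproduction event, is paired
  with one RS male of her group chosen uniformly (a male may serve several
  females); the litter is Poisson(offspring_mean + 1) upper-truncated one
  above its mean.  This calibration of the truncated-Poisson litter rule
  reproduces the reference census sizes (about 600 / 1200 / 6000 individuals
  for 50-group monogamy / polygynandry / polygyny) via the demographic
  balance  census = n_females * (1 - infant_mortality) * E[litter] /
  birth_interval * E[lifetime].
* genomes are diploid microsatellites under the strict stepwise mutation
  model; each transmitted allele mutates +-1 with probability mu per
  reproduction event (birth is the generational event of this
  overlapping-generations model).

Genetics has no feedback on demography (no selection), so populations can be
run with genetics disabled for demography-only studies at identical census
dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .coalescent import MsatConfig, simulate_msat_dataset
from .dataset import GenotypeDataset, unbiased_gene_diversity

__all__ = [
    "LifeHistory",
    "MatingSystem",
    "MONOGAMY",
    "POLYGYNANDRY",
    "POLYGYNY",
    "Population",
    "SimRecord",
    "make_founder_pool",
    "init_population",
    "advance_tick",
    "apply_mortality",
    "reproduce",
    "fill_vacancies",
    "colonize",
    "genetic_summary",
    "run",
]

_NEVER = -(1 << 30)
_EMPTY_GENO = np.zeros((0, 0, 2), dtype=np.int16)


@dataclass(frozen=True)
class LifeHistory:
    """Life-history parameters, in ticks (1 tick = 3 months).

    Defaults are the study conditions: 7-year mean lifespan, 10-year cap,
    weaning at one tick, maturity at 2 years, yearly litters.
    """

    lifespan_mean: int = 28
    lifespan_max: int = 40
    infant_mortality: float = 0.3
    offspring_mean: int = 2
    weaning_age: int = 1
    reproductive_age: int = 8
    birth_interval: int = 4
    mu: float = 5e-4

    def __post_init__(self):
        if not 0.0 <= self.infant_mortality <= 1.0:
            raise ValueError("infant_mortality must be in [0, 1]")
        if not self.weaning_age < self.reproductive_age < self.lifespan_max:
            raise ValueError("need weaning_age < reproductive_age < lifespan_max")
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError("mu must be in [0, 1]")


@dataclass(frozen=True)
class MatingSystem:
    """RS complement per group; the sex ratio defines the mating system."""

    rs_males: int
    rs_females: int
    label: str = ""

    def __post_init__(self):
        if self.rs_males < 1 or self.rs_females < 1:
            raise ValueError("RS complements must be >= 1")


MONOGAMY = MatingSystem(1, 1, "monogamy")
POLYGYNANDRY = MatingSystem(2, 2, "polygynandry")
POLYGYNY = MatingSystem(1, 10, "polygyny")


def _trunc_poisson_cdf(lam: float, upper: int) -> np.ndarray:
    pmf = sps.poisson.pmf(np.arange(upper + 1), lam)
    return np.cumsum(pmf / pmf.sum())


@dataclass
class SimRecord:
    """Time series of population summaries; ``extinct`` flags truncation."""

    table: pd.DataFrame
    extinct: bool = False


class Population:
    """Mutable agent-based state, stored as flat arrays with slot recycling.

    Individuals live in slots ``0.._top``; dead slots are reused for
    newborns.  Every living individual belongs to exactly one group by
    construction (``group[i]`` is single-valued).
    """

    def __init__(
        self,
        n_groups: int,
        mating: MatingSystem,
        life: LifeHistory,
        n_loci: int = 0,
        capacity: int | None = None,
    ):
        self.n_groups = int(n_groups)
        self.mating = mating
        self.life = life
        self.n_loci = int(n_loci)
        self.tick = 0
        self.quota_m = mating.rs_males
        self.quota_f = mating.rs_females
        if capacity is None:
            per_group = (
                mating.rs_females
                * (1.0 - life.infant_mortality)
                * self._litter_mean()
                / life.birth_interval
                * (life.lifespan_mean + 1)
            )
            capacity = int(1.7 * n_groups * max(per_group, 1.0)) + n_groups * (
                mating.rs_males + mating.rs_females
            ) + 64
        self._cap = capacity
        self._top = 0
        self._free = np.zeros(capacity, dtype=np.int64)
        self._n_free = 0
        self._meta = np.zeros(3, dtype=np.int64)
        self.alive = np.zeros(capacity, dtype=bool)
        self.female = np.zeros(capacity, dtype=bool)
        self.age = np.zeros(capacity, dtype=np.int32)
        self.lifespan = np.zeros(capacity, dtype=np.int32)
        self.group = np.zeros(capacity, dtype=np.int32)
        self.rs = np.zeros(capacity, dtype=bool)
        self.last_birth = np.full(capacity, _NEVER, dtype=np.int64)
        self.geno = (
            np.zeros((capacity, n_loci, 2), dtype=np.int16) if n_loci else None
        )
        self._lifespan_cdf = _trunc_poisson_cdf(life.lifespan_mean, life.lifespan_max)
        self._litter_cdf = _trunc_poisson_cdf(
            life.offspring_mean + 1, life.offspring_mean + 2
        )

    def _litter_mean(self) -> float:
        lam, upper = self.life.offspring_mean + 1, self.life.offspring_mean + 2
        k = np.arange(upper + 1)
        pmf = sps.poisson.pmf(k, lam)
        pmf /= pmf.sum()
        return float((k * pmf).sum())

    # -- slot management ---------------------------------------------------
    def _grow(self, needed: int) -> None:
        new_cap = max(int(self._cap * 1.6), self._cap + needed + 64)
        for name in ("alive", "female", "rs"):
            a = getattr(self, name)
            b = np.zeros(new_cap, dtype=bool)
            b[: self._cap] = a
            setattr(self, name, b)
        for name, dt in (("age", np.int32), ("lifespan", np.int32), ("group", np.int32)):
            a = getattr(self, name)
            b = np.zeros(new_cap, dtype=dt)
            b[: self._cap] = a
            setattr(self, name, b)
        lb = np.full(new_cap, _NEVER, dtype=np.int64)
        lb[: self._cap] = self.last_birth
        self.last_birth = lb
        fr = np.zeros(new_cap, dtype=np.int64)
        fr[: self._cap] = self._free
        self._free = fr
        if self.geno is not None:
            g = np.zeros((new_cap, self.n_loci, 2), dtype=np.int16)
            g[: self._cap] = self.geno
            self.geno = g
        self._cap = new_cap

    def _alloc(self, n: int) -> np.ndarray:
        out = np.empty(n, dtype=np.int64)
        take = min(n, self._n_free)
        for i in range(take):
            self._n_free -= 1
            out[i] = self._free[self._n_free]
        rest = n - take
        if rest:
            if self._top + rest > self._cap:
                self._grow(rest)
            out[take:] = np.arange(self._top, self._top + rest)
            self._top += rest
        return out

    # -- summaries ----------------------------------------------------------
    def census(self) -> int:
        return int(self.alive[: self._top].sum())

    def n_rs(self) -> int:
        m = self.alive[: self._top] & self.rs[: self._top]
        return int(m.sum())

    def living_indices(self) -> np.ndarray:
        return np.flatnonzero(self.alive[: self._top])

    def draw_lifespans(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return np.searchsorted(self._lifespan_cdf, rng.random(n)).astype(np.int32)

    def draw_litters(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return np.searchsorted(self._litter_cdf, rng.random(n)).astype(np.int64)

    def stage_of(self, idx: np.ndarray) -> np.ndarray:
        """Life-stage labels (offspring/juvenile/adult) from age thresholds."""
        age = self.age[idx]
        out = np.where(
            age < self.life.weaning_age,
            "offspring",
            np.where(age < self.life.reproductive_age, "juvenile", "adult"),
        )
        return out.astype(object)


def make_founder_pool(
    n_loci: int,
    rng: np.random.Generator,
    theta: float = 20.0,
    pool_genes: int = 200,
) -> np.ndarray:
    """Founding gene pool: a coalescent SMM sample at the founding diversity.

    Returns a (n_loci, pool_genes) array of allele states; founder genotypes
    are drawn from it with replacement, per locus.  theta=20 gives the
    high-diversity source population (equilibrium He about 0.84).
    """
    ds = simulate_msat_dataset(MsatConfig(theta, n_loci, pool_genes), rng)
    return np.stack([ds.genes_at(l) for l in range(n_loci)], axis=0)


def init_population(
    n_groups: int,
    mating: MatingSystem,
    life: LifeHistory,
    founder_pool: np.ndarray | None,
    rng: np.random.Generator,
) -> Population:
    """Found every group with its full RS complement of adults.

    Founders are aged exactly at reproductive age and immediately eligible;
    their alleles are sampled with replacement from ``founder_pool``
    (per locus).  ``founder_pool=None`` disables genetics entirely.
    """
    if n_groups < 1:
        raise ValueError("n_groups must be >= 1")
    if founder_pool is not None:
        founder_pool = np.asarray(founder_pool)
        if founder_pool.ndim != 2 or founder_pool.shape[1] == 0:
            raise ValueError("founder pool must be a non-empty (n_loci, pool) array")
    n_loci = 0 if founder_pool is None else founder_pool.shape[0]
    pop = Population(n_groups, mating, life, n_loci=n_loci)
    qm, qf = mating.rs_males, mating.rs_females
    per_group = qm + qf
    n = n_groups * per_group
    slots = pop._alloc(n)
    pop.alive[slots] = True
    sex_pattern = np.concatenate([np.zeros(qm, dtype=bool), np.ones(qf, dtype=bool)])
    pop.female[slots] = np.tile(sex_pattern, n_groups)
    pop.age[slots] = life.reproductive_age
    pop.lifespan[slots] = pop.draw_lifespans(n, rng)
    pop.group[slots] = np.repeat(np.arange(n_groups, dtype=np.int32), per_group)
    pop.rs[slots] = True
    pop.last_birth[slots] = -life.birth_interval
    if founder_pool is not None:
        pool_size = founder_pool.shape[1]
        picks = rng.integers(0, pool_size, size=(n, n_loci, 2))
        pop.geno[slots] = founder_pool[
            np.arange(n_loci)[None, :, None], picks
        ].astype(np.int16)
    return pop


def apply_mortality(pop: Population, rng: np.random.Generator) -> None:
    """Kill every individual whose age exceeds its lifespan draw.

    Infant mortality is handled at birth inside :func:`reproduce` (weaning
    age is one tick, so at-birth application is equivalent).
    """
    top = pop._top
    dead = np.flatnonzero(
        pop.alive[:top] & (pop.age[:top] > pop.lifespan[:top])
    )
    if dead.size:
        pop.alive[dead] = False
        pop.rs[dead] = False
        nf = pop._n_free
        pop._free[nf : nf + dead.size] = dead
        pop._n_free = nf + dead.size


def reproduce(pop: Population, rng: np.random.Generator) -> int:
    """One synchronous reproduction sweep over all groups.

    Every eligible RS female (mature, past her birth interval, with at least
    one living RS male in her group) is assigned one RS male uniformly at
    random; litters are drawn per pair and thinned by infant survival.
    Offspring inherit one uniformly chosen allele per locus from each
    parent; each transmitted allele mutates +-1 with probability mu.
    Returns the number of surviving newborns.
    """
    top = pop._top
    alive = pop.alive[:top]
    rs = pop.rs[:top]
    fem = pop.female[:top]
    grp = pop.group[:top]
    age = pop.age[:top]
    life = pop.life

    rs_alive = alive & rs
    m_idx = np.flatnonzero(rs_alive & ~fem)
    if m_idx.size == 0:
        return 0
    f_idx = np.flatnonzero(rs_alive & fem)
    if f_idx.size == 0:
        return 0
    eligible = (age[f_idx] >= life.reproductive_age) & (
        pop.tick - pop.last_birth[f_idx] >= life.birth_interval
    )
    f_idx = f_idx[eligible]
    if f_idx.size == 0:
        return 0

    m_grp = grp[m_idx]
    order = np.argsort(m_grp, kind="stable")
    m_sorted = m_idx[order]
    counts = np.bincount(m_grp, minlength=pop.n_groups)
    offsets = np.concatenate(([0], np.cumsum(counts)))
    fg = grp[f_idx]
    c = counts[fg]
    with_male = c > 0
    f_idx = f_idx[with_male]
    if f_idx.size == 0:
        return 0
    fg = fg[with_male]
    c = c[with_male]
    fathers = m_sorted[offsets[fg] + (rng.random(f_idx.size) * c).astype(np.int64)]

    litters = pop.draw_litters(f_idx.size, rng)
    pop.last_birth[f_idx] = pop.tick  # the reproduction event resets the interval
    total = int(litters.sum())
    if total == 0:
        return 0
    moms = np.repeat(f_idx, litters)
    dads = np.repeat(fathers, litters)
    survive = rng.random(total) >= life.infant_mortality
    moms = moms[survive]
    dads = dads[survive]
    n_off = moms.size
    if n_off == 0:
        return 0

    mom_groups = grp[moms]
    slots = pop._alloc(n_off)
    pop.alive[slots] = True
    pop.female[slots] = rng.random(n_off) < 0.5
    pop.age[slots] = 0
    pop.lifespan[slots] = pop.draw_lifespans(n_off, rng)
    pop.group[slots] = mom_groups
    pop.rs[slots] = False
    pop.last_birth[slots] = _NEVER

    if pop.geno is not None:
        L = pop.n_loci
        pick = rng.integers(0, 2, size=(2, n_off, L, 1))
        mat = np.take_along_axis(pop.geno[moms], pick[0], axis=2)[:, :, 0]
        pat = np.take_along_axis(pop.geno[dads], pick[1], axis=2)[:, :, 0]
        if life.mu > 0.0:
            for gam in (pat, mat):
                mask = rng.random(gam.shape) < life.mu
                hits = int(mask.sum())
                if hits:
                    gam[mask] += (rng.integers(0, 2, size=hits) * 2 - 1).astype(np.int16)
        pop.geno[slots, :, 0] = pat
        pop.geno[slots, :, 1] = mat
    return n_off


def fill_vacancies(pop: Population, rng: np.random.Generator) -> None:
    """Fill open RS slots.

    Female vacancies are strictly philopatric: a uniform draw among the
    group's own non-RS adult females, or nothing.  Male vacancies are
    filled by migrants — a uniform draw among non-RS adult males living in
    *other* groups — but only into an *established* group, one that still
    holds at least one breeding (RS) female: males migrate to reproduce,
    and a group with no breeding female attracts no migrants.  A group
    that loses its female line therefore dies out and is eventually
    re-founded by colonization, rather than persisting as a sterile sink
    for migrant males.  Migrants change group membership; unfillable
    vacancies persist to later ticks.
    """
    top = pop._top
    alive = pop.alive[:top]
    rs = pop.rs[:top]
    fem = pop.female[:top]
    grp = pop.group[:top]
    adult = alive & ~rs & (pop.age[:top] >= pop.life.reproductive_age)

    rs_alive = alive & rs
    rsf = np.bincount(grp[rs_alive & fem], minlength=pop.n_groups)
    need_f = pop.quota_f - rsf
    groups_f = np.flatnonzero(need_f > 0)
    if groups_f.size:
        adf = adult & fem
        for g in groups_f:
            cand = np.flatnonzero(adf & (grp == g))
            k = min(int(need_f[g]), cand.size)
            if k:
                chosen = rng.choice(cand, size=k, replace=False)
                pop.rs[chosen] = True
                rsf[g] += k

    rsm = np.bincount(grp[rs_alive & ~fem], minlength=pop.n_groups)
    need_m = pop.quota_m - rsm
    groups_m = np.flatnonzero((need_m > 0) & (rsf > 0))
    if groups_m.size:
        adm = adult & ~fem
        for g in groups_m:
            cand = np.flatnonzero(adm & (grp != g))
            k = min(int(need_m[g]), cand.size)
            if k:
                chosen = rng.choice(cand, size=k, replace=False)
                pop.rs[chosen] = True
                pop.group[chosen] = g
                adm[chosen] = False


def colonize(pop: Population, rng: np.random.Generator) -> None:
    """Re-found vanished (empty) groups.

    A full RS complement is drawn uniformly from all non-RS adults
    population-wide (both sexes, any group — colonization overrides female
    philopatry).  Re-founding is deferred while candidates of either sex are
    insufficient.
    """
    top = pop._top
    alive = pop.alive[:top]
    members = np.bincount(pop.group[:top][alive], minlength=pop.n_groups)
    empty = np.flatnonzero(members == 0)
    if empty.size == 0:
        return
    grp = pop.group[:top]
    fem = pop.female[:top]
    adult = alive & ~pop.rs[:top] & (pop.age[:top] >= pop.life.reproductive_age)
    for g in empty:
        cand_m = np.flatnonzero(adult & ~fem)
        cand_f = np.flatnonzero(adult & fem)
        if cand_m.size < pop.quota_m or cand_f.size < pop.quota_f:
            continue
        cm = rng.choice(cand_m, size=pop.quota_m, replace=False)
        cf = rng.choice(cand_f, size=pop.quota_f, replace=False)
        sel = np.concatenate([cm, cf])
        pop.group[sel] = g
        pop.rs[sel] = True
        adult[sel] = False


def advance_tick(pop: Population, rng: np.random.Generator, fast: bool | None = None) -> None:
    """Apply one tick: aging, mortality, reproduction, migration, colonization.

    ``fast`` selects the compiled single-pass kernel (default whenever numba
    is importable); ``fast=False`` runs the numpy reference composition of
    :func:`apply_mortality`, :func:`reproduce`, :func:`fill_vacancies` and
    :func:`colonize`.  Both paths implement identical event rules.
    """
    from . import _kernels

    if fast is None:
        fast = _kernels.HAVE_NUMBA
    if not fast:
        pop.age[: pop._top] += 1
        apply_mortality(pop, rng)
        reproduce(pop, rng)
        fill_vacancies(pop, rng)
        colonize(pop, rng)
        pop.tick += 1
        return

    life = pop.life
    # worst-case births this tick: every RS female litters at the cap
    max_births = pop.n_groups * pop.quota_f * (life.offspring_mean + 2)
    if pop._top + max_births > pop._cap:
        pop._grow(max_births)
    geno = pop.geno
    if geno is None:
        geno = _EMPTY_GENO
    meta = pop._meta
    meta[0] = pop._top
    meta[1] = pop._n_free
    meta[2] = pop.tick
    mu = life.mu
    log1m_mu = float(np.log1p(-mu)) if mu > 0.0 else 0.0
    _kernels.social_tick(
        meta,
        pop.alive,
        pop.female,
        pop.age,
        pop.lifespan,
        pop.group,
        pop.rs,
        pop.last_birth,
        geno,
        pop._free,
        pop._lifespan_cdf,
        pop._litter_cdf,
        pop.n_groups,
        pop.quota_m,
        pop.quota_f,
        life.reproductive_age,
        life.birth_interval,
        life.infant_mortality,
        log1m_mu,
        rng,
    )
    pop._top = int(meta[0])
    pop._n_free = int(meta[1])
    pop.tick = int(meta[2])


def genetic_summary(pop_or_dataset):
    """Per-locus unbiased gene diversity, mean allele number, and FST.

    FST = (HT - HS) / HT with HS the unweighted mean within-group diversity
    and HT the pooled diversity, both averaged over loci before taking the
    ratio; defined as 0 when HT = 0.
    """
    if isinstance(pop_or_dataset, Population):
        pop = pop_or_dataset
        if pop.geno is None:
            raise ValueError("population carries no genotypes")
        idx = pop.living_indices()
        if idx.size == 0:
            raise ValueError("empty population has no genetic summary")
        geno = pop.geno[idx]
        groups = pop.group[idx]
    else:
        ds = pop_or_dataset
        if ds.n_individuals == 0:
            raise ValueError("empty dataset has no genetic summary")
        geno = ds.genotypes
        groups = None if ds.groups is None else np.asarray(ds.groups)

    n_loci = geno.shape[1]
    he = np.empty(n_loci)
    n_alleles = np.empty(n_loci)
    for l in range(n_loci):
        _, counts = np.unique(geno[:, l, :], return_counts=True)
        he[l] = unbiased_gene_diversity(counts)
        n_alleles[l] = counts.size

    fst = 0.0
    if groups is not None:
        hs = np.zeros(n_loci)
        gids = np.unique(groups)
        for g in gids:
            sub = geno[groups == g]
            for l in range(n_loci):
                _, counts = np.unique(sub[:, l, :], return_counts=True)
                hs[l] += unbiased_gene_diversity(counts)
        hs /= gids.size
        ht_bar = float(he.mean())
        hs_bar = float(hs.mean())
        fst = 0.0 if ht_bar <= 0.0 else (ht_bar - hs_bar) / ht_bar
    return he, float(n_alleles.mean()), fst


def run(
    pop: Population,
    n_ticks: int,
    record_every: int,
    rng: np.random.Generator,
    record_genetics: bool | None = None,
    fast: bool | None = None,
) -> SimRecord:
    """Advance ``n_ticks`` ticks, recording summaries every ``record_every``.

    The initial state is always recorded.  If the population goes extinct
    the record is truncated and flagged.
    """
    if n_ticks < 1:
        raise ValueError("n_ticks must be >= 1")
    if record_genetics is None:
        record_genetics = pop.geno is not None

    rows = []

    def snapshot():
        census = pop.census()
        mean_he = mean_k = fst = np.nan
        if record_genetics and census > 0:
            he, mean_k, fst = genetic_summary(pop)
            mean_he = float(he.mean())
        rows.append((pop.tick, census, pop.n_rs(), mean_he, mean_k, fst))

    snapshot()
    extinct = False
    for t in range(1, n_ticks + 1):
        advance_tick(pop, rng, fast=fast)
        if pop.census() == 0:
            extinct = True
            snapshot()
            break
        if t % record_every == 0:
            snapshot()
    table = pd.DataFrame(
        rows,
        columns=["tick", "census_size", "n_rs", "mean_he", "mean_allele_number", "fst"],
    )
    return SimRecord(table=table, extinct=extinct)
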