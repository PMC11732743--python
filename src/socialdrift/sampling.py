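"""Sampling schemes over simulated populations and GENEPOP interchange.

Sampling mirrors field practice for social species: individuals are taken
from the population alive at the final tick, among offspring, juveniles, RS
individuals and non-RS females.  Non-RS adult males are never sampled — in a
real population they would be dispersing floaters not attached to any group.

Three schemes are implemented:

``RANDOM_POOL``
    n individuals drawn uniformly from the eligible members of a randomly
    chosen pool of ``pool_size`` groups (e.g. 30 groups out of 50).
``SMALL_POOL``
    the same with a pool of five groups (localized sampling).
``ONE_PER_GROUP``
    n distinct groups, one eligible individual each (kin avoidance).

GENEPOP files use the classic dialect: title line, one locus name per line,
a single ``Pop`` block and 3-digit allele codes.  Internal (root-relative,
possibly negative) repeat states are shifted by a fixed documented offset
into 001..999; the offset and ploidy are recorded on the title line so a
round trip is lossless.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .dataset import GenotypeDataset
from .social import Population

__all__ = [
    "SchemeKind",
    "SamplingScheme",
    "SamplingError",
    "GenepopExportError",
    "draw_sample",
    "write_genepop",
    "read_genepop",
]

DEFAULT_OFFSET = 100


class SchemeKind(str, Enum):
    RANDOM_POOL = "random_pool"
    ONE_PER_GROUP = "one_per_group"
    SMALL_POOL = "small_pool"


@dataclass(frozen=True)
class SamplingScheme:
    kind: SchemeKind
    n_individuals: int
    pool_size: int | None = None  # groups the sample may come from

    def __post_init__(self):
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if self.kind is SchemeKind.SMALL_POOL:
            object.__setattr__(self, "pool_size", 5)
        if self.kind is SchemeKind.RANDOM_POOL and self.pool_size is None:
            raise ValueError("RANDOM_POOL needs pool_size")


class SamplingError(RuntimeError):
    """Raised when a scheme's constraints cannot be met, naming the constraint."""


class GenepopExportError(ValueError):
    """Raised when an allele code falls outside 001..999 after the offset."""


def _eligible_indices(pop: Population) -> np.ndarray:
    """Living individuals that may be sampled (no non-RS adult males)."""
    top = pop._top
    alive = pop.alive[:top]
    adult_male_non_rs = (
        ~pop.female[:top]
        & ~pop.rs[:top]
        & (pop.age[:top] >= pop.life.reproductive_age)
    )
    return np.flatnonzero(alive & ~adult_male_non_rs)


def _class_labels(pop: Population, idx: np.ndarray) -> list[str]:
    stages = pop.stage_of(idx)
    rs = pop.rs[idx]
    return [("RS" if r else str(s)) for s, r in zip(stages, rs)]


def draw_sample(
    pop: Population, scheme: SamplingScheme, rng: np.random.Generator
) -> GenotypeDataset:
    """Draw one sample from the current population state.

    Individuals are drawn uniformly without replacement subject to the
    scheme's group constraints; ``ONE_PER_GROUP`` guarantees distinct
    groups.  Raises :class:`SamplingError` on any shortfall.
    """
    if pop.geno is None:
        raise SamplingError("population carries no genotypes to sample")
    elig = _eligible_indices(pop)
    if elig.size == 0:
        raise SamplingError("no eligible individuals alive at the final tick")
    groups_of = pop.group[elig]
    n = scheme.n_individuals

    if scheme.kind is SchemeKind.ONE_PER_GROUP:
        gids = np.unique(groups_of)
        if gids.size < n:
            raise SamplingError(
                f"one-per-group needs {n} groups with eligible members, "
                f"only {gids.size} available"
            )
        chosen_groups = rng.choice(gids, size=n, replace=False)
        picks = []
        for g in chosen_groups:
            members = elig[groups_of == g]
            picks.append(members[rng.integers(members.size)])
        picks = np.array(picks)
    else:
        pool_size = scheme.pool_size
        gids = np.unique(pop.group[pop.living_indices()])
        if gids.size < pool_size:
            raise SamplingError(
                f"pool of {pool_size} groups requested, only {gids.size} "
                "non-empty groups exist"
            )
        pool = rng.choice(gids, size=pool_size, replace=False)
        in_pool = elig[np.isin(groups_of, pool)]
        if in_pool.size < n:
            raise SamplingError(
                f"{n} individuals requested from a pool of {pool_size} groups "
                f"holding only {in_pool.size} eligible individuals"
            )
        picks = rng.choice(in_pool, size=n, replace=False)

    geno = pop.geno[picks].astype(np.int64)
    return GenotypeDataset(
        geno,
        individual_ids=[f"ind_{int(i)}" for i in picks],
        groups=pop.group[picks].copy(),
        classes=_class_labels(pop, picks),
    )


# ---------------------------------------------------------------------------
# GENEPOP dialect
# ---------------------------------------------------------------------------


def write_genepop(dataset: GenotypeDataset, destination, offset: int = DEFAULT_OFFSET, title: str | None = None) -> None:
    """Write a dataset as a GENEPOP file (3-digit allele codes).

    Haploid data are coded as homozygous diploids, which is noted on the
    title line together with the offset so :func:`read_genepop` can restore
    the dataset exactly.
    """
    g = dataset.genotypes
    lo = int(g.min()) + offset
    hi = int(g.max()) + offset
    if lo < 1 or hi > 999:
        raise GenepopExportError(
            f"allele codes {lo}..{hi} outside 001..999; re-export with an "
            f"offset in [{1 - int(g.min())}, {999 - int(g.max())}]"
        )
    if title is None:
        title = "socialdrift genotypes"
    header = f"{title} | ploidy={dataset.ploidy} offset={offset}"
    lines = [header]
    lines.extend(dataset.locus_names)
    lines.append("Pop")
    for i in range(dataset.n_individuals):
        codes = []
        for l in range(dataset.n_loci):
            alleles = dataset.genotypes[i, l, :]
            if dataset.ploidy == 1:
                a = alleles[0] + offset
                codes.append(f"{a:03d}{a:03d}")
            else:
                codes.append(f"{alleles[0] + offset:03d}{alleles[1] + offset:03d}")
        lines.append(f"{dataset.individual_ids[i]} ,  " + " ".join(codes))
    text = "\n".join(lines) + "\n"
    if hasattr(destination, "write"):
        destination.write(text)
    else:
        with open(destination, "w") as fh:
            fh.write(text)


def read_genepop(source) -> GenotypeDataset:
    """Read a GENEPOP file written by :func:`write_genepop`.

    Also accepts plain third-party single-``Pop`` GENEPOP files with 3-digit
    diploid codes (then ploidy=2 and offset=0 are assumed).
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source) as fh:
            text = fh.read()
    lines = [ln.rstrip("\n") for ln in io.StringIO(text) if ln.strip()]
    header = lines[0]
    ploidy, offset = 2, 0
    if "|" in header:
        for token in header.split("|")[-1].split():
            if token.startswith("ploidy="):
                ploidy = int(token.split("=")[1])
            elif token.startswith("offset="):
                offset = int(token.split("=")[1])
    loci = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        # locus names may also be comma-separated on one line
        loci.extend([t.strip() for t in lines[i].split(",") if t.strip()])
        i += 1
    if i == len(lines):
        raise ValueError("no 'Pop' line found; not a GENEPOP file")
    i += 1
    ids, rows = [], []
    for ln in lines[i:]:
        if ln.strip().lower() == "pop":
            raise ValueError("multiple Pop blocks are not supported")
        name, _, geno_part = ln.partition(",")
        ids.append(name.strip())
        codes = geno_part.split()
        if len(codes) != len(loci):
            raise ValueError(
                f"individual {name.strip()!r} has {len(codes)} genotypes "
                f"for {len(loci)} loci"
            )
        row = []
        for code in codes:
            if len(code) != 6:
                raise ValueError(f"expected 6-digit diploid code, got {code!r}")
            a, b = int(code[:3]) - offset, int(code[3:]) - offset
            row.append((a, b))
        rows.append(row)
    arr = np.array(rows, dtype=np.int64)  # (n, L, 2)
    if ploidy == 1:
        if not np.all(arr[:, :, 0] == arr[:, :, 1]):
            raise ValueError("haploid-coded file contains heterozygous codes")
        arr = arr[:, :, :1]
    return GenotypeDataset(arr, locus_names=loci, individual_ids=ids)
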