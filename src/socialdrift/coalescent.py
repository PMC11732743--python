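"""Kingman coalescent generator of microsatellite data under the strict
stepwise mutation model (SMM).

Time is measured in units of 4N generations, so with k ancestral lineages the
next coalescence is exponential with rate k(k-1) and mutations fall on a
genealogy as a Poisson process of rate ``theta`` per unit branch length
(theta = 4*N*mu per locus).  Allele states are repeat counts relative to the
root, coded 0 at the root; each mutation shifts a lineage by +1 or -1 with
equal probability.

Besides the unconditional generator the module provides the
conditional-on-allele-number equilibrium heterozygosity simulator used by the
mutation-drift-equilibrium test: mutations are added to a fresh genealogy one
at a time (uniformly on the tree, probability proportional to branch length)
until the sample carries exactly k distinct alleles.  Because the SMM is
homoplasic the allele count is not monotone in the mutation count, and two
stopping rules are provided: ``first_passage`` (stop the instant the count
first equals k; the k-th allele is then typically young and rare, so the
retained configurations are uneven) and ``last_exit`` (keep mutating and
retain the last k-allele configuration before the count first exceeds k, so
homoplasy has equilibrated the configuration at that allele number).  The
default is ``last_exit``, which reproduces the behavior of the standard
heterozygosity-test software, including its documented mild expansion bias
on stationary data; a replicate that fails within a mutation cap is
discarded and redrawn.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import GenotypeDataset, unbiased_gene_diversity

__all__ = [
    "GeneTree",
    "MsatConfig",
    "simulate_genealogy",
    "drop_smm_mutations",
    "expected_he_smm",
    "simulate_msat_dataset",
    "heq_conditional",
    "conditional_allele_states",
]


@dataclass
class GeneTree:
    """Coalescent genealogy of ``n_leaves`` gene copies.

    Nodes 0..n-1 are leaves (depth 0); nodes n..2n-2 are internal, indexed
    in coalescence order, the last one being the root (a child therefore
    always has a smaller index than its parent).  ``branch_length[v]`` is
    the time (4N units) from node v to its parent; 0 for the root.
    """

    n_leaves: int
    parent: np.ndarray
    branch_length: np.ndarray
    node_time: np.ndarray

    @property
    def total_length(self) -> float:
        return float(self.branch_length.sum())

    @property
    def n_nodes(self) -> int:
        return 2 * self.n_leaves - 1

    @property
    def leaf_sets(self) -> np.ndarray:
        """(n_nodes, n_leaves) boolean incidence matrix, built on demand."""
        if getattr(self, "_leaf_sets", None) is None:
            n = self.n_leaves
            ls = np.zeros((self.n_nodes, n), dtype=bool)
            ls[np.arange(n), np.arange(n)] = True
            for v in range(self.n_nodes - 1):  # children precede parents
                if self.parent[v] >= 0:
                    ls[self.parent[v]] |= ls[v]
            self._leaf_sets = ls
        return self._leaf_sets


@dataclass
class MsatConfig:
    """Scenario for one coalescent microsatellite dataset.

    theta: scaled mutation parameter 4*N*mu per locus (dimensionless).
    """

    theta: float
    n_loci: int
    n_genes: int

    def __post_init__(self):
        if self.theta < 0:
            raise ValueError("theta must be >= 0")
        if self.n_genes < 2:
            raise ValueError("n_genes must be >= 2")
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")


def simulate_genealogy(n_genes: int, rng: np.random.Generator) -> GeneTree:
    """Draw one Kingman genealogy for ``n_genes`` gene copies.

    While k lineages remain the waiting time is Exp(rate k(k-1)) in
    4N-generation units and the coalescing pair is uniform over pairs.
    """
    n = int(n_genes)
    if n < 2:
        raise ValueError("n_genes must be >= 2")
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.int32)
    node_time = np.zeros(n_nodes)

    ks = np.arange(n, 1, -1, dtype=float)
    waits = rng.exponential(1.0 / (ks * (ks - 1.0)))
    u = rng.random((n - 1, 2))

    active = list(range(n))
    t = 0.0
    for step in range(n - 1):
        k = n - step
        t += waits[step]
        i = int(u[step, 0] * k)
        a = active[i]
        active[i] = active[-1]
        active.pop()
        j = int(u[step, 1] * (k - 1))
        b = active[j]
        new = n + step
        active[j] = new
        parent[a] = new
        parent[b] = new
        node_time[new] = t
    branch_length = np.zeros(n_nodes)
    has_parent = parent >= 0
    branch_length[has_parent] = node_time[parent[has_parent]] - node_time[has_parent]
    return GeneTree(n, parent, branch_length, node_time)


def drop_smm_mutations(
    tree: GeneTree,
    theta: float,
    rng: np.random.Generator,
    return_count: bool = False,
):
    """Superimpose SMM mutations on a genealogy.

    The mutation count on each branch is Poisson(theta * length); each
    mutation shifts all subtended leaves by +-1 with equal probability.
    Returns the leaf allele states (root state 0), and optionally the total
    number of mutations.
    """
    if theta < 0:
        raise ValueError("theta must be >= 0")
    muts = rng.poisson(theta * tree.branch_length)
    total = int(muts.sum())
    states = np.zeros(tree.n_leaves, dtype=np.int64)
    if total:
        # net displacement per branch (sum of fair +-1 steps), cascaded
        # from the root down: a child's displacement adds its ancestors'.
        disp = np.zeros(tree.n_nodes, dtype=np.int64)
        hit = np.flatnonzero(muts)
        disp[hit] = 2 * rng.binomial(muts[hit], 0.5) - muts[hit]
        parent = tree.parent
        for v in range(tree.n_nodes - 2, -1, -1):  # parents precede children
            disp[v] += disp[parent[v]]
        states = disp[: tree.n_leaves].copy()
    if return_count:
        return states, total
    return states


def expected_he_smm(theta: float) -> float:
    """Equilibrium gene diversity of a strict-SMM locus: 1 - 1/sqrt(1+2*theta)."""
    if theta < 0:
        raise ValueError("theta must be >= 0")
    return 1.0 - 1.0 / np.sqrt(1.0 + 2.0 * theta)


def simulate_msat_dataset(
    config: MsatConfig, rng: np.random.Generator, ploidy: int = 1
) -> GenotypeDataset:
    """Simulate ``n_loci`` independent SMM loci for one sample.

    With ``ploidy=2`` gene copies are paired into diploid individuals in
    input order (exchangeable, so the pairing carries no information).
    """
    genes = np.empty((config.n_loci, config.n_genes), dtype=np.int64)
    for l in range(config.n_loci):
        tree = simulate_genealogy(config.n_genes, rng)
        genes[l] = drop_smm_mutations(tree, config.theta, rng)
    return GenotypeDataset.from_gene_matrix(genes, ploidy=ploidy)


def _conditional_walk_states(
    tree: GeneTree, k_target: int, rng: np.random.Generator, cap: int, rule: str
):
    """Mutation walk on one genealogy, conditioned on the allele number.

    ``rule='first_passage'`` stops the first time the sample shows k
    alleles; ``rule='last_exit'`` keeps mutating and retains the last
    k-allele configuration seen before the count first exceeds k.
    Returns the leaf states, or None if the walk failed within the cap
    (caller redraws)."""
    n = tree.n_leaves
    states = np.zeros(n, dtype=np.int64)
    if k_target == 1:
        return states
    cum = np.cumsum(tree.branch_length)
    total = cum[-1]
    leaf_idx = {}
    kept = None
    n_mut = 0
    while n_mut < cap:
        # draw randoms in blocks to cut per-mutation overhead
        block = min(64, cap - n_mut)
        us = rng.random(block)
        steps = rng.integers(0, 2, size=block) * 2 - 1
        for m in range(block):
            b = int(np.searchsorted(cum, us[m] * total, side="right"))
            idx = leaf_idx.get(b)
            if idx is None:
                idx = np.flatnonzero(tree.leaf_sets[b])
                leaf_idx[b] = idx
            states[idx] += steps[m]
            n_mut += 1
            k = np.unique(states).size
            if rule == "first_passage":
                if k == k_target:
                    return states
            else:
                if k == k_target:
                    kept = states.copy()
                elif k > k_target and kept is not None:
                    return kept
    return kept


DEFAULT_RULE = "last_exit"


def conditional_allele_states(
    n_genes: int,
    k_alleles: int,
    rng: np.random.Generator,
    max_mutations: int | None = None,
    rule: str = DEFAULT_RULE,
) -> np.ndarray:
    """One sample of allele states conditional on the allele number.

    Simulates a fresh genealogy and applies the conditional mutation rule
    described in the module docstring.  The cap defaults to 50 * n_genes
    mutations; on a cap hit the genealogy is redrawn.
    """
    if not 1 <= k_alleles <= n_genes:
        raise ValueError("need 1 <= k_alleles <= n_genes")
    if rule not in ("first_passage", "last_exit"):
        raise ValueError("rule must be 'first_passage' or 'last_exit'")
    cap = 50 * n_genes if max_mutations is None else int(max_mutations)
    while True:
        tree = simulate_genealogy(n_genes, rng)
        states = _conditional_walk_states(tree, k_alleles, rng, cap, rule)
        if states is not None:
            return states


def heq_conditional(
    n_genes: int,
    k_alleles: int,
    n_reps: int,
    rng: np.random.Generator,
    max_mutations: int | None = None,
    rule: str = DEFAULT_RULE,
    fast: bool | None = None,
) -> np.ndarray:
    """Equilibrium-heterozygosity distribution given the allele number.

    Returns ``n_reps`` draws of the unbiased gene diversity of SMM samples
    of ``n_genes`` gene copies carrying exactly ``k_alleles`` alleles.
    ``fast`` selects the compiled batch kernel (default when numba is
    available); both paths implement identical conditional rules.
    """
    from . import _kernels

    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if not 1 <= k_alleles <= n_genes:
        raise ValueError("need 1 <= k_alleles <= n_genes")
    if rule not in ("first_passage", "last_exit"):
        raise ValueError("rule must be 'first_passage' or 'last_exit'")
    cap = 50 * n_genes if max_mutations is None else int(max_mutations)
    if fast is None:
        fast = _kernels.HAVE_NUMBA
    if fast:
        return _kernels.conditional_heq_batch(
            n_genes, k_alleles, n_reps, cap, 0 if rule == "first_passage" else 1, rng
        )
    out = np.empty(n_reps)
    for r in range(n_reps):
        states = conditional_allele_states(n_genes, k_alleles, rng, cap, rule)
        _, counts = np.unique(states, return_counts=True)
        out[r] = unbiased_gene_diversity(counts)
    return out
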