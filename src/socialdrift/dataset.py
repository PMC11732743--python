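"""Shared genotype container.

``GenotypeDataset`` is the interchange object between the three data
generators (coalescent, Wright-Fisher forward, social-group forward) and the
two inference stages (mutation-drift-equilibrium test, LD-based Ne).  Alleles
are microsatellite repeat counts stored as plain integers relative to an
arbitrary root state; a fixed positive offset is applied only at GENEPOP
export time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GenotypeDataset", "unbiased_gene_diversity"]


def unbiased_gene_diversity(counts) -> float:
    """Nei's unbiased gene diversity n/(n-1) * (1 - sum p_i^2).

    ``counts`` are allele copy numbers (any order, zeros allowed).
    Requires at least two gene copies in total.
    """
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    if n < 2:
        raise ValueError("gene diversity needs at least 2 gene copies")
    p = counts / n
    return float(n / (n - 1.0) * (1.0 - np.sum(p * p)))


@dataclass
class GenotypeDataset:
    """Individuals x loci x ploidy integer repeat-count states.

    genotypes
        int array of shape ``(n_individuals, n_loci, ploidy)``.
    groups
        optional per-individual source group id.
    classes
        optional per-individual life-stage label
        (``offspring``/``juvenile``/``adult``/``RS``).
    """

    genotypes: np.ndarray
    locus_names: list[str] = field(default_factory=list)
    individual_ids: list[str] = field(default_factory=list)
    groups: np.ndarray | None = None
    classes: list[str] | None = None

    def __post_init__(self):
        g = np.asarray(self.genotypes)
        if g.ndim != 3:
            raise ValueError("genotypes must be (individuals, loci, ploidy)")
        if g.shape[2] not in (1, 2):
            raise ValueError("ploidy must be 1 or 2")
        self.genotypes = g
        if not self.locus_names:
            self.locus_names = [f"locus_{i + 1}" for i in range(g.shape[1])]
        if not self.individual_ids:
            self.individual_ids = [f"ind_{i + 1}" for i in range(g.shape[0])]

    # -- shape ------------------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]

    @property
    def ploidy(self) -> int:
        return self.genotypes.shape[2]

    @property
    def n_genes(self) -> int:
        return self.n_individuals * self.ploidy

    # -- construction ------------------------------------------------------
    @classmethod
    def from_gene_matrix(cls, genes: np.ndarray, ploidy: int = 1, **kw) -> "GenotypeDataset":
        """Build from a (n_loci, n_genes) matrix of gene copies.

        For ``ploidy=2`` consecutive gene copies are paired into individuals
        in input order (pairing is arbitrary and never affects allele-count
        based statistics).
        """
        genes = np.asarray(genes)
        n_loci, n_genes = genes.shape
        if n_genes % ploidy:
            raise ValueError("n_genes not divisible by ploidy")
        n_ind = n_genes // ploidy
        g = genes.T.reshape(n_ind, ploidy, n_loci).transpose(0, 2, 1)
        return cls(np.ascontiguousarray(g), **kw)

    # -- per-locus views ---------------------------------------------------
    def genes_at(self, locus: int) -> np.ndarray:
        """All gene copies at one locus, flattened over individuals."""
        return self.genotypes[:, locus, :].ravel()

    def allele_counts(self, locus: int) -> np.ndarray:
        _, counts = np.unique(self.genes_at(locus), return_counts=True)
        return counts

    def n_alleles(self, locus: int) -> int:
        return int(np.unique(self.genes_at(locus)).size)

    def he(self, locus: int) -> float:
        return unbiased_gene_diversity(self.allele_counts(locus))

    def mean_he(self) -> float:
        return float(np.mean([self.he(l) for l in range(self.n_loci)]))

    def mean_allele_number(self) -> float:
        return float(np.mean([self.n_alleles(l) for l in range(self.n_loci)]))

    def subset(self, individuals=None, loci=None) -> "GenotypeDataset":
        ind = np.arange(self.n_individuals) if individuals is None else np.asarray(individuals)
        loc = np.arange(self.n_loci) if loci is None else np.asarray(loci)
        return GenotypeDataset(
            self.genotypes[np.ix_(ind, loc)],
            locus_names=[self.locus_names[i] for i in loc],
            individual_ids=[self.individual_ids[i] for i in ind],
            groups=None if self.groups is None else np.asarray(self.groups)[ind],
            classes=None if self.classes is None else [self.classes[i] for i in ind],
        )
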