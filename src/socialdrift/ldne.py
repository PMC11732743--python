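"""Contemporary Ne from linkage disequilibrium between unlinked loci.

For every pair of loci and every pair of (retained) alleles, the Burrows
composite disequilibrium is estimated from unphased diploid genotypes,

    Delta_hat = S/(S-1) * ( mean(X*Y)/2 - 2*pA*pB ),

with X, Y the per-individual allele copy counts (0/1/2) — i.e. half the
unbiased sample covariance of X and Y ("Weir's unbiased estimator").  It is
standardized into the composite correlation

    r^2 = Delta_hat^2 / [ (pA(1-pA) + D_A) (pB(1-pB) + D_B) ],

where D_A = P_AA - pA^2 is the within-locus Hardy-Weinberg departure
(Var(X)/2 = pA(1-pA) + D_A, so this is a true squared correlation of the
copy counts).  r^2 is averaged with unit weight over all allele-pair
comparisons of all locus pairs.

The mean r^2 contains a sampling component that depends only on the number
S of sampled individuals; subtracting it leaves the drift signal r2_drift,
which is inverted for Ne under either a random-mating or a lifetime-
monogamy drift expectation.  All regression constants of the corrections
are pinned in ``BIAS_CORRECTIONS`` below.  Alleles observed as a single
copy are excluded by default (rare alleles disproportionately inflate
r^2); a non-positive r2_drift yields an infinite, flagged estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .dataset import GenotypeDataset

__all__ = [
    "LDNeConfig",
    "LDNeEstimate",
    "BIAS_CORRECTIONS",
    "filter_singletons",
    "pairwise_r2",
    "estimate_ne",
    "solve_ne",
    "expected_r2_sample",
]

# One table for every numeric constant of the sampling-bias corrections and
# the drift-equation inversions (the empirical small-sample regressions of
# the LD method, as shipped in standard LD-Ne software).  Keyed by
# (mating_model, size_regime):
#   E[r2_sample] = c0 + c1/S + c2/S^2
#   Ne_hat       = (a + sqrt(a^2 - b * r2_drift)) / (2 * r2_drift)
# (the discriminant is clamped at 0; it only goes negative for Ne of a few)
BIAS_CORRECTIONS = {
    ("random", "large"): {"sample": (0.0, 1.0, 3.19), "solve": (1.0 / 3.0, 2.76)},
    ("random", "small"): {"sample": (0.0018, 0.907, 4.44), "solve": (0.308, 2.08)},
    ("monogamy", "large"): {"sample": (0.0, 1.0, 3.19), "solve": (2.0 / 3.0, 7.2)},
    ("monogamy", "small"): {"sample": (0.0018, 0.907, 4.44), "solve": (0.618, 5.24)},
}
_LARGE_S = 30  # the two empirical regimes split at S = 30 individuals


@dataclass(frozen=True)
class LDNeConfig:
    mating_model: str = "random"  # 'random' or 'monogamy'
    exclude_singletons: bool = True

    def __post_init__(self):
        if self.mating_model not in ("random", "monogamy"):
            raise ValueError("mating_model must be 'random' or 'monogamy'")


@dataclass
class LDNeEstimate:
    """Point estimate with its ingredients.

    ``ne_point`` is ``inf`` (and ``infinite`` True) when the bias-corrected
    drift signal is non-positive — the data carry no detectable drift LD at
    this sample size.
    """

    mean_r2: float
    expected_r2_sample: float
    r2_drift: float
    ne_point: float
    n_comparisons: int
    harmonic_mean_s: float
    mating_model: str
    infinite: bool


class FilteredDataset(NamedTuple):
    """Dataset plus the per-locus retained alleles after screening."""

    dataset: GenotypeDataset
    retained: list[np.ndarray]  # allele states kept, per original locus
    kept_loci: np.ndarray  # indices of loci with >= 2 retained alleles


def filter_singletons(dataset: GenotypeDataset, min_copies: int = 2) -> FilteredDataset:
    """Exclude alleles observed fewer than ``min_copies`` times (default:
    singletons) from pairwise comparisons; drop loci left with < 2 alleles.

    Genotypes are not modified — excluded alleles simply contribute no
    comparisons (their copies still count toward sample frequencies).
    """
    retained = []
    kept = []
    for l in range(dataset.n_loci):
        values, counts = np.unique(dataset.genes_at(l), return_counts=True)
        keep = values[counts >= min_copies]
        retained.append(keep)
        if keep.size >= 2:
            kept.append(l)
    return FilteredDataset(dataset, retained, np.array(kept, dtype=int))


def _copy_counts(dataset: GenotypeDataset, locus: int, alleles: np.ndarray) -> np.ndarray:
    """(S, k) matrix of per-individual copy counts of each allele."""
    g = dataset.genotypes[:, locus, :]
    return (g[:, :, None] == alleles[None, None, :]).sum(axis=1).astype(float)


def pairwise_r2(
    dataset: GenotypeDataset,
    locus_i: int,
    locus_j: int,
    retained_i: np.ndarray | None = None,
    retained_j: np.ndarray | None = None,
) -> np.ndarray:
    """Burrows r^2 for every retained allele pair of two loci.

    Returns a flat array with one unit-weight comparison per allele pair.
    """
    if dataset.ploidy != 2:
        raise ValueError("the LD method needs unphased diploid genotypes")
    S = dataset.n_individuals
    if S < 2:
        raise ValueError("need at least 2 individuals")

    def _alleles(locus, retained):
        if retained is None:
            retained = np.unique(dataset.genes_at(locus))
        return np.asarray(retained)

    ai = _alleles(locus_i, retained_i)
    aj = _alleles(locus_j, retained_j)
    if ai.size < 2 or aj.size < 2:
        return np.empty(0)
    X = _copy_counts(dataset, locus_i, ai)  # (S, ki)
    Y = _copy_counts(dataset, locus_j, aj)  # (S, kj)
    pX = X.mean(axis=0) / 2.0
    pY = Y.mean(axis=0) / 2.0
    # Delta_hat = S/(S-1) * (mean(XY)/2 - 2 pA pB), all allele pairs at once
    cross = X.T @ Y / S  # (ki, kj) of mean(X*Y)
    delta = (S / (S - 1.0)) * (cross / 2.0 - 2.0 * np.outer(pX, pY))
    # composite-correlation denominators: Var(X)/2 = p(1-p) + D_hom
    dX = pX * (1.0 - pX) + (X == 2).mean(axis=0) - pX**2
    dY = pY * (1.0 - pY) + (Y == 2).mean(axis=0) - pY**2
    r2 = delta**2 / np.outer(dX, dY)
    return r2.ravel()


def expected_r2_sample(S: int, mating_model: str = "random") -> float:
    """Sampling component of mean r^2 for S diploid individuals."""
    regime = "large" if S >= _LARGE_S else "small"
    c0, c1, c2 = BIAS_CORRECTIONS[(mating_model, regime)]["sample"]
    return c0 + c1 / S + c2 / S**2


def solve_ne(r2_drift: float, S: int, mating_model: str = "random") -> float:
    """Invert the drift expectation of r^2 for Ne; inf when r2_drift <= 0."""
    if r2_drift <= 0.0:
        return float("inf")
    regime = "large" if S >= _LARGE_S else "small"
    a, b = BIAS_CORRECTIONS[(mating_model, regime)]["solve"]
    disc = max(a * a - b * r2_drift, 0.0)
    return (a + np.sqrt(disc)) / (2.0 * r2_drift)


def estimate_ne(dataset: GenotypeDataset, config: LDNeConfig | None = None) -> LDNeEstimate:
    """LD Ne estimate over all locus pairs of a diploid dataset.

    Simulated samples are complete (no missing genotypes), so every
    comparison rests on the same S individuals and the harmonic mean of S
    across comparisons equals S itself; it is reported for fidelity with
    the standard output of LD-based estimators.
    """
    if config is None:
        config = LDNeConfig()
    if config.exclude_singletons:
        filt = filter_singletons(dataset)
    else:
        filt = filter_singletons(dataset, min_copies=1)
    kept = filt.kept_loci
    if kept.size < 2:
        raise ValueError("need at least 2 polymorphic loci after screening")
    values = []
    for a in range(kept.size):
        for b in range(a + 1, kept.size):
            li, lj = kept[a], kept[b]
            values.append(
                pairwise_r2(dataset, li, lj, filt.retained[li], filt.retained[lj])
            )
    r2 = np.concatenate(values)
    S = dataset.n_individuals
    mean_r2 = float(r2.mean())
    exp_r2 = expected_r2_sample(S, config.mating_model)
    drift = mean_r2 - exp_r2
    ne = solve_ne(drift, S, config.mating_model)
    return LDNeEstimate(
        mean_r2=mean_r2,
        expected_r2_sample=exp_r2,
        r2_drift=drift,
        ne_point=float(ne),
        n_comparisons=int(r2.size),
        harmonic_mean_s=float(S),
        mating_model=config.mating_model,
        infinite=not np.isfinite(ne),
    )
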