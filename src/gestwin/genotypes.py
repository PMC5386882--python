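"""Diallelic genotype simulation under Hardy-Weinberg equilibrium (HWE).

Genotypes count copies of the minor allele (additive 0/1/2 coding) and the
minor allele is always the effect allele.  Loci are organised into *classes*:
every locus within a class shares the same minor allele frequency and effect
parameters, which keeps the parameter space of downstream model fitting small
while still allowing many loci.

Full-sibling genotype pairs are drawn from the exact 3x3 joint distribution
implied by random mating of HWE parents and Mendelian segregation of two
offspring.  Under additive coding this joint distribution has sibling
genotype covariance ``p*q`` (half the HWE genotypic variance ``2pq``), i.e. a
sibling correlation of 1/2.  Linkage disequilibrium, dominance and parental
genotypes are deliberately out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "CONSTANT",
    "VARYING",
    "GAMMA_SEARCH_BOUND",
    "LocusClass",
    "GenotypePairMatrix",
    "sibling_joint_table",
    "draw_sibling_genotype_pairs",
    "draw_independent_genotypes",
    "locus_labels",
    "write_genotype_matrix",
]

CONSTANT = "constant"
VARYING = "varying"

#: bound on |gamma| used when searching constant-effect classes
GAMMA_SEARCH_BOUND = 5.0


@dataclass(frozen=True)
class LocusClass:
    """One class of ``count`` identical susceptibility loci.

    Parameters
    ----------
    kind:
        ``"constant"`` for a locus whose allele multiplies the hazard by
        ``exp(gamma)`` uniformly across gestation, or ``"varying"`` for a
        locus whose per-allele log-hazard contribution follows a Gaussian
        window centred at gestational day ``mu`` with spread ``sigma`` and
        total mass ``gamma``.
    gamma:
        Dimensionless log-hazard effect size per allele copy.
    maf:
        Minor allele frequency, in ``(0, 0.5]``.
    count:
        Number of identical, independently segregating loci in the class.
    mu, sigma:
        Day of peak effect and spread (gestational days); required for
        varying classes, ignored for constant ones.
    """

    kind: str
    gamma: float
    maf: float
    count: int = 1
    mu: float | None = None
    sigma: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in (CONSTANT, VARYING):
            raise ValueError(f"kind must be {CONSTANT!r} or {VARYING!r}, got {self.kind!r}")
        if not 0.0 < self.maf <= 0.5:
            raise ValueError(f"maf must be in (0, 0.5], got {self.maf}")
        if int(self.count) != self.count or self.count < 1:
            raise ValueError(f"count must be a positive integer, got {self.count}")
        object.__setattr__(self, "count", int(self.count))
        if self.kind == VARYING:
            if self.mu is None or self.sigma is None:
                raise ValueError("varying-effect class requires mu and sigma")
            if self.sigma <= 0:
                raise ValueError(f"sigma must be > 0, got {self.sigma}")


@dataclass(frozen=True)
class GenotypePairMatrix:
    """Joint distribution of additive sibling genotypes at one locus.

    ``probs[i, j]`` is the probability that sibling 1 carries ``i`` and
    sibling 2 carries ``j`` copies of the minor allele.  The matrix is
    symmetric, sums to one, and has HWE marginals ``(q^2, 2pq, p^2)``.
    """

    probs: np.ndarray
    maf: float

    def validate(self, atol: float = 1e-12) -> None:
        p, q = self.maf, 1.0 - self.maf
        m = self.probs
        if m.shape != (3, 3):
            raise ValueError("probs must be 3x3")
        if np.any(m < -atol):
            raise ValueError("negative joint probability")
        if abs(m.sum() - 1.0) > atol:
            raise ValueError("joint probabilities do not sum to 1")
        if np.max(np.abs(m - m.T)) > atol:
            raise ValueError("joint table not symmetric")
        hwe = np.array([q * q, 2 * p * q, p * p])
        if np.max(np.abs(m.sum(axis=1) - hwe)) > atol:
            raise ValueError("marginals deviate from HWE frequencies")


def sibling_joint_table(p: float) -> GenotypePairMatrix:
    """Closed-form joint genotype distribution for a full-sibling pair.

    The nine entries follow from enumerating HWE parents and Mendelian
    transmission to two offspring; e.g. a (0, 2) pair requires two
    heterozygous parents (frequency ``2pq`` each) and the right homozygote
    at both crosses (probability 1/4 each), giving ``(pq/2)^2``.

    ``p = 0`` is accepted as the degenerate monomorphic case.
    """
    if not 0.0 <= p <= 0.5:
        raise ValueError(f"minor allele frequency must lie in [0, 0.5], got {p}")
    q = 1.0 - p
    probs = np.array(
        [
            [q * q * (q + p * p / 4), p * q * q * (1 - p / 2), (p * q / 2) ** 2],
            [p * q * q * (1 - p / 2), p * q * (1 + p * q), p * p * q * (1 - q / 2)],
            [(p * q / 2) ** 2, p * p * q * (1 - q / 2), p * p * (p + q * q / 4)],
        ]
    )
    return GenotypePairMatrix(probs=probs, maf=p)


def draw_sibling_genotype_pairs(
    p: float, n_pairs: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n_pairs`` i.i.d. sibling genotype pairs at a locus with MAF ``p``.

    Sampling is a single categorical draw over the nine cells of the joint
    table, which is distributionally identical to conditional sequential
    sampling.  Returns two int arrays ``(g1, g2)`` with values in {0, 1, 2}.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    table = sibling_joint_table(p)
    flat = table.probs.ravel()
    # inverse-CDF draw over the 9 cells (cheaper than rng.choice for big n)
    cells = np.searchsorted(np.cumsum(flat), rng.random(n_pairs), side="right")
    return (cells // 3).astype(np.int8), (cells % 3).astype(np.int8)


def draw_independent_genotypes(
    p: float, n_ind: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw genotypes of unrelated individuals from HWE ``(q^2, 2pq, p^2)``."""
    if n_ind < 1:
        raise ValueError("n_ind must be >= 1")
    if not 0.0 <= p <= 0.5:
        raise ValueError(f"minor allele frequency must lie in [0, 0.5], got {p}")
    q = 1.0 - p
    cdf = np.cumsum([q * q, 2 * p * q, p * p])
    return np.searchsorted(cdf, rng.random(n_ind), side="right").astype(np.int8)


def locus_labels(classes: Sequence[LocusClass]) -> list[str]:
    """Stable per-locus column labels, one per locus (classes expanded)."""
    labels = []
    for k, lc in enumerate(classes):
        for j in range(lc.count):
            labels.append(f"class{k + 1}_{lc.kind}_{j + 1}")
    return labels


def write_genotype_matrix(path, matrix: np.ndarray, classes: Sequence[LocusClass]) -> None:
    """Write a (individuals x loci) 0/1/2 matrix as TSV with locus headers."""
    labels = locus_labels(classes)
    if matrix.ndim != 2 or matrix.shape[1] != len(labels):
        raise ValueError("matrix columns do not match expanded locus count")
    header = "\t".join(labels)
    np.savetxt(path, matrix, fmt="%d", delimiter="\t", header=header, comments="")
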