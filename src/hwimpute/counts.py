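"""Genotype counts for a biallelic marker.

The triple (n_AA, n_AB, n_BB) is the atom every test in this package
consumes.  Allele A is the reference allele as labeled in the input (VCF
REF); all statistics are invariant to swapping the labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError

#: Integer coding of genotypes in sample-level vectors.
AA, AB, BB, MISSING = 0, 1, 2, -1

GENOTYPE_LABELS = ("AA", "AB", "BB")


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype counts (n_AA, n_AB, n_BB) at one biallelic marker."""

    n_AA: int
    n_AB: int
    n_BB: int

    def __post_init__(self) -> None:
        for name in ("n_AA", "n_AB", "n_BB"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise DomainError(f"{name} must be a non-negative integer, got {v!r}")
        if self.n == 0:
            raise DomainError("total sample size n must be >= 1")

    @property
    def n(self) -> int:
        """Total sample size."""
        return self.n_AA + self.n_AB + self.n_BB

    @property
    def n_A(self) -> int:
        """Count of A alleles, 2*n_AA + n_AB."""
        return 2 * self.n_AA + self.n_AB

    @property
    def n_B(self) -> int:
        """Count of B alleles, 2*n_BB + n_AB."""
        return 2 * self.n_BB + self.n_AB

    @property
    def p_A(self) -> float:
        return self.n_A / (2 * self.n)

    @property
    def p_B(self) -> float:
        return self.n_B / (2 * self.n)

    @property
    def p_m(self) -> float:
        """Minor allele frequency min(p_A, p_B)."""
        return min(self.p_A, self.p_B)

    @property
    def is_monomorphic(self) -> bool:
        return self.n_A == 0 or self.n_B == 0

    def swapped(self) -> "GenotypeCounts":
        """Counts with the A/B allele labels exchanged."""
        return GenotypeCounts(self.n_BB, self.n_AB, self.n_AA)

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.n_AA, self.n_AB, self.n_BB)

    @classmethod
    def from_genotypes(cls, genotypes: np.ndarray) -> "GenotypeCounts":
        """Count a genotype vector coded 0/1/2 with -1 (MISSING) ignored."""
        g = np.asarray(genotypes)
        return cls(
            int(np.sum(g == AA)),
            int(np.sum(g == AB)),
            int(np.sum(g == BB)),
        )
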