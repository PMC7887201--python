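"""Core domain types and per-individual statistics for trait introgression.

A diploid individual is represented as an ``L x 2`` binary matrix: rows are
marker loci, columns are the two homologous chromosome copies, and a 1 marks
the *desirable* allele at that position (the recurrent parent's allele in the
background, the donor's allele at the target loci).  Chromosome structure is
not stored on the genotype itself; it is encoded entirely in the
recombination-frequency vector, where an entry of exactly 0.5 marks a
chromosome boundary (free recombination).

Locus indices are 0-based throughout the library.  The on-disk formats
(see :mod:`introgress.io`) use 1-based indices, and the conversion happens
only at that boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

__all__ = [
    "Genotype",
    "RecombMap",
    "TargetSet",
    "STAGES",
    "recovery_percentage",
    "recovery_percentages",
    "is_positive",
    "positive_mask",
    "count_target_alleles",
]

#: Selection stages: "backcross" individuals need at least one desirable
#: allele per target locus, "selfed" individuals need both (homozygous).
STAGES = ("backcross", "selfed")


def _as_binary_array(values, name: str, dtype=np.uint8) -> np.ndarray:
    arr = np.asarray(values)
    if arr.size == 0:
        raise ValueError(f"{name} must be non-empty")
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{name} entries must all be 0 or 1")
    return np.ascontiguousarray(arr, dtype=dtype)


@dataclass(frozen=True, eq=False)
class Genotype:
    """A diploid genotype: ``L x 2`` binary matrix of allele desirability.

    Parameters
    ----------
    alleles
        Array-like of shape ``(L, 2)`` with entries in {0, 1}; column ``m``
        is chromosome copy ``m`` and 1 marks the desirable allele.
    """

    alleles: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.alleles)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError(
                f"alleles must have shape (L, 2) for a diploid; got {arr.shape}"
            )
        object.__setattr__(self, "alleles", _as_binary_array(arr, "alleles"))

    @property
    def L(self) -> int:
        """Number of marker loci."""
        return self.alleles.shape[0]

    @property
    def ploidy(self) -> int:
        return 2

    @property
    def is_homozygous(self) -> bool:
        return bool((self.alleles[:, 0] == self.alleles[:, 1]).all())

    def haplotype(self, copy: int = 0) -> np.ndarray:
        """Return chromosome copy ``copy`` (0 or 1) as a length-L vector."""
        return self.alleles[:, copy].copy()

    @classmethod
    def from_haplotypes(cls, first, second) -> "Genotype":
        return cls(np.column_stack([first, second]))

    @classmethod
    def homozygous(cls, haplotype) -> "Genotype":
        """Fully inbred genotype carrying ``haplotype`` on both copies."""
        return cls.from_haplotypes(haplotype, haplotype)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Genotype):
            return NotImplemented
        return np.array_equal(self.alleles, other.alleles)

    def __repr__(self) -> str:  # compact: full matrices are not informative
        return f"Genotype(L={self.L}, homozygous={self.is_homozygous})"


@dataclass(frozen=True, eq=False)
class RecombMap:
    """Recombination frequencies between adjacent loci.

    ``r[l]`` is the probability of a crossover switch between locus ``l`` and
    ``l + 1`` during meiosis; each entry lies in [0, 0.5] and entries equal to
    exactly 0.5 mark chromosome boundaries (unlinked neighbours).
    """

    r: np.ndarray

    def __post_init__(self) -> None:
        arr = np.ascontiguousarray(np.asarray(self.r, dtype=np.float64))
        if arr.ndim != 1 or arr.size < 1:
            raise ValueError("r must be a 1-d vector of length L-1 >= 1")
        if (arr < 0).any() or (arr > 0.5).any():
            raise ValueError("recombination frequencies must lie in [0, 0.5]")
        object.__setattr__(self, "r", arr)

    @property
    def n_intervals(self) -> int:
        return self.r.size

    @property
    def L(self) -> int:
        """Number of loci this map spans."""
        return self.r.size + 1

    @property
    def chromosome_boundaries(self) -> np.ndarray:
        """Interval indices whose frequency is exactly 0.5."""
        return np.flatnonzero(self.r == 0.5)

    @property
    def n_chromosomes(self) -> int:
        return int(self.chromosome_boundaries.size) + 1

    @classmethod
    def uniform(cls, L: int, value: float = 0.0) -> "RecombMap":
        """Constant map with ``L - 1`` intervals all equal to ``value``."""
        return cls(np.full(L - 1, float(value)))

    def __repr__(self) -> str:
        return f"RecombMap(L={self.L}, n_chromosomes={self.n_chromosomes})"


@dataclass(frozen=True, eq=False)
class TargetSet:
    """The set of loci to introgress from the donor (0-based indices)."""

    loci: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.loci, dtype=np.int64)
        if arr.ndim != 1 or arr.size < 1:
            raise ValueError("a TargetSet needs at least one locus")
        arr = np.unique(arr)
        if arr.size != np.asarray(self.loci).size:
            raise ValueError("target loci must be distinct")
        if (arr < 0).any():
            raise ValueError("target locus indices must be >= 0")
        object.__setattr__(self, "loci", np.ascontiguousarray(arr))

    @property
    def Z(self) -> int:
        """Number of target loci."""
        return self.loci.size

    @classmethod
    def from_one_based(cls, indices: Iterable[int]) -> "TargetSet":
        return cls(np.asarray(list(indices), dtype=np.int64) - 1)

    def to_one_based(self) -> np.ndarray:
        return self.loci + 1

    def validate_for(self, L: int) -> None:
        if int(self.loci[-1]) >= L:
            raise ValueError(
                f"target locus {int(self.loci[-1])} out of range for L={L}"
            )

    def target_mask(self, L: int) -> np.ndarray:
        self.validate_for(L)
        mask = np.zeros(L, dtype=bool)
        mask[self.loci] = True
        return mask

    def background_mask(self, L: int) -> np.ndarray:
        return ~self.target_mask(L)

    def __repr__(self) -> str:
        return f"TargetSet(loci={self.loci.tolist()})"


def _check_stage(stage: str) -> None:
    if stage not in STAGES:
        raise ValueError(f"stage must be one of {STAGES}, got {stage!r}")


def recovery_percentage(genotype: Genotype, targets: TargetSet) -> float:
    """Recurrent-parent background recovery, in percent.

    The number of desirable alleles at non-target (background) loci divided
    by the total number of background alleles, times 100.
    """
    targets.validate_for(genotype.L)
    if targets.Z >= genotype.L:
        raise ValueError(
            "recovery percentage undefined: every locus is a target "
            "(empty background)"
        )
    bg = targets.background_mask(genotype.L)
    n_bg = genotype.L - targets.Z
    return 100.0 * float(genotype.alleles[bg].sum()) / (2.0 * n_bg)


def recovery_percentages(population: np.ndarray, targets: TargetSet) -> np.ndarray:
    """Vectorised :func:`recovery_percentage` over an ``(N, L, 2)`` array."""
    pop = np.asarray(population)
    L = pop.shape[1]
    targets.validate_for(L)
    if targets.Z >= L:
        raise ValueError("recovery percentage undefined: empty background")
    bg = targets.background_mask(L)
    return 100.0 * pop[:, bg, :].sum(axis=(1, 2)) / (2.0 * (L - targets.Z))


def is_positive(genotype: Genotype, targets: TargetSet, stage: str = "backcross") -> bool:
    """Whether the individual carries the donor alleles at every target locus.

    At the ``backcross`` stage one desirable allele per target suffices
    (targets are expected heterozygous); after selfing (``selfed``) both
    copies must be desirable.
    """
    _check_stage(stage)
    targets.validate_for(genotype.L)
    rows = genotype.alleles[targets.loci]
    if stage == "backcross":
        return bool((rows.max(axis=1) == 1).all())
    return bool((rows.min(axis=1) == 1).all())


def positive_mask(
    population: np.ndarray, targets: TargetSet, stage: str = "backcross"
) -> np.ndarray:
    """Vectorised :func:`is_positive` over an ``(N, L, 2)`` array."""
    _check_stage(stage)
    pop = np.asarray(population)
    targets.validate_for(pop.shape[1])
    rows = pop[:, targets.loci, :]
    if stage == "backcross":
        return (rows.max(axis=2) == 1).all(axis=1)
    return (rows.min(axis=2) == 1).all(axis=1)


def count_target_alleles(genotype: Genotype, targets: TargetSet) -> int:
    """Total desirable alleles across the target loci (0 .. 2Z)."""
    targets.validate_for(genotype.L)
    return int(genotype.alleles[targets.loci].sum())
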