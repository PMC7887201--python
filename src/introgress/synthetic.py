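"""Synthetic donor/recurrent-parent pairs and recombination maps.

The generator emulates the structure of the empirical maize introgression
data sets: two fully homozygous inbred lines at a prescribed Nei genetic
similarity, a small set of target loci carried only by the donor, and a
recombination map whose chromosome boundaries are encoded as entries of
exactly 0.5.  Three presets reproduce the published case structure
(low/moderate/high initial similarity):

========  ====  ==========  ==================
preset     L    similarity  interpretation
========  ====  ==========  ==================
case1     195   0.58        low similarity
case2     173   0.72        moderate similarity
case3     172   0.89        high similarity
========  ====  ==========  ==================

For fully homozygous binary lines Nei's genetic identity collapses to the
proportion of loci at which the two lines carry the same allele; the
similarity here counts *all* loci, including the Z target loci that
mismatch by construction, so the feasible range is [0, (L - Z) / L].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Tuple

import numpy as np

from .genetics import Genotype, RecombMap, TargetSet

__all__ = [
    "CASE_PRESETS",
    "CasePreset",
    "nei_similarity",
    "generate_parent_pair",
    "generate_recomb_map",
    "generate_case",
]


@dataclass(frozen=True)
class CasePreset:
    L: int
    similarity: float
    n_targets: int = 3


CASE_PRESETS = {
    "case1": CasePreset(L=195, similarity=0.58),
    "case2": CasePreset(L=173, similarity=0.72),
    "case3": CasePreset(L=172, similarity=0.89),
}


def nei_similarity(a: Genotype, b: Genotype) -> float:
    """Nei genetic identity between two fully homozygous inbred lines.

    For binary inbreds the general allele-frequency formula reduces to the
    proportion of loci with identical genotypes, which is what is returned.
    Heterozygous input is rejected: the generator contract covers inbreds
    only.
    """
    if a.L != b.L:
        raise ValueError("genotypes differ in locus count")
    if not a.is_homozygous or not b.is_homozygous:
        raise ValueError("Nei similarity is defined here for homozygous inbreds only")
    return float(np.mean(a.haplotype(0) == b.haplotype(0)))


def generate_parent_pair(
    L: int,
    targets: TargetSet,
    similarity: float,
    rng: np.random.Generator,
) -> Tuple[Genotype, Genotype]:
    """Homozygous donor/RP pair at (approximately) the requested similarity.

    The RP is desirable (1) at every background locus and undesirable (0) at
    the targets; the donor is desirable at the targets and at a uniformly
    random background subset sized so the realised Nei similarity is the
    feasible value closest to ``similarity``.  Since target loci always
    mismatch, similarities above ``(L - Z) / L`` are infeasible.
    """
    targets.validate_for(L)
    Z = targets.Z
    if Z >= L:
        raise ValueError("need at least one background locus")
    if not (0.0 <= similarity <= 1.0):
        raise ValueError("similarity must lie in [0, 1]")
    n_match = int(round(similarity * L))
    if n_match > L - Z:
        raise ValueError(
            f"similarity {similarity} infeasible with Z={Z} always-mismatching "
            f"targets; the feasible range is [0, {(L - Z) / L:.4f}]"
        )
    tmask = targets.target_mask(L)
    rp_hap = np.ones(L, dtype=np.uint8)
    rp_hap[tmask] = 0
    donor_hap = np.zeros(L, dtype=np.uint8)
    donor_hap[tmask] = 1
    background = np.flatnonzero(~tmask)
    chosen = rng.choice(background, size=n_match, replace=False)
    donor_hap[chosen] = 1
    return Genotype.homozygous(donor_hap), Genotype.homozygous(rp_hap)


def generate_recomb_map(
    L: int,
    n_chromosomes: int,
    rng: np.random.Generator,
    law: Callable[[np.random.Generator, int], np.ndarray] | None = None,
) -> RecombMap:
    """Synthetic recombination map with ``n_chromosomes - 1`` boundaries.

    Loci are split into near-equal chromosomes; the boundary intervals are
    exactly 0.5 (free recombination between chromosomes) and every
    within-chromosome interval is drawn i.i.d. from ``law`` (default:
    uniform on [0, 0.1)), truncated into [0, 0.5).
    """
    if n_chromosomes < 1:
        raise ValueError("n_chromosomes must be >= 1")
    if L < n_chromosomes:
        raise ValueError("need at least one locus per chromosome")
    if law is None:
        law = lambda g, size: g.uniform(0.0, 0.1, size)  # noqa: E731
    values = np.clip(np.asarray(law(rng, L - 1), dtype=np.float64), 0.0, np.nextafter(0.5, 0.0))
    sizes = np.full(n_chromosomes, L // n_chromosomes)
    sizes[: L % n_chromosomes] += 1
    boundaries = np.cumsum(sizes)[:-1] - 1  # interval after each chromosome end
    values[boundaries] = 0.5
    return RecombMap(values)


def _default_targets(L: int, n_targets: int) -> TargetSet:
    # evenly spread across the genome so the targets land on distinct
    # chromosomes under the default 10-chromosome split
    loci = ((np.arange(n_targets) + 0.5) / n_targets * L).astype(np.int64)
    return TargetSet(loci)


def generate_case(
    name: str,
    rng: np.random.Generator,
    n_chromosomes: int = 10,
    law: Callable[[np.random.Generator, int], np.ndarray] | None = None,
) -> Tuple[Genotype, Genotype, TargetSet, RecombMap]:
    """Generate (donor, rp, targets, recomb_map) for a named preset.

    The default 10 chromosomes reflect the maize karyotype the presets
    emulate; the target loci are placed deterministically at even spacing so
    repeated studies are comparable, while the donor background subset and
    the map are drawn from ``rng``.
    """
    try:
        preset = CASE_PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; choose from {sorted(CASE_PRESETS)}"
        ) from None
    targets = _default_targets(preset.L, preset.n_targets)
    donor, rp = generate_parent_pair(preset.L, targets, preset.similarity, rng)
    recomb = generate_recomb_map(preset.L, n_chromosomes, rng, law=law)
    return donor, rp, targets, recomb
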