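"""Gamete formation under the no-interference Markov recombination model.

Meiosis is modelled as a two-state Markov chain along the genome: the
transmitted allele at locus 1 comes from a uniformly chosen chromosome copy,
and between adjacent loci ``l`` and ``l + 1`` the transmitting copy switches
with probability ``r[l]`` and stays with probability ``1 - r[l]``.  An entry
of 0.5 makes neighbouring loci assort independently (chromosome boundary);
crossover interference is not modelled.

Besides the stochastic samplers this module provides
:func:`gamete_probability`, the exact probability of producing a given
gamete, evaluated either by a forward pass over the two-state chain (any L)
or by brute-force enumeration of all ``2^L`` inheritance paths (small L).
The enumeration route is deliberately independent of the forward pass so the
two can serve as mutual checks.
"""

from __future__ import annotations

import math
from typing import List

import numpy as np

from .genetics import Genotype, RecombMap

__all__ = [
    "sample_inheritance",
    "sample_gamete",
    "sample_gametes",
    "gametes_from_alleles",
    "gamete_probability",
    "cross",
    "self_fertilize",
]

_ENUM_MAX_L = 20


def _check_compatible(genotype: Genotype, recomb: RecombMap) -> None:
    if genotype.L != recomb.L:
        raise ValueError(
            f"genotype has L={genotype.L} loci but the recombination map "
            f"spans L={recomb.L}"
        )


def _sample_sources(r: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """``(n, L)`` matrix of transmitting-copy indices (0/1) for n meioses."""
    L = r.size + 1
    flips = np.empty((n, L), dtype=bool)
    flips[:, 0] = rng.random(n) < 0.5
    flips[:, 1:] = rng.random((n, r.size)) < r
    # the source at locus l is the running XOR of the switch indicators
    return np.logical_xor.accumulate(flips, axis=1).astype(np.int8)


def sample_inheritance(recomb: RecombMap, rng: np.random.Generator) -> np.ndarray:
    """Draw one latent inheritance path.

    Returns a length-L vector over {0, 1} naming the chromosome copy
    transmitted at each locus: uniform at the first locus, then switching
    between loci ``l`` and ``l + 1`` with probability ``r[l]``.
    """
    return _sample_sources(recomb.r, 1, rng)[0]


def gametes_from_alleles(
    alleles: np.ndarray, r: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    """``(n, L)`` gametes drawn from an ``(L, 2)`` allele matrix (fast path)."""
    sources = _sample_sources(r, n, rng)
    return np.asarray(alleles)[np.arange(r.size + 1), sources]


def sample_gamete(
    genotype: Genotype, recomb: RecombMap, rng: np.random.Generator
) -> np.ndarray:
    """Draw one random gamete (length-L binary vector) from an individual."""
    _check_compatible(genotype, recomb)
    return gametes_from_alleles(genotype.alleles, recomb.r, 1, rng)[0]


def sample_gametes(
    genotype: Genotype, recomb: RecombMap, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` independent gametes as an ``(n, L)`` binary matrix."""
    _check_compatible(genotype, recomb)
    return gametes_from_alleles(genotype.alleles, recomb.r, n, rng)


def _forward_logprob(alleles: np.ndarray, r: np.ndarray, gamete: np.ndarray) -> float:
    """Log Pr(gamete) by the two-state forward pass, renormalised each step."""
    w = 0.5 * (alleles[0, :] == gamete[0]).astype(np.float64)
    total = w[0] + w[1]
    if total == 0.0:
        return -math.inf
    logp = math.log(total)
    w /= total
    for l in range(1, alleles.shape[0]):
        rl = r[l - 1]
        w0 = w[0] * (1.0 - rl) + w[1] * rl
        w1 = w[0] * rl + w[1] * (1.0 - rl)
        w = np.array([w0, w1]) * (alleles[l, :] == gamete[l])
        total = w[0] + w[1]
        if total == 0.0:
            return -math.inf
        logp += math.log(total)
        w /= total
    return logp


def _enumerate_probability(
    alleles: np.ndarray, r: np.ndarray, gamete: np.ndarray
) -> float:
    """Pr(gamete) by summing over all 2^L inheritance paths (L <= 20)."""
    L = alleles.shape[0]
    if L > _ENUM_MAX_L:
        raise ValueError(f"enumeration is limited to L <= {_ENUM_MAX_L}; got L={L}")
    paths = (np.arange(2**L)[:, None] >> np.arange(L)[None, :]) & 1  # (2^L, L)
    switch = paths[:, 1:] != paths[:, :-1]
    probs = 0.5 * np.prod(np.where(switch, r, 1.0 - r), axis=1)
    emitted = alleles[np.arange(L), paths]  # (2^L, L)
    consistent = (emitted == gamete).all(axis=1)
    return float(probs[consistent].sum())


def gamete_probability(
    genotype: Genotype,
    recomb: RecombMap,
    gamete,
    method: str = "forward",
) -> float:
    """Exact probability that one meiosis of ``genotype`` yields ``gamete``.

    ``method="forward"`` runs the two-state forward pass (any L);
    ``method="enumerate"`` sums all ``2^L`` inheritance paths directly and is
    restricted to small L.  The two agree to floating-point precision.
    """
    _check_compatible(genotype, recomb)
    g = np.asarray(gamete)
    if g.shape != (genotype.L,):
        raise ValueError(f"gamete must be a length-{genotype.L} vector")
    if method == "forward":
        return math.exp(_forward_logprob(genotype.alleles, recomb.r, g))
    if method == "enumerate":
        return _enumerate_probability(genotype.alleles, recomb.r, g)
    raise ValueError(f"unknown method {method!r}")


def cross(
    first: Genotype,
    second: Genotype,
    recomb: RecombMap,
    n: int,
    rng: np.random.Generator,
) -> List[Genotype]:
    """Produce ``n`` progeny, each pairing one fresh gamete from each parent."""
    if first.L != second.L:
        raise ValueError(f"parents differ in locus count: {first.L} vs {second.L}")
    _check_compatible(first, recomb)
    if n < 1:
        raise ValueError("n must be >= 1")
    g1 = gametes_from_alleles(first.alleles, recomb.r, n, rng)
    g2 = gametes_from_alleles(second.alleles, recomb.r, n, rng)
    return [Genotype.from_haplotypes(g1[i], g2[i]) for i in range(n)]


def self_fertilize(
    genotype: Genotype, recomb: RecombMap, n: int, rng: np.random.Generator
) -> List[Genotype]:
    """Self-fertilise: ``n`` progeny from two independent gametes each."""
    return cross(genotype, genotype, recomb, n, rng)
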