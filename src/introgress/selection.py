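"""Baseline parental-selection scores and truncation selection.

Two classical scores for choosing backcross parents:

* **background GEBV** — with uniform marker weights, the genomic estimated
  breeding value of the background reduces to the count of desirable alleles
  at non-target loci.  It ignores linkage entirely.
* **PCV** (predicted cross value) — the probability that one meiosis of the
  individual yields an "elite" gamete carrying the desirable allele at
  *every* locus, accounting for the recombination map.  Because a backcross
  parent is always mated to the (homozygous, background-perfect) recurrent
  parent, the single-individual gamete probability is the relevant form.

PCV is computed by an exact forward recursion over the two-state inheritance
chain.  For realistic genomes (L ~ 200 with many heterozygous loci) the raw
probability underflows double precision, so the recursion renormalises at
every step and accumulates the log; ranking is done on the log scale.
"""

from __future__ import annotations

import logging
import math
from typing import List, Sequence

import numpy as np

from .genetics import Genotype, RecombMap, TargetSet, is_positive

__all__ = [
    "SelectionError",
    "gebv_background",
    "gebv_backgrounds",
    "pcv",
    "pcv_log",
    "pcv_logs",
    "rank_select",
    "select_indices",
]

logger = logging.getLogger(__name__)


class SelectionError(RuntimeError):
    """Raised when selection is impossible (no positive individuals left)."""


def gebv_background(
    genotype: Genotype, targets: TargetSet, weights=None
) -> float:
    """Background breeding value: weighted count of desirable background alleles.

    With the default uniform weights this is an integer in
    ``[0, 2 (L - Z)]``.  A per-locus weight vector may be supplied but the
    canonical score uses ones.
    """
    targets.validate_for(genotype.L)
    bg = targets.background_mask(genotype.L)
    counts = genotype.alleles.sum(axis=1)[bg]
    if weights is None:
        return int(counts.sum())
    w = np.asarray(weights, dtype=np.float64)
    if w.shape != (genotype.L,):
        raise ValueError(f"weights must have length L={genotype.L}")
    return float((counts * w[bg]).sum())


def gebv_backgrounds(population: np.ndarray, targets: TargetSet) -> np.ndarray:
    """Vectorised uniform-weight :func:`gebv_background` over ``(N, L, 2)``."""
    pop = np.asarray(population)
    bg = targets.background_mask(pop.shape[1])
    return pop[:, bg, :].sum(axis=(1, 2)).astype(np.int64)


def pcv_logs(population: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Log-PCV for every individual of an ``(N, L, 2)`` population.

    Forward pass over the two-state inheritance chain: state weights start at
    ``(0.5 [G[0,0]=1], 0.5 [G[0,1]=1])``; each step mixes the states with the
    stay/switch probabilities ``1 - r_l`` / ``r_l`` and zeroes states whose
    allele at the next locus is undesirable.  The running total is
    renormalised at every locus, so the result is exact in log space for any
    L.  Individuals that cannot produce an elite gamete get ``-inf``.
    """
    pop = np.asarray(population, dtype=np.float64)
    n, L, _ = pop.shape
    w = 0.5 * (pop[:, 0, :] == 1.0)  # (N, 2)
    logp = np.zeros(n)
    alive = np.ones(n, dtype=bool)
    total = w.sum(axis=1)
    dead = total == 0.0
    alive &= ~dead
    logp[dead] = -np.inf
    total[dead] = 1.0
    w /= total[:, None]
    logp[alive] += np.log(total[alive])
    for l in range(1, L):
        rl = r[l - 1]
        mixed = np.empty_like(w)
        mixed[:, 0] = w[:, 0] * (1.0 - rl) + w[:, 1] * rl
        mixed[:, 1] = w[:, 0] * rl + w[:, 1] * (1.0 - rl)
        w = mixed * (pop[:, l, :] == 1.0)
        total = w.sum(axis=1)
        dead = alive & (total == 0.0)
        logp[dead] = -np.inf
        alive &= ~dead
        total[~alive] = 1.0
        w /= total[:, None]
        logp[alive] += np.log(total[alive])
    return logp


def pcv_log(genotype: Genotype, recomb: RecombMap) -> float:
    """Natural log of the PCV (``-inf`` when the PCV is exactly zero)."""
    if genotype.L != recomb.L:
        raise ValueError(
            f"genotype has L={genotype.L} loci but the map spans L={recomb.L}"
        )
    return float(pcv_logs(genotype.alleles[None, :, :], recomb.r)[0])


def pcv(genotype: Genotype, recomb: RecombMap) -> float:
    """Predicted cross value: Pr(one random gamete is desirable at all loci).

    Note the returned float underflows to 0.0 below ~1e-308; use
    :func:`pcv_log` when only the ranking matters.
    """
    return math.exp(pcv_log(genotype, recomb))


def select_indices(
    scores: np.ndarray,
    positives: np.ndarray,
    k: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Indices of the ``k`` best positive individuals, random tie-breaking.

    ``scores`` and the boolean mask ``positives`` are aligned to the
    population.  Raises :class:`SelectionError` when no individual is
    positive; returns all positives (with a warning) when fewer than ``k``
    exist.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    pos_idx = np.flatnonzero(np.asarray(positives, dtype=bool))
    if pos_idx.size == 0:
        raise SelectionError("no positive individuals to select from")
    if pos_idx.size < k:
        logger.warning(
            "only %d positive individuals available for k=%d; returning all",
            pos_idx.size,
            k,
        )
        return pos_idx
    s = np.asarray(scores, dtype=np.float64)[pos_idx]
    tiebreak = rng.random(pos_idx.size)
    order = np.lexsort((tiebreak, -s))  # primary: score desc; ties: random
    return pos_idx[order[:k]]


def rank_select(
    population: Sequence[Genotype],
    scores: Sequence[float],
    k: int,
    targets: TargetSet,
    stage: str = "backcross",
    rng: np.random.Generator | None = None,
) -> List[Genotype]:
    """Truncation selection: keep positives, return the k highest-scoring.

    Non-positive individuals are discarded before ranking (trait first,
    background second).  Ties are broken by a seeded uniform draw so repeated
    runs with the same generator are reproducible.
    """
    if len(scores) != len(population):
        raise ValueError("scores must align with the population")
    rng = rng if rng is not None else np.random.default_rng()
    positives = np.array([is_positive(g, targets, stage) for g in population])
    idx = select_indices(np.asarray(scores, dtype=np.float64), positives, k, rng)
    return [population[i] for i in idx]
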