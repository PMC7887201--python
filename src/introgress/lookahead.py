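"""Look-ahead Monte Carlo (LMC) scoring of backcross candidates.

Instead of scoring a candidate on its own genome, the look-ahead score
simulates where the candidate can still go: from its current generation
``t`` each simulated path draws a target-positive gamete, pairs it with the
recurrent-parent haplotype to form the next backcross individual, repeats
until the final backcross generation ``T``, and then self-fertilises the
terminal individual into an evaluation population of K progeny.  For path
``j`` let ``n_j`` be the number of selfed progeny that are homozygous for
all target alleles *and* reach the required background recovery, and ``v_j``
the best recovery among the homozygous-positive progeny.  The score averages
``(n_j / K) * v_j`` over P independent paths, so it lies in [0, 100] and
rewards candidates whose descendants are simultaneously likely to fix the
targets and to recover the recurrent-parent background by the deadline.

"Draw a target-positive gamete" is realised as rejection sampling with a cap
on the number of attempts; a path that exhausts the cap at any step is
counted as failed and contributes 0 (a candidate that struggles to transmit
its targets *should* be penalised).  As the batch size grows this is
distributionally identical to simulating a batch of gametes, keeping the
positive ones and picking one uniformly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ._kernels import lmc_scores_kernel
from .genetics import (
    Genotype,
    RecombMap,
    TargetSet,
    is_positive,
    positive_mask,
    recovery_percentages,
)
from .meiosis import gametes_from_alleles

__all__ = ["LookaheadConfig", "PathOutcome", "simulate_lookahead_path", "lmc_score", "lmc_scores"]

_MAX_SEED = 2**31 - 1


@dataclass(frozen=True)
class LookaheadConfig:
    """Tuning knobs of the look-ahead score.

    Parameters
    ----------
    rounds
        P, number of independent descendant paths per candidate.
    selfing_progeny
        K, size of the selfed evaluation population at the deadline
        (defaults to one cross's worth of progeny, 200).
    success_threshold
        Background recovery (percent) a selfed descendant must reach to
        count as a success.
    max_gamete_attempts
        Rejection-sampling cap per backcross step; exhausting it marks the
        path as failed.
    target_generation
        T, the final backcross generation the look-ahead simulates to.
    """

    rounds: int = 50
    selfing_progeny: int = 200
    success_threshold: float = 95.0
    max_gamete_attempts: int = 200
    target_generation: int = 3

    def __post_init__(self) -> None:
        if self.rounds < 1:
            raise ValueError("rounds (P) must be >= 1")
        if self.selfing_progeny < 1:
            raise ValueError("selfing_progeny (K) must be >= 1")
        if not (0.0 < self.success_threshold <= 100.0):
            raise ValueError("success_threshold must lie in (0, 100]")
        if self.max_gamete_attempts < 1:
            raise ValueError("max_gamete_attempts must be >= 1")
        if self.target_generation < 1:
            raise ValueError("target_generation (T) must be >= 1")

    def with_target_generation(self, T: int) -> "LookaheadConfig":
        return replace(self, target_generation=T)


@dataclass(frozen=True)
class PathOutcome:
    """Result of one simulated descendant path.

    ``n_success`` selfed progeny were homozygous-positive with recovery at or
    above the threshold; ``best_recovery`` is the maximum recovery among
    homozygous-positive progeny (0 when there were none); ``failed`` flags a
    path that could not find a target-positive gamete within the attempt cap
    at some backcross step.
    """

    n_success: int
    best_recovery: float
    failed: bool


def _rp_haplotype(rp: Genotype) -> np.ndarray:
    if not rp.is_homozygous:
        raise ValueError("the recurrent parent must be homozygous")
    return rp.haplotype(0)


def simulate_lookahead_path(
    genotype: Genotype,
    rp: Genotype,
    recomb: RecombMap,
    generation: int,
    config: LookaheadConfig,
    targets: TargetSet,
    rng: np.random.Generator,
) -> PathOutcome:
    """Simulate one descendant path of a backcross candidate (reference path).

    From generation ``generation`` to ``config.target_generation`` a
    target-positive gamete is rejection-sampled and paired with the RP
    haplotype; at the deadline the terminal individual is selfed into
    ``config.selfing_progeny`` progeny which are scored for homozygous
    positivity and background recovery.

    This is the plain NumPy single-path implementation; population scoring
    uses an equivalent compiled batch kernel (:func:`lmc_scores`).
    """
    if generation > config.target_generation:
        raise ValueError("current generation is past the target generation")
    if not is_positive(genotype, targets, "backcross"):
        raise ValueError("look-ahead paths are only defined for positive candidates")
    rp_hap = _rp_haplotype(rp)
    tmask = targets.target_mask(genotype.L)

    current = genotype.alleles
    for _ in range(config.target_generation - generation):
        gametes = gametes_from_alleles(
            current, recomb.r, config.max_gamete_attempts, rng
        )
        ok = (gametes[:, tmask] == 1).all(axis=1)
        hits = np.flatnonzero(ok)
        if hits.size == 0:
            return PathOutcome(n_success=0, best_recovery=0.0, failed=True)
        current = np.column_stack([gametes[hits[0]], rp_hap])

    K = config.selfing_progeny
    g1 = gametes_from_alleles(current, recomb.r, K, rng)
    g2 = gametes_from_alleles(current, recomb.r, K, rng)
    progeny = np.stack([g1, g2], axis=2)
    homozygous_positive = positive_mask(progeny, targets, "selfed")
    if not homozygous_positive.any():
        return PathOutcome(n_success=0, best_recovery=0.0, failed=False)
    recov = recovery_percentages(progeny[homozygous_positive], targets)
    n = int((recov >= config.success_threshold).sum())
    return PathOutcome(n_success=n, best_recovery=float(recov.max()), failed=False)


def lmc_scores(
    population,
    rp: Genotype,
    recomb: RecombMap,
    generation: int,
    config: LookaheadConfig,
    targets: TargetSet,
    rng: np.random.Generator,
) -> np.ndarray:
    """Look-ahead Monte Carlo score for every individual of a population.

    ``population`` is an ``(N, L, 2)`` array or a sequence of
    :class:`Genotype`.  Each candidate is scored on an independent seeded
    substream so that scores are not correlated through shared draws.
    Non-positive candidates score exactly 0.
    """
    if generation > config.target_generation:
        raise ValueError("current generation is past the target generation")
    if isinstance(population, np.ndarray):
        pop = np.ascontiguousarray(population, dtype=np.uint8)
    else:
        pop = np.ascontiguousarray(
            np.stack([g.alleles for g in population]), dtype=np.uint8
        )
    L = pop.shape[1]
    if L != recomb.L:
        raise ValueError(f"population has L={L} loci but the map spans L={recomb.L}")
    targets.validate_for(L)
    if targets.Z >= L:
        raise ValueError("recovery undefined: no background loci")
    rp_hap = np.ascontiguousarray(_rp_haplotype(rp), dtype=np.uint8)
    seeds = rng.integers(0, _MAX_SEED, size=pop.shape[0], dtype=np.int64)
    return lmc_scores_kernel(
        pop,
        rp_hap,
        recomb.r,
        targets.target_mask(L),
        config.target_generation - generation,
        config.rounds,
        config.selfing_progeny,
        float(config.success_threshold),
        config.max_gamete_attempts,
        L - targets.Z,
        seeds,
    )


def lmc_score(
    genotype: Genotype,
    rp: Genotype,
    recomb: RecombMap,
    generation: int,
    config: LookaheadConfig,
    targets: TargetSet,
    rng: np.random.Generator,
) -> float:
    """Score one candidate: mean of ``(n_j / K) * v_j`` over P paths.

    Lies in [0, 100]; 0 for a candidate that is not target-positive.
    """
    if not is_positive(genotype, targets, "backcross"):
        return 0.0
    return float(
        lmc_scores(
            genotype.alleles[None, :, :], rp, recomb, generation, config, targets, rng
        )[0]
    )
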