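"""Orchestration of a full trait-introgression program.

A program starts from two homozygous inbred parents: the donor carrying the
desirable alleles at the target loci and the recurrent parent (RP) whose
background genome is to be recovered.  The deterministic F1 is backcrossed
to the RP to form BC1; in each later generation the best target-positive
individuals (by the configured selection score) are chosen as parents and
backcrossed again; after the final backcross the selected BCT parents are
self-fertilised to fix the targets, giving the BCTF2 evaluation population.

Every backcross generation and the selfed generation contain
``crosses_per_generation x progeny_per_cross`` individuals.  A replicate
succeeds when the best homozygous-positive BCTF2 individual reaches the
configured background-recovery threshold.

Reproducibility: replicate ``i`` of a run derives all its randomness from
``(seed, i)``.  The stream that creates the BC1 population is deliberately
independent of the selection method, so runs that differ only in ``method``
start from identical BC1 populations and can be compared pairwise replicate
by replicate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd

from .genetics import (
    Genotype,
    RecombMap,
    TargetSet,
    is_positive,
    positive_mask,
    recovery_percentages,
)
from .lookahead import LookaheadConfig, lmc_scores
from .meiosis import gametes_from_alleles
from .selection import (
    SelectionError,
    gebv_backgrounds,
    pcv_logs,
    select_indices,
)

__all__ = [
    "METHODS",
    "ProgramConfig",
    "ReplicateResult",
    "make_f1",
    "run_program",
    "run_replicates",
    "success_probability",
    "summarize_generation",
    "max_recovery_ecdf",
]

logger = logging.getLogger(__name__)

METHODS = ("gebv", "pcv", "lmc")
_METHOD_CODE = {m: i for i, m in enumerate(METHODS)}

#: Crosses per generation under the two resource scenarios
#: (1: limited resources, 2: moderate resources).
SCENARIO_CROSSES = {1: 2, 2: 6}


@dataclass
class ProgramConfig:
    """Configuration of one trait-introgression program run."""

    n_backcross: int = 3
    crosses_per_generation: int = 2
    progeny_per_cross: int = 200
    method: str = "gebv"
    replicates: int = 100
    success_threshold: float = 95.0
    seed: int = 0
    lookahead: LookaheadConfig = field(default_factory=LookaheadConfig)

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {self.method!r}")
        for name in ("n_backcross", "crosses_per_generation", "progeny_per_cross", "replicates"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0.0 < self.success_threshold <= 100.0):
            raise ValueError("success_threshold must lie in (0, 100]")
        # the look-ahead always simulates to this program's final backcross
        if self.lookahead.target_generation != self.n_backcross:
            self.lookahead = self.lookahead.with_target_generation(self.n_backcross)

    @classmethod
    def scenario(cls, number: int, **overrides) -> "ProgramConfig":
        """Preset resource scenarios: 1 = 2 crosses/gen, 2 = 6 crosses/gen."""
        if number not in SCENARIO_CROSSES:
            raise ValueError(f"scenario must be one of {sorted(SCENARIO_CROSSES)}")
        overrides.setdefault("crosses_per_generation", SCENARIO_CROSSES[number])
        return cls(**overrides)

    @property
    def generation_size(self) -> int:
        return self.crosses_per_generation * self.progeny_per_cross

    def generation_labels(self) -> List[str]:
        labels = [f"BC{t}" for t in range(1, self.n_backcross + 1)]
        labels.append(f"BC{self.n_backcross}F2")
        return labels


@dataclass
class ReplicateResult:
    """Per-generation statistics of one replicate.

    ``recovery[label]`` and ``positive[label]`` are aligned arrays over all
    individuals of that generation (labels ``BC1`` ... ``BCT`` use the
    backcross positivity rule, the final ``BC{T}F2`` label the homozygous
    rule).  ``bctf2_max_recovery`` is NaN when the selfed generation holds no
    homozygous-positive individual (or the replicate went extinct earlier).
    """

    recovery: Dict[str, np.ndarray]
    positive: Dict[str, np.ndarray]
    bctf2_max_recovery: float
    success: bool
    extinct: bool = False


def make_f1(donor: Genotype, rp: Genotype) -> Genotype:
    """The deterministic F1 of two homozygous parents.

    Column 1 is the donor haplotype, column 2 the RP haplotype, so the F1
    carries exactly half its material from each parent.
    """
    if donor.L != rp.L:
        raise ValueError("donor and recurrent parent differ in locus count")
    if not donor.is_homozygous or not rp.is_homozygous:
        raise ValueError("the F1 cross is only deterministic for homozygous parents")
    return Genotype.from_haplotypes(donor.haplotype(0), rp.haplotype(0))


def _score_population(
    pop: np.ndarray,
    method: str,
    rp: Genotype,
    recomb: RecombMap,
    generation: int,
    cfg: ProgramConfig,
    targets: TargetSet,
    rng: np.random.Generator,
) -> np.ndarray:
    if method == "gebv":
        return gebv_backgrounds(pop, targets).astype(np.float64)
    if method == "pcv":
        return pcv_logs(pop, recomb.r)
    return lmc_scores(pop, rp, recomb, generation, cfg.lookahead, targets, rng)


def _select_parents(
    pop: np.ndarray,
    generation: int,
    cfg: ProgramConfig,
    rp: Genotype,
    recomb: RecombMap,
    targets: TargetSet,
    rng: np.random.Generator,
) -> np.ndarray:
    """Indices of the parents chosen from a backcross population."""
    positives = positive_mask(pop, targets, "backcross")
    if not positives.any():
        raise SelectionError(
            f"no target-positive individuals in generation BC{generation}"
        )
    scores = np.full(pop.shape[0], -np.inf)
    pos_idx = np.flatnonzero(positives)
    scores[pos_idx] = _score_population(
        pop[pos_idx], cfg.method, rp, recomb, generation, cfg, targets, rng
    )
    chosen = select_indices(scores, positives, cfg.crosses_per_generation, rng)
    if logger.isEnabledFor(logging.DEBUG):
        sel = set(chosen.tolist())
        for i in pos_idx:
            logger.debug(
                "BC%d candidate %d: score=%.6g selected=%s",
                generation,
                i,
                scores[i],
                i in sel,
            )
    return chosen


def _progeny_with_rp(
    parents: np.ndarray, rp_hap: np.ndarray, recomb: RecombMap, n_each: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Backcross each parent (K, L, 2) to the homozygous RP, n_each progeny."""
    blocks = []
    for k in range(parents.shape[0]):
        gametes = gametes_from_alleles(parents[k], recomb.r, n_each, rng)
        rp_side = np.broadcast_to(rp_hap, gametes.shape)
        blocks.append(np.stack([gametes, rp_side], axis=2))
    return np.concatenate(blocks, axis=0)


def _self_progeny(
    parents: np.ndarray, recomb: RecombMap, n_each: int, rng: np.random.Generator
) -> np.ndarray:
    blocks = []
    for k in range(parents.shape[0]):
        g1 = gametes_from_alleles(parents[k], recomb.r, n_each, rng)
        g2 = gametes_from_alleles(parents[k], recomb.r, n_each, rng)
        blocks.append(np.stack([g1, g2], axis=2))
    return np.concatenate(blocks, axis=0)


def run_program(
    cfg: ProgramConfig,
    donor: Genotype,
    rp: Genotype,
    recomb: RecombMap,
    targets: TargetSet,
    rng: np.random.Generator,
    bc1_rng: np.random.Generator | None = None,
) -> ReplicateResult:
    """Run one replicate of the full program (F1 -> BC1..BCT -> BCTF2).

    ``bc1_rng``, when given, supplies the randomness that creates the BC1
    population so that different selection methods can share identical BC1
    populations; all later randomness (selection tie-breaks, look-ahead
    paths, backcross and selfing meioses) comes from ``rng``.
    """
    targets.validate_for(donor.L)
    if not is_positive(donor, targets, "selfed"):
        raise ValueError("the donor must be homozygous-desirable at all target loci")
    if donor.L != recomb.L:
        raise ValueError("recombination map does not span the parents' loci")
    bc1_rng = bc1_rng if bc1_rng is not None else rng
    f1 = make_f1(donor, rp)
    rp_hap = rp.haplotype(0)
    labels = cfg.generation_labels()
    selfed_label = labels[-1]

    recovery: Dict[str, np.ndarray] = {}
    positive: Dict[str, np.ndarray] = {}

    # BC1: the unique F1 genotype is crossed to the RP once per allotted cross
    pop = _progeny_with_rp(
        f1.alleles[None, :, :], rp_hap, recomb,
        cfg.generation_size, bc1_rng,
    )
    recovery["BC1"] = recovery_percentages(pop, targets)
    positive["BC1"] = positive_mask(pop, targets, "backcross")

    try:
        for t in range(2, cfg.n_backcross + 1):
            chosen = _select_parents(pop, t - 1, cfg, rp, recomb, targets, rng)
            pop = _progeny_with_rp(
                pop[chosen], rp_hap, recomb, cfg.progeny_per_cross, rng
            )
            recovery[f"BC{t}"] = recovery_percentages(pop, targets)
            positive[f"BC{t}"] = positive_mask(pop, targets, "backcross")

        chosen = _select_parents(pop, cfg.n_backcross, cfg, rp, recomb, targets, rng)
        selfed = _self_progeny(pop[chosen], recomb, cfg.progeny_per_cross, rng)
    except SelectionError as err:
        logger.warning("replicate failed: %s", err)
        for label in labels:
            recovery.setdefault(label, np.empty(0))
            positive.setdefault(label, np.empty(0, dtype=bool))
        return ReplicateResult(recovery, positive, float("nan"), False, extinct=True)

    recovery[selfed_label] = recovery_percentages(selfed, targets)
    positive[selfed_label] = positive_mask(selfed, targets, "selfed")
    pos = positive[selfed_label]
    if pos.any():
        best = float(recovery[selfed_label][pos].max())
    else:
        best = float("nan")
    success = bool(pos.any() and best >= cfg.success_threshold)
    return ReplicateResult(recovery, positive, best, success)


def _replicate_rngs(cfg: ProgramConfig, rep: int):
    bc1_ss = np.random.SeedSequence([cfg.seed, rep, 0])
    method_ss = np.random.SeedSequence([cfg.seed, rep, 1, _METHOD_CODE[cfg.method]])
    return np.random.default_rng(method_ss), np.random.default_rng(bc1_ss)


def _one_replicate(cfg, donor, rp, recomb, targets, rep):
    rng, bc1_rng = _replicate_rngs(cfg, rep)
    return run_program(cfg, donor, rp, recomb, targets, rng, bc1_rng=bc1_rng)


def run_replicates(
    cfg: ProgramConfig,
    donor: Genotype,
    rp: Genotype,
    recomb: RecombMap,
    targets: TargetSet,
    n_jobs: int = 1,
) -> List[ReplicateResult]:
    """Run ``cfg.replicates`` independent replicates, deterministically seeded.

    Replicate ``i`` uses streams derived from ``(cfg.seed, i)``; the BC1
    stream ignores the method, so runs differing only in ``cfg.method`` are
    paired on identical BC1 populations.  With ``n_jobs > 1`` replicates run
    in parallel worker processes; results are independent of ``n_jobs``.
    """
    reps = range(cfg.replicates)
    if n_jobs > 1:
        from joblib import Parallel, delayed

        return Parallel(n_jobs=n_jobs)(
            delayed(_one_replicate)(cfg, donor, rp, recomb, targets, i) for i in reps
        )
    return [_one_replicate(cfg, donor, rp, recomb, targets, i) for i in reps]


def success_probability(results: Sequence[ReplicateResult], threshold: float) -> float:
    """Fraction of replicates whose best homozygous-positive BCTF2 individual
    reached ``threshold`` percent background recovery."""
    if len(results) == 0:
        raise ValueError("need at least one replicate")
    best = np.array([r.bctf2_max_recovery for r in results])
    with np.errstate(invalid="ignore"):
        return float(np.mean(np.where(np.isnan(best), False, best >= threshold)))


def summarize_generation(
    results: Sequence[ReplicateResult], generation: str, top_k: int = 10
) -> pd.DataFrame:
    """Per-replicate recovery summary of the positive individuals.

    Columns: replicate, n_positive, min/mean/max recovery, mean of the top
    ``top_k`` (over however many positives exist, flagged by ``top_k_n``).
    Replicates without positive individuals are excluded with a warning.
    """
    rows = []
    for i, res in enumerate(results):
        if generation not in res.recovery:
            raise KeyError(f"no generation {generation!r} in replicate {i}")
        rec = res.recovery[generation][res.positive[generation]]
        if rec.size == 0:
            warnings.warn(
                f"replicate {i} has no positive individuals in {generation}; excluded",
                stacklevel=2,
            )
            continue
        top = np.sort(rec)[::-1][:top_k]
        rows.append(
            {
                "replicate": i,
                "n_positive": int(rec.size),
                "min": float(rec.min()),
                "mean": float(rec.mean()),
                "max": float(rec.max()),
                f"top{top_k}_mean": float(top.mean()),
                f"top{top_k}_n": int(top.size),
            }
        )
    return pd.DataFrame(rows)


def max_recovery_ecdf(results: Sequence[ReplicateResult], generation: str):
    """Empirical CDF of the per-replicate maximum recovery among positives.

    Returns ``(values, cumulative_fraction)``: the point ``(x, F)`` means a
    fraction ``F`` of replicates achieved a maximum recovery <= ``x``.
    """
    maxima = []
    for res in results:
        rec = res.recovery[generation][res.positive[generation]]
        if rec.size:
            maxima.append(rec.max())
    values = np.sort(np.asarray(maxima, dtype=float))
    frac = np.arange(1, values.size + 1) / values.size
    return values, frac
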