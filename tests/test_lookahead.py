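"""Tests of the look-ahead Monte Carlo score against analytic limits."""

import numpy as np
import pytest

import introgress as ig
from introgress.lookahead import simulate_lookahead_path


def intact_chromosome_case(L=12, target_loci=(2, 5, 8)):
    """Candidate with one fully desirable chromosome, RP haplotype on the
    other, and no recombination anywhere: every look-ahead path reproduces
    the candidate, and selfing is a pure single-block Mendelian experiment."""
    targets = ig.TargetSet(list(target_loci))
    rp_hap = np.ones(L, dtype=np.uint8)
    rp_hap[list(target_loci)] = 0
    rp = ig.Genotype.homozygous(rp_hap)
    candidate = ig.Genotype.from_haplotypes(np.ones(L, dtype=np.uint8), rp_hap)
    rmap = ig.RecombMap.uniform(L, 0.0)
    return candidate, rp, rmap, targets


class TestConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"rounds": 0},
            {"selfing_progeny": 0},
            {"success_threshold": 0.0},
            {"success_threshold": 101.0},
            {"max_gamete_attempts": 0},
            {"target_generation": 0},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ig.LookaheadConfig(**kwargs)

    def test_defaults(self):
        cfg = ig.LookaheadConfig()
        assert (cfg.rounds, cfg.selfing_progeny) == (50, 200)
        assert cfg.success_threshold == 95.0
        assert cfg.max_gamete_attempts == 200


class TestSimulatePath:
    def test_non_positive_candidate_rejected(self, rng):
        candidate, rp, rmap, targets = intact_chromosome_case()
        bad = ig.Genotype.homozygous(rp.haplotype(0))  # lacks the targets
        with pytest.raises(ValueError):
            simulate_lookahead_path(bad, rp, rmap, 1, ig.LookaheadConfig(), targets, rng)

    def test_generation_past_deadline_rejected(self, rng):
        candidate, rp, rmap, targets = intact_chromosome_case()
        cfg = ig.LookaheadConfig(target_generation=2)
        with pytest.raises(ValueError):
            simulate_lookahead_path(candidate, rp, rmap, 3, cfg, targets, rng)

    def test_unlucky_gamete_budget_marks_path_failed(self):
        # With a single attempt per step and three unlinked heterozygous
        # targets, most paths fail to find a positive gamete (p = 1/8 each).
        candidate, rp, _, targets = intact_chromosome_case()
        rmap = ig.RecombMap.uniform(candidate.L, 0.5)
        cfg = ig.LookaheadConfig(max_gamete_attempts=1, rounds=1, selfing_progeny=10)
        rng = np.random.default_rng(0)
        outcomes = [
            simulate_lookahead_path(candidate, rp, rmap, 1, cfg, targets, rng)
            for _ in range(200)
        ]
        failed = np.mean([o.failed for o in outcomes])
        # surviving both steps has probability (1/8)^2 = 1/64
        assert failed >= 0.9
        assert all(o.n_success == 0 and o.best_recovery == 0.0 for o in outcomes if o.failed)

    def test_at_deadline_the_candidate_itself_is_selfed(self):
        # generation == target_generation: no backcross steps at all
        candidate, rp, rmap, targets = intact_chromosome_case()
        cfg = ig.LookaheadConfig(target_generation=3, selfing_progeny=400)
        out = simulate_lookahead_path(
            candidate, rp, rmap, 3, cfg, targets, np.random.default_rng(1)
        )
        assert not out.failed
        # intact-block selfing: homozygous-positive progeny have 100% recovery
        assert out.best_recovery == pytest.approx(100.0)
        sigma = 400 * np.sqrt(0.25 * 0.75 / 400)
        assert out.n_success == pytest.approx(100, abs=4 * sigma)


class TestLmcScore:
    def test_non_positive_candidate_scores_zero(self, rng):
        _, rp, rmap, targets = intact_chromosome_case()
        assert ig.lmc_score(rp, rp, rmap, 1, ig.LookaheadConfig(), targets, rng) == 0.0

    def test_impossible_target_scores_zero_in_batch(self, rng):
        candidate, rp, rmap, targets = intact_chromosome_case()
        pop = np.stack([candidate.alleles, rp.alleles])
        scores = ig.lmc_scores(pop, rp, rmap, 1, ig.LookaheadConfig(rounds=5), targets, rng)
        assert scores[1] == 0.0 and scores[0] > 0.0

    def test_perfect_homozygote_at_deadline_scores_its_recovery(self):
        # all paths give n = K and best recovery 100 -> Q = 100 exactly
        L = 10
        targets = ig.TargetSet([4])
        perfect = ig.Genotype.homozygous(np.ones(L, dtype=np.uint8))
        rp_hap = np.ones(L, dtype=np.uint8)
        rp_hap[4] = 0
        rp = ig.Genotype.homozygous(rp_hap)
        rmap = ig.RecombMap.uniform(L, 0.1)
        cfg = ig.LookaheadConfig(rounds=1, selfing_progeny=50, target_generation=3)
        q = ig.lmc_score(perfect, rp, rmap, 3, cfg, targets, np.random.default_rng(2))
        assert q == pytest.approx(100.0)

    def test_intact_chromosome_limit_is_25(self):
        # The desirable block survives every backcross intact (r = 0), so the
        # selfed generation is a 1:2:1 single-block segregation: a quarter of
        # progeny are homozygous-positive with 100% recovery -> Q -> 25.
        candidate, rp, rmap, targets = intact_chromosome_case()
        cfg = ig.LookaheadConfig(
            rounds=200, selfing_progeny=200, success_threshold=95.0, target_generation=3
        )
        q = ig.lmc_score(candidate, rp, rmap, 1, cfg, targets, np.random.default_rng(3))
        sigma = np.sqrt(100.0**2 * 0.25 * 0.75 / cfg.selfing_progeny / cfg.rounds)
        assert q == pytest.approx(25.0, abs=3 * sigma)

    def test_score_bounded_and_reproducible(self, tiny_case):
        donor, rp, rmap, targets = (
            tiny_case["donor"],
            tiny_case["rp"],
            tiny_case["recomb"],
            tiny_case["targets"],
        )
        f1 = ig.make_f1(donor, rp)
        cfg = ig.LookaheadConfig(rounds=20)
        a = ig.lmc_score(f1, rp, rmap, 1, cfg, targets, np.random.default_rng(4))
        b = ig.lmc_score(f1, rp, rmap, 1, cfg, targets, np.random.default_rng(4))
        assert a == b
        assert 0.0 <= a <= 100.0

    def test_mean_invariant_to_rounds(self):
        # P controls only the variance of Q, not its expectation
        candidate, rp, rmap, targets = intact_chromosome_case()
        rmap = ig.RecombMap.uniform(candidate.L, 0.05)
        small = [
            ig.lmc_score(
                candidate, rp, rmap, 1,
                ig.LookaheadConfig(rounds=10, selfing_progeny=50, target_generation=3),
                targets, np.random.default_rng(100 + i),
            )
            for i in range(60)
        ]
        large = [
            ig.lmc_score(
                candidate, rp, rmap, 1,
                ig.LookaheadConfig(rounds=100, selfing_progeny=50, target_generation=3),
                targets, np.random.default_rng(500 + i),
            )
            for i in range(6)
        ]
        se = np.std(small, ddof=1) / np.sqrt(len(small)) + np.std(large, ddof=1) / np.sqrt(len(large))
        assert abs(np.mean(small) - np.mean(large)) < 4 * se + 1e-9

    def test_allelewise_dominance_orders_expected_scores(self):
        # a candidate whose genotype is allele-wise >= another's cannot have
        # a smaller expected score
        L = 10
        targets = ig.TargetSet([3, 6])
        rp_hap = np.ones(L, dtype=np.uint8)
        rp_hap[[3, 6]] = 0
        rp = ig.Genotype.homozygous(rp_hap)
        rmap = ig.RecombMap.uniform(L, 0.2)
        hi_col = np.ones(L, dtype=np.uint8)
        lo_col = hi_col.copy()
        lo_col[[1, 8]] = 0  # strictly fewer desirable background alleles
        hi = ig.Genotype.from_haplotypes(hi_col, rp_hap)
        lo = ig.Genotype.from_haplotypes(lo_col, rp_hap)
        cfg = ig.LookaheadConfig(
            rounds=100, selfing_progeny=100, success_threshold=60.0, target_generation=3
        )
        hi_q = [
            ig.lmc_score(hi, rp, rmap, 1, cfg, targets, np.random.default_rng(1000 + i))
            for i in range(10)
        ]
        lo_q = [
            ig.lmc_score(lo, rp, rmap, 1, cfg, targets, np.random.default_rng(2000 + i))
            for i in range(10)
        ]
        se = np.std(hi_q, ddof=1) / np.sqrt(10) + np.std(lo_q, ddof=1) / np.sqrt(10)
        assert np.mean(hi_q) >= np.mean(lo_q) - 2 * se

    def test_batch_kernel_agrees_with_reference_path_simulator(self):
        # the compiled population kernel and the plain NumPy single-path
        # routine estimate the same expectation
        L = 12
        targets = ig.TargetSet([2, 5, 8])
        rp_hap = np.ones(L, dtype=np.uint8)
        rp_hap[[2, 5, 8]] = 0
        rp = ig.Genotype.homozygous(rp_hap)
        rng = np.random.default_rng(3)
        rmap = ig.generate_recomb_map(L, 2, rng)
        col = rng.integers(0, 2, L).astype(np.uint8)
        col[[2, 5, 8]] = 1
        candidate = ig.Genotype.from_haplotypes(col, rp_hap)
        cfg = ig.LookaheadConfig(
            rounds=1, selfing_progeny=100, success_threshold=60.0, target_generation=3
        )
        ref = []
        for _ in range(2000):
            out = simulate_lookahead_path(candidate, rp, rmap, 1, cfg, targets, rng)
            ref.append(0.0 if out.failed else out.n_success / 100 * out.best_recovery)
        kernel_cfg = ig.LookaheadConfig(
            rounds=40, selfing_progeny=100, success_threshold=60.0, target_generation=3
        )
        ker = [
            ig.lmc_score(candidate, rp, rmap, 1, kernel_cfg, targets, np.random.default_rng(i))
            for i in range(50)
        ]
        se = np.std(ref, ddof=1) / np.sqrt(len(ref)) + np.std(ker, ddof=1) / np.sqrt(len(ker))
        assert np.mean(ref) == pytest.approx(np.mean(ker), abs=4 * se)
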