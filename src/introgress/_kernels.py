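"""Numba-compiled inner loops for the look-ahead Monte Carlo score.

Scoring a whole backcross population look-ahead style is the computational
bottleneck of the simulator: every candidate spawns P descendant paths, each
ending in a selfed evaluation population of K progeny.  The kernel below
keeps that affordable by collapsing each candidate to its *segregating* loci
— the loci where anything can still differ from the recurrent parent, i.e.
where the candidate is heterozygous or carries a non-RP allele.  Outside
that set every descendant is fixed at the RP allele, so those loci
contribute a constant to recovery and need not be simulated.

The collapse is exact under the no-interference Markov chain: the effective
recombination fraction between two retained loci separated by intervals
``k`` is ``r_eff = 0.5 * (1 - prod_k (1 - 2 r_k))`` (the probability of an
odd number of switches).  A chromosome boundary (r = 0.5) inside the gap
makes ``r_eff = 0.5`` exactly.
"""

import numpy as np
from numba import njit

__all__ = ["lmc_scores_kernel"]


@njit(cache=True)
def _draw_gamete(a, b, r_eff, out):
    """One gamete from chromosome pair (a, b) under the collapsed chain."""
    src = 0 if np.random.random() < 0.5 else 1
    for p in range(a.size):
        if p > 0 and np.random.random() < r_eff[p - 1]:
            src = 1 - src
        out[p] = a[p] if src == 0 else b[p]


@njit(cache=True)
def _score_one(
    c1,
    c2,
    rp,
    r,
    is_target,
    n_bc_steps,
    rounds,
    K,
    threshold,
    attempt_cap,
    n_background,
):
    L = c1.size

    # ---- collapse to segregating loci -------------------------------------
    idx = np.empty(L, np.int64)
    n_h = 0
    fixed_bg2 = 0.0  # background alleles contributed by fixed loci (x2)
    for l in range(L):
        variable = (c1[l] != c2[l]) or (c1[l] != rp[l])
        if is_target[l]:
            if c1[l] == 0 and c2[l] == 0:
                return 0.0  # can never transmit this target allele
            if variable:
                idx[n_h] = l
                n_h += 1
            # else fixed desirable on both copies and on the RP side
        elif variable:
            idx[n_h] = l
            n_h += 1
        else:
            fixed_bg2 += 2.0 * c1[l]

    r_eff = np.empty(max(n_h - 1, 0))
    for j in range(n_h - 1):
        prod = 1.0
        for k in range(idx[j], idx[j + 1]):
            prod *= 1.0 - 2.0 * r[k]
        r_eff[j] = 0.5 * (1.0 - prod)

    a1 = np.empty(n_h, np.uint8)
    a2 = np.empty(n_h, np.uint8)
    rp_h = np.empty(n_h, np.uint8)
    tgt_h = np.empty(n_h, np.bool_)
    for j in range(n_h):
        l = idx[j]
        a1[j] = c1[l]
        a2[j] = c2[l]
        rp_h[j] = rp[l]
        tgt_h[j] = is_target[l]

    denom = 2.0 * n_background
    g1 = np.empty(n_h, np.uint8)
    g2 = np.empty(n_h, np.uint8)
    w1 = np.empty(n_h, np.uint8)
    w2 = np.empty(n_h, np.uint8)

    # ---- simulate P descendant paths --------------------------------------
    q_total = 0.0
    for _ in range(rounds):
        for j in range(n_h):
            w1[j] = a1[j]
            w2[j] = a2[j]
        failed = False
        for _step in range(n_bc_steps):
            found = False
            for _att in range(attempt_cap):
                _draw_gamete(w1, w2, r_eff, g1)
                ok = True
                for j in range(n_h):
                    if tgt_h[j] and g1[j] == 0:
                        ok = False
                        break
                if ok:
                    found = True
                    break
            if not found:
                failed = True
                break
            for j in range(n_h):
                w1[j] = g1[j]
                w2[j] = rp_h[j]
        if failed:
            continue  # exhausted the gamete budget: path contributes 0

        n_success = 0
        best = 0.0
        for _k in range(K):
            _draw_gamete(w1, w2, r_eff, g1)
            _draw_gamete(w1, w2, r_eff, g2)
            positive = True
            for j in range(n_h):
                if tgt_h[j] and (g1[j] == 0 or g2[j] == 0):
                    positive = False
                    break
            if not positive:
                continue
            s = fixed_bg2
            for j in range(n_h):
                if not tgt_h[j]:
                    s += g1[j] + g2[j]
            recovery = 100.0 * s / denom
            if recovery > best:
                best = recovery
            if recovery >= threshold:
                n_success += 1
        q_total += (n_success / K) * best
    return q_total / rounds


@njit(cache=True)
def lmc_scores_kernel(
    pop,
    rp,
    r,
    is_target,
    n_bc_steps,
    rounds,
    K,
    threshold,
    attempt_cap,
    n_background,
    seeds,
):
    """Look-ahead Monte Carlo Q for every individual of ``pop`` (N, L, 2).

    Each candidate is scored on its own seeded stream (``seeds[i]``) so that
    scores are independent across candidates and reproducible.
    Non-positive candidates score 0.
    """
    N = pop.shape[0]
    L = pop.shape[1]
    out = np.zeros(N)
    c1 = np.empty(L, np.uint8)
    c2 = np.empty(L, np.uint8)
    for i in range(N):
        np.random.seed(seeds[i])
        for l in range(L):
            c1[l] = pop[i, l, 0]
            c2[l] = pop[i, l, 1]
        out[i] = _score_one(
            c1,
            c2,
            rp,
            r,
            is_target,
            n_bc_steps,
            rounds,
            K,
            threshold,
            attempt_cap,
            n_background,
        )
    return out
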