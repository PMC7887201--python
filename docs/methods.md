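# Methods

## The breeding model

The simulator models a diploid trait-introgression program on `L` biallelic
markers.  Genotypes are `L x 2` binary matrices whose entries flag allele
*desirability* — 1 for the allele the breeder wants at that position (the
recurrent parent's allele in the background, the donor's allele at the `Z`
target loci).  Both founding parents are fully homozygous inbreds, so the
F1 is deterministic: one chromosome set from each parent.

Meiosis is a first-order two-state Markov chain along the marker order: the
transmitted copy at the first locus is uniform, and between adjacent loci
`l` and `l+1` the transmitting copy switches with probability `r[l]`.  This
is the standard no-crossover-interference model implied by a pairwise
recombination-frequency parameterisation; `r[l] = 0.5` makes neighbours
assort independently and is used to encode chromosome boundaries, so a
single flat locus axis suffices and no per-chromosome container exists.
Interference models (chi-square/gamma), sex-specific maps and mutation are
out of scope.

Each backcross generation, target-positive individuals (at least one
desirable allele at every target locus) are ranked by the configured score
and the top `crosses_per_generation` are each mated to the RP with
`progeny_per_cross` offspring.  Because the RP is homozygous its gamete is
its haplotype, drawn without simulation — exact and fast.  After the final
backcross the selected parents are selfed once to form the evaluation
generation, where positivity requires homozygosity at every target.
Ties in ranking are broken by a seeded uniform draw; if fewer positives than
parents exist all positives are used (with a warning), and a generation with
no positives aborts the replicate as a failure.

## Selection scores

* **Background GEBV** — the count of desirable background alleles under
  uniform marker weights (a weight-vector hook exists but defaults to
  ones).  Linkage-blind; the weakest baseline.
* **PCV** — the probability that a single meiosis yields a gamete desirable
  at *every* locus.  Computed by an exact forward pass over the two-state
  chain: state weights start at `(½·[G[1,1]=1], ½·[G[1,2]=1])`, are mixed
  with stay/switch probabilities each step, and states whose next-locus
  allele is undesirable are zeroed.  With ~200 heterozygous loci the raw
  value underflows doubles, so the pass renormalises every step and
  accumulates the log; ranking uses the log scale, which is all selection
  needs.  Equivalence with brute-force enumeration over all `2^L`
  inheritance paths is asserted in the tests to 1e-12 on hundreds of random
  instances.
* **LMC** — for each candidate at generation `t`, simulate `P` independent
  descendant paths: per backcross step, rejection-sample a target-positive
  gamete (cap `max_gamete_attempts`; exhaustion marks the path failed,
  contributing 0 — a deliberate choice, since a candidate that cannot
  transmit its targets should be penalised), pair it with the RP haplotype;
  at generation `T` self the terminal individual into `K` progeny, count
  the homozygous-positive ones at or above the recovery threshold (`n`) and
  record the best homozygous-positive recovery (`v`); average `(n/K)·v`.
  Rejection sampling is distributionally equivalent to the batch variant
  ("simulate many gametes, keep positives, pick one uniformly") in the
  large-batch limit, and bounds the per-step cost.

### Parameter defaults

| parameter | default | meaning |
|---|---|---|
| `n_backcross` (T) | 3 | backcross generations before selfing |
| `crosses_per_generation` | 2 (scenario 1) / 6 (scenario 2) | parents selected = crosses made |
| `progeny_per_cross` | 200 | offspring per cross and per selfing |
| `replicates` | 100 | independent program replicates |
| `success_threshold` | 95 % | recovery defining "success" in the selfed generation |
| LMC `rounds` (P) | 50 | descendant paths per candidate |
| LMC `selfing_progeny` (K) | 200 | selfed evaluation population per path (one cross's worth) |
| LMC `max_gamete_attempts` | 200 | rejection-sampling cap per backcross step |

The scenario presets (2 vs 6 crosses, 200 progeny each, so 400 vs 1200
individuals per generation) represent limited vs moderate resource
allocations, spread evenly across generations.  P and K are not pinned down
by any external constraint; K defaults to one selfing's progeny count and P
to a value at which candidate rankings are stable — the test suite checks
that the expected score is invariant to P and that doubling it only shrinks
variance.  The look-ahead's `target_generation` always follows the
program's `n_backcross`.  Exactly one terminal individual is selfed per
look-ahead path, and exactly the selected BCT parents are selfed in the
program itself; both are the minimal-assumption readings of a backcross
pipeline ending "with a selfing", and both are configuration-visible
choices rather than hidden constants.

## Randomness and reproducibility

All stochastic operations take a `numpy.random.Generator`.  The replicate
runner derives every stream from `SeedSequence((seed, replicate, purpose))`;
the stream that builds BC1 ignores the selection method, so runs differing
only in method share identical BC1 populations and can be compared pairwise
— the comparison tests exploit this pairing.  Inside the LMC batch kernel
each candidate receives its own integer seed, keeping candidate scores
independent and the whole pipeline bit-reproducible for a given seed,
including under replicate-level parallelism.

## Numerical and performance choices

The LMC kernel (numba-compiled) collapses each candidate to its
*segregating* loci — positions where the candidate is heterozygous or
differs from the RP.  All other loci are fixed at the RP allele in every
descendant and contribute a constant to recovery.  The collapsed chain uses
the exact two-point recombination fraction
`r_eff = ½(1 − Π_k (1 − 2 r_k))` across the skipped intervals, which is the
probability of an odd number of switches; a chromosome boundary inside the
gap gives `r_eff = 0.5` exactly, so the collapse introduces no
approximation.  A plain-NumPy single-path routine
(`simulate_lookahead_path`) implements the same procedure without the
collapse and is statistically cross-checked against the kernel in the test
suite.  Probability-1/0 degeneracies (homozygous candidates, impossible
targets) short-circuit before any sampling.

## What the synthetic data does and does not show

The generator emulates the structure of empirical maize introgression data:
homozygous parent pairs at Nei similarities 0.58/0.72/0.89 on 195/173/172
markers, three donor targets, ten chromosomes (the maize karyotype).  For
homozygous binary inbreds Nei's identity reduces to the match proportion,
counted over *all* loci including the Z always-mismatching targets, so the
feasible maximum is `(L − Z)/L`.  Within-chromosome recombination
frequencies are i.i.d. uniform on [0, 0.1) (mean 0.05, a ~5 cM marker
spacing); target loci are placed at even spacing, landing on distinct
chromosomes.

This map is exchangeable and moderately loose, unlike a real genetic map
with clustered tightly-linked blocks and targets potentially sitting in
low-recombination regions (linkage drag).  Background recovery is therefore
*easier* here than on empirical data: absolute success probabilities at the
95 % threshold saturate near 1 for all methods, and method differences show
up mainly below the threshold and in the recovery distributions.  Passing
the directional tests (recovery improves BC1→BC3, more resources never
hurt, LMC not worse than PCV not worse than GEBV on success probability)
demonstrates the machinery and the qualitative ordering under these
conditions; it does not reproduce empirical success probabilities, which
depend on the real genotypes, maps and unpublished look-ahead
hyper-parameters.  The comparison study in the tests and acceptance script
uses the moderate-similarity preset with 30 shared-BC1 replicates per cell,
a size at which the directional effects are resolvable in minutes on one
core.

## Known limitations

* Single donor, uniform resource allocation across generations; optimising
  budget allocation or multi-donor pyramiding is out of scope.
* GEBV here is the uniform-weight allele count, not a trained marker-effect
  predictor; no phenotypes are modelled.
* The LMC score's absolute value depends on its threshold: above-threshold
  discrimination relies only on the `v` (best-recovery) factor, so in easy
  settings LMC optimises success probability rather than maximum recovery.
* File formats carry desirability-coded genotypes; mapping raw marker data
  (e.g. VCF alleles) onto desirability must happen upstream.
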