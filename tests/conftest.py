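import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def tiny_case():
    """A small fully-specified introgression problem (L=12, 2 chromosomes)."""
    import introgress as ig

    L = 12
    targets = ig.TargetSet([2, 7])
    rp_hap = np.ones(L, dtype=np.uint8)
    rp_hap[targets.loci] = 0
    donor_hap = np.zeros(L, dtype=np.uint8)
    donor_hap[targets.loci] = 1
    donor_hap[[0, 4, 9]] = 1  # some shared background
    r = np.full(L - 1, 0.1)
    r[5] = 0.5  # chromosome boundary
    return {
        "L": L,
        "targets": targets,
        "rp": ig.Genotype.homozygous(rp_hap),
        "donor": ig.Genotype.homozygous(donor_hap),
        "recomb": ig.RecombMap(r),
    }


def random_genotype(rng, L, force_target_loci=None):
    """Random diploid genotype; optionally desirable at given loci (copy 1)."""
    import introgress as ig

    alleles = rng.integers(0, 2, size=(L, 2))
    if force_target_loci is not None:
        alleles[np.asarray(force_target_loci), 0] = 1
    return ig.Genotype(alleles)
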