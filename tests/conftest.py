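import numpy as np
import pytest

from chordwgs import CNProfile, GenomeBuild, Segment, SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def hg19():
    return GenomeBuild.hg19()


def make_toy_genome(n_chroms=2, chrom_len=1_000_000, cen=(450_000, 550_000)):
    """Small genome for brute-force oracles (per-bp computations stay cheap)."""
    names = [f"chr{i + 1}" for i in range(n_chroms)]
    return GenomeBuild(
        chrom_names=names,
        chrom_lengths={c: chrom_len for c in names},
        arm_bounds={c: {"p": (0, cen[0]), "q": (cen[1], chrom_len)} for c in names},
        autosome_flags={c: True for c in names},
    )


@pytest.fixture
def toy_genome():
    return make_toy_genome()


def uniform_profile(sample_id, genome, tcn=2, minor=1):
    segs = [
        Segment(sample_id, chrom, start, end, tcn, minor)
        for chrom, arm, start, end in genome.arms()
    ]
    return CNProfile(sample_id, segs)


@pytest.fixture(scope="session")
def small_cohort():
    """A 40-sample synthetic cohort shared across read-only tests."""
    return simulate_cohort(SimulationConfig(n_samples=40, seed=17))
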