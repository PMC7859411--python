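"""Interleaving, oscillation, and the chromothripsis statistical tests."""

from itertools import combinations, product
from math import comb, factorial

import numpy as np
import pytest
from scipy import stats

from chordwgs import (
    ChromothripsisConfig,
    CNProfile,
    Segment,
    SVRecord,
    breakpoint_enrichment_test,
    classify,
    exponential_spacing_test,
    fragment_joins_test,
    interleaved_clusters,
    max_oscillation,
)
from chordwgs.chromothripsis import interleaves

from conftest import make_toy_genome


def sv(pos1, pos2, sample="S1", chrom="chr1", strands=("+", "-")):
    return SVRecord(sample, chrom, pos1, strands[0], chrom, pos2, strands[1])


class TestInterleaving:
    def test_overlapping_non_nested(self):
        clusters = interleaved_clusters([sv(1, 10), sv(5, 20)], "chr1")
        assert [len(c) for c in clusters] == [2]

    def test_nested_not_interleaved(self):
        clusters = interleaved_clusters([sv(1, 100), sv(10, 20)], "chr1")
        assert sorted(len(c) for c in clusters) == [1, 1]

    def test_disjoint_not_interleaved(self):
        clusters = interleaved_clusters([sv(1, 10), sv(20, 30)], "chr1")
        assert sorted(len(c) for c in clusters) == [1, 1]

    def test_chained_intervals_single_cluster(self):
        # 7 pairwise-chained intervals; brute-force pair check agrees
        svs = [sv(10 * i, 10 * i + 15) for i in range(7)]
        clusters = interleaved_clusters(svs, "chr1")
        assert [len(c) for c in clusters] == [7]
        edges = sum(interleaves(a, b) for a, b in combinations(svs, 2))
        assert edges == 6  # consecutive pairs only

    def test_symmetry_and_order_invariance(self):
        rng = np.random.default_rng(0)
        svs = [sv(int(a), int(a) + int(b) + 1)
               for a, b in zip(rng.integers(0, 1000, 12), rng.integers(1, 500, 12))]
        for a, b in combinations(svs, 2):
            assert interleaves(a, b) == interleaves(b, a)
        sizes = sorted(len(c) for c in interleaved_clusters(svs, "chr1"))
        rng.shuffle(svs)
        assert sorted(len(c) for c in interleaved_clusters(svs, "chr1")) == sizes


def brute_force_oscillation(tcn):
    """Longest contiguous window alternating strictly between two values."""
    best = 0
    for i in range(len(tcn)):
        for j in range(i, len(tcn)):
            w = tcn[i : j + 1]
            if len(set(w)) <= 2 and all(a != b for a, b in zip(w, w[1:])):
                best = max(best, len(w))
    return best


class TestOscillation:
    def _profile(self, tcns):
        segs = [
            Segment("S1", "chr1", 100 * i, 100 * (i + 1), t, min(1, t // 2))
            for i, t in enumerate(tcns)
        ]
        return CNProfile("S1", segs)

    @pytest.mark.parametrize(
        "tcns",
        [
            [2, 1, 2, 1, 2, 1, 2],
            [2, 2, 2],
            [2, 1, 2, 3, 2, 3, 2, 3, 2],
            [4, 2, 4, 2, 1, 2, 1],
            [0, 1, 0, 1, 0],
        ],
    )
    def test_matches_brute_force(self, tcns):
        prof = self._profile(tcns)
        expected = brute_force_oscillation(tcns)
        assert max_oscillation(prof, "chr1", 0, 100 * len(tcns)) == expected

    def test_seven_segment_pattern(self):
        prof = self._profile([2, 1, 2, 1, 2, 1, 2])
        assert max_oscillation(prof, "chr1", 0, 700) == 7

    def test_constant_is_one(self):
        prof = self._profile([3, 3, 3, 3])
        assert max_oscillation(prof, "chr1", 0, 400) == 1

    def test_region_restriction(self):
        prof = self._profile([2, 1, 2, 1, 5, 5, 5])
        assert max_oscillation(prof, "chr1", 0, 400) == 4


def enumeration_multinomial_p(counts):
    """Full-enumeration exact multinomial GOF oracle (uniform null)."""
    counts = tuple(counts)
    n, k = sum(counts), len(counts)

    def prob(c):
        coef = factorial(n)
        for ci in c:
            coef //= factorial(ci)
        return coef / k**n

    p_obs = prob(counts)
    total = 0.0
    for c in product(range(n + 1), repeat=k - 1):
        if sum(c) > n:
            continue
        full = (*c, n - sum(c))
        if prob(full) <= p_obs * (1 + 1e-12):
            total += prob(full)
    return total


class TestFragmentJoins:
    def _cluster(self, counts):
        strands = [("+", "-"), ("-", "+"), ("+", "+"), ("-", "-")]
        svs = []
        pos = 0
        for count, st in zip(counts, strands):
            for _ in range(count):
                svs.append(sv(pos, pos + 10, strands=st))
                pos += 100
        return svs

    def test_perfect_fit_p_one(self):
        assert fragment_joins_test(self._cluster([3, 3, 3, 3])) == pytest.approx(1.0)

    def test_extreme_skew_small_p(self):
        assert fragment_joins_test(self._cluster([12, 0, 0, 0])) < 0.001

    @pytest.mark.parametrize("counts", [(5, 1, 1, 1), (4, 2, 1, 1), (3, 3, 2, 0), (8, 0, 0, 0)])
    def test_exact_p_equals_enumeration_oracle(self, counts):
        p = fragment_joins_test(self._cluster(list(counts)))
        assert p == pytest.approx(enumeration_multinomial_p(counts), rel=1e-9)

    def test_large_n_uses_chi_square(self):
        counts = [20, 4, 4, 4]
        p = fragment_joins_test(self._cluster(counts))
        n = sum(counts)
        stat = sum((c - n / 4) ** 2 / (n / 4) for c in counts)
        assert p == pytest.approx(float(stats.chi2.sf(stat, df=3)), rel=1e-12)

    def test_too_small_cluster_raises(self):
        with pytest.raises(ValueError):
            fragment_joins_test(self._cluster([1, 1, 0, 0]))


class TestEnrichment:
    def test_all_breakpoints_on_small_chromosome(self):
        g = make_toy_genome(n_chroms=20, chrom_len=1_000_000)  # each chrom = 5%
        svs = [sv(10 * i, 10 * i + 5, chrom="chr1") for i in range(10)]  # 20 breakends
        p = breakpoint_enrichment_test(svs, "chr1", g)
        assert p == pytest.approx(0.05**20, rel=1e-9)

    def test_proportional_breakpoints_null(self):
        g = make_toy_genome(n_chroms=4, chrom_len=1_000_000)
        rng = np.random.default_rng(1)
        svs = []
        for chrom in g.chrom_names:
            for _ in range(25):
                a = int(rng.integers(0, 900_000))
                svs.append(sv(a, a + 10, chrom=chrom))
        p = breakpoint_enrichment_test(svs, "chr1", g)
        assert 0.05 < p  # no enrichment signal

    def test_zero_breakpoints_p_one(self):
        g = make_toy_genome(n_chroms=2)
        svs = [sv(10, 100, chrom="chr2")]
        assert breakpoint_enrichment_test(svs, "chr1", g) == 1.0


class TestExponentialSpacing:
    def test_regular_grid_rejected(self):
        bp = np.arange(50) * 1000
        p, tested = exponential_spacing_test(bp)
        assert tested and p < 1e-6

    def test_exponential_gaps_level_is_conservative(self):
        """Under i.i.d. exponential gaps the test holds its nominal level.

        The rate is estimated from the same gaps, so the p-values are
        stochastically conservative (Lilliefors effect) rather than exactly
        uniform; the operational guarantee is that truly exponential spacing
        is rejected at most at the nominal rate.
        """
        pvals = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            gaps = rng.exponential(1000, size=60)
            bp = np.cumsum(gaps)
            p, _ = exponential_spacing_test(bp)
            pvals.append(p)
        pvals = np.array(pvals)
        assert (pvals < 0.05).mean() <= 0.05
        assert pvals.min() > 0.0 and pvals.max() <= 1.0

    def test_two_breakpoints_no_test(self):
        p, tested = exponential_spacing_test([100, 200])
        assert p == 1.0 and not tested


class TestClassify:
    def _planted(self, seed=0):
        from chordwgs import GenomeBuild, SimulationConfig, simulate_cn_profile
        from chordwgs.simulate import simulate_sv_set

        genome = GenomeBuild.hg19()
        rng = np.random.default_rng(seed)
        cfg = SimulationConfig()
        prof = simulate_cn_profile(4, genome, rng, "S1", cfg)
        svs, prof, regions = simulate_sv_set(
            prof, cfg, rng, genome, plant_chromothripsis=True
        )
        return svs, prof, regions, genome

    def test_planted_event_detected_criteria_set_one(self):
        svs, prof, regions, genome = self._planted(seed=42)
        calls = classify("S1", svs, prof, genome)
        hits = [
            c for c in calls
            if c.high_confidence and c.criteria_set == 1 and c.chrom == regions[0][0]
        ]
        assert hits, [c for c in calls if c.chrom == regions[0][0]]

    def test_six_interleaved_but_short_oscillation_not_called(self, hg19):
        # strong interleaved cluster with a skewed join mix on a flat profile
        svs = [sv(1_000_000 + 10_000 * i, 1_500_000 + 10_000 * i) for i in range(8)]
        prof = CNProfile("S1", [Segment("S1", "chr1", 0, 249_250_621, 2, 1)])
        calls = classify("S1", svs, prof, hg19)
        assert calls and not any(c.high_confidence for c in calls)
        assert all(c.max_oscillation_run < 7 for c in calls)

    def test_three_intra_joins_cannot_reach_alpha(self):
        """With only 3 joins the exact multinomial floor is 4/64 ≈ 0.0625, so
        a 3-SV cluster can never pass the joins criterion at alpha 0.05."""
        assert enumeration_multinomial_p((3, 0, 0, 0)) == pytest.approx(4 / 64)
        cluster = [sv(0, 100), sv(50, 150), sv(120, 200)]
        assert fragment_joins_test(cluster) == pytest.approx(4 / 64)

    def test_criteria_set_two_inter_chromosomal_route(self, hg19):
        # 4 interleaved intra (all deletion-like joins) + 4 translocations
        # into the region + 9-segment oscillation
        intra = [sv(10_000_000 + 4_000_000 * i, 20_000_000 + 4_000_000 * i,
                    strands=("+", "-")) for i in range(4)]
        tra = [
            SVRecord("S1", "chr1", 12_000_000 + i * 1_000_000, "+", "chr5", 1_000_000 + i, "-")
            for i in range(4)
        ]
        tcns = [2, 1, 2, 1, 2, 1, 2, 1, 2]
        segs = [
            Segment("S1", "chr1", 10_000_000 + 3_000_000 * i, 10_000_000 + 3_000_000 * (i + 1), t, min(1, t // 2))
            for i, t in enumerate(tcns)
        ]
        segs.append(Segment("S1", "chr1", 0, 10_000_000, 2, 1))
        prof = CNProfile("S1", segs)
        calls = classify("S1", intra + tra, prof, hg19)
        region_calls = [c for c in calls if c.n_intra_interleaved == 4]
        assert region_calls and region_calls[0].n_inter_sv == 4
        assert region_calls[0].p_fragment_joins == pytest.approx(
            enumeration_multinomial_p((4, 0, 0, 0)), rel=1e-9
        )
        assert region_calls[0].high_confidence and region_calls[0].criteria_set == 2

    def test_joins_direction_flip(self, hg19):
        svs, prof, regions, genome = self._planted(seed=42)
        flipped = ChromothripsisConfig(joins_direction="greater")
        calls = classify("S1", svs, prof, genome, flipped)
        assert not any(
            c.high_confidence for c in calls if c.chrom == regions[0][0]
        )
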