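"""High-confidence chromothripsis detection from SVs and CN segments.

Chromothripsis shatters a chromosomal region and rejoins the fragments,
leaving (a) clusters of *interleaved* intra-chromosomal SVs — breakpoint
intervals that overlap without nesting — and (b) copy number oscillating
between two states across many adjacent segments.  A region is called
high-confidence when it satisfies one of two criteria sets:

1. >= 6 interleaved intra-chromosomal SVs, >= 7 adjacent segments
   oscillating between two CN states, fragment-joins test p < 0.05, and
   either the chromosomal breakpoint-enrichment test or the exponential
   breakpoint-spacing test p < 0.05; or
2. >= 3 interleaved intra-chromosomal SVs and >= 4 inter-chromosomal SVs
   with a breakend in the region, >= 7 oscillating segments, and the
   fragment-joins test p < 0.05.

The fragment-joins statistic is a goodness-of-fit of the four
intra-chromosomal join classes (deletion-like, duplication-like,
head-to-head, tail-to-tail) against equal proportions — chi-square with
3 df for n >= 20 joins, exact multinomial below that.  The criterion
direction (p < 0.05 qualifies) is applied as stated; ``joins_direction``
can flip it to require consistency with random joining instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import lgamma

import numpy as np
from scipy import stats

from .core import CNProfile, GenomeBuild, SVRecord

JOIN_CLASSES = ("DEL-like", "DUP-like", "h2hINV", "t2tINV")


@dataclass
class ChromothripsisConfig:
    min_intra_set1: int = 6
    min_intra_set2: int = 3
    min_inter_set2: int = 4
    min_oscillation: int = 7
    alpha: float = 0.05
    joins_direction: str = "less"  # "less": p < alpha qualifies; "greater": p >= alpha
    exact_multinomial_below: int = 20


@dataclass
class ChromothripsisCall:
    sample_id: str
    chrom: str
    start: int
    end: int
    n_intra_interleaved: int
    n_inter_sv: int
    max_oscillation_run: int
    p_fragment_joins: float
    p_enrichment: float
    p_exponential: float
    high_confidence: bool
    criteria_set: int  # 1, 2, or 0 for none

    def __post_init__(self) -> None:
        assert self.n_intra_interleaved >= 0 and self.n_inter_sv >= 0
        for p in (self.p_fragment_joins, self.p_enrichment, self.p_exponential):
            assert 0.0 <= p <= 1.0
        assert not self.high_confidence or self.criteria_set in (1, 2)


def interleaves(a: SVRecord, b: SVRecord) -> bool:
    """Two intra-chromosomal SVs interleave iff their breakpoint intervals
    overlap and neither contains the other."""
    if not (a.intra and b.intra) or a.chrom1 != b.chrom1:
        return False
    overlap = a.pos1 < b.pos2 and b.pos1 < a.pos2
    a_in_b = b.pos1 <= a.pos1 and a.pos2 <= b.pos2
    b_in_a = a.pos1 <= b.pos1 and b.pos2 <= a.pos2
    return overlap and not a_in_b and not b_in_a


def interleaved_clusters(svs: list[SVRecord], chrom: str) -> list[list[SVRecord]]:
    """Connected components of the interleaving graph on one chromosome.

    Clusters are returned sorted by leftmost breakpoint; order of the input
    does not matter.
    """
    intra = sorted(
        (s for s in svs if s.intra and s.chrom1 == chrom),
        key=lambda s: (s.pos1, s.pos2),
    )
    n = len(intra)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in combinations(range(n), 2):
        if interleaves(intra[i], intra[j]):
            parent[find(i)] = find(j)
    groups: dict[int, list[SVRecord]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(intra[i])
    return sorted(groups.values(), key=lambda g: min(s.pos1 for s in g))


def cluster_region(cluster: list[SVRecord]) -> tuple[int, int]:
    """Breakpoint hull of a cluster (no padding)."""
    return min(s.pos1 for s in cluster), max(s.pos2 for s in cluster) + 1


def max_oscillation(profile: CNProfile, chrom: str, start: int, end: int) -> int:
    """Longest run of adjacent segments whose total CN alternates strictly
    between exactly two values (A B A B ...), within [start, end)."""
    segs = [s for s in profile.by_chrom(chrom) if s.start < end and s.end > start]
    tcn = [s.tcn for s in segs]
    if not tcn:
        return 0
    best = run = 1
    for i in range(1, len(tcn)):
        if tcn[i] != tcn[i - 1] and (run == 1 or tcn[i] == tcn[i - 2]):
            run += 1
        elif tcn[i] != tcn[i - 1]:
            run = 2  # previous segment starts a new two-value alternation
        else:
            run = 1
        best = max(best, run)
    return best


def _exact_multinomial_p(counts: np.ndarray) -> float:
    """Exact multinomial GOF p against equal proportions: total probability of
    outcomes no more probable than the observed one (enumeration)."""
    counts = np.asarray(counts, dtype=int)
    n, k = int(counts.sum()), counts.size
    log_uniform = -n * np.log(k)

    def log_mult_coef(c: tuple[int, ...]) -> float:
        return lgamma(n + 1) - sum(lgamma(ci + 1) for ci in c)

    obs_logp = log_mult_coef(tuple(counts)) + log_uniform
    total = 0.0
    # enumerate compositions of n into k parts
    def rec(prefix: list[int], remaining: int, slots: int) -> None:
        nonlocal total
        if slots == 1:
            c = tuple(prefix + [remaining])
            lp = log_mult_coef(c) + log_uniform
            if lp <= obs_logp + 1e-12:
                total += np.exp(lp)
            return
        for v in range(remaining + 1):
            rec(prefix + [v], remaining - v, slots - 1)

    rec([], n, k)
    return min(1.0, total)


def fragment_joins_test(
    cluster: list[SVRecord], cfg: ChromothripsisConfig | None = None
) -> float:
    """GOF of intra-chromosomal join-class counts vs equal proportions."""
    cfg = cfg or ChromothripsisConfig()
    counts = np.array([sum(1 for sv in cluster if sv.sv_class == c) for c in JOIN_CLASSES])
    n = int(counts.sum())
    if n < 3:
        raise ValueError("fragment joins test needs >= 3 intra-chromosomal SVs")
    if n < cfg.exact_multinomial_below:
        return _exact_multinomial_p(counts)
    stat = ((counts - n / 4.0) ** 2 / (n / 4.0)).sum()
    return float(stats.chi2.sf(stat, df=3))


def breakpoint_enrichment_test(
    svs: list[SVRecord], chrom: str, genome: GenomeBuild
) -> float:
    """One-sided binomial tail: are breakpoints over-represented on ``chrom``
    relative to its share of the genome?"""
    breakends: list[tuple[str, int]] = []
    for s in svs:
        breakends.append((s.chrom1, s.pos1))
        breakends.append((s.chrom2, s.pos2))
    total = len(breakends)
    obs = sum(1 for c, _ in breakends if c == chrom)
    if total == 0:
        return 1.0
    p_chrom = genome.chrom_lengths[chrom] / sum(genome.chrom_lengths.values())
    return float(stats.binom.sf(obs - 1, total, p_chrom))


def exponential_spacing_test(breakpoints) -> tuple[float, bool]:
    """KS test of inter-breakpoint gaps against an exponential with the
    region's empirical rate.  Returns (p, tested); fewer than 3 breakpoints
    cannot be tested (p = 1, tested = False)."""
    bp = np.sort(np.asarray(breakpoints, dtype=float))
    if bp.size < 3:
        return 1.0, False
    gaps = np.diff(bp)
    span = bp[-1] - bp[0]
    if span <= 0:
        return 1.0, False
    scale = span / (bp.size - 1)  # 1 / rate
    res = stats.kstest(gaps, "expon", args=(0, scale))
    return float(res.pvalue), True


def _joins_pass(p: float, cfg: ChromothripsisConfig) -> bool:
    if cfg.joins_direction == "less":
        return p < cfg.alpha
    if cfg.joins_direction == "greater":
        return p >= cfg.alpha
    raise ValueError(f"joins_direction must be 'less' or 'greater', got {cfg.joins_direction!r}")


def classify(
    sample_id: str,
    svs: list[SVRecord],
    profile: CNProfile,
    genome: GenomeBuild,
    cfg: ChromothripsisConfig | None = None,
) -> list[ChromothripsisCall]:
    """Evaluate both criteria sets on every interleaved cluster of a sample.

    Clusters smaller than the weaker intra-SV requirement are skipped; all
    per-region diagnostics are emitted for inspection (there is no manual
    curation stage — the diagnostics replace it).
    """
    cfg = cfg or ChromothripsisConfig()
    sample_svs = [s for s in svs if s.sample_id == sample_id]
    calls: list[ChromothripsisCall] = []
    for chrom in sorted({s.chrom1 for s in sample_svs if s.intra}):
        for cluster in interleaved_clusters(sample_svs, chrom):
            if len(cluster) < cfg.min_intra_set2:
                continue
            start, end = cluster_region(cluster)
            n_intra = len(cluster)
            n_inter = sum(
                1 for s in sample_svs
                if not s.intra
                and ((s.chrom1 == chrom and start <= s.pos1 < end)
                     or (s.chrom2 == chrom and start <= s.pos2 < end))
            )
            osc = max_oscillation(profile, chrom, start, end)
            p_joins = fragment_joins_test(cluster, cfg)
            p_enr = breakpoint_enrichment_test(sample_svs, chrom, genome)
            region_bps = sorted(p for s in cluster for p in (s.pos1, s.pos2))
            p_exp, _ = exponential_spacing_test(region_bps)

            joins_ok = _joins_pass(p_joins, cfg)
            set1 = (
                n_intra >= cfg.min_intra_set1
                and osc >= cfg.min_oscillation
                and joins_ok
                and (p_enr < cfg.alpha or p_exp < cfg.alpha)
            )
            set2 = (
                n_intra >= cfg.min_intra_set2
                and n_inter >= cfg.min_inter_set2
                and osc >= cfg.min_oscillation
                and joins_ok
            )
            criteria = 1 if set1 else (2 if set2 else 0)
            calls.append(
                ChromothripsisCall(
                    sample_id=sample_id, chrom=chrom, start=start, end=end,
                    n_intra_interleaved=n_intra, n_inter_sv=n_inter,
                    max_oscillation_run=osc, p_fragment_joins=p_joins,
                    p_enrichment=p_enr, p_exponential=p_exp,
                    high_confidence=criteria > 0, criteria_set=criteria,
                )
            )
    return calls
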