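"""Synthetic tumor-cohort generator.

Emulates the statistical structure of a low-mutation-burden skull-base
tumor WGS cohort so every analysis stage can be exercised without
controlled-access patient data: ~80 tumors, purity 0.2–0.9, clonal SNV
VAFs near purity/2 at ~76x depth, a median of ~18 coding mutations per
tumor (TMB ~0.5/Mb over 35 Mb), five SCNA-group archetypes, ~38 background
SVs per tumor with occasional chromothripsis clusters, and exponential
proportional-hazards survival with marker-dependent hazard ratios.

The generator emits the data bundle and, separately, a truth table
(per-sample purity, SCNA group, WGD flag, marker flags, chromothripsis
regions).  Truth is written under ``truth/`` inside the output directory
and is never read by any analysis stage.

SCNA archetypes
---------------
Each group has a fixed arm plan applied with high per-arm inclusion
probability, so groups are internally coherent and mutually separable:

1. extensive gains (1q, 7p, 7q) and losses, but no losses of 4, 9, 14;
2. extensive losses (including 4, 9, 14), no gains;
3. scattered deletions (4, 9, 14q);
4. near-diploid;
5. whole-genome doubled: tcn=4/minor=2 over a 0.55–0.9 fraction of the
   autosomal genome, arms taken in a fixed order so profiles share a core.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from math import log
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    CNProfile,
    GenomeBuild,
    SampleMetadata,
    Segment,
    SVRecord,
    VariantRecord,
    write_metadata,
    write_segments,
    write_sv_bedpe,
    write_variants,
)

logger = logging.getLogger("chordwgs")

# arm plans reference GISTIC-significant arms: gains 1q/7p/7q, losses
# 1p/3/4/9/10/13q/14q/18/22q
_GAIN_ARMS = ["chr1q", "chr7p", "chr7q"]
_LOSS_ARMS_FULL = [
    "chr1p", "chr3p", "chr3q", "chr4p", "chr4q", "chr9p", "chr9q",
    "chr10p", "chr10q", "chr13q", "chr14q", "chr18p", "chr18q", "chr22q",
]
_LOSS_ARMS_NO_4_9_14 = [
    a for a in _LOSS_ARMS_FULL if a[:-1] not in ("chr4", "chr9", "chr14")
]
_LOSS_ARMS_SCATTERED = [
    "chr1p", "chr4p", "chr4q", "chr5q", "chr8p", "chr9p", "chr9q",
    "chr12q", "chr13q", "chr14q", "chr16q", "chr18p", "chr18q", "chr22q",
]

# marker gene loci (hg19 footprints)
GENE_LOCI: dict[str, tuple[str, int, int]] = {
    "PBRM1": ("chr3", 52_579_368, 52_719_866),
    "SETD2": ("chr3", 47_057_898, 47_205_467),
    "CDKN2A": ("chr9", 21_967_751, 21_995_300),
    "CDKN2B": ("chr9", 22_002_902, 22_009_280),
    "SMARCB1": ("chr22", 24_129_150, 24_176_705),
    "TBXT": ("chr6", 166_571_145, 166_582_804),
    "LYST": ("chr1", 235_824_346, 236_030_227),
}

#: focal-deletion window on 9q21.11 (hg19 band approximation)
FOCAL_9Q21_WINDOW: tuple[str, int, int] = ("chr9", 71_000_000, 71_700_000)


@dataclass
class SurvivalConfig:
    """Exponential proportional-hazards truth: h(t) = h0 * exp(beta' x).

    Baseline hazards are per month; log-HRs follow the reported marker
    effects (PBRM1+: CSS HR 4.79 / RFS 5.72; 22q deletion: CSS 5.88 /
    RFS 3.74; focal 9q21.11 deletion: RFS 3.63).  Censoring is uniform on
    the follow-up window (months).
    """

    baseline_hazard_css: float = 0.0025
    baseline_hazard_rfs: float = 0.018
    log_hr_css: dict[str, float] = field(
        default_factory=lambda: {"pbrm1_plus": log(4.79), "del22q": log(5.88)}
    )
    log_hr_rfs: dict[str, float] = field(
        default_factory=lambda: {
            "pbrm1_plus": log(5.72),
            "del22q": log(3.74),
            "del9q21_focal": log(3.63),
        }
    )
    censor_window: tuple[float, float] = (10.0, 157.0)


@dataclass
class SimulationConfig:
    """All generator tunables; the defaults are the emulated study conditions."""

    n_samples: int = 80
    purity_range: tuple[float, float] = (0.2, 0.9)
    depth_mean: float = 76.0
    normal_depth_mean: float = 41.0
    snvs_per_sample: int = 200
    coding_snvs_mean: float = 18.0
    subclonal_fraction: float = 0.25
    subclonal_ccf_range: tuple[float, float] = (0.2, 0.7)
    # deliberately filter-failing records planted per sample
    n_low_support: int = 4  # single-caller calls
    n_common_maf: int = 3  # pop_maf above 0.1%
    group_proportions: tuple[float, ...] = (0.2, 0.3125, 0.1625, 0.2375, 0.0875)
    arm_inclusion_prob: tuple[float, ...] = (0.95, 0.95, 0.9, 0.01, 1.0)
    sv_background_rate: float = 38.0
    sv_intra_fraction: float = 0.8
    chromothripsis_rate: float = 0.0875  # ~7 of 80 tumors
    # marker prevalences (PBRM1+ 10/80, SETD2 3/80, CDKN2A/B 11/80, TBXT 4/80, LYST 3/80)
    marker_prevalence: dict[str, float] = field(
        default_factory=lambda: {
            "pbrm1": 0.125, "setd2": 0.0375, "cdkn2ab": 0.1375,
            "tbxt": 0.05, "lyst": 0.0375,
        }
    )
    survival: SurvivalConfig = field(default_factory=SurvivalConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.group_proportions) - 1.0) > 1e-9:
            raise ValueError("group_proportions must sum to 1")
        if not (0 < self.purity_range[0] <= self.purity_range[1] <= 1):
            raise ValueError("purity_range must satisfy 0 < lo <= hi <= 1")
        if self.sv_background_rate < 0 or self.chromothripsis_rate < 0:
            raise ValueError("rates must be >= 0")


# ---------------------------------------------------------------------------
# Copy-number profiles
# ---------------------------------------------------------------------------


def _arm_states(group: int, genome: GenomeBuild, cfg: SimulationConfig, rng) -> dict[str, tuple[int, int]]:
    """Per-arm (tcn, minor) plan for one sample of the given archetype."""
    if not 1 <= group <= 5:
        raise ValueError(f"group must be 1..5, got {group}")
    p_incl = cfg.arm_inclusion_prob[group - 1]
    states: dict[str, tuple[int, int]] = {}
    arm_keys = [f"{c}{a}" for c, a, _, _ in genome.arms()]
    for key in arm_keys:
        states[key] = (2, 1)
    if group == 1:
        for key in _GAIN_ARMS:
            if key in states and rng.random() < p_incl:
                states[key] = (3, 1)
        for key in _LOSS_ARMS_NO_4_9_14:
            if key in states and rng.random() < p_incl:
                states[key] = (1, 0)
    elif group == 2:
        for key in _LOSS_ARMS_FULL:
            if key in states and rng.random() < p_incl:
                states[key] = (1, 0)
    elif group == 3:
        for key in _LOSS_ARMS_SCATTERED:
            if key in states and rng.random() < p_incl:
                states[key] = (1, 0)
    elif group == 4:
        for key in arm_keys:
            if rng.random() < p_incl:
                states[key] = (1, 0) if rng.random() < 0.7 else (3, 1)
    elif group == 5:
        target = rng.uniform(0.55, 0.9)
        auto_arms = [
            (f"{c}{a}", e - s) for c, a, s, e in genome.arms() if genome.is_autosome(c)
        ]
        total = sum(length for _, length in auto_arms)
        covered = 0
        # fixed arm order (largest first) so two WGD profiles share a common core
        for key, length in sorted(auto_arms, key=lambda t: -t[1]):
            if covered / total >= target:
                break
            states[key] = (4, 2)
            covered += length
    else:
        raise ValueError(f"group must be 1..5, got {group}")
    return states


def simulate_cn_profile(
    group: int,
    genome: GenomeBuild,
    rng: np.random.Generator,
    sample_id: str = "S0",
    cfg: SimulationConfig | None = None,
) -> CNProfile:
    """One allele-specific profile drawn from an SCNA archetype (1..5)."""
    cfg = cfg or SimulationConfig()
    states = _arm_states(group, genome, cfg, rng)
    segments = [
        Segment(sample_id, chrom, start, end, *states[f"{chrom}{arm}"])
        for chrom, arm, start, end in genome.arms()
    ]
    return CNProfile(sample_id, segments)


def _plant_focal_deletion(
    profile: CNProfile, chrom: str, start: int, end: int, tcn: int, minor: int
) -> CNProfile:
    """Overwrite [start, end) with a focal segment of the given state."""
    new_segs: list[Segment] = []
    sid = profile.sample_id
    for seg in profile.segments:
        if seg.chrom != chrom or seg.end <= start or seg.start >= end:
            new_segs.append(seg)
            continue
        if seg.start < start:
            new_segs.append(Segment(sid, chrom, seg.start, start, seg.tcn, seg.mcn_minor))
        if seg.end > end:
            new_segs.append(Segment(sid, chrom, end, seg.end, seg.tcn, seg.mcn_minor))
    new_segs.append(Segment(sid, chrom, start, end, tcn, minor))
    return CNProfile(sid, new_segs)


# ---------------------------------------------------------------------------
# Variants
# ---------------------------------------------------------------------------

_GENE_POOL = [
    "B2M", "MAP3K4", "TP53", "MLH1", "ARID1A", "BAG1", "ITGA6", "CSDE1", "KDM6A",
]


def _neutral_intervals(profile: CNProfile) -> list[tuple[str, int, int]]:
    return [
        (s.chrom, s.start, s.end)
        for s in profile.segments
        if s.tcn == 2 and s.mcn_minor == 1
    ]


def _draw_positions(intervals, n, rng) -> list[tuple[str, int]]:
    lengths = np.array([e - s for _, s, e in intervals], dtype=float)
    picks = rng.choice(len(intervals), size=n, p=lengths / lengths.sum())
    out = []
    for i in picks:
        chrom, s, e = intervals[i]
        out.append((chrom, int(rng.integers(s, e))))
    return out


def simulate_variants(
    profile: CNProfile,
    purity: float,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[VariantRecord]:
    """Somatic SNVs for one tumor.

    Variants are placed in copy-neutral segments; a clonal heterozygous SNV
    at cancer-cell fraction *c* draws ``t_alt ~ Binom(t_depth, purity*c/2)``
    with ``t_depth ~ Poisson(depth_mean)``.  A configurable fraction is
    subclonal (c < 1).  A handful of deliberately filter-failing records
    (single-caller support, common population MAF) is planted per sample.
    """
    if not (0 < purity <= 1):
        raise ValueError(f"purity must be in (0, 1], got {purity}")
    intervals = _neutral_intervals(profile)
    if not intervals:
        logger.warning("%s: no copy-neutral territory; no variants drawn", profile.sample_id)
        return []
    sid = profile.sample_id
    bases = np.array(["A", "C", "G", "T"])

    def draw(n, *, coding=False, gene_from=None, n_callers=None, pop_maf=0.0):
        records = []
        for chrom, pos0 in _draw_positions(intervals, n, rng):
            ccf = 1.0
            if rng.random() < config.subclonal_fraction:
                ccf = rng.uniform(*config.subclonal_ccf_range)
            depth = max(1, int(rng.poisson(config.depth_mean)))
            t_alt = int(rng.binomial(depth, purity * ccf / 2.0))
            n_depth = max(1, int(rng.poisson(config.normal_depth_mean)))
            ref, alt = rng.choice(bases, size=2, replace=False)
            records.append(
                VariantRecord(
                    sample_id=sid, chrom=chrom, pos=pos0 + 1, ref=str(ref), alt=str(alt),
                    t_alt=t_alt, t_depth=depth,
                    n_alt=int(rng.binomial(n_depth, 0.001)), n_depth=n_depth,
                    n_callers=int(n_callers if n_callers is not None else rng.integers(2, 6)),
                    pop_maf=float(pop_maf),
                    is_coding=coding,
                    is_nonsynonymous=coding and rng.random() < 0.7,
                    gene=str(rng.choice(gene_from)) if (coding and gene_from is not None) else "",
                )
            )
        return records

    n_coding = int(rng.poisson(config.coding_snvs_mean))
    n_passenger = max(0, config.snvs_per_sample - n_coding)
    variants = draw(n_passenger)
    variants += draw(n_coding, coding=True, gene_from=_GENE_POOL)
    variants += draw(config.n_low_support, n_callers=1)
    variants += draw(
        config.n_common_maf, pop_maf=float(rng.uniform(0.002, 0.05))
    )
    return variants


# ---------------------------------------------------------------------------
# Structural variants and planted chromothripsis
# ---------------------------------------------------------------------------

_INTRA_STRANDS = {
    "DEL-like": ("+", "-"), "DUP-like": ("-", "+"),
    "h2hINV": ("+", "+"), "t2tINV": ("-", "-"),
}
_JOIN_NAMES = list(_INTRA_STRANDS)

#: join-class mix of planted shattering events: heavy fragment loss makes
#: most retained-fragment joins deletion-like.
PLANTED_JOIN_PROBS = (0.85, 0.05, 0.05, 0.05)


def _random_sv(sample_id: str, genome: GenomeBuild, rng, intra: bool) -> SVRecord:
    chroms = [c for c in genome.chrom_names if genome.is_autosome(c)]
    weights = np.array([genome.chrom_lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    if intra:
        chrom = str(rng.choice(chroms, p=weights))
        length = genome.chrom_lengths[chrom]
        span = int(min(length / 4, rng.lognormal(13.0, 1.2)))  # median ~0.4 Mb
        p1 = int(rng.integers(0, max(1, length - span - 1)))
        cls = _JOIN_NAMES[int(rng.integers(0, 4))]
        s1, s2 = _INTRA_STRANDS[cls]
        return SVRecord(sample_id, chrom, p1, s1, chrom, p1 + span + 1, s2)
    c1, c2 = rng.choice(chroms, size=2, replace=False, p=weights)
    return SVRecord(
        sample_id,
        str(c1), int(rng.integers(0, genome.chrom_lengths[str(c1)])), "+-"[rng.integers(2)],
        str(c2), int(rng.integers(0, genome.chrom_lengths[str(c2)])), "+-"[rng.integers(2)],
    )


def _plant_chromothripsis(
    profile: CNProfile, genome: GenomeBuild, rng
) -> tuple[list[SVRecord], CNProfile, tuple[str, int, int]]:
    """Plant one shattering event; returns (SVs, rewritten profile, region).

    2n sorted breakpoints are paired as (b_j, b_{j+n}) so every pair of the n
    intervals interleaves (one cluster of size n by construction); the window
    segments are rewritten to oscillate between two total-CN values across
    2n-1 adjacent fragments (~50% fragment loss).
    """
    sid = profile.sample_id
    # a q-arm window on one of the larger autosomes
    chrom = str(rng.choice(["chr3", "chr4", "chr5", "chr6", "chr9"]))
    q_start, q_end = genome.arm_bounds[chrom]["q"]
    width = 40_000_000
    start = int(rng.integers(q_start, q_end - width))
    end = start + width

    n_sv = int(rng.integers(12, 19))
    bp = np.sort(rng.integers(start, end, size=2 * n_sv))
    bp = np.unique(bp)
    while bp.size < 2 * n_sv:  # regenerate collisions (astronomically rare)
        bp = np.unique(np.concatenate([bp, rng.integers(start, end, size=2 * n_sv)]))
    bp = np.sort(bp[: 2 * n_sv])
    classes = rng.choice(_JOIN_NAMES, size=n_sv, p=PLANTED_JOIN_PROBS)
    svs = []
    for j in range(n_sv):
        s1, s2 = _INTRA_STRANDS[str(classes[j])]
        svs.append(SVRecord(sid, chrom, int(bp[j]), s1, chrom, int(bp[j + n_sv]), s2))

    base_seg = profile.segment_at(chrom, start)
    base_tcn, base_minor = (base_seg.tcn, base_seg.mcn_minor) if base_seg else (2, 1)
    hi = (base_tcn, base_minor) if base_tcn >= 1 else (2, 1)
    lo = (max(0, hi[0] - 1), min(hi[1], max(0, (hi[0] - 1)) // 2))
    pieces = []
    cuts = [start, *map(int, bp), end]
    for i in range(len(cuts) - 1):
        if cuts[i + 1] <= cuts[i]:
            continue
        tcn, minor = hi if i % 2 == 0 else lo
        pieces.append((cuts[i], cuts[i + 1], tcn, minor))
    # clear the window once, then lay down the oscillating fragments
    new_profile = _plant_focal_deletion(profile, chrom, start, end, hi[0], hi[1])
    segs = [seg for seg in new_profile.segments if not (seg.chrom == chrom and seg.start == start and seg.end == end)]
    for s, e, tcn, minor in pieces:
        segs.append(Segment(sid, chrom, s, e, tcn, minor))
    return svs, CNProfile(sid, segs), (chrom, start, end)


def simulate_sv_set(
    profile: CNProfile,
    config: SimulationConfig,
    rng: np.random.Generator,
    genome: GenomeBuild | None = None,
    plant_chromothripsis: bool | None = None,
) -> tuple[list[SVRecord], CNProfile, list[tuple[str, int, int]]]:
    """Background SVs plus an optional planted chromothripsis event.

    Returns (SVs, possibly rewritten profile, planted regions).
    """
    genome = genome or GenomeBuild.hg19()
    svs: list[SVRecord] = []
    n_bg = int(rng.poisson(config.sv_background_rate))
    for _ in range(n_bg):
        svs.append(
            _random_sv(profile.sample_id, genome, rng, rng.random() < config.sv_intra_fraction)
        )
    regions: list[tuple[str, int, int]] = []
    if plant_chromothripsis is None:
        plant_chromothripsis = rng.random() < config.chromothripsis_rate
    if plant_chromothripsis:
        planted, profile, region = _plant_chromothripsis(profile, genome, rng)
        svs += planted
        regions.append(region)
    return svs, profile, regions


# ---------------------------------------------------------------------------
# Survival
# ---------------------------------------------------------------------------


def simulate_survival(
    markers: pd.DataFrame,
    covariates: pd.DataFrame,
    config: SurvivalConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Draw (time, event) pairs for both endpoints from exponential PH truth.

    ``markers`` holds boolean columns named in the log-HR maps; covariates
    are passed through untouched (their true effect is zero).
    """
    n = len(markers)
    out = {}
    for endpoint, h0, betas in (
        ("css", config.baseline_hazard_css, config.log_hr_css),
        ("rfs", config.baseline_hazard_rfs, config.log_hr_rfs),
    ):
        lp = np.zeros(n)
        for name, beta in betas.items():
            if not np.isfinite(beta):
                raise ValueError(f"log-HR for {name} must be finite")
            if name in markers.columns:
                lp += beta * markers[name].to_numpy(dtype=float)
        hazard = h0 * np.exp(lp)
        t_event = rng.exponential(1.0 / hazard)
        censor = rng.uniform(*config.censor_window, size=n)
        time = np.minimum(t_event, censor)
        out[f"{endpoint}_months"] = np.maximum(time, 0.5)
        out[f"{endpoint}_event"] = t_event <= censor
    return pd.DataFrame(out, index=markers.index)


# ---------------------------------------------------------------------------
# Whole-cohort assembly
# ---------------------------------------------------------------------------


@dataclass
class Cohort:
    """In-memory bundle plus the ground truth used to generate it."""

    profiles: list[CNProfile]
    variants: list[VariantRecord]
    svs: list[SVRecord]
    metadata: list[SampleMetadata]
    truth: pd.DataFrame
    chromothripsis_regions: dict[str, list[tuple[str, int, int]]]


def _plant_marker_data(
    sid: str,
    profile: CNProfile,
    rng,
    cfg: SimulationConfig,
) -> tuple[CNProfile, list[VariantRecord], list[SVRecord], dict[str, bool]]:
    """Plant driver-marker lesions and return the marker truth flags."""
    variants: list[VariantRecord] = []
    svs: list[SVRecord] = []
    flags: dict[str, bool] = {}

    def marker_variant(gene: str) -> VariantRecord:
        chrom, g_start, g_end = GENE_LOCI[gene]
        return VariantRecord(
            sample_id=sid, chrom=chrom, pos=int(rng.integers(g_start, g_end)) + 1,
            ref="C", alt="T", t_alt=20, t_depth=76, n_alt=0, n_depth=41,
            n_callers=4, pop_maf=0.0, is_coding=True, is_nonsynonymous=True, gene=gene,
        )

    def marker_sv(gene: str) -> SVRecord:
        chrom, g_start, g_end = GENE_LOCI[gene]
        pos = int(rng.integers(g_start, g_end))
        return SVRecord(sid, chrom, pos, "+", chrom, pos + int(2e6), "-")

    for gene, key in (("PBRM1", "pbrm1"), ("SETD2", "setd2"),
                      ("TBXT", "tbxt"), ("LYST", "lyst")):
        hit = rng.random() < cfg.marker_prevalence[key]
        flags[f"{key}_plus"] = hit
        if hit:
            if rng.random() < 0.5:
                variants.append(marker_variant(gene))
            else:
                svs.append(marker_sv(gene))

    hit = rng.random() < cfg.marker_prevalence["cdkn2ab"]
    flags["cdkn2ab_plus"] = hit
    if hit:
        u = rng.random()
        if u < 0.8:  # homozygous deletion over the locus (the dominant mechanism)
            profile = _plant_focal_deletion(
                profile, "chr9", GENE_LOCI["CDKN2A"][1] - 50_000,
                GENE_LOCI["CDKN2B"][2] + 50_000, 0, 0,
            )
        elif u < 0.9:
            svs.append(marker_sv("CDKN2A"))
        else:
            variants.append(marker_variant("CDKN2A"))

    # occasional focal 9q21.11 deletion independent of arm-level 9q loss
    if rng.random() < 0.15:
        chrom, w_start, w_end = FOCAL_9Q21_WINDOW
        seg = profile.segment_at(chrom, w_start)
        if seg is None or seg.tcn >= 2:
            profile = _plant_focal_deletion(profile, chrom, w_start, w_end, 1, 0)
    return profile, variants, svs, flags


def _derive_cn_marker_truth(profile: CNProfile, genome: GenomeBuild) -> dict[str, bool]:
    """Marker flags implied by the final profile geometry (not by the caller
    modules): 22q arm loss >= 90%, any deletion over the 9q21.11 window,
    homozygous deletion over CDKN2A/B."""
    q_start, q_end = genome.arm_bounds["chr22"]["q"]
    loss_bp = sum(
        max(0, min(s.end, q_end) - max(s.start, q_start))
        for s in profile.by_chrom("chr22")
        if s.tcn < 2
    )
    del22q = loss_bp / (q_end - q_start) >= 0.9

    chrom, w_start, w_end = FOCAL_9Q21_WINDOW
    del9q21 = any(
        s.tcn < 2 and s.start < w_end and s.end > w_start
        for s in profile.by_chrom(chrom)
    )
    locus_start, locus_end = GENE_LOCI["CDKN2A"][1], GENE_LOCI["CDKN2B"][2]
    homdel = any(
        s.tcn == 0 and s.start < locus_end and s.end > locus_start
        for s in profile.by_chrom("chr9")
    )
    return {"del22q": del22q, "del9q21_focal": del9q21, "cdkn2ab_homdel": homdel}


def simulate_cohort(
    config: SimulationConfig | None = None, genome: GenomeBuild | None = None
) -> Cohort:
    """Generate a full cohort in memory; all randomness flows from config.seed."""
    config = config or SimulationConfig()
    genome = genome or GenomeBuild.hg19()
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    groups = rng.choice(
        np.arange(1, 6), size=n, p=np.asarray(config.group_proportions)
    )
    purities = rng.uniform(*config.purity_range, size=n)

    profiles: list[CNProfile] = []
    variants: list[VariantRecord] = []
    svs: list[SVRecord] = []
    truth_rows = []
    marker_frames = []
    ct_regions: dict[str, list[tuple[str, int, int]]] = {}

    for i in range(n):
        sid = f"S{i + 1:03d}"
        profile = simulate_cn_profile(int(groups[i]), genome, rng, sid, config)
        profile, planted_vars, planted_svs, flags = _plant_marker_data(
            sid, profile, rng, config
        )
        sample_svs, profile, regions = simulate_sv_set(profile, config, rng, genome)
        ct_regions[sid] = regions
        sample_vars = simulate_variants(profile, float(purities[i]), config, rng)
        profiles.append(profile)
        variants += sample_vars + planted_vars
        svs += sample_svs + planted_svs

        # truth is derived from the final data, so a background SV that happens
        # to land in a marker-gene footprint counts as a hit
        all_sample_svs = sample_svs + planted_svs
        for gene, key in (("PBRM1", "pbrm1_plus"), ("SETD2", "setd2_plus"),
                          ("TBXT", "tbxt_plus"), ("LYST", "lyst_plus"),
                          ("CDKN2A", "cdkn2ab_plus")):
            chrom, g_start, g_end = GENE_LOCI[gene]
            if gene == "CDKN2A":
                g_end = GENE_LOCI["CDKN2B"][2]
            hit_sv = any(
                (s.chrom1 == chrom and g_start <= s.pos1 < g_end)
                or (s.chrom2 == chrom and g_start <= s.pos2 < g_end)
                for s in all_sample_svs
            )
            flags[key] = flags[key] or hit_sv

        cn_flags = _derive_cn_marker_truth(profile, genome)
        flags["cdkn2ab_plus"] = flags["cdkn2ab_plus"] or cn_flags.pop("cdkn2ab_homdel")
        flags.update(cn_flags)
        wgd_truth = int(groups[i]) == 5
        marker_frames.append({"sample": sid, **flags})
        truth_rows.append(
            {
                "sample": sid, "purity": float(purities[i]),
                "scna_group": int(groups[i]), "wgd": wgd_truth,
                "n_chromothripsis": len(regions),
                "chromothripsis_regions": ";".join(
                    f"{c}:{s}-{e}" for c, s, e in regions
                ),
                **flags,
            }
        )

    markers = pd.DataFrame(marker_frames).set_index("sample")
    ages = np.clip(rng.normal(44.7, 17.0, size=n), 7, 79)
    sexes = np.where(rng.random(n) < 0.625, "M", "F")
    covariates = pd.DataFrame(
        {
            "age": ages,
            "sex": sexes,
            "pre_rt": rng.random(n) < 0.15,
            "post_rt": rng.random(n) < 0.525,
        },
        index=markers.index,
    )
    surv = simulate_survival(markers, covariates, config.survival, rng)

    histologies = rng.choice(
        ["classic", "chondroid", "dedifferentiated"], size=n, p=[0.80, 0.175, 0.025]
    )
    metadata = [
        SampleMetadata(
            sample_id=sid, age=float(covariates.loc[sid, "age"]),
            sex=str(covariates.loc[sid, "sex"]), histology=str(histologies[i]),
            pre_rt=bool(covariates.loc[sid, "pre_rt"]),
            post_rt=bool(covariates.loc[sid, "post_rt"]),
            recurred=bool(surv.loc[sid, "rfs_event"]),
            rfs_months=float(surv.loc[sid, "rfs_months"]),
            died=bool(surv.loc[sid, "css_event"]),
            os_months=float(surv.loc[sid, "css_months"]),
        )
        for i, sid in enumerate(markers.index)
    ]
    truth = pd.DataFrame(truth_rows).set_index("sample")
    return Cohort(profiles, variants, svs, metadata, truth, ct_regions)


def write_cohort(cohort: Cohort, out_dir: str | Path, force: bool = False) -> dict[str, Path]:
    """Write the bundle; truth goes under ``truth/`` so analysis stages that
    read the data directory never see it.  Same cohort -> byte-identical files."""
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} exists and is not empty (use force=True)")
    (out / "truth").mkdir(parents=True, exist_ok=True)
    paths = {
        "segments": out / "segments.tsv",
        "variants": out / "variants.tsv",
        "svs": out / "svs.bedpe",
        "metadata": out / "metadata.tsv",
        "truth": out / "truth" / "truth.tsv",
    }
    write_segments(cohort.profiles, paths["segments"])
    write_variants(cohort.variants, paths["variants"])
    write_sv_bedpe(cohort.svs, paths["svs"])
    write_metadata(cohort.metadata, paths["metadata"])
    cohort.truth.sort_index().to_csv(paths["truth"], sep="\t")
    return paths


def bundle_checksum(out_dir: str | Path) -> str:
    """SHA-256 over the data bundle files (determinism checks)."""
    h = hashlib.sha256()
    out = Path(out_dir)
    for name in ("segments.tsv", "variants.tsv", "svs.bedpe", "metadata.tsv"):
        h.update((out / name).read_bytes())
    return h.hexdigest()
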