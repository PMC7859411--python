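"""Driver-marker assembly and outcome models.

Assembles per-sample driver flags (gene-disrupting mutation or SV breakend,
CDKN2A/B homozygous deletion, 22q arm loss, focal 9q21.11 deletion), tests
marker co-occurrence / mutual exclusivity with a one-sided Fisher exact
test, relates markers to chordoma-specific survival (CSS) and
recurrence-free survival (RFS) through Cox proportional-hazards models
adjusted for age, sex, and pre-/post-surgery radiation therapy (Efron tie
handling), applies Bonferroni control when scanning arm-level events, and
compares paired primary/recurrence samples by shared-alteration fractions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from scipy import stats

from .core import CNProfile, GenomeBuild, SampleMetadata, SVRecord, VariantRecord
from .scna import ArmEvent, call_arm_events, classify_state

log = logging.getLogger("chordwgs")

#: default marker gene footprints (hg19)
DEFAULT_GENE_LOCI: dict[str, tuple[str, int, int]] = {
    "PBRM1": ("chr3", 52_579_368, 52_719_866),
    "SETD2": ("chr3", 47_057_898, 47_205_467),
    "CDKN2A": ("chr9", 21_967_751, 21_995_300),
    "CDKN2B": ("chr9", 22_002_902, 22_009_280),
    "SMARCB1": ("chr22", 24_129_150, 24_176_705),
    "TBXT": ("chr6", 166_571_145, 166_582_804),
    "LYST": ("chr1", 235_824_346, 236_030_227),
}

#: focal 9q21.11 deletion window (hg19 band approximation; configurable)
DEFAULT_9Q21_WINDOW: tuple[str, int, int] = ("chr9", 71_000_000, 71_700_000)

ADJUSTMENT_COVARIATES = ["age", "sex_male", "pre_rt", "post_rt"]


# ---------------------------------------------------------------------------
# Marker assembly
# ---------------------------------------------------------------------------


def _variant_hits(variants: list[VariantRecord], sid: str, gene: str) -> bool:
    return any(
        v.sample_id == sid and v.gene == gene and v.is_nonsynonymous
        for v in variants
    )


def _sv_hits(svs: list[SVRecord], sid: str, locus: tuple[str, int, int]) -> bool:
    chrom, start, end = locus
    for s in svs:
        if s.sample_id != sid:
            continue
        if (s.chrom1 == chrom and start <= s.pos1 < end) or (
            s.chrom2 == chrom and start <= s.pos2 < end
        ):
            return True
    return False


def _homdel_over(profile: CNProfile, locus: tuple[str, int, int]) -> bool:
    chrom, start, end = locus
    return any(
        s.tcn == 0 and s.start < end and s.end > start for s in profile.by_chrom(chrom)
    )


def _deletion_over(profile: CNProfile, window: tuple[str, int, int]) -> bool:
    chrom, start, end = window
    return any(
        s.tcn < 2 and s.start < end and s.end > start for s in profile.by_chrom(chrom)
    )


def assemble_markers(
    variants: list[VariantRecord],
    svs: list[SVRecord],
    profiles: list[CNProfile],
    genome: GenomeBuild,
    loci: dict[str, tuple[str, int, int]] | None = None,
    focal_9q21_window: tuple[str, int, int] | None = None,
) -> pd.DataFrame:
    """Boolean marker table indexed by sample.

    gene+ = nonsynonymous variant in the gene OR SV breakend inside the gene
    footprint (for CDKN2A/B additionally a homozygous deletion overlapping
    the locus); del22q = arm-level 22q loss; del9q21_focal = any deletion
    segment overlapping the 9q21.11 window.  Combined flags are exact ORs of
    their components.  Deterministic and idempotent.
    """
    loci = loci if loci is not None else DEFAULT_GENE_LOCI
    window = focal_9q21_window or DEFAULT_9Q21_WINDOW
    for gene in ("PBRM1", "SETD2", "CDKN2A", "CDKN2B", "TBXT", "LYST"):
        if gene not in loci:
            raise KeyError(f"missing locus definition for gene {gene}")
    rows = []
    for profile in sorted(profiles, key=lambda p: p.sample_id):
        sid = profile.sample_id
        arm_losses = {
            (e.chrom, e.arm)
            for e in call_arm_events(profile, genome)
            if e.direction == "loss"
        }
        gene_plus = {}
        for gene, key in (("PBRM1", "pbrm1_plus"), ("SETD2", "setd2_plus"),
                          ("TBXT", "tbxt_plus"), ("LYST", "lyst_plus")):
            gene_plus[key] = _variant_hits(variants, sid, gene) or _sv_hits(
                svs, sid, loci[gene]
            )
        cdkn_locus = (
            loci["CDKN2A"][0],
            min(loci["CDKN2A"][1], loci["CDKN2B"][1]),
            max(loci["CDKN2A"][2], loci["CDKN2B"][2]),
        )
        cdkn = (
            _variant_hits(variants, sid, "CDKN2A")
            or _variant_hits(variants, sid, "CDKN2B")
            or _sv_hits(svs, sid, cdkn_locus)
            or _homdel_over(profile, cdkn_locus)
        )
        del22q = ("chr22", "q") in arm_losses
        del9q21 = _deletion_over(profile, window)
        rows.append(
            {
                "sample": sid, **gene_plus, "cdkn2ab_plus": cdkn,
                "del22q": del22q, "del9q21_focal": del9q21,
                "combined_css": gene_plus["pbrm1_plus"] or del22q,
                "combined_rfs": gene_plus["pbrm1_plus"] or del9q21 or del22q,
            }
        )
    return pd.DataFrame(rows).set_index("sample")


# ---------------------------------------------------------------------------
# Mutual exclusivity
# ---------------------------------------------------------------------------


def mutual_exclusivity(flags_a, flags_b) -> tuple[int, float]:
    """One-sided Fisher exact test for fewer co-occurrences than expected.

    Returns (co-occurrence count, p).  A degenerate all-false vector cannot
    show exclusivity: p = 1.
    """
    a = np.asarray(flags_a, dtype=bool)
    b = np.asarray(flags_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("marker vectors must have equal length")
    both = int((a & b).sum())
    if a.sum() == 0 or b.sum() == 0:
        log.warning("mutual_exclusivity: a marker is absent from the cohort; p = 1")
        return both, 1.0
    table = [
        [both, int((a & ~b).sum())],
        [int((~a & b).sum()), int((~a & ~b).sum())],
    ]
    _, p = stats.fisher_exact(table, alternative="less")
    return both, float(p)


# ---------------------------------------------------------------------------
# Proportional-hazards models
# ---------------------------------------------------------------------------


@dataclass
class SurvivalFit:
    endpoint: str  # "css" | "rfs"
    marker: str
    hr: float | None
    ci95: tuple[float, float] | None
    p: float | None
    n: int
    n_events: int
    adjusted: list[str] = field(default_factory=lambda: list(ADJUSTMENT_COVARIATES))
    bonferroni_m: int = 1
    p_adj: float | None = None
    status: str = "ok"  # "ok" | "no-fit" | "non-convergence"
    reason: str = ""


def _frame(metadata: list[SampleMetadata], endpoint: str) -> pd.DataFrame:
    if endpoint not in ("css", "rfs"):
        raise ValueError("endpoint must be 'css' or 'rfs'")
    rows = {
        m.sample_id: {
            "time": m.os_months if endpoint == "css" else m.rfs_months,
            "event": m.died if endpoint == "css" else m.recurred,
            "age": m.age,
            "sex_male": m.sex == "M",
            "pre_rt": m.pre_rt,
            "post_rt": m.post_rt,
        }
        for m in metadata
    }
    return pd.DataFrame.from_dict(rows, orient="index").astype(float)


def fit_ph(
    endpoint: str,
    marker: pd.Series,
    metadata: list[SampleMetadata],
    adjust: bool = True,
) -> SurvivalFit:
    """Adjusted Cox PH fit for one marker; Wald HR, 95% CI, p (Efron ties)."""
    df = _frame(metadata, endpoint)
    name = str(marker.name) if marker.name else "marker"
    df[name] = marker.reindex(df.index).astype(float)
    if df[name].isna().any():
        raise ValueError("marker vector does not cover all samples")
    if not adjust:
        df = df[["time", "event", name]]
    n, n_events = len(df), int(df["event"].sum())

    def no_fit(status: str, reason: str) -> SurvivalFit:
        return SurvivalFit(
            endpoint=endpoint, marker=name, hr=None, ci95=None, p=None,
            n=n, n_events=n_events,
            adjusted=list(ADJUSTMENT_COVARIATES) if adjust else [],
            status=status, reason=reason,
        )

    if df[name].nunique() < 2:
        return no_fit("no-fit", "marker constant across cohort")
    for value in (0.0, 1.0):
        stratum = df[df[name] == value]
        if len(stratum) and stratum["event"].sum() == 0:
            return no_fit("no-fit", f"no events in marker={int(value)} stratum")
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except ConvergenceError as err:
        return no_fit("non-convergence", str(err))
    row = cph.summary.loc[name]
    return SurvivalFit(
        endpoint=endpoint, marker=name,
        hr=float(row["exp(coef)"]),
        ci95=(float(row["exp(coef) lower 95%"]), float(row["exp(coef) upper 95%"])),
        p=float(row["p"]), n=n, n_events=n_events,
        adjusted=list(ADJUSTMENT_COVARIATES) if adjust else [],
    )


def km_curves(
    endpoint: str, marker: pd.Series, metadata: list[SampleMetadata]
) -> pd.DataFrame:
    """Kaplan-Meier survival curves per marker stratum (long format)."""
    df = _frame(metadata, endpoint)
    flags = marker.reindex(df.index).astype(bool)
    frames = []
    for value, label in ((False, "negative"), (True, "positive")):
        sub = df[flags == value]
        if sub.empty:
            continue
        km = KaplanMeierFitter()
        km.fit(sub["time"], sub["event"], label=label)
        frame = km.survival_function_.reset_index()
        frame.columns = ["time", "survival"]
        frame.insert(0, "stratum", label)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-corrected p over m tests, capped at 1."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return min(1.0, m * p)


def arm_scan(
    endpoint: str,
    arm_events: list[ArmEvent],
    metadata: list[SampleMetadata],
    m: int | None = None,
    min_carriers: int = 3,
) -> list[SurvivalFit]:
    """Fit every recurrent arm event against the endpoint with Bonferroni control.

    ``m`` defaults to the number of events actually tested; it is exposed as a
    parameter because the multiplicity budget may be defined per endpoint or
    jointly across endpoints.
    """
    sample_ids = [md.sample_id for md in metadata]
    carriers: dict[str, set[str]] = {}
    for e in arm_events:
        carriers.setdefault(e.key, set()).add(e.sample_id)
    tested = {
        key: ids for key, ids in sorted(carriers.items())
        if min_carriers <= len(ids & set(sample_ids))
    }
    m_eff = m if m is not None else len(tested)
    fits = []
    for key, ids in tested.items():
        flags = pd.Series(
            [sid in ids for sid in sample_ids], index=sample_ids, name=key
        )
        fit = fit_ph(endpoint, flags, metadata)
        fit.bonferroni_m = m_eff
        if fit.p is not None:
            fit.p_adj = bonferroni(fit.p, m_eff)
        fits.append(fit)
    return fits


# ---------------------------------------------------------------------------
# Paired-sample shared fractions
# ---------------------------------------------------------------------------


def _variant_keys(variants: list[VariantRecord], sid: str, indel: bool) -> set:
    out = set()
    for v in variants:
        if v.sample_id != sid:
            continue
        if (len(v.ref) != len(v.alt)) == indel:
            out.add((v.chrom, v.pos, v.ref, v.alt))
    return out


def _scna_shared(primary: CNProfile, recurrence: CNProfile) -> dict[str, float]:
    """Partition of altered territory (union convention, interval-wise).

    Over the jointly covered genome: ``shared`` = bp altered with identical
    five-state classification in both samples; ``primary_only`` = bp altered
    in the primary where the recurrence state differs; ``recurrence_only`` =
    bp altered in the recurrence only.  The three fractions sum to 1 over the
    altered union.
    """
    shared = p_only = r_only = 0
    chroms = {s.chrom for s in primary.segments} | {s.chrom for s in recurrence.segments}
    for chrom in chroms:
        segs_p = primary.by_chrom(chrom)
        segs_r = recurrence.by_chrom(chrom)
        bounds = sorted(
            {s.start for s in segs_p + segs_r} | {s.end for s in segs_p + segs_r}
        )
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            sp = next((s for s in segs_p if s.start <= lo < s.end), None)
            sr = next((s for s in segs_r if s.start <= lo < s.end), None)
            if sp is None or sr is None:
                continue
            st_p = classify_state(sp.tcn, sp.mcn_minor)
            st_r = classify_state(sr.tcn, sr.mcn_minor)
            altered_p = st_p.name != "NEUTRAL"
            altered_r = st_r.name != "NEUTRAL"
            if not (altered_p or altered_r):
                continue
            width = hi - lo
            if altered_p and altered_r and st_p == st_r:
                shared += width
            elif altered_p:
                p_only += width
            else:
                r_only += width
    total = shared + p_only + r_only
    if total == 0:
        return {"shared": 1.0, "primary_only": 0.0, "recurrence_only": 0.0}
    return {
        "shared": shared / total,
        "primary_only": p_only / total,
        "recurrence_only": r_only / total,
    }


def shared_fraction(
    pairs: list[tuple[str, str]],
    variants: list[VariantRecord],
    profiles: list[CNProfile],
) -> pd.DataFrame:
    """Per-pair shared / primary-only / recurrence-only proportions for
    SCNAs, SNVs, and indels (denominator: union of alterations per class)."""
    by_id = {p.sample_id: p for p in profiles}
    rows = []
    for primary_id, recurrence_id in pairs:
        if primary_id not in by_id or recurrence_id not in by_id:
            log.warning("pair (%s, %s): missing profile; skipped", primary_id, recurrence_id)
            continue
        for cls, indel in (("snv", False), ("indel", True)):
            kp = _variant_keys(variants, primary_id, indel)
            kr = _variant_keys(variants, recurrence_id, indel)
            union = kp | kr
            if not union:
                continue
            rows.append(
                {
                    "primary": primary_id, "recurrence": recurrence_id, "class": cls,
                    "shared": len(kp & kr) / len(union),
                    "primary_only": len(kp - kr) / len(union),
                    "recurrence_only": len(kr - kp) / len(union),
                }
            )
        scna = _scna_shared(by_id[primary_id], by_id[recurrence_id])
        rows.append(
            {"primary": primary_id, "recurrence": recurrence_id, "class": "scna", **scna}
        )
    return pd.DataFrame(rows)
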