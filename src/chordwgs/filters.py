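"""Ensemble somatic-variant retention filter and tumor mutational burden.

A variant survives only if it was called by at least two of the ensemble
callers, reaches the minimum tumor VAF and alt-read support, stays below
the maximum normal VAF, satisfies tumor/normal depth floors, and is rare
in population databases.  Every rejection is labeled with the first
failing rule in a fixed order so filter output is reproducible record by
record.

Boundary semantics: the exclusion rules name what is removed (e.g. tumor
VAF *below* 0.07 is excluded), so a record sitting exactly on a threshold
is kept.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import VariantRecord


@dataclass
class FilterConfig:
    """Thresholds of the retention filter plus the TMB denominator.

    ``coding_mb`` is the coding territory (megabases) used as the TMB
    denominator; configurable because estimates of the human coding
    footprint vary (default 35 Mb).
    """

    min_callers: int = 2
    min_t_vaf: float = 0.07
    max_n_vaf: float = 0.02
    min_t_alt: int = 3
    min_t_depth: int = 8
    min_n_depth: int = 6
    max_pop_maf: float = 0.001
    coding_mb: float = 35.0

    def __post_init__(self) -> None:
        numeric = (
            self.min_callers, self.min_t_vaf, self.max_n_vaf, self.min_t_alt,
            self.min_t_depth, self.min_n_depth, self.max_pop_maf,
        )
        if any(v < 0 for v in numeric):
            raise ValueError("filter thresholds must be non-negative")
        if self.coding_mb <= 0:
            raise ValueError("coding_mb must be positive")


#: Rejection reasons in evaluation order; the first failing rule labels the record.
RULE_ORDER = ("n_callers", "t_vaf", "n_vaf", "t_alt", "t_depth", "n_depth", "pop_maf")


def _first_failure(v: VariantRecord, cfg: FilterConfig) -> str | None:
    # Zero depth makes VAF undefined: the VAF rule is skipped and the record
    # falls through to the read-count/depth rules instead of dividing by zero.
    if v.n_callers < cfg.min_callers:
        return "n_callers"
    if v.t_depth > 0 and v.t_vaf < cfg.min_t_vaf:
        return "t_vaf"
    if v.n_depth > 0 and v.n_vaf > cfg.max_n_vaf:
        return "n_vaf"
    if v.t_alt < cfg.min_t_alt:
        return "t_alt"
    if v.t_depth < cfg.min_t_depth:
        return "t_depth"
    if v.n_depth < cfg.min_n_depth:
        return "n_depth"
    if v.pop_maf > cfg.max_pop_maf:
        return "pop_maf"
    return None


def apply_filters(
    variants: list[VariantRecord], cfg: FilterConfig | None = None
) -> tuple[list[VariantRecord], list[tuple[VariantRecord, str]]]:
    """Partition variants into (kept, rejected-with-reason).

    The kept and rejected sets are disjoint and jointly exhaust the input;
    tightening any threshold can only shrink the kept set.
    """
    cfg = cfg or FilterConfig()
    kept: list[VariantRecord] = []
    rejected: list[tuple[VariantRecord, str]] = []
    for v in variants:
        reason = _first_failure(v, cfg)
        if reason is None:
            kept.append(v)
        else:
            rejected.append((v, reason))
    return kept, rejected


def compute_tmb(
    kept_variants: list[VariantRecord], cfg: FilterConfig | None = None
) -> dict[str, float]:
    """Coding mutations per megabase, per sample (SNVs and indels alike)."""
    cfg = cfg or FilterConfig()
    counts: dict[str, int] = {}
    for v in kept_variants:
        counts.setdefault(v.sample_id, 0)
        if v.is_coding:
            counts[v.sample_id] += 1
    return {sid: n / cfg.coding_mb for sid, n in sorted(counts.items())}
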