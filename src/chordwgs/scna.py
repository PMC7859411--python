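"""Allele-specific SCNA landscape: CN states, arm events, WGD, clustering.

Every segment maps to one of five copy-number states (homozygous deletion,
hemizygous deletion, copy neutral, LOH, amplification).  Arm-level events
require the gain or loss to cover at least 90% of the arm; whole-genome
doubling (WGD) requires major copy number >= 2 over strictly more than 50%
of the covered autosomal genome.  Tumor-tumor distance is the base-pair
fraction of the jointly covered genome on which the two five-state profiles
disagree (computed interval-wise, never literally per base).  Cohorts are
grouped by agglomerative clustering with the group count picked at the
maximum-curvature elbow of the within-cluster dispersion curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .core import CNProfile, GenomeBuild, Segment, ValidationError

log = logging.getLogger("chordwgs")


class CNState(Enum):
    HOMDEL = 0
    HEMIDEL = 1
    NEUTRAL = 2
    LOH = 3
    AMP = 4


def classify_state(tcn: int, minor: int) -> CNState:
    """Total function (tcn, minor) -> five-state classification.

    Amplification (tcn >= 3) takes precedence over LOH when minor = 0.
    """
    if tcn == 0:
        return CNState.HOMDEL
    if tcn == 1:
        return CNState.HEMIDEL
    if tcn >= 3:
        return CNState.AMP
    return CNState.LOH if minor == 0 else CNState.NEUTRAL


@dataclass
class ArmEvent:
    """Arm-level gain or loss covering >= 90% of the arm."""

    sample_id: str
    chrom: str
    arm: str  # "p" / "q"
    direction: str  # "gain" / "loss"
    covered_fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.covered_fraction <= 1.0:
            raise ValidationError("covered_fraction outside [0,1]")

    @property
    def key(self) -> str:
        return f"{self.chrom}{self.arm}_{self.direction}"


def _overlap(seg: Segment, start: int, end: int) -> int:
    return max(0, min(seg.end, end) - max(seg.start, start))


def call_arm_events(
    profile: CNProfile, genome: GenomeBuild, threshold: float = 0.9
) -> list[ArmEvent]:
    """Directional arm calls: gain bp (tcn>2) and loss bp (tcn<2) per arm.

    Uncovered base pairs count in the denominator (the full arm length) but
    never in the numerator, so sparse profiles cannot fake an arm event.
    """
    events: list[ArmEvent] = []
    for chrom, arm, a_start, a_end in genome.arms():
        arm_bp = a_end - a_start
        gain_bp = loss_bp = covered_bp = 0
        for seg in profile.by_chrom(chrom):
            ov = _overlap(seg, a_start, a_end)
            if ov == 0:
                continue
            covered_bp += ov
            if seg.tcn > 2:
                gain_bp += ov
            elif seg.tcn < 2:
                loss_bp += ov
        if covered_bp == 0:
            log.warning("%s: arm %s%s fully uncovered; no call", profile.sample_id, chrom, arm)
            continue
        for direction, bp in (("gain", gain_bp), ("loss", loss_bp)):
            frac = bp / arm_bp
            if frac >= threshold:
                events.append(ArmEvent(profile.sample_id, chrom, arm, direction, frac))
    return events


def call_wgd(profile: CNProfile, genome: GenomeBuild) -> tuple[bool, float]:
    """WGD call: strict > 50% of covered autosomal bp with major CN >= 2."""
    covered = mcn2 = 0
    for seg in profile.segments:
        if not genome.is_autosome(seg.chrom):
            continue
        covered += seg.length
        if seg.mcn_major >= 2:
            mcn2 += seg.length
    fraction = mcn2 / covered if covered else 0.0
    return fraction > 0.5, fraction


# ---------------------------------------------------------------------------
# Length-weighted CN-state distance
# ---------------------------------------------------------------------------


def _chrom_arrays(profile: CNProfile) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Per chromosome: (starts, ends, state codes) as arrays for fast lookup."""
    out = {}
    for chrom in sorted({s.chrom for s in profile.segments}):
        segs = profile.by_chrom(chrom)
        starts = np.array([s.start for s in segs])
        ends = np.array([s.end for s in segs])
        states = np.array([classify_state(s.tcn, s.mcn_minor).value for s in segs])
        out[chrom] = (starts, ends, states)
    return out


def _pair_distance(
    a: dict, b: dict, normalize: bool
) -> float:
    diff_bp = 0
    joint_bp = 0
    for chrom in set(a) & set(b):
        sa, ea, va = a[chrom]
        sb, eb, vb = b[chrom]
        bounds = np.unique(np.concatenate([sa, ea, sb, eb]))
        lo, hi = bounds[:-1], bounds[1:]
        # covering segment index for each elementary interval, or -1 in a gap
        ia = np.searchsorted(sa, lo, side="right") - 1
        ib = np.searchsorted(sb, lo, side="right") - 1
        cov_a = (ia >= 0) & (lo < ea[np.clip(ia, 0, None)])
        cov_b = (ib >= 0) & (lo < eb[np.clip(ib, 0, None)])
        both = cov_a & cov_b
        if not both.any():
            continue
        width = (hi - lo)[both]
        mismatch = va[ia[both]] != vb[ib[both]]
        joint_bp += int(width.sum())
        diff_bp += int(width[mismatch].sum())
    if normalize:
        if joint_bp == 0:
            raise ValidationError("profiles share no covered territory; distance undefined")
        return diff_bp / joint_bp
    return float(diff_bp)


def pairwise_distance(
    profiles: list[CNProfile], genome: GenomeBuild, normalize: bool = True
) -> np.ndarray:
    """Symmetric matrix of per-bp five-state disagreement fractions.

    With ``normalize=False`` the raw disagreeing base-pair count is returned
    (the unnormalized per-bp sum), which is only comparable across pairs when
    coverage is complete.
    """
    if len(profiles) < 2:
        raise ValidationError("need at least two profiles")
    for prof in profiles:
        for seg in prof.segments:
            if not genome.has_chrom(seg.chrom):
                raise ValidationError(f"{prof.sample_id}: unknown chromosome {seg.chrom}")
    arrays = [_chrom_arrays(p) for p in profiles]
    n = len(profiles)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d = _pair_distance(arrays[i], arrays[j], normalize)
            except ValidationError as err:
                raise ValidationError(
                    f"pair ({profiles[i].sample_id}, {profiles[j].sample_id}): {err}"
                ) from err
            D[i, j] = D[j, i] = d
    return D


# ---------------------------------------------------------------------------
# Cohort clustering with elbow-selected k
# ---------------------------------------------------------------------------


@dataclass
class CohortClustering:
    sample_ids: list[str]
    distance: np.ndarray
    linkage_tree: np.ndarray
    chosen_k: int
    labels: np.ndarray  # 1..chosen_k, label 1 = largest cluster
    dispersion: dict[int, float]  # k -> W(k)


def _within_dispersion(D: np.ndarray, labels: np.ndarray) -> float:
    """W = mean pairwise distance over all within-cluster pairs (pooled)."""
    total = 0.0
    n_pairs = 0
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        if idx.size < 2:
            continue
        sub = D[np.ix_(idx, idx)][np.triu_indices(idx.size, 1)]
        total += sub.sum()
        n_pairs += sub.size
    return total / n_pairs if n_pairs else 0.0


def _relabel_by_size(labels: np.ndarray) -> np.ndarray:
    """Deterministic labels: 1 = largest cluster, ties by first appearance."""
    uniq, counts = np.unique(labels, return_counts=True)
    first_seen = {lab: int(np.argmax(labels == lab)) for lab in uniq}
    order = sorted(uniq, key=lambda lab: (-counts[list(uniq).index(lab)], first_seen[lab]))
    mapping = {lab: rank + 1 for rank, lab in enumerate(order)}
    return np.array([mapping[lab] for lab in labels])


def cluster_cohort(
    distance: np.ndarray,
    sample_ids: list[str] | None = None,
    k_max: int = 8,
    method: str = "average",
    zero_tol: float = 1e-12,
) -> CohortClustering:
    """Agglomerative clustering; k picked by the maximum-curvature elbow.

    For k = 1..k_max the pooled within-cluster mean pairwise distance W(k)
    is computed and the chosen k maximizes the discrete second difference of
    log W — the point of maximum curvature of the dispersion curve.  The log
    scale makes the curvature criterion scale-free: W typically decays
    geometrically while clusters are still being separated and flattens once
    the real group count is passed, and the raw second difference would
    otherwise always peak at small k.  A cohort of (near-)identical profiles
    degenerates to k = 1.
    """
    D = np.asarray(distance, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or not np.allclose(D, D.T) or np.abs(np.diag(D)).max() > zero_tol:
        raise ValidationError("distance must be a symmetric matrix with zero diagonal")
    if k_max >= n:
        raise ValidationError(f"k_max={k_max} must be < number of samples ({n})")
    if sample_ids is None:
        sample_ids = [f"S{i}" for i in range(n)]
    Z = linkage(squareform(D, checks=False), method=method)

    dispersion: dict[int, float] = {}
    labels_for_k: dict[int, np.ndarray] = {}
    for k in range(1, k_max + 1):
        labels_for_k[k] = fcluster(Z, t=k, criterion="maxclust")
        dispersion[k] = _within_dispersion(D, labels_for_k[k])

    if dispersion[1] <= zero_tol:
        chosen = 1
    else:
        eps = zero_tol * dispersion[1]
        log_w = {k: np.log(dispersion[k] + eps) for k in dispersion}
        curvature = {
            k: log_w[k - 1] - 2 * log_w[k] + log_w[k + 1] for k in range(2, k_max)
        }
        chosen = max(curvature, key=lambda k: (curvature[k], -k)) if curvature else 1
    labels = _relabel_by_size(labels_for_k[chosen])
    return CohortClustering(
        sample_ids=list(sample_ids), distance=D, linkage_tree=Z,
        chosen_k=int(labels.max()), labels=labels, dispersion=dispersion,
    )
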