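"""Domain types, genome model, and tab-separated readers/writers.

All downstream analysis modules consume the validated containers defined
here — :class:`Segment`, :class:`CNProfile`, :class:`VariantRecord`,
:class:`SVRecord`, :class:`SampleMetadata` — never raw files.

Coordinate conventions
----------------------
Internally every interval is 0-based half-open.  On disk the SEG-like
segment TSV is 1-based inclusive (the convention of segment files), BEDPE
is 0-based half-open, and variant positions are 1-based.  The genome arm
table is 0-based half-open.  Chromosome names are normalized to carry the
``chr`` prefix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

log = logging.getLogger("chordwgs")


def setup_logging(level: str = "INFO") -> None:
    """Configure the package logger once (used by the CLI)."""
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )


def load_config(path: str | Path | None) -> dict:
    """Load a nested YAML config; missing path returns an empty mapping.

    Sections mirror the pipeline stages (``simulate``, ``filters``,
    ``purity``, ``scna``, ``chromothripsis``, ``survival``); each stage's
    dataclass config accepts the corresponding section as keyword overrides.
    """
    if path is None:
        return {}
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise FormatError(f"config file {path} must hold a mapping")
    return cfg


class FormatError(ValueError):
    """A file does not conform to its declared on-disk format."""


class ValidationError(ValueError):
    """A record violates a domain invariant."""


def normalize_chrom(name: str) -> str:
    name = str(name).strip()
    if not name:
        raise FormatError("empty chromosome name")
    return name if name.startswith("chr") else "chr" + name


# ---------------------------------------------------------------------------
# Genome model
# ---------------------------------------------------------------------------

_SEX_CHROMS = {"chrX", "chrY"}


@dataclass
class GenomeBuild:
    """Chromosome and arm geometry (data, not code — any build accepted).

    ``arm_bounds`` maps chromosome -> {"p": (start, end), "q": (start, end)}
    in 0-based half-open bp; the centromere gap between p end and q start is
    not part of either arm.
    """

    chrom_names: list[str]
    chrom_lengths: dict[str, int]
    arm_bounds: dict[str, dict[str, tuple[int, int]]]
    autosome_flags: dict[str, bool]

    def __post_init__(self) -> None:
        for chrom in self.chrom_names:
            length = self.chrom_lengths[chrom]
            arms = self.arm_bounds.get(chrom, {})
            prev_end = 0
            for arm in ("p", "q"):
                if arm not in arms:
                    continue
                s, e = arms[arm]
                if not (0 <= s < e <= length):
                    raise ValidationError(
                        f"{chrom}{arm} bounds [{s},{e}) outside [0,{length})"
                    )
                if s < prev_end:
                    raise ValidationError(f"{chrom} arms overlap")
                prev_end = e
        if self.autosomal_length() <= 0:
            raise ValidationError("genome has no autosomal territory")

    def has_chrom(self, chrom: str) -> bool:
        return chrom in self.chrom_lengths

    def is_autosome(self, chrom: str) -> bool:
        return self.autosome_flags.get(chrom, False)

    def autosomal_length(self) -> int:
        return sum(
            self.chrom_lengths[c] for c in self.chrom_names if self.autosome_flags.get(c)
        )

    def arms(self) -> list[tuple[str, str, int, int]]:
        """All (chrom, arm, start, end) tuples in genome order."""
        out = []
        for chrom in self.chrom_names:
            for arm in ("p", "q"):
                if arm in self.arm_bounds.get(chrom, {}):
                    s, e = self.arm_bounds[chrom][arm]
                    out.append((chrom, arm, s, e))
        return out

    @classmethod
    def from_arm_table(cls, path: str | Path) -> "GenomeBuild":
        """Read a TSV with columns chrom, arm, start, end (0-based half-open)."""
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "arm": str})
        _require_columns(df, ["chrom", "arm", "start", "end"], path)
        chrom_names: list[str] = []
        arm_bounds: dict[str, dict[str, tuple[int, int]]] = {}
        lengths: dict[str, int] = {}
        for _, row in df.iterrows():
            chrom = normalize_chrom(row["chrom"])
            arm = str(row["arm"])
            if arm not in ("p", "q"):
                raise FormatError(f"{path}: arm must be 'p' or 'q', got {arm!r}")
            if chrom not in arm_bounds:
                chrom_names.append(chrom)
                arm_bounds[chrom] = {}
            arm_bounds[chrom][arm] = (int(row["start"]), int(row["end"]))
            lengths[chrom] = max(lengths.get(chrom, 0), int(row["end"]))
        autosomes = {c: c not in _SEX_CHROMS for c in chrom_names}
        return cls(chrom_names, lengths, arm_bounds, autosomes)

    @classmethod
    def hg19(cls) -> "GenomeBuild":
        """The packaged hg19 arm table (UCSC gap-track centromeres)."""
        with resources.as_file(
            resources.files("chordwgs.data").joinpath("hg19_arms.tsv")
        ) as p:
            return cls.from_arm_table(p)


# ---------------------------------------------------------------------------
# Record types
# ---------------------------------------------------------------------------


@dataclass
class Segment:
    """Allele-specific copy-number interval.

    ``tcn`` is total copy number; ``mcn_minor`` the minor-allele copy
    number.  Major copy number (MCN, the more frequent allele) is
    ``tcn - mcn_minor``.
    """

    sample_id: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    tcn: int
    mcn_minor: int

    def __post_init__(self) -> None:
        self.chrom = normalize_chrom(self.chrom)
        if self.end <= self.start:
            raise ValidationError(
                f"segment {self.chrom}:{self.start}-{self.end}: end must exceed start"
            )
        if self.mcn_minor < 0 or self.tcn < self.mcn_minor:
            raise ValidationError(
                f"segment {self.chrom}:{self.start}-{self.end}: "
                f"tcn={self.tcn} < mcn_minor={self.mcn_minor}"
            )
        if 2 * self.mcn_minor > self.tcn:
            raise ValidationError(
                f"segment {self.chrom}:{self.start}-{self.end}: minor allele "
                f"count {self.mcn_minor} exceeds tcn/2 (tcn={self.tcn})"
            )

    @property
    def mcn_major(self) -> int:
        return self.tcn - self.mcn_minor

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class CNProfile:
    """Per-sample copy-number profile: non-overlapping sorted segments.

    Gaps between segments are missing data and are excluded from every
    denominator downstream.
    """

    sample_id: str
    segments: list[Segment] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.segments = sorted(self.segments, key=lambda s: (s.chrom, s.start))
        prev: Segment | None = None
        for seg in self.segments:
            if seg.sample_id != self.sample_id:
                raise ValidationError(
                    f"segment sample {seg.sample_id} != profile {self.sample_id}"
                )
            if prev is not None and prev.chrom == seg.chrom and seg.start < prev.end:
                raise ValidationError(
                    f"{self.sample_id} {seg.chrom}: segments overlap at "
                    f"{seg.start} < {prev.end}"
                )
            prev = seg

    def by_chrom(self, chrom: str) -> list[Segment]:
        return [s for s in self.segments if s.chrom == chrom]

    def segment_at(self, chrom: str, pos0: int) -> Segment | None:
        """Segment covering 0-based position, or None in a gap."""
        for s in self.by_chrom(chrom):
            if s.start <= pos0 < s.end:
                return s
        return None


@dataclass
class VariantRecord:
    """Somatic SNV/indel with tumor/normal allele counts and annotations."""

    sample_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    t_alt: int
    t_depth: int
    n_alt: int
    n_depth: int
    n_callers: int = 1
    pop_maf: float = 0.0
    is_coding: bool = False
    is_nonsynonymous: bool = False
    gene: str = ""

    def __post_init__(self) -> None:
        self.chrom = normalize_chrom(self.chrom)
        if not (0 <= self.t_alt <= self.t_depth):
            raise ValidationError(
                f"{self.sample_id} {self.chrom}:{self.pos}: "
                f"t_alt={self.t_alt} not in [0, t_depth={self.t_depth}]"
            )
        if not (0 <= self.n_alt <= self.n_depth):
            raise ValidationError(
                f"{self.sample_id} {self.chrom}:{self.pos}: "
                f"n_alt={self.n_alt} not in [0, n_depth={self.n_depth}]"
            )
        if not (0.0 <= self.pop_maf <= 1.0):
            raise ValidationError(
                f"{self.sample_id} {self.chrom}:{self.pos}: pop_maf={self.pop_maf}"
            )

    @property
    def t_vaf(self) -> float:
        return self.t_alt / self.t_depth if self.t_depth > 0 else 0.0

    @property
    def n_vaf(self) -> float:
        return self.n_alt / self.n_depth if self.n_depth > 0 else 0.0


SV_CLASSES = ("DEL-like", "DUP-like", "h2hINV", "t2tINV", "TRA")

_INTRA_CLASS_BY_STRANDS = {
    ("+", "-"): "DEL-like",
    ("-", "+"): "DUP-like",
    ("+", "+"): "h2hINV",
    ("-", "-"): "t2tINV",
}


@dataclass
class SVRecord:
    """Paired-breakend rearrangement.

    Intra-chromosomal classes follow breakend orientation: +/- deletion-like,
    -/+ tandem-duplication-like, +/+ head-to-head inverted, -/- tail-to-tail
    inverted; inter-chromosomal records are translocations (TRA).
    """

    sample_id: str
    chrom1: str
    pos1: int  # 0-based breakend
    strand1: str
    chrom2: str
    pos2: int
    strand2: str
    sv_class: str = ""

    def __post_init__(self) -> None:
        self.chrom1 = normalize_chrom(self.chrom1)
        self.chrom2 = normalize_chrom(self.chrom2)
        for strand in (self.strand1, self.strand2):
            if strand not in ("+", "-"):
                raise FormatError(f"malformed strand {strand!r}")
        if self.intra and self.pos1 >= self.pos2:
            raise ValidationError(
                f"intra-chromosomal SV on {self.chrom1} needs pos1 < pos2 "
                f"({self.pos1} >= {self.pos2})"
            )
        expected = self.classify_strands()
        if not self.sv_class:
            self.sv_class = expected
        elif self.sv_class != expected:
            raise ValidationError(
                f"sv_class {self.sv_class} inconsistent with strands "
                f"{self.strand1}/{self.strand2} (expected {expected})"
            )

    @property
    def intra(self) -> bool:
        return self.chrom1 == self.chrom2

    def classify_strands(self) -> str:
        if not self.intra:
            return "TRA"
        return _INTRA_CLASS_BY_STRANDS[(self.strand1, self.strand2)]


@dataclass
class SampleMetadata:
    """Clinical covariates and outcome endpoints for one patient sample."""

    sample_id: str
    age: float
    sex: str  # "F" / "M"
    histology: str = "classic"
    pre_rt: bool = False
    post_rt: bool = False
    recurred: bool = False
    rfs_months: float = 0.0
    died: bool = False
    os_months: float = 0.0

    def __post_init__(self) -> None:
        if self.rfs_months <= 0 or self.os_months <= 0:
            raise ValidationError(f"{self.sample_id}: follow-up times must be > 0")
        if self.sex not in ("F", "M"):
            raise ValidationError(f"{self.sample_id}: sex must be F or M")


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: missing required column(s) {missing}; found {list(df.columns)}"
        )


def read_segments(path: str | Path, genome: GenomeBuild) -> list[CNProfile]:
    """Read a SEG-like TSV (1-based inclusive on disk) into validated profiles."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "chrom": str})
    _require_columns(df, ["sample", "chrom", "start", "end", "tcn", "mcn_minor"], path)
    by_sample: dict[str, list[Segment]] = {}
    for i, row in df.iterrows():
        chrom = normalize_chrom(row["chrom"])
        if not genome.has_chrom(chrom):
            raise FormatError(f"{path} line {i + 2}: unknown chromosome {chrom!r}")
        seg = Segment(
            sample_id=str(row["sample"]),
            chrom=chrom,
            start=int(row["start"]) - 1,  # 1-based inclusive -> 0-based half-open
            end=int(row["end"]),
            tcn=int(row["tcn"]),
            mcn_minor=int(row["mcn_minor"]),
        )
        by_sample.setdefault(seg.sample_id, []).append(seg)
    return [CNProfile(sid, segs) for sid, segs in sorted(by_sample.items())]


def read_sv_bedpe(path: str | Path) -> list[SVRecord]:
    """Read BEDPE (0-based half-open); the ``name`` column carries sample id."""
    cols = [
        "chrom1", "start1", "end1", "chrom2", "start2", "end2",
        "name", "score", "strand1", "strand2",
    ]
    df = pd.read_csv(path, sep="\t", header=None, names=cols, comment="#", dtype=str)
    if df.empty:
        return []
    records = []
    for _, row in df.iterrows():
        c1, c2 = normalize_chrom(row["chrom1"]), normalize_chrom(row["chrom2"])
        p1, p2 = int(row["start1"]), int(row["start2"])
        s1, s2 = str(row["strand1"]), str(row["strand2"])
        if c1 == c2 and p1 > p2:
            p1, p2 = p2, p1
            s1, s2 = s2, s1
        records.append(
            SVRecord(
                sample_id=str(row["name"]),
                chrom1=c1, pos1=p1, strand1=s1,
                chrom2=c2, pos2=p2, strand2=s2,
            )
        )
    return records


_VARIANT_COLUMNS = [
    "sample", "chrom", "pos", "ref", "alt", "t_alt", "t_depth",
    "n_alt", "n_depth", "n_callers", "is_coding", "is_nonsynonymous", "gene",
]


def _as_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    return str(value).strip().lower() in ("1", "true", "t", "yes")


def read_variants(path: str | Path) -> list[VariantRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "chrom": str, "gene": str})
    _require_columns(df, _VARIANT_COLUMNS, path)
    if "pop_maf" not in df.columns:
        log.warning("%s: pop_maf column absent; imputing 0 for all records", path)
        df["pop_maf"] = 0.0
    df["gene"] = df["gene"].fillna("")
    return [
        VariantRecord(
            sample_id=str(r["sample"]), chrom=str(r["chrom"]), pos=int(r["pos"]),
            ref=str(r["ref"]), alt=str(r["alt"]),
            t_alt=int(r["t_alt"]), t_depth=int(r["t_depth"]),
            n_alt=int(r["n_alt"]), n_depth=int(r["n_depth"]),
            n_callers=int(r["n_callers"]), pop_maf=float(r["pop_maf"]),
            is_coding=_as_bool(r["is_coding"]),
            is_nonsynonymous=_as_bool(r["is_nonsynonymous"]),
            gene=str(r["gene"]),
        )
        for _, r in df.iterrows()
    ]


def read_metadata(path: str | Path) -> list[SampleMetadata]:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "sex": str, "histology": str})
    _require_columns(
        df,
        ["sample", "age", "sex", "histology", "pre_rt", "post_rt",
         "recurred", "rfs_months", "died", "os_months"],
        path,
    )
    return [
        SampleMetadata(
            sample_id=str(r["sample"]), age=float(r["age"]), sex=str(r["sex"]),
            histology=str(r["histology"]),
            pre_rt=_as_bool(r["pre_rt"]), post_rt=_as_bool(r["post_rt"]),
            recurred=_as_bool(r["recurred"]), rfs_months=float(r["rfs_months"]),
            died=_as_bool(r["died"]), os_months=float(r["os_months"]),
        )
        for _, r in df.iterrows()
    ]


# ---------------------------------------------------------------------------
# Writers (deterministic ordering so outputs are diffable)
# ---------------------------------------------------------------------------


def write_table(records: Iterable, path: str | Path) -> None:
    """Write a homogeneous list of domain records to TSV.

    Dispatches on record type; ordering is deterministic: (sample, chrom, pos)
    for positional records, sample id otherwise.  ``write_table`` and the
    matching reader round-trip loss-lessly.
    """
    records = list(records)
    if not records:
        raise ValidationError("write_table: empty record list (type unknown)")
    first = records[0]
    if isinstance(first, CNProfile):
        write_segments(records, path)
    elif isinstance(first, VariantRecord):
        write_variants(records, path)
    elif isinstance(first, SVRecord):
        write_sv_bedpe(records, path)
    elif isinstance(first, SampleMetadata):
        write_metadata(records, path)
    else:
        _write_generic(records, path)


def _write_generic(records: list, path: str | Path) -> None:
    names = [f.name for f in fields(records[0])]
    df = pd.DataFrame([[getattr(r, n) for n in names] for r in records], columns=names)
    df.to_csv(path, sep="\t", index=False)


def write_segments(profiles: Iterable[CNProfile], path: str | Path) -> None:
    rows = []
    for prof in sorted(profiles, key=lambda p: p.sample_id):
        for s in prof.segments:
            rows.append((s.sample_id, s.chrom, s.start + 1, s.end, s.tcn, s.mcn_minor))
    pd.DataFrame(
        rows, columns=["sample", "chrom", "start", "end", "tcn", "mcn_minor"]
    ).to_csv(path, sep="\t", index=False)


def write_variants(variants: Iterable[VariantRecord], path: str | Path) -> None:
    ordered = sorted(variants, key=lambda v: (v.sample_id, v.chrom, v.pos, v.ref, v.alt))
    rows = [
        (v.sample_id, v.chrom, v.pos, v.ref, v.alt, v.t_alt, v.t_depth,
         v.n_alt, v.n_depth, v.n_callers, v.pop_maf, v.is_coding,
         v.is_nonsynonymous, v.gene)
        for v in ordered
    ]
    pd.DataFrame(
        rows, columns=["sample", "chrom", "pos", "ref", "alt", "t_alt", "t_depth",
                       "n_alt", "n_depth", "n_callers", "pop_maf", "is_coding",
                       "is_nonsynonymous", "gene"]
    ).to_csv(path, sep="\t", index=False)


def write_sv_bedpe(svs: Iterable[SVRecord], path: str | Path) -> None:
    ordered = sorted(svs, key=lambda s: (s.sample_id, s.chrom1, s.pos1, s.chrom2, s.pos2))
    rows = [
        (s.chrom1, s.pos1, s.pos1 + 1, s.chrom2, s.pos2, s.pos2 + 1,
         s.sample_id, ".", s.strand1, s.strand2)
        for s in ordered
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)


def write_metadata(metadata: Iterable[SampleMetadata], path: str | Path) -> None:
    ordered = sorted(metadata, key=lambda m: m.sample_id)
    rows = [
        (m.sample_id, m.age, m.sex, m.histology, m.pre_rt, m.post_rt,
         m.recurred, m.rfs_months, m.died, m.os_months)
        for m in ordered
    ]
    pd.DataFrame(
        rows, columns=["sample", "age", "sex", "histology", "pre_rt", "post_rt",
                       "recurred", "rfs_months", "died", "os_months"]
    ).to_csv(path, sep="\t", index=False)
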