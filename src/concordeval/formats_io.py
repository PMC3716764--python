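"""Readers and writers for the formats the pipeline touches.

VCF (single-sample, 4.1), BED3 capture targets, FASTA reference and a
tab-separated SNP-array genotype table are mapped onto small domain types.
Coordinate conventions: VCF and array positions are 1-based; BED intervals
are 0-based half-open.  :func:`pos_in_interval` owns the off-by-one.
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from cyvcf2 import VCF

__all__ = [
    "Genotype",
    "VariantRecord",
    "TargetInterval",
    "ArrayGenotypeRecord",
    "VcfFormatError",
    "read_vcf",
    "write_vcf",
    "read_bed",
    "normalize_intervals",
    "pos_in_interval",
    "find_containing_interval",
    "read_array_table",
    "write_array_table",
]

VALID_BASES = frozenset("ACGT")


class Genotype(enum.Enum):
    """Diploid genotype state of one sample at one site."""

    HOM_REF = 0
    HET = 1
    HOM_ALT = 2
    NO_CALL = 3

    @property
    def is_variant(self) -> bool:
        """A site is *variant* when at least one alternate allele is called."""
        return self in (Genotype.HET, Genotype.HOM_ALT)

    @property
    def is_called(self) -> bool:
        return self is not Genotype.NO_CALL


class VcfFormatError(ValueError):
    """Malformed VCF/BED/array-table content, naming the offending line."""


@dataclass(frozen=True)
class VariantRecord:
    """One single-sample variant call with the annotations the filters use.

    ``id_`` is ``None`` for novel sites; a non-``None`` id marks the site as
    dbSNP-known.  Annotation fields (``qual``, ``depth``, ``mq0``, ``qd``,
    ``hrun``, ``sb``) are ``None`` when the caller did not emit them.
    ``filter_status`` is ``("PASS",)`` or a tuple of failed filter names.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    genotype: Genotype
    id_: str | None = None
    qual: float | None = None
    depth: int | None = None
    mq0: int | None = None
    qd: float | None = None
    hrun: int | None = None
    sb: float | None = None
    filter_status: tuple[str, ...] = ("PASS",)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")
        if self.depth is not None and self.depth < 0:
            raise ValueError("depth must be >= 0")
        if (
            self.mq0 is not None
            and self.depth is not None
            and not 0 <= self.mq0 <= self.depth
        ):
            raise ValueError(f"mq0 must be in [0, depth], got {self.mq0}/{self.depth}")

    @property
    def vclass(self) -> str:
        """``"SNP"`` iff ref and alt are single bases, else ``"INDEL"``."""
        return "SNP" if len(self.ref) == 1 and len(self.alt) == 1 else "INDEL"

    @property
    def known(self) -> bool:
        return self.id_ is not None

    @property
    def passed(self) -> bool:
        return self.filter_status == ("PASS",)

    def with_filter(self, status: tuple[str, ...]) -> "VariantRecord":
        return replace(self, filter_status=status)


@dataclass(frozen=True, order=True)
class TargetInterval:
    """Capture target, BED convention: 0-based start, exclusive end."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"start must be < end: {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ArrayGenotypeRecord:
    """One SNP-array genotype call (Birdseed-style A/B allele frame)."""

    marker: str
    chrom: str
    pos: int  # 1-based
    allele_a: str
    allele_b: str
    call: str  # AA | AB | BB | NO_CALL
    confidence: float

    def __post_init__(self) -> None:
        if self.allele_a == self.allele_b:
            raise ValueError(f"marker {self.marker}: allele_a == allele_b")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(
                f"marker {self.marker}: confidence {self.confidence} outside [0, 1]"
            )
        if self.call not in ("AA", "AB", "BB", "NO_CALL"):
            raise ValueError(f"marker {self.marker}: bad call {self.call!r}")


def pos_in_interval(pos: int, interval: TargetInterval) -> bool:
    """Is a 1-based position inside a 0-based half-open interval?"""
    return interval.start <= pos - 1 < interval.end


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_GT_MAP = {0: Genotype.HOM_REF, 1: Genotype.HET, 2: Genotype.HOM_ALT}

_VCF_HEADER_LINES = [
    "##fileformat=VCFv4.1",
    '##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    '##INFO=<ID=MQ0,Number=1,Type=Integer,Description="Number of reads with mapping quality zero">',
    '##INFO=<ID=QD,Number=1,Type=Float,Description="Variant confidence / quality by depth">',
    '##INFO=<ID=HRun,Number=1,Type=Integer,Description="Largest contiguous homopolymer run of the variant allele">',
    '##INFO=<ID=SB,Number=1,Type=Float,Description="Strand bias">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
]

_FILTER_DESCRIPTIONS = {
    "MQ0_FRACTION": "MQ0/DP above threshold",
    "LOW_DP": "Depth below threshold",
    "LOW_QUAL": "Site quality below threshold",
    "LOW_QD": "Quality by depth below threshold",
    "HRUN": "Homopolymer run above threshold",
    "STRAND_BIAS": "Strand bias at or above threshold",
}


def read_vcf(path: str | Path, sample: str | None = None) -> list[VariantRecord]:
    """Read a VCF into :class:`VariantRecord` objects for one sample.

    Multi-allelic records are split into one record per alternate allele.
    Records whose ref or alt contain bases outside ``ACGT`` are skipped and
    counted (see :func:`read_vcf_with_stats`).
    """
    records, _ = read_vcf_with_stats(path, sample=sample)
    return records


def read_vcf_with_stats(
    path: str | Path, sample: str | None = None
) -> tuple[list[VariantRecord], dict[str, int]]:
    """As :func:`read_vcf`, also returning skip/warning counters."""
    path = str(path)
    try:
        vcf = VCF(path)
    except Exception as exc:  # cyvcf2 raises bare OSError on parse failure
        raise VcfFormatError(f"{path}: cannot open as VCF: {exc}") from exc
    samples = list(vcf.samples)
    if not samples:
        raise VcfFormatError(f"{path}: no sample columns")
    if sample is None:
        col = 0
    else:
        try:
            col = samples.index(sample)
        except ValueError:
            raise KeyError(f"sample {sample!r} not in {samples}") from None

    stats = {"n_skipped_ambiguous": 0, "n_split_multiallelic": 0}
    records: list[VariantRecord] = []
    for var in vcf:
        alts = var.ALT or []
        if len(alts) > 1:
            stats["n_split_multiallelic"] += 1
        gt = var.genotypes[col]
        alleles = [a for a in gt[:-1] if isinstance(a, int)]
        filt = ("PASS",) if var.FILTER is None else tuple(var.FILTER.split(";"))
        for ai, alt in enumerate(alts, start=1):
            ref = var.REF
            if set(ref) - VALID_BASES or set(alt) - VALID_BASES:
                stats["n_skipped_ambiguous"] += 1
                continue
            if any(a < 0 for a in gt[:-1]) or not alleles:
                genotype = Genotype.NO_CALL
            else:
                n_alt = sum(1 for a in alleles if a == ai)
                genotype = _GT_MAP[min(n_alt, 2)]
            records.append(
                VariantRecord(
                    chrom=var.CHROM,
                    pos=var.POS,
                    ref=ref,
                    alt=alt,
                    genotype=genotype,
                    id_=var.ID if var.ID not in (None, ".") else None,
                    qual=None if var.QUAL is None else round(var.QUAL, 2),
                    depth=_info_int(var, "DP"),
                    mq0=_info_int(var, "MQ0"),
                    qd=_info_float(var, "QD"),
                    hrun=_info_int(var, "HRun"),
                    sb=_info_float(var, "SB"),
                    filter_status=filt,
                )
            )
    vcf.close()
    return records, stats


def _info_int(var, key: str) -> int | None:
    v = var.INFO.get(key)
    return None if v is None else int(v)


def _info_float(var, key: str) -> float | None:
    # htslib stores INFO floats as float32; round to the 2-decimal precision
    # the writer emits so a write/read cycle is exact on the domain fields
    v = var.INFO.get(key)
    return None if v is None else round(float(v), 2)


_GT_STRING = {
    Genotype.HOM_REF: "0/0",
    Genotype.HET: "0/1",
    Genotype.HOM_ALT: "1/1",
    Genotype.NO_CALL: "./.",
}


def write_vcf(
    records: Sequence[VariantRecord], path: str | Path, sample: str = "SAMPLE"
) -> None:
    """Write records as a single-sample VCF 4.1 file.

    Records must be sorted by (chrom, pos).  Annotations travel in INFO;
    ``filter_status`` populates FILTER.
    """
    order = [(r.chrom, r.pos) for r in records]
    if order != sorted(order):
        raise ValueError("records must be sorted by (chrom, pos)")
    lines = list(_VCF_HEADER_LINES)
    for chrom in sorted({r.chrom for r in records}):
        lines.append(f"##contig=<ID={chrom}>")
    filters_used = sorted(
        {f for r in records for f in r.filter_status if f != "PASS"}
    )
    for name in filters_used:
        desc = _FILTER_DESCRIPTIONS.get(name, name)
        lines.append(f'##FILTER=<ID={name},Description="{desc}">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample
    )
    for r in records:
        info_parts = []
        if r.depth is not None:
            info_parts.append(f"DP={r.depth}")
        if r.mq0 is not None:
            info_parts.append(f"MQ0={r.mq0}")
        if r.qd is not None:
            info_parts.append(f"QD={r.qd:.2f}")
        if r.hrun is not None:
            info_parts.append(f"HRun={r.hrun}")
        if r.sb is not None:
            info_parts.append(f"SB={r.sb:.2f}")
        lines.append(
            "\t".join(
                [
                    r.chrom,
                    str(r.pos),
                    r.id_ if r.id_ is not None else ".",
                    r.ref,
                    r.alt,
                    f"{r.qual:.2f}" if r.qual is not None else ".",
                    ";".join(r.filter_status),
                    ";".join(info_parts) if info_parts else ".",
                    "GT",
                    _GT_STRING[r.genotype],
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


def read_bed(path: str | Path) -> list[TargetInterval]:
    """Read BED3 target intervals, normalized (sorted, overlaps merged)."""
    intervals: list[TargetInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise VcfFormatError(f"{path}:{lineno}: expected >= 3 BED columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                raise VcfFormatError(
                    f"{path}:{lineno}: start {start} >= end {end}"
                )
            intervals.append(TargetInterval(chrom, start, end))
    return normalize_intervals(intervals)


def normalize_intervals(intervals: Iterable[TargetInterval]) -> list[TargetInterval]:
    """Sort intervals and merge overlapping ones.

    Abutting half-open intervals ([a,b), [b,c)) are *not* merged: zero
    overlap.  Idempotent.
    """
    out: list[TargetInterval] = []
    for iv in sorted(intervals):
        if out and out[-1].chrom == iv.chrom and iv.start < out[-1].end:
            prev = out.pop()
            out.append(TargetInterval(prev.chrom, prev.start, max(prev.end, iv.end)))
        else:
            out.append(iv)
    return out


def find_containing_interval(
    chrom: str, pos: int, intervals: Sequence[TargetInterval]
) -> TargetInterval | None:
    """Return the normalized interval containing 1-based ``pos``, if any."""
    import bisect

    keyed = [(iv.chrom, iv.start) for iv in intervals]
    i = bisect.bisect_right(keyed, (chrom, pos - 1)) - 1
    if i >= 0:
        iv = intervals[i]
        if iv.chrom == chrom and pos_in_interval(pos, iv):
            return iv
    return None


def write_bed(intervals: Sequence[TargetInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


# ---------------------------------------------------------------------------
# SNP-array genotype table
# ---------------------------------------------------------------------------

_ARRAY_COLUMNS = ["marker", "chrom", "pos", "allele_a", "allele_b", "call", "confidence"]
_CALL_ALIASES = {"NOCALL": "NO_CALL", "NO_CALL": "NO_CALL", "---": "NO_CALL"}


def read_array_table(path: str | Path) -> list[ArrayGenotypeRecord]:
    """Read a tab-separated array genotype table (header required)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(_ARRAY_COLUMNS) - set(df.columns)
    if missing:
        raise VcfFormatError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        call = str(row.call).upper()
        call = _CALL_ALIASES.get(call, call)
        conf = float(row.confidence)
        if not 0.0 <= conf <= 1.0:
            raise VcfFormatError(
                f"{path}: marker {row.marker}: confidence {conf} outside [0, 1]"
            )
        records.append(
            ArrayGenotypeRecord(
                marker=str(row.marker),
                chrom=str(row.chrom),
                pos=int(row.pos),
                allele_a=str(row.allele_a),
                allele_b=str(row.allele_b),
                call=call,
                confidence=conf,
            )
        )
    return records


def write_array_table(records: Sequence[ArrayGenotypeRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (r.marker, r.chrom, r.pos, r.allele_a, r.allele_b, r.call, r.confidence)
            for r in records
        ],
        columns=_ARRAY_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)
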