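"""Post-call hard filters for SNP and INDEL records.

The filter expressions mirror the GATK-VariantFiltration style used in
WGA-vs-genomic capture resequencing comparisons:

SNPs fail when::

    (MQ0 / DP) > 0.05  or  DP < 5  or  QUAL < 30.0
    or QD < 5.0  or  HRun > 5  or  SB >= -0.10

INDELs fail when::

    (MQ0 / DP) > 0.05  or  SB >= -1.0  or  QUAL < 10

Inequalities are applied exactly as written (strict for < and >, inclusive
for the SB >= bound).  A record with a missing annotation skips that term —
a missing value never fails a filter — and the skip is counted.  DP = 0
fails LOW_DP and skips the MQ0 fraction term (division guard).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .formats_io import VariantRecord

__all__ = [
    "FilterThresholds",
    "FilterOutcome",
    "FilterSummary",
    "apply_snp_filter",
    "apply_indel_filter",
    "filter_callset",
    "SNP_TERMS",
    "INDEL_TERMS",
]

SNP_TERMS = ("MQ0_FRACTION", "LOW_DP", "LOW_QUAL", "LOW_QD", "HRUN", "STRAND_BIAS")
INDEL_TERMS = ("MQ0_FRACTION", "STRAND_BIAS", "LOW_QUAL")


@dataclass(frozen=True)
class FilterThresholds:
    """Hard-filter thresholds; defaults are the standard expression values."""

    snp_mq0_fraction: float = 0.05
    snp_min_dp: int = 5
    snp_min_qual: float = 30.0
    snp_min_qd: float = 5.0
    snp_max_hrun: int = 5
    snp_sb_bound: float = -0.10
    indel_mq0_fraction: float = 0.05
    indel_sb_bound: float = -1.0
    indel_min_qual: float = 10.0


@dataclass(frozen=True)
class FilterOutcome:
    passed: bool
    failed_terms: tuple[str, ...]
    skipped_terms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        assert self.passed == (not self.failed_terms)

    @property
    def filter_status(self) -> tuple[str, ...]:
        return ("PASS",) if self.passed else self.failed_terms


@dataclass
class FilterSummary:
    """Aggregate counts over a callset; a record can fail several terms."""

    n_records: int = 0
    n_pass: int = 0
    failed_term_counts: dict[str, int] = field(default_factory=dict)
    skipped_term_counts: dict[str, int] = field(default_factory=dict)

    def add(self, outcome: FilterOutcome) -> None:
        self.n_records += 1
        if outcome.passed:
            self.n_pass += 1
        for t in outcome.failed_terms:
            self.failed_term_counts[t] = self.failed_term_counts.get(t, 0) + 1
        for t in outcome.skipped_terms:
            self.skipped_term_counts[t] = self.skipped_term_counts.get(t, 0) + 1


def apply_snp_filter(
    record: VariantRecord, thresholds: FilterThresholds | None = None
) -> FilterOutcome:
    """Evaluate the SNP hard-filter expression on one record."""
    if record.vclass != "SNP":
        raise ValueError(f"apply_snp_filter on {record.vclass} record")
    t = thresholds or FilterThresholds()
    failed: list[str] = []
    skipped: list[str] = []

    _mq0_term(record, t.snp_mq0_fraction, failed, skipped)
    if record.depth is None:
        skipped.append("LOW_DP")
    elif record.depth < t.snp_min_dp:
        failed.append("LOW_DP")
    if record.qual is None:
        skipped.append("LOW_QUAL")
    elif record.qual < t.snp_min_qual:
        failed.append("LOW_QUAL")
    if record.qd is None:
        skipped.append("LOW_QD")
    elif record.qd < t.snp_min_qd:
        failed.append("LOW_QD")
    if record.hrun is None:
        skipped.append("HRUN")
    elif record.hrun > t.snp_max_hrun:
        failed.append("HRUN")
    if record.sb is None:
        skipped.append("STRAND_BIAS")
    elif record.sb >= t.snp_sb_bound:
        failed.append("STRAND_BIAS")
    return FilterOutcome(not failed, tuple(failed), tuple(skipped))


def apply_indel_filter(
    record: VariantRecord, thresholds: FilterThresholds | None = None
) -> FilterOutcome:
    """Evaluate the INDEL hard-filter expression on one record."""
    if record.vclass != "INDEL":
        raise ValueError(f"apply_indel_filter on {record.vclass} record")
    t = thresholds or FilterThresholds()
    failed: list[str] = []
    skipped: list[str] = []

    _mq0_term(record, t.indel_mq0_fraction, failed, skipped)
    if record.sb is None:
        skipped.append("STRAND_BIAS")
    elif record.sb >= t.indel_sb_bound:
        failed.append("STRAND_BIAS")
    if record.qual is None:
        skipped.append("LOW_QUAL")
    elif record.qual < t.indel_min_qual:
        failed.append("LOW_QUAL")
    return FilterOutcome(not failed, tuple(failed), tuple(skipped))


def _mq0_term(
    record: VariantRecord, bound: float, failed: list[str], skipped: list[str]
) -> None:
    # DP = 0 fails LOW_DP elsewhere; the fraction is left unevaluated.
    if record.mq0 is None or record.depth is None or record.depth == 0:
        skipped.append("MQ0_FRACTION")
    elif record.mq0 / record.depth > bound:
        failed.append("MQ0_FRACTION")


def filter_callset(
    records: Iterable[VariantRecord], thresholds: FilterThresholds | None = None
) -> tuple[list[VariantRecord], FilterSummary]:
    """Apply the class-appropriate filter to every record.

    Returns the PASS-only records (with ``filter_status`` updated on every
    input record's copy) and a :class:`FilterSummary`.
    """
    summary = FilterSummary()
    passing: list[VariantRecord] = []
    for rec in records:
        outcome = (
            apply_snp_filter(rec, thresholds)
            if rec.vclass == "SNP"
            else apply_indel_filter(rec, thresholds)
        )
        summary.add(outcome)
        updated = rec.with_filter(outcome.filter_status)
        if outcome.passed:
            passing.append(updated)
    return passing, summary


def annotate_filters(
    records: Iterable[VariantRecord], thresholds: FilterThresholds | None = None
) -> list[VariantRecord]:
    """Return all records with ``filter_status`` set (PASS and failed alike)."""
    out = []
    for rec in records:
        outcome = (
            apply_snp_filter(rec, thresholds)
            if rec.vclass == "SNP"
            else apply_indel_filter(rec, thresholds)
        )
        out.append(rec.with_filter(outcome.filter_status))
    return out
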