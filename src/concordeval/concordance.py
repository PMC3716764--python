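"""Merge two PASS-only callsets and compute genotype-concordance metrics.

The central objects are the merged site table and the 4x4 genotype
concordance matrix (evaluation genotype x comparison genotype).  From the
matrix follow the two headline metrics:

* **NRS** (non-reference sensitivity): of the sites called variant in the
  comparison callset, the fraction also called variant in the evaluation
  callset.  Evaluation hom-ref or no-call at a comparison-variant site
  reduces NRS.
* **NRD** (non-reference discrepancy): among sites genotyped in *both*
  callsets, excluding concordant hom-ref pairs, the fraction of discordant
  genotypes.  A no-call in either callset is excluded from numerator and
  denominator.

A site absent from one callset is interpreted as implicitly hom-ref there
(the caller emitted no record); an explicit ``./.`` record is a no-call.
Both reduce NRS; only the no-call is excluded from NRD.

Undefined ratios (zero denominators) are returned as ``None``, never as 0
or 100.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .formats_io import (
    Genotype,
    TargetInterval,
    VariantRecord,
    find_containing_interval,
    pos_in_interval,
)

__all__ = [
    "MergedSite",
    "MergeResult",
    "ConcordanceMatrix",
    "CallsetSummary",
    "VennPartition",
    "merge_callsets",
    "concordance_matrix",
    "nrs",
    "nrd",
    "venn_partition",
    "callset_summary",
    "tstv_ratio",
    "is_transition",
]

_GENOTYPE_ORDER = (Genotype.HOM_REF, Genotype.HET, Genotype.HOM_ALT, Genotype.NO_CALL)


@dataclass(frozen=True)
class MergedSite:
    """One genomic site after merging the evaluation and comparison callsets.

    Sites hom-ref/no-call in both callsets are never materialized.  When the
    two callsets disagree on the alternate allele, both alts are retained and
    the site is genotype-discordant downstream even if the genotype *states*
    coincide.
    """

    chrom: str
    pos: int
    ref: str
    g_eval: Genotype
    g_comp: Genotype
    alt_eval: str | None = None
    alt_comp: str | None = None
    known: bool = False
    vclass: str = "SNP"

    @property
    def alt_mismatch(self) -> bool:
        return (
            self.alt_eval is not None
            and self.alt_comp is not None
            and self.alt_eval != self.alt_comp
        )

    @property
    def genotypes_discordant(self) -> bool:
        """Genotype disagreement, counting alt-allele mismatch as discordance."""
        return self.g_eval != self.g_comp or self.alt_mismatch


@dataclass
class MergeResult:
    sites: list[MergedSite]
    n_ref_conflicts: int = 0
    n_off_target_eval: int = 0
    n_off_target_comp: int = 0


@dataclass(frozen=True)
class ConcordanceMatrix:
    """4x4 genotype-pair counts, rows = evaluation, columns = comparison.

    Index order HOM_REF, HET, HOM_ALT, NO_CALL.  ``n_alt_mismatch`` counts
    sites whose genotype states agree but whose alternate alleles differ;
    they sit in diagonal cells yet are discordant for NRD.
    """

    counts: np.ndarray
    n_alt_mismatch: int = 0

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.shape != (4, 4):
            raise ValueError("concordance matrix must be 4x4")
        if (c < 0).any():
            raise ValueError("negative cell count")
        object.__setattr__(self, "counts", c)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def cell(self, g_eval: Genotype, g_comp: Genotype) -> int:
        return int(self.counts[g_eval.value, g_comp.value])

    def to_frame(self) -> pd.DataFrame:
        names = [g.name for g in _GENOTYPE_ORDER]
        return pd.DataFrame(self.counts, index=names, columns=names).rename_axis(
            index="evaluation", columns="comparison"
        )


@dataclass(frozen=True)
class CallsetSummary:
    """Per-callset summary: count, dbSNP fraction, TsTv ratios.

    TsTv ratios are ``None`` when undefined (no transversions, or no
    records in the stratum).
    """

    n_variants: int
    dbsnp_percent: float | None
    tstv_overall: float | None
    tstv_novel: float | None
    tstv_known: float | None


@dataclass(frozen=True)
class VennPartition:
    n_eval_only: int
    n_comp_only: int
    n_intersection: int
    summary_eval_only: CallsetSummary | None = None
    summary_comp_only: CallsetSummary | None = None
    summary_intersection: CallsetSummary | None = None

    @property
    def union_size(self) -> int:
        return self.n_eval_only + self.n_comp_only + self.n_intersection


# ---------------------------------------------------------------------------
# Merging
# ---------------------------------------------------------------------------


def merge_callsets(
    eval_records: Iterable[VariantRecord],
    comp_records: Iterable[VariantRecord],
    targets: Sequence[TargetInterval] | None = None,
) -> MergeResult:
    """Merge two PASS-only callsets into one site table.

    SNP sites are keyed by (chrom, pos): alternate-allele disagreement at a
    shared position is retained as a discordance, matching a coordinate-based
    intersection.  INDELs are keyed by (chrom, pos, ref, alt) exactly.  Sites
    present in one callset only get an implicit hom-ref genotype in the other.
    A ref mismatch at a shared SNP key excludes the site and is counted.
    """
    result = MergeResult(sites=[])

    def on_target(rec: VariantRecord) -> bool:
        if targets is None:
            return True
        return find_containing_interval(rec.chrom, rec.pos, targets) is not None

    def keep(records: Iterable[VariantRecord], which: str) -> dict:
        kept: dict[tuple, VariantRecord] = {}
        for rec in records:
            if not rec.passed:
                raise ValueError("merge_callsets requires PASS-only records")
            if not on_target(rec):
                if which == "eval":
                    result.n_off_target_eval += 1
                else:
                    result.n_off_target_comp += 1
                continue
            if rec.vclass == "SNP":
                key = (rec.chrom, rec.pos, "SNP")
            else:
                key = (rec.chrom, rec.pos, "INDEL", rec.ref, rec.alt)
            kept[key] = rec
        return kept

    eval_by_key = keep(eval_records, "eval")
    comp_by_key = keep(comp_records, "comp")

    for key in sorted(set(eval_by_key) | set(comp_by_key), key=lambda k: (k[0], k[1], k[2])):
        e = eval_by_key.get(key)
        c = comp_by_key.get(key)
        if e is not None and c is not None and e.ref != c.ref:
            result.n_ref_conflicts += 1
            continue
        g_eval = e.genotype if e is not None else Genotype.HOM_REF
        g_comp = c.genotype if c is not None else Genotype.HOM_REF
        if not (g_eval.is_variant or g_comp.is_variant):
            continue  # both hom-ref/no-call: never materialized
        ref = e.ref if e is not None else c.ref
        result.sites.append(
            MergedSite(
                chrom=key[0],
                pos=key[1],
                ref=ref,
                g_eval=g_eval,
                g_comp=g_comp,
                alt_eval=e.alt if e is not None else None,
                alt_comp=c.alt if c is not None else None,
                known=(e is not None and e.known) or (c is not None and c.known),
                vclass=key[2],
            )
        )
    return result


# ---------------------------------------------------------------------------
# Matrix and metrics
# ---------------------------------------------------------------------------


def concordance_matrix(
    merged: Iterable[MergedSite], vclass: str | None = None
) -> ConcordanceMatrix:
    """Tally (g_eval, g_comp) pairs into the 4x4 matrix."""
    counts = np.zeros((4, 4), dtype=np.int64)
    n_alt_mismatch = 0
    for site in merged:
        if vclass is not None and site.vclass != vclass:
            continue
        counts[site.g_eval.value, site.g_comp.value] += 1
        if site.g_eval == site.g_comp and site.alt_mismatch:
            n_alt_mismatch += 1
    return ConcordanceMatrix(counts, n_alt_mismatch)


def nrs(matrix: ConcordanceMatrix) -> float | None:
    """Non-reference sensitivity, in percent.

    NRS = 100 x (sites variant in both) / (sites variant in the comparison
    callset).  ``None`` when the comparison callset has no variant sites.
    """
    variant = (Genotype.HET, Genotype.HOM_ALT)
    denom = sum(matrix.cell(ge, gc) for gc in variant for ge in _GENOTYPE_ORDER)
    if denom == 0:
        return None
    numer = sum(matrix.cell(ge, gc) for gc in variant for ge in variant)
    return 100.0 * numer / denom


def nrd(matrix: ConcordanceMatrix) -> float | None:
    """Non-reference discrepancy, in percent.

    Over sites called in both callsets (no-calls excluded) and not
    concordant hom-ref: 100 x discordant / eligible.  Diagonal cells with an
    alternate-allele mismatch count as discordant.  ``None`` when no site is
    eligible.
    """
    called = (Genotype.HOM_REF, Genotype.HET, Genotype.HOM_ALT)
    denom = 0
    discordant = 0
    for ge in called:
        for gc in called:
            if ge == gc == Genotype.HOM_REF:
                continue
            n = matrix.cell(ge, gc)
            denom += n
            if ge != gc:
                discordant += n
    discordant += matrix.n_alt_mismatch
    if denom == 0:
        return None
    return 100.0 * discordant / denom


def venn_partition(
    merged: Iterable[MergedSite], vclass: str | None = None, summaries: bool = True
) -> VennPartition:
    """Coordinate-level Venn split of the merged sites.

    eval-only: evaluation variant, comparison hom-ref/no-call; comp-only
    symmetric; intersection: variant in both.  Per-partition TsTv and dbSNP
    summaries are computed for SNPs from the partition's site lists.
    """
    eval_only: list[MergedSite] = []
    comp_only: list[MergedSite] = []
    both: list[MergedSite] = []
    for site in merged:
        if vclass is not None and site.vclass != vclass:
            continue
        ev, cv = site.g_eval.is_variant, site.g_comp.is_variant
        if ev and cv:
            both.append(site)
        elif ev:
            eval_only.append(site)
        elif cv:
            comp_only.append(site)
    mk = _partition_summary if summaries else lambda sites: None
    return VennPartition(
        n_eval_only=len(eval_only),
        n_comp_only=len(comp_only),
        n_intersection=len(both),
        summary_eval_only=mk(eval_only),
        summary_comp_only=mk(comp_only),
        summary_intersection=mk(both),
    )


def _partition_summary(sites: list[MergedSite]) -> CallsetSummary | None:
    snps = [s for s in sites if s.vclass == "SNP"]
    rows = []
    for s in snps:
        alt = s.alt_eval if s.alt_eval is not None else s.alt_comp
        rows.append((s.ref, alt, s.known))
    return _summarize_rows(rows)


# ---------------------------------------------------------------------------
# Callset summaries
# ---------------------------------------------------------------------------

_TRANSITIONS = {frozenset("AG"), frozenset("CT")}


def is_transition(ref: str, alt: str) -> bool:
    """Transitions are the purine and pyrimidine swaps A<->G, C<->T."""
    return frozenset((ref, alt)) in _TRANSITIONS


def tstv_ratio(pairs: Iterable[tuple[str, str]]) -> float | None:
    """Transitions / transversions; ``None`` when transversions = 0."""
    ts = tv = 0
    for ref, alt in pairs:
        if is_transition(ref, alt):
            ts += 1
        else:
            tv += 1
    if tv == 0:
        return None
    return ts / tv


def callset_summary(records: Sequence[VariantRecord]) -> CallsetSummary:
    """Summarize one PASS-only callset of a single variant class.

    For SNPs, TsTv ratios are computed overall and stratified by dbSNP
    membership (known = id present, novel = id absent).  INDEL summaries
    carry ``None`` TsTv fields.
    """
    rows = [
        (r.ref, r.alt, r.known) for r in records if r.vclass == "SNP"
    ]
    base = _summarize_rows(rows)
    n = len(records)
    if n == 0:
        return CallsetSummary(0, None, None, None, None)
    dbsnp = 100.0 * sum(1 for r in records if r.known) / n
    return CallsetSummary(
        n_variants=n,
        dbsnp_percent=dbsnp,
        tstv_overall=base.tstv_overall,
        tstv_novel=base.tstv_novel,
        tstv_known=base.tstv_known,
    )


def _summarize_rows(rows: list[tuple[str, str, bool]]) -> CallsetSummary:
    n = len(rows)
    if n == 0:
        return CallsetSummary(0, None, None, None, None)
    dbsnp = 100.0 * sum(1 for _, _, k in rows if k) / n
    return CallsetSummary(
        n_variants=n,
        dbsnp_percent=dbsnp,
        tstv_overall=tstv_ratio((r, a) for r, a, _ in rows),
        tstv_novel=tstv_ratio((r, a) for r, a, k in rows if not k) if any(not k for *_, k in rows) else None,
        tstv_known=tstv_ratio((r, a) for r, a, k in rows if k) if any(k for *_, k in rows) else None,
    )
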