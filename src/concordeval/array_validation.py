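"""Validate sequencing-derived SNP genotypes against SNP-array genotypes.

Array markers are first restricted to capture targets and to a per-call
confidence criterion (Birdseed-style scores are better when *lower*, so the
default keeps calls with confidence at most 0.05; the direction is
configurable).  A/B array calls are mapped onto the reference frame of the
sequencing callset, the array becomes the comparison callset, and the
concordance engine produces the matrix, NRS/NRD, and a three-category
allele spectrum (concordant / NRS-contributing / NRD-contributing).

Markers whose alleles cannot be oriented against ref/alt even after
reverse complementation — in particular A/T and C/G markers, where the
complement is ambiguous — are excluded and counted rather than guessed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd

from . import allele_bias, concordance
from .concordance import ConcordanceMatrix, MergedSite
from .formats_io import (
    ArrayGenotypeRecord,
    Genotype,
    TargetInterval,
    VariantRecord,
    find_containing_interval,
)

__all__ = [
    "ValidatedSite",
    "ValidationResult",
    "filter_array_sites",
    "array_to_genotype",
    "validate",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_AMBIGUOUS_PAIRS = ({"A", "T"}, {"C", "G"})  # self-complementary allele pairs


@dataclass(frozen=True)
class ValidatedSite:
    marker: str
    chrom: str
    pos: int
    g_seq: Genotype
    g_array: Genotype
    category: str  # CONCORDANT | NRS_CONTRIBUTING | NRD_CONTRIBUTING


@dataclass
class ValidationResult:
    matrix: ConcordanceMatrix
    nrs: float | None
    nrd: float | None
    sites: list[ValidatedSite]
    spectrum: pd.DataFrame
    n_excluded_strand_conflict: int = 0
    n_excluded_off_target: int = 0
    n_excluded_confidence: int = 0


def filter_array_sites(
    records: Iterable[ArrayGenotypeRecord],
    targets: Sequence[TargetInterval],
    confidence_threshold: float = 0.05,
    direction: Literal["at-most", "at-least"] = "at-most",
) -> tuple[list[ArrayGenotypeRecord], dict[str, int]]:
    """Keep markers on a capture target meeting the confidence criterion.

    Returns the retained records and per-reason exclusion counts.
    """
    retained = []
    counts = {"off_target": 0, "confidence": 0}
    for rec in records:
        if find_containing_interval(rec.chrom, rec.pos, targets) is None:
            counts["off_target"] += 1
            continue
        ok = (
            rec.confidence <= confidence_threshold
            if direction == "at-most"
            else rec.confidence >= confidence_threshold
        )
        if not ok:
            counts["confidence"] += 1
            continue
        retained.append(rec)
    return retained, counts


def array_to_genotype(
    record: ArrayGenotypeRecord, ref: str, alt: str | None
) -> Genotype | None:
    """Map an A/B array call onto HOM_REF/HET/HOM_ALT in the reference frame.

    Alleles are matched against (ref, alt) directly, or after reverse
    complementation when the direct match fails.  ``None`` signals a
    strand/allele conflict (including complement-ambiguous A/T and C/G
    markers when complementation would be needed or the orientation cannot
    be established); the caller excludes and counts such markers.
    """
    if record.call == "NO_CALL":
        return Genotype.NO_CALL
    pair = {record.allele_a, record.allele_b}
    expected = {ref} if alt is None else {ref, alt}

    def orient(a: str, b: str) -> Genotype | None:
        # a, b: marker alleles in the candidate frame; which one is ref?
        if alt is None:
            if ref not in (a, b):
                return None
            ref_is_a = a == ref
        else:
            if {a, b} != expected:
                return None
            ref_is_a = a == ref
        n_b = {"AA": 0, "AB": 1, "BB": 2}[record.call]
        n_alt = n_b if ref_is_a else 2 - n_b
        return (Genotype.HOM_REF, Genotype.HET, Genotype.HOM_ALT)[n_alt]

    if pair in _AMBIGUOUS_PAIRS:
        # complement equals the pair itself: strand cannot be resolved unless
        # the expected alleles are the same ambiguous pair AND we accept the
        # direct orientation; too risky — exclude.
        return None
    direct = orient(record.allele_a, record.allele_b)
    if direct is not None:
        return direct
    return orient(_COMPLEMENT[record.allele_a], _COMPLEMENT[record.allele_b])


def validate(
    seq_records: Sequence[VariantRecord],
    array_records: Iterable[ArrayGenotypeRecord],
    targets: Sequence[TargetInterval],
    confidence_threshold: float = 0.05,
    direction: Literal["at-most", "at-least"] = "at-most",
    reference: Mapping[str, str] | None = None,
) -> ValidationResult:
    """Concordance of sequencing SNP genotypes against array genotypes.

    The array is the comparison callset: array-variant markers missed by
    sequencing reduce NRS; called genotype disagreements contribute to NRD.
    Sequencing records must be PASS-only SNPs; a sequencing site without an
    array marker is outside the validation universe and ignored.

    At markers without a sequencing record the reference allele is read
    from ``reference`` (chrom -> sequence) when provided; without it, the
    marker's A allele is taken as the reference frame, which leaves hom
    calls at such markers orientation-ambiguous (see :func:`_infer_ref`).
    """
    retained, excl = filter_array_sites(
        array_records, targets, confidence_threshold, direction
    )
    seq_by_pos: dict[tuple[str, int], VariantRecord] = {}
    for rec in seq_records:
        if rec.vclass != "SNP":
            continue
        if not rec.passed:
            raise ValueError("validate requires PASS-only sequencing records")
        if find_containing_interval(rec.chrom, rec.pos, targets) is not None:
            seq_by_pos[(rec.chrom, rec.pos)] = rec

    merged: list[MergedSite] = []
    sites: list[ValidatedSite] = []
    n_conflict = 0
    for arr in retained:
        seq = seq_by_pos.get((arr.chrom, arr.pos))
        if seq is not None:
            ref, alt = seq.ref, seq.alt
        elif reference is not None:
            ref, alt = reference[arr.chrom][arr.pos - 1], None
        else:
            ref, alt = _infer_ref(arr), None
        g_array = array_to_genotype(arr, ref, alt)
        if g_array is None:
            n_conflict += 1
            continue
        g_seq = seq.genotype if seq is not None else Genotype.HOM_REF
        if not (g_seq.is_variant or g_array.is_variant):
            continue  # concordant hom-ref / uninformative marker
        site = MergedSite(
            chrom=arr.chrom,
            pos=arr.pos,
            ref=ref,
            g_eval=g_seq,
            g_comp=g_array,
            alt_eval=seq.alt if seq is not None else None,
            alt_comp=None,
            known=seq.known if seq is not None else False,
            vclass="SNP",
        )
        merged.append(site)
        sites.append(
            ValidatedSite(
                marker=arr.marker,
                chrom=arr.chrom,
                pos=arr.pos,
                g_seq=g_seq,
                g_array=g_array,
                category=allele_bias.categorize_site(site, mode="3way"),
            )
        )

    matrix = concordance.concordance_matrix(merged)
    categorized = [(s, allele_bias.categorize_site(s, "3way")) for s in merged if s.alt_eval is not None]
    spec = allele_bias.spectrum(categorized, mode="3way")
    return ValidationResult(
        matrix=matrix,
        nrs=concordance.nrs(matrix),
        nrd=concordance.nrd(matrix),
        sites=sites,
        spectrum=spec,
        n_excluded_strand_conflict=n_conflict,
        n_excluded_off_target=excl["off_target"],
        n_excluded_confidence=excl["confidence"],
    )


def _infer_ref(arr: ArrayGenotypeRecord) -> str:
    # Without a sequencing record the reference allele is unknown; take
    # allele_a as the reference frame.  Only hom-ref ("AA") markers matter
    # here — variant array calls at such markers enter as NRS-contributing
    # regardless of which allele is labelled ref, and the chosen frame makes
    # "AA" map to HOM_REF.
    return arr.allele_a
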