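"""Seeded generators for every input the evaluation pipeline consumes.

The generators emulate a paired capture-resequencing experiment: capture
targets with a programmed GC% spread, a reference sequence, two
single-sample callsets whose genotype pairs follow a programmed joint
distribution (hence programmed NRS/NRD), allele spectra with a programmed
transition/transversion ratio and dbSNP fraction, GC-penalized coverage
with consistent read placements, and SNP-array genotypes with programmed
discordance and no-call rates.

Every generator is a pure function of its :class:`SyntheticConfig`: the
config's seed fully determines the output, and the latent truth behind each
fixture is returned alongside it so tests can compare pipeline estimates to
analytic values instead of reverse-engineering the files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .formats_io import (
    ArrayGenotypeRecord,
    Genotype,
    TargetInterval,
    VariantRecord,
)
from .gc_coverage import TargetGC, quartile_bins

__all__ = [
    "SyntheticConfig",
    "joint_from_concordance",
    "analytic_nrs",
    "analytic_nrd",
    "boost_discordance",
    "generate_targets",
    "generate_paired_callsets",
    "generate_coverage_and_reads",
    "generate_array",
    "corrupt_callset",
]

_G = (Genotype.HOM_REF, Genotype.HET, Genotype.HOM_ALT, Genotype.NO_CALL)
_VARIANT = (Genotype.HET.value, Genotype.HOM_ALT.value)
_CALLED = (Genotype.HOM_REF.value, Genotype.HET.value, Genotype.HOM_ALT.value)

_TRANSITION_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSION_PARTNERS = {
    "A": ("C", "T"),
    "G": ("C", "T"),
    "C": ("A", "G"),
    "T": ("A", "G"),
}


# ---------------------------------------------------------------------------
# Joint genotype distribution construction and analytic metrics
# ---------------------------------------------------------------------------


def joint_from_concordance(
    nrs_percent: float,
    nrd_percent: float,
    het_fraction: float = 0.65,
) -> np.ndarray:
    """Build a 4x4 joint genotype distribution implying given NRS and NRD.

    Rows index the evaluation genotype, columns the comparison genotype,
    order HOM_REF/HET/HOM_ALT/NO_CALL, probabilities over *materialized*
    merged sites (at least one genotype variant).  The construction places
    the comparison-variant mass at 1 before normalization, splits the NRS
    loss between evaluation hom-ref and no-call, and sizes both-variant and
    evaluation-unique discordance so the called-site discrepancy equals the
    requested NRD.  ``het_fraction`` is the het share of concordant
    both-variant sites.
    """
    nrs = nrs_percent / 100.0
    nrd = nrd_percent / 100.0
    if not 0 < nrs <= 1 or not 0 <= nrd < 1:
        raise ValueError("need 0 < NRS <= 100 and 0 <= NRD < 100")
    miss = 1.0 - nrs  # comp-variant, eval not variant
    # called discordance outside the both-variant cells (eval hom-ref at a
    # comp-variant site, or eval-unique) is capped so the both-variant
    # discordant mass stays non-negative
    cap = nrd * nrs / (1.0 - nrd) if nrd > 0 else 0.0
    t = 0.5 * cap
    m_homref = min(miss / 2.0, t / 2.0)  # (HOM_REF, variant): reduces NRS and feeds NRD
    e_unique = t - m_homref  # (variant, HOM_REF): eval-unique, feeds NRD
    m_nocall = miss - m_homref  # (NO_CALL, variant): reduces NRS only
    dd = nrd * (nrs + m_homref + e_unique) - (m_homref + e_unique)
    dd = max(dd, 0.0)
    concordant = nrs - dd
    if concordant < 0:
        raise ValueError("requested NRD too large for requested NRS")

    j = np.zeros((4, 4))
    j[Genotype.HET.value, Genotype.HET.value] = concordant * het_fraction
    j[Genotype.HOM_ALT.value, Genotype.HOM_ALT.value] = concordant * (1 - het_fraction)
    j[Genotype.HET.value, Genotype.HOM_ALT.value] = dd / 2.0
    j[Genotype.HOM_ALT.value, Genotype.HET.value] = dd / 2.0
    j[Genotype.HOM_REF.value, Genotype.HET.value] = m_homref
    j[Genotype.NO_CALL.value, Genotype.HET.value] = m_nocall
    j[Genotype.HET.value, Genotype.HOM_REF.value] = e_unique
    return j / j.sum()


def analytic_nrs(joint: np.ndarray) -> float:
    """NRS (%) implied by a joint genotype distribution."""
    j = np.asarray(joint, dtype=float)
    denom = j[:, list(_VARIANT)].sum()
    numer = j[np.ix_(list(_VARIANT), list(_VARIANT))].sum()
    return 100.0 * numer / denom


def analytic_nrd(joint: np.ndarray) -> float:
    """NRD (%) implied by a joint genotype distribution."""
    j = np.asarray(joint, dtype=float)
    denom = numer = 0.0
    for ge in _CALLED:
        for gc in _CALLED:
            if ge == gc == Genotype.HOM_REF.value:
                continue
            denom += j[ge, gc]
            if ge != gc:
                numer += j[ge, gc]
    return 100.0 * numer / denom


def boost_discordance(joint: np.ndarray, factor: float) -> np.ndarray:
    """Scale all off-diagonal (discordant/missed) mass by ``factor``.

    Concordant diagonal cells absorb the change proportionally; used to give
    high-GC targets elevated discordance.
    """
    j = np.asarray(joint, dtype=float).copy()
    diag = np.eye(4, dtype=bool)
    off_mass = j[~diag].sum()
    if off_mass == 0 or factor == 1.0:
        return j / j.sum()
    j[~diag] *= factor
    new_off = j[~diag].sum()
    if new_off >= 1.0:
        raise ValueError("discordance boost exceeds total probability")
    diag_mass = j[diag].sum()
    j[diag] *= (1.0 - new_off) / diag_mass
    return j / j.sum()


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


def _default_joint() -> np.ndarray:
    # chr12-capture-scale SNP concordance: NRS 99.63%, NRD 0.29%
    return joint_from_concordance(99.63, 0.29)


def _default_joint_indel() -> np.ndarray:
    # chr12-capture-scale INDEL concordance: NRS 94.07%, NRD 10.7%
    return joint_from_concordance(94.07, 10.7)


@dataclass
class SyntheticConfig:
    """Generative parameters for all synthetic fixtures.

    Defaults emulate the chr12-scale custom-capture experiment: ~3.87 Mbp
    scaled down to a testable span, ~224x mean target coverage, SNP dbSNP
    fraction 98.6% with TsTv 2.43 (known) / 1.48 (novel), INDEL dbSNP
    fraction 34%, and a joint genotype distribution implying SNP NRS 99.63%
    / NRD 0.29%.
    """

    seed: int = 0
    # targets / reference
    n_targets: int = 80
    target_length: tuple[int, int] = (300, 1500)
    gap_length: tuple[int, int] = (200, 800)
    gc_range: tuple[float, float] = (30.0, 70.0)
    chrom: str = "chrS"
    # callsets
    n_snps: int = 5000
    n_indels: int = 500
    joint_snp: np.ndarray = field(default_factory=_default_joint)
    joint_indel: np.ndarray = field(default_factory=_default_joint_indel)
    dbsnp_fraction_snp: float = 0.986
    dbsnp_fraction_indel: float = 0.34
    tstv_known: float = 2.43
    tstv_novel: float = 1.48
    allele_spectrum: Mapping[str, Sequence[float]] | None = None
    filter_fail_fraction: float = 0.0
    gc_discordance_boost: float = 1.0
    # coverage / reads
    mean_coverage: float = 224.0
    read_length: int = 101
    gc_penalty: float = 1.0  # multiplier on expected coverage above the GC Q3
    coverage_noise_cv: float = 0.1
    # array
    array_offtarget_fraction: float = 0.15
    array_homref_fraction: float = 0.5
    array_nocall_rate: float = 0.01
    array_discordance_rate: float = 0.0
    array_lowconf_fraction: float = 0.05

    def rng(self, *stream: int) -> np.random.Generator:
        return np.random.Generator(
            np.random.PCG64(np.random.SeedSequence([int(self.seed), *map(int, stream)]))
        )


# ---------------------------------------------------------------------------
# Targets and reference
# ---------------------------------------------------------------------------


def _sequence_with_gc(rng: np.random.Generator, length: int, gc: float) -> str:
    """Sequence of ``length`` with an exact GC base count (within rounding)."""
    n_gc = int(round(length * gc / 100.0))
    bases = np.concatenate(
        [
            rng.choice(list("GC"), size=n_gc),
            rng.choice(list("AT"), size=length - n_gc),
        ]
    )
    rng.shuffle(bases)
    return "".join(bases)


def generate_targets(
    config: SyntheticConfig,
) -> tuple[list[TargetInterval], dict[str, str], list[TargetGC]]:
    """Generate capture targets, the reference sequence and per-target GC.

    Targets are non-overlapping, sorted, separated by gaps, on a single
    synthetic chromosome.  Each target's programmed GC% is drawn uniformly
    from ``gc_range`` and realized exactly (up to rounding) in the target
    sequence, so the realized value sits within 2 percentage points of the
    programmed one even for short targets.
    """
    rng = config.rng(1)
    parts: list[str] = []
    targets: list[TargetInterval] = []
    gcs: list[TargetGC] = []
    pos = 0
    for _ in range(config.n_targets):
        gap = int(rng.integers(config.gap_length[0], config.gap_length[1] + 1))
        parts.append(_sequence_with_gc(rng, gap, 40.0))
        pos += gap
        length = int(rng.integers(config.target_length[0], config.target_length[1] + 1))
        gc = float(rng.uniform(*config.gc_range))
        seq = _sequence_with_gc(rng, length, gc)
        parts.append(seq)
        iv = TargetInterval(config.chrom, pos, pos + length)
        targets.append(iv)
        from .gc_coverage import gc_percent

        realized, amb = gc_percent(seq)
        gcs.append(TargetGC(iv, realized, amb))
        pos += length
    tail = int(rng.integers(config.gap_length[0], config.gap_length[1] + 1))
    parts.append(_sequence_with_gc(rng, tail, 40.0))
    reference = {config.chrom: "".join(parts)}
    return targets, reference, gcs


# ---------------------------------------------------------------------------
# Paired callsets
# ---------------------------------------------------------------------------

_SPECTRUM_ORDER = ("A/C", "A/G", "A/T", "C/G", "C/T", "G/T")


def _draw_alt(
    rng: np.random.Generator, ref: str, known: bool, config: SyntheticConfig
) -> str:
    tstv = config.tstv_known if known else config.tstv_novel
    if rng.random() < tstv / (1.0 + tstv):
        return _TRANSITION_PARTNER[ref]
    return str(rng.choice(_TRANSVERSION_PARTNERS[ref]))


def _passing_annotations(
    rng: np.random.Generator, vclass: str, coverage: float
) -> dict:
    """Annotation values strictly inside the pass region (margined)."""
    # floats carry 2-decimal precision (the VCF writer's emitted precision)
    dp = max(6, int(rng.poisson(max(coverage, 6.0))))
    mq0 = min(int(rng.binomial(dp, 0.005)), int(0.049 * dp))
    ann = {
        "depth": dp,
        "mq0": mq0,
        "qual": round(float(rng.uniform(35.0, 1500.0)), 2),
        "qd": round(float(rng.uniform(6.0, 25.0)), 2),
        "hrun": int(rng.integers(0, 5)),
    }
    ann["sb"] = round(float(rng.uniform(-3.0, -0.2 if vclass == "SNP" else -1.2)), 2)
    return ann


_SNP_FAIL_TERMS = ("MQ0_FRACTION", "LOW_DP", "LOW_QUAL", "LOW_QD", "HRUN", "STRAND_BIAS")
_INDEL_FAIL_TERMS = ("MQ0_FRACTION", "STRAND_BIAS", "LOW_QUAL")


def _failing_annotations(
    rng: np.random.Generator, vclass: str, coverage: float
) -> dict:
    """Annotations violating exactly one uniformly chosen filter term."""
    ann = _passing_annotations(rng, vclass, coverage)
    term = str(rng.choice(_SNP_FAIL_TERMS if vclass == "SNP" else _INDEL_FAIL_TERMS))
    if term == "MQ0_FRACTION":
        ann["mq0"] = min(ann["depth"], int(np.ceil(0.06 * ann["depth"])))
    elif term == "LOW_DP":
        ann["depth"] = int(rng.integers(1, 5))
        ann["mq0"] = 0
    elif term == "LOW_QUAL":
        ann["qual"] = round(float(rng.uniform(0.0, 29.0 if vclass == "SNP" else 9.0)), 2)
    elif term == "LOW_QD":
        ann["qd"] = round(float(rng.uniform(0.0, 4.9)), 2)
    elif term == "HRUN":
        ann["hrun"] = int(rng.integers(6, 11))
    elif term == "STRAND_BIAS":
        ann["sb"] = round(float(rng.uniform(-0.09 if vclass == "SNP" else -0.9, 1.0)), 2)
    return ann


def generate_paired_callsets(
    config: SyntheticConfig,
    targets: Sequence[TargetInterval],
    reference: Mapping[str, str],
    target_gcs: Sequence[TargetGC] | None = None,
) -> tuple[list[VariantRecord], list[VariantRecord], pd.DataFrame]:
    """Generate the evaluation and comparison callsets plus the truth table.

    Site positions are drawn uniformly over target bases without collision;
    each site's genotype pair follows the configured joint distribution
    (optionally discordance-boosted in the top GC quartile); ref is the
    reference base; alt follows the TsTv model (or a per-category allele
    spectrum when configured); dbSNP ids are assigned at the configured
    fraction; a configured fraction of records receives filter-failing
    annotations.  A hom-ref genotype emits no record; NO_CALL emits an
    explicit ``./.`` record.

    The truth table records one row per site: chrom, pos, ref, alt, vclass,
    g_eval, g_comp, known, gc_bin, pass_eval, pass_comp.
    """
    rng = config.rng(2)
    chrom = config.chrom
    ref_seq = reference[chrom]

    bin4: set[TargetInterval] = set()
    target_of_pos: dict[int, TargetInterval] = {}
    if target_gcs is not None and len(target_gcs) >= 4:
        binning = quartile_bins(target_gcs)
        bin4 = {iv for iv, b in binning.assignment.items() if b == 4}
    joint = {"SNP": np.asarray(config.joint_snp), "INDEL": np.asarray(config.joint_indel)}
    joint_boost = {
        k: boost_discordance(v, config.gc_discordance_boost) for k, v in joint.items()
    }

    all_pos = np.concatenate(
        [np.arange(iv.start + 1, iv.end + 1) for iv in targets]
    )  # 1-based; leave the final base of each target usable for indel ref+1
    n_sites = config.n_snps + config.n_indels
    if n_sites > len(all_pos):
        raise ValueError("more sites requested than target bases available")
    pos_for_iv = {}
    for iv in targets:
        for p in range(iv.start + 1, iv.end + 1):
            pos_for_iv[p] = iv
    chosen = np.sort(rng.choice(all_pos, size=n_sites, replace=False))
    vclasses = np.array(["SNP"] * config.n_snps + ["INDEL"] * config.n_indels)
    rng.shuffle(vclasses)

    spectrum_cfg = None
    if config.allele_spectrum is not None:
        spectrum_cfg = {
            cat: np.asarray(p, dtype=float) / np.sum(p)
            for cat, p in config.allele_spectrum.items()
        }

    eval_records: list[VariantRecord] = []
    comp_records: list[VariantRecord] = []
    truth_rows = []
    rs_counter = 1

    for pos, vclass in zip(chosen, vclasses):
        pos = int(pos)
        iv = pos_for_iv[pos]
        j = joint_boost[vclass] if iv in bin4 else joint[vclass]
        pair = int(rng.choice(16, p=j.ravel()))
        g_eval, g_comp = _G[pair // 4], _G[pair % 4]

        known = rng.random() < (
            config.dbsnp_fraction_snp if vclass == "SNP" else config.dbsnp_fraction_indel
        )
        ref_base = ref_seq[pos - 1]
        if vclass == "SNP":
            if spectrum_cfg is not None:
                cat = _category_of(g_eval, g_comp)
                combo = _SPECTRUM_ORDER[
                    int(rng.choice(6, p=spectrum_cfg[cat]))
                ]
                a, b = combo.split("/")
                ref, alt = (a, b) if rng.random() < 0.5 else (b, a)
            else:
                ref = ref_base
                alt = _draw_alt(rng, ref, known, config)
        else:
            if rng.random() < 0.5:  # insertion
                ref = ref_base
                alt = ref_base + str(rng.choice(list("ACGT")))
            else:  # deletion: ref spans two bases
                nxt = ref_seq[pos] if pos < len(ref_seq) else "A"
                ref = ref_base + nxt
                alt = ref_base

        id_ = f"rs{900000 + rs_counter}" if known else None
        rs_counter += 1
        site_cov = config.mean_coverage

        def make_record(genotype: Genotype) -> tuple[VariantRecord | None, bool]:
            """Returns (record or None, passes_filters)."""
            if genotype is Genotype.HOM_REF:
                return None, True
            fail = rng.random() < config.filter_fail_fraction
            ann = (
                _failing_annotations(rng, vclass, site_cov)
                if fail
                else _passing_annotations(rng, vclass, site_cov)
            )
            rec = VariantRecord(
                chrom=chrom, pos=pos, ref=ref, alt=alt, genotype=genotype,
                id_=id_, **ann,
            )
            return rec, not fail

        rec_e, pass_e = make_record(g_eval)
        rec_c, pass_c = make_record(g_comp)
        if rec_e is not None:
            eval_records.append(rec_e)
        if rec_c is not None:
            comp_records.append(rec_c)
        truth_rows.append(
            {
                "chrom": chrom,
                "pos": pos,
                "ref": ref,
                "alt": alt,
                "vclass": vclass,
                "g_eval": g_eval.name,
                "g_comp": g_comp.name,
                "known": known,
                "gc_bin": 4 if iv in bin4 else 0,
                "pass_eval": pass_e,
                "pass_comp": pass_c,
            }
        )
    truth = pd.DataFrame(truth_rows)
    return eval_records, comp_records, truth


def _category_of(g_eval: Genotype, g_comp: Genotype) -> str:
    if g_eval.is_variant and g_comp.is_variant:
        return "CONCORDANT" if g_eval == g_comp else "DISCORDANT"
    if g_comp.is_variant:
        return "COMP_UNIQUE"
    if g_eval.is_variant:
        return "EVAL_UNIQUE"
    return "CONCORDANT"  # unreachable for materialized sites


# ---------------------------------------------------------------------------
# Coverage and reads
# ---------------------------------------------------------------------------


def generate_coverage_and_reads(
    config: SyntheticConfig,
    targets: Sequence[TargetInterval],
    target_gcs: Sequence[TargetGC],
) -> tuple[pd.DataFrame, list["ReadPlacement"], pd.DataFrame]:
    """Per-target coverage table, read placements and per-site depths.

    Expected coverage for a target is ``mean_coverage`` times the GC penalty
    when the target sits above the third GC quartile.  Read placements are
    drawn so every read overlaps its target by at least one base; the number
    of reads per target matches its realized coverage via N = C x len / L.
    """
    from .downsampling import ReadPlacement

    rng = config.rng(3)
    binning = quartile_bins(target_gcs)
    cov_rows = []
    reads: list[ReadPlacement] = []
    expected: dict[TargetInterval, float] = {}
    read_i = 0
    for iv in targets:
        penalty = config.gc_penalty if binning.assignment.get(iv) == 4 else 1.0
        exp_cov = config.mean_coverage * penalty
        expected[iv] = exp_cov
        for callset in ("eval", "comp"):
            med = max(
                0.0, float(rng.normal(exp_cov, config.coverage_noise_cv * exp_cov))
            )
            cov_rows.append(
                {
                    "chrom": iv.chrom,
                    "start": iv.start,
                    "end": iv.end,
                    "callset": callset,
                    "median_coverage": med,
                    "mean_coverage": med,
                }
            )
        n_reads = rng.poisson(exp_cov * iv.length / config.read_length)
        starts = rng.integers(
            iv.start - config.read_length + 1, iv.end, size=n_reads
        )
        for s in starts:
            reads.append(
                ReadPlacement(
                    read_id=f"r{read_i}",
                    chrom=iv.chrom,
                    start=int(s),
                    end=int(s) + config.read_length,
                    pair_id=f"p{read_i // 2}",
                )
            )
            read_i += 1
    coverage = pd.DataFrame(cov_rows)

    depth_rows = []
    for iv in targets:
        exp_cov = expected[iv]
        for pos in range(iv.start + 1, iv.end + 1, max(1, iv.length // 8)):
            depth_rows.append(
                {
                    "chrom": iv.chrom,
                    "pos": pos,
                    "depth": int(rng.poisson(exp_cov)),
                }
            )
    return coverage, reads, pd.DataFrame(depth_rows)


# ---------------------------------------------------------------------------
# SNP array
# ---------------------------------------------------------------------------


def generate_array(
    config: SyntheticConfig,
    truth: pd.DataFrame,
    targets: Sequence[TargetInterval],
    reference: Mapping[str, str],
) -> pd.DataFrame:
    """Array genotype table whose calls copy the evaluation-callset truth.

    Markers are placed at truth SNP sites (genotype = truth ``g_eval`` with
    programmed no-call and discordance rates applied), at additional
    on-target hom-ref positions, and at off-target positions (excluded by
    the validation target filter).  ``allele_a``/``allele_b`` carry ref/alt
    in random orientation; low-confidence markers receive scores above the
    usual Birdseed-style retention threshold.

    Returns both the array table (as a DataFrame matching the array-table
    schema) and, in ``df.attrs["truth_genotype"]``, the post-corruption
    genotype per marker.
    """
    rng = config.rng(4)
    chrom = config.chrom
    rows = []
    truth_g: dict[str, str] = {}
    marker_i = 1

    def confidence() -> float:
        if rng.random() < config.array_lowconf_fraction:
            return float(rng.uniform(0.06, 0.5))
        return float(rng.uniform(0.0, 0.04))

    def corrupted(g: Genotype) -> Genotype:
        # the discordance rate applies to variant genotypes only, so the
        # validation NRD estimate converges to the programmed rate; hom-ref
        # markers stay clean (a corrupted hom-ref would add discordant sites
        # outside the programmed-variant universe)
        if rng.random() < config.array_nocall_rate:
            return Genotype.NO_CALL
        if g.is_variant and rng.random() < config.array_discordance_rate:
            if g is Genotype.HET:
                return Genotype.HOM_REF if rng.random() < 0.5 else Genotype.HOM_ALT
            return Genotype.HET  # HOM_ALT -> HET
        return g

    call_of = {
        Genotype.HOM_REF: ("AA", "BB"),  # (allele_a == ref, allele_a == alt)
        Genotype.HET: ("AB", "AB"),
        Genotype.HOM_ALT: ("BB", "AA"),
        Genotype.NO_CALL: ("NO_CALL", "NO_CALL"),
    }

    def emit(pos: int, ref: str, alt: str, g: Genotype) -> None:
        nonlocal marker_i
        a_is_ref = rng.random() < 0.5
        allele_a, allele_b = (ref, alt) if a_is_ref else (alt, ref)
        call = call_of[g][0 if a_is_ref else 1]
        marker = f"SNP_A-{marker_i}"
        marker_i += 1
        rows.append(
            {
                "marker": marker,
                "chrom": chrom,
                "pos": pos,
                "allele_a": allele_a,
                "allele_b": allele_b,
                "call": call,
                "confidence": confidence(),
            }
        )
        truth_g[marker] = g.name

    snp_truth = truth[truth["vclass"] == "SNP"]
    for row in snp_truth.itertuples(index=False):
        emit(int(row.pos), row.ref, row.alt, corrupted(Genotype[row.g_eval]))

    # extra on-target hom-ref markers at positions not used by the callsets
    used = set(snp_truth["pos"])
    n_extra = int(config.array_homref_fraction * len(snp_truth))
    ref_seq = reference[chrom]
    candidates = [
        p
        for iv in targets
        for p in range(iv.start + 1, iv.end + 1, 37)
        if p not in used
    ]
    extra = rng.choice(len(candidates), size=min(n_extra, len(candidates)), replace=False)
    for i in np.sort(extra):
        pos = candidates[int(i)]
        ref = ref_seq[pos - 1]
        emit(pos, ref, _TRANSITION_PARTNER[ref], corrupted(Genotype.HOM_REF))

    # off-target markers, dropped by the validation target filter
    n_off = int(config.array_offtarget_fraction * len(rows))
    span_end = len(ref_seq)
    on_target = {p for iv in targets for p in range(iv.start + 1, iv.end + 1)}
    off_added = 0
    while off_added < n_off:
        pos = int(rng.integers(1, span_end + 1))
        if pos in on_target:
            continue
        ref = ref_seq[pos - 1]
        emit(pos, ref, _TRANSITION_PARTNER[ref], Genotype.HOM_REF)
        off_added += 1

    df = pd.DataFrame(rows).sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    df.attrs["truth_genotype"] = truth_g
    return df


def corrupt_callset(
    records: Sequence[VariantRecord],
    het_to_homref_rate: float,
    seed: int,
) -> list[VariantRecord]:
    """Drop a programmed fraction of variant records (variant -> hom-ref).

    Models loss of sensitivity in a sequencing callset: each variant record
    is removed with the given probability, so the site reverts to implicit
    hom-ref when merged.  Seeded and deterministic.
    """
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(int(seed))))
    out = []
    for rec in records:
        if rec.genotype.is_variant and rng.random() < het_to_homref_rate:
            continue
        out.append(rec)
    return out


# ---------------------------------------------------------------------------
# File emission helpers
# ---------------------------------------------------------------------------


def write_fasta(reference: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in reference.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def generate_fixture_files(config: SyntheticConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate the full fixture family on disk; returns the path map."""
    from .formats_io import write_array_table, write_bed, write_vcf
    from .downsampling import write_placement_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    targets, reference, gcs = generate_targets(config)
    eval_recs, comp_recs, truth = generate_paired_callsets(
        config, targets, reference, gcs
    )
    coverage, reads, depths = generate_coverage_and_reads(config, targets, gcs)
    array_df = generate_array(config, truth, targets, reference)

    paths = {
        "targets": outdir / "targets.bed",
        "reference": outdir / "reference.fa",
        "eval_vcf": outdir / "evaluation.vcf",
        "comp_vcf": outdir / "comparison.vcf",
        "truth": outdir / "truth.tsv",
        "coverage": outdir / "coverage.tsv",
        "reads": outdir / "reads.tsv",
        "depths": outdir / "depths.tsv",
        "array": outdir / "array.tsv",
    }
    write_bed(targets, paths["targets"])
    write_fasta(reference, paths["reference"])
    write_vcf(sorted(eval_recs, key=lambda r: (r.chrom, r.pos)), paths["eval_vcf"], sample="WGA")
    write_vcf(sorted(comp_recs, key=lambda r: (r.chrom, r.pos)), paths["comp_vcf"], sample="GENOMIC")
    truth.to_csv(paths["truth"], sep="\t", index=False)
    coverage.to_csv(paths["coverage"], sep="\t", index=False)
    write_placement_table(reads, paths["reads"])
    depths.to_csv(paths["depths"], sep="\t", index=False)
    array_df.to_csv(paths["array"], sep="\t", index=False)
    return paths
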