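"""Merging, Venn partitions, concordance matrix, NRS/NRD, TsTv summaries.

NRS/NRD computed from the 4x4 matrix are checked against brute-force
re-scans of the merged site list, including exhaustive small tables and
randomized fixtures.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from concordeval.concordance import (
    ConcordanceMatrix,
    MergedSite,
    callset_summary,
    concordance_matrix,
    is_transition,
    merge_callsets,
    nrd,
    nrs,
    tstv_ratio,
    venn_partition,
)
from concordeval.formats_io import Genotype, TargetInterval

from conftest import make_snp

G = Genotype


# ---------------------------------------------------------------------------
# Brute-force oracles: re-scan the site list, never the matrix
# ---------------------------------------------------------------------------


def nrs_bruteforce(sites: list[MergedSite]) -> float | None:
    comp_variant = [s for s in sites if s.g_comp.is_variant]
    if not comp_variant:
        return None
    hits = sum(1 for s in comp_variant if s.g_eval.is_variant)
    return 100.0 * hits / len(comp_variant)


def nrd_bruteforce(sites: list[MergedSite]) -> float | None:
    eligible = [
        s
        for s in sites
        if s.g_eval.is_called
        and s.g_comp.is_called
        and not (s.g_eval is G.HOM_REF and s.g_comp is G.HOM_REF)
    ]
    if not eligible:
        return None
    disc = sum(1 for s in eligible if s.genotypes_discordant)
    return 100.0 * disc / len(eligible)


def venn_bruteforce(sites: list[MergedSite]) -> tuple[int, int, int]:
    e = sum(1 for s in sites if s.g_eval.is_variant and not s.g_comp.is_variant)
    c = sum(1 for s in sites if s.g_comp.is_variant and not s.g_eval.is_variant)
    b = sum(1 for s in sites if s.g_eval.is_variant and s.g_comp.is_variant)
    return e, c, b


def sites_from_pairs(pairs) -> list[MergedSite]:
    return [
        MergedSite("c", i + 1, "A", ge, gc, alt_eval="G", alt_comp="G")
        for i, (ge, gc) in enumerate(pairs)
    ]


# the 12 genotype pairs of a materialized site (at least one variant)
MATERIALIZED_PAIRS = [
    (ge, gc)
    for ge in G
    for gc in G
    if ge.is_variant or gc.is_variant
]


# ---------------------------------------------------------------------------
# Merging
# ---------------------------------------------------------------------------


class TestMergeCallsets:
    def test_same_alt_het_in_both(self):
        e = [make_snp(pos=100)]
        c = [make_snp(pos=100)]
        sites = merge_callsets(e, c).sites
        assert len(sites) == 1
        assert (sites[0].g_eval, sites[0].g_comp) == (G.HET, G.HET)
        assert not sites[0].genotypes_discordant

    def test_absent_from_evaluation_is_implicit_homref(self):
        sites = merge_callsets([], [make_snp(pos=100)]).sites
        assert (sites[0].g_eval, sites[0].g_comp) == (G.HOM_REF, G.HET)

    def test_explicit_nocall_distinct_from_absence(self):
        e = [make_snp(pos=100, genotype=G.NO_CALL)]
        c = [make_snp(pos=100)]
        sites = merge_callsets(e, c).sites
        assert sites[0].g_eval is G.NO_CALL

    def test_alt_mismatch_retained_and_discordant(self):
        e = [make_snp(pos=100, ref="A", alt="G")]
        c = [make_snp(pos=100, ref="A", alt="T")]
        sites = merge_callsets(e, c).sites
        assert len(sites) == 1
        assert sites[0].alt_eval == "G" and sites[0].alt_comp == "T"
        assert sites[0].genotypes_discordant  # same state, different alt

    def test_ref_conflict_excluded_and_counted(self):
        e = [make_snp(pos=100, ref="A", alt="G")]
        c = [make_snp(pos=100, ref="C", alt="G")]
        result = merge_callsets(e, c)
        assert result.sites == [] and result.n_ref_conflicts == 1

    def test_target_restriction(self):
        targets = [TargetInterval("chr12", 0, 150)]
        e = [make_snp(pos=100), make_snp(pos=500)]
        result = merge_callsets(e, [], targets)
        assert len(result.sites) == 1
        assert result.n_off_target_eval == 1

    def test_non_pass_records_rejected(self):
        with pytest.raises(ValueError, match="PASS"):
            merge_callsets([make_snp(filter_status=("LOW_DP",))], [])

    def test_indels_keyed_by_ref_alt(self):
        # same position, different indel alleles: two separate sites
        e = [make_snp(pos=100, ref="A", alt="AT")]
        c = [make_snp(pos=100, ref="A", alt="ATT")]
        sites = merge_callsets(e, c).sites
        assert len(sites) == 2

    def test_six_site_merge_case_enumeration(self):
        """Hand-enumerated merge outcomes over the main case families."""
        e = [
            make_snp(pos=10),                                  # shared, concordant
            make_snp(pos=20, genotype=G.HOM_ALT),              # shared, discordant state
            make_snp(pos=30),                                  # eval-only
            make_snp(pos=50, ref="C", alt="G"),                # shared, alt mismatch
            make_snp(pos=60, genotype=G.NO_CALL),              # eval no-call
        ]
        c = [
            make_snp(pos=10),
            make_snp(pos=20),
            make_snp(pos=40),                                  # comp-only
            make_snp(pos=50, ref="C", alt="T"),
            make_snp(pos=60),
        ]
        sites = {s.pos: s for s in merge_callsets(e, c).sites}
        assert len(sites) == 6
        assert not sites[10].genotypes_discordant
        assert sites[20].genotypes_discordant
        assert (sites[30].g_eval, sites[30].g_comp) == (G.HET, G.HOM_REF)
        assert (sites[40].g_eval, sites[40].g_comp) == (G.HOM_REF, G.HET)
        assert sites[50].genotypes_discordant and sites[50].alt_mismatch
        assert (sites[60].g_eval, sites[60].g_comp) == (G.NO_CALL, G.HET)


# ---------------------------------------------------------------------------
# Venn
# ---------------------------------------------------------------------------


class TestVennPartition:
    def test_identical_callsets(self):
        sites = sites_from_pairs([(G.HET, G.HET)] * 5)
        v = venn_partition(sites)
        assert (v.n_eval_only, v.n_comp_only, v.n_intersection) == (0, 0, 5)

    def test_hand_counted_fixture(self):
        pairs = (
            [(G.HET, G.HET)] * 3
            + [(G.HET, G.HOM_REF), (G.HOM_ALT, G.NO_CALL)]
            + [(G.HOM_REF, G.HET)]
        )
        v = venn_partition(sites_from_pairs(pairs))
        assert (v.n_eval_only, v.n_comp_only, v.n_intersection) == (2, 1, 3)
        assert v.union_size == 6

    def test_disjoint_callsets(self):
        pairs = [(G.HET, G.HOM_REF), (G.HOM_REF, G.HET)]
        assert venn_partition(sites_from_pairs(pairs)).n_intersection == 0

    def test_swapping_callsets_swaps_unique_counts(self):
        rng = np.random.default_rng(7)
        pairs = [MATERIALIZED_PAIRS[i] for i in rng.integers(0, len(MATERIALIZED_PAIRS), size=300)]
        v = venn_partition(sites_from_pairs(pairs))
        swapped = venn_partition(sites_from_pairs([(b, a) for a, b in pairs]))
        assert v.n_intersection == swapped.n_intersection
        assert (v.n_eval_only, v.n_comp_only) == (
            swapped.n_comp_only,
            swapped.n_eval_only,
        )


# ---------------------------------------------------------------------------
# Matrix + metrics
# ---------------------------------------------------------------------------


class TestConcordanceMatrix:
    def test_single_cell(self):
        m = concordance_matrix(sites_from_pairs([(G.HET, G.HET)] * 10))
        assert m.cell(G.HET, G.HET) == 10 and m.total == 10

    def test_empty_merge_zero_matrix(self):
        m = concordance_matrix([])
        assert m.total == 0

    def test_mixed_fixture_matches_hand_tally(self):
        pairs = [
            (G.HET, G.HET),
            (G.HET, G.HET),
            (G.HOM_ALT, G.HET),
            (G.HOM_REF, G.HET),
            (G.NO_CALL, G.HOM_ALT),
            (G.HET, G.HOM_REF),
        ]
        m = concordance_matrix(sites_from_pairs(pairs))
        assert m.cell(G.HET, G.HET) == 2
        assert m.cell(G.HOM_ALT, G.HET) == 1
        assert m.cell(G.HOM_REF, G.HET) == 1
        assert m.cell(G.NO_CALL, G.HOM_ALT) == 1
        assert m.cell(G.HET, G.HOM_REF) == 1
        assert m.total == 6

    def test_homref_homref_cell_empty_by_construction(self, small_fixture):
        from concordeval.synthetic_data import generate_paired_callsets

        cfg, targets, reference, gcs = small_fixture
        e, c, _ = generate_paired_callsets(cfg, targets, reference, gcs)
        m = concordance_matrix(merge_callsets(e, c, targets).sites)
        assert m.cell(G.HOM_REF, G.HOM_REF) == 0


class TestNrsNrd:
    def test_identical_callsets_nrs_100_nrd_0(self):
        m = concordance_matrix(sites_from_pairs([(G.HET, G.HET)] * 20))
        assert nrs(m) == 100.0
        assert nrd(m) == 0.0

    def test_nrs_by_definition(self):
        pairs = [(G.HET, G.HET)] * 6 + [(G.HOM_REF, G.HET)] * 2 + [(G.NO_CALL, G.HET)] * 2
        assert nrs(concordance_matrix(sites_from_pairs(pairs))) == pytest.approx(60.0)

    def test_nrd_example(self):
        pairs = [(G.HET, G.HET)] * 8 + [(G.HET, G.HOM_ALT), (G.HOM_REF, G.HET)]
        assert nrd(concordance_matrix(sites_from_pairs(pairs))) == pytest.approx(20.0)

    def test_all_discordant_nrd_100(self):
        pairs = [(G.HET, G.HOM_ALT)] * 4
        assert nrd(concordance_matrix(sites_from_pairs(pairs))) == 100.0

    def test_nocall_excluded_from_nrd_but_reduces_nrs(self):
        pairs = [(G.HET, G.HET)] * 9 + [(G.NO_CALL, G.HET)]
        m = concordance_matrix(sites_from_pairs(pairs))
        assert nrs(m) == pytest.approx(90.0)
        assert nrd(m) == 0.0

    def test_undefined_denominators_return_none(self):
        only_eval = concordance_matrix(sites_from_pairs([(G.HET, G.HOM_REF)]))
        assert nrs(only_eval) is None  # no comparison-variant site
        only_nocall = concordance_matrix(sites_from_pairs([(G.HET, G.NO_CALL)]))
        assert nrd(only_nocall) is None  # nothing called in both

    def test_exhaustive_pair_multisets_match_bruteforce(self):
        """All genotype-pair multisets of up to 3 sites, plus sampled larger
        ones, agree exactly with the list re-scan oracle."""
        for k in (1, 2, 3):
            for combo in itertools.combinations_with_replacement(
                MATERIALIZED_PAIRS, k
            ):
                sites = sites_from_pairs(combo)
                m = concordance_matrix(sites)
                assert nrs(m) == nrs_bruteforce(sites)
                assert nrd(m) == nrd_bruteforce(sites)

    def test_random_fixtures_match_bruteforce(self):
        rng = np.random.default_rng(123)
        for _ in range(30):
            idx = rng.integers(0, len(MATERIALIZED_PAIRS), size=1000)
            sites = sites_from_pairs([MATERIALIZED_PAIRS[i] for i in idx])
            m = concordance_matrix(sites)
            assert nrs(m) == pytest.approx(nrs_bruteforce(sites), abs=1e-12)
            assert nrd(m) == pytest.approx(nrd_bruteforce(sites), abs=1e-12)
            v = venn_partition(sites, summaries=False)
            assert (v.n_eval_only, v.n_comp_only, v.n_intersection) == venn_bruteforce(sites)


# ---------------------------------------------------------------------------
# TsTv and callset summaries
# ---------------------------------------------------------------------------


class TestSummaries:
    def test_transition_definition(self):
        assert is_transition("A", "G") and is_transition("T", "C")
        assert not is_transition("A", "C") and not is_transition("G", "T")

    def test_tstv_29_transitions_12_transversions(self):
        pairs = [("A", "G")] * 15 + [("C", "T")] * 14 + [("A", "C")] * 7 + [("G", "T")] * 5
        assert tstv_ratio(pairs) == pytest.approx(29 / 12)
        assert tstv_ratio(pairs) == pytest.approx(2.4167, abs=5e-5)

    def test_all_transitions_undefined(self):
        assert tstv_ratio([("A", "G")] * 10) is None

    def test_all_known_dbsnp_percent_100(self):
        records = [make_snp(pos=p, id_=f"rs{p}") for p in range(1, 6)]
        assert callset_summary(records).dbsnp_percent == 100.0

    def test_twenty_snp_fixture_matches_hand_computation(self):
        # 8 known transitions, 4 known transversions, 6 novel transitions,
        # 2 novel transversions
        records = (
            [make_snp(pos=p, ref="A", alt="G", id_=f"rs{p}") for p in range(1, 9)]
            + [make_snp(pos=p, ref="A", alt="C", id_=f"rs{p}") for p in range(9, 13)]
            + [make_snp(pos=p, ref="C", alt="T") for p in range(13, 19)]
            + [make_snp(pos=p, ref="C", alt="G") for p in range(19, 21)]
        )
        s = callset_summary(records)
        assert s.n_variants == 20
        assert s.dbsnp_percent == pytest.approx(60.0)
        assert s.tstv_overall == pytest.approx(14 / 6)
        assert s.tstv_known == pytest.approx(8 / 4)
        assert s.tstv_novel == pytest.approx(6 / 2)

    def test_empty_callset(self):
        s = callset_summary([])
        assert s.n_variants == 0 and s.dbsnp_percent is None
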