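"""Allele combinations, concordance categories, spectra, and Fisher tests."""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from concordeval.allele_bias import (
    COMBINATIONS,
    FOUR_WAY,
    allele_combination,
    bias_report,
    categorize_site,
    fisher_exact_2x2,
    pairwise_bias_test,
    spectrum,
)
from concordeval.concordance import MergedSite
from concordeval.formats_io import Genotype

G = Genotype


def fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Exact-arithmetic enumeration of the two-sided Fisher p-value."""
    n, row1, col1 = a + b + c + d, a + b, a + c
    if row1 in (0, n) or col1 in (0, n):
        return 1.0

    def point(x: int) -> Fraction:
        return Fraction(comb(col1, x) * comb(n - col1, row1 - x), comb(n, row1))

    p_obs = point(a)
    total = sum(
        p
        for x in range(max(0, row1 + col1 - n), min(row1, col1) + 1)
        if (p := point(x)) <= p_obs
    )
    return float(total)


def site(ge, gc, ref="A", alt_e="G", alt_c="G"):
    return MergedSite(
        "c", 1, ref, ge, gc,
        alt_eval=alt_e if ge.is_called and ge.is_variant or ge is G.NO_CALL else None,
        alt_comp=alt_c if gc.is_called and gc.is_variant or gc is G.NO_CALL else None,
    )


class TestAlleleCombination:
    def test_symmetry(self):
        assert allele_combination("C", "T") == allele_combination("T", "C") == "C/T"
        assert allele_combination("A", "G") == "A/G"

    def test_twelve_ordered_pairs_map_to_six_values(self):
        values = {
            allele_combination(a, b)
            for a, b in itertools.permutations("ACGT", 2)
        }
        assert values == set(COMBINATIONS)
        assert len(values) == 6

    @pytest.mark.parametrize("pair", [("A", "A"), ("A", "N"), ("X", "G")])
    def test_invalid_bases_rejected(self, pair):
        with pytest.raises(ValueError):
            allele_combination(*pair)


class TestCategorize:
    def test_concordant(self):
        assert categorize_site(site(G.HET, G.HET)) == "CONCORDANT"

    def test_comp_unique_includes_nocall_eval(self):
        assert categorize_site(site(G.NO_CALL, G.HET)) == "COMP_UNIQUE"
        assert categorize_site(site(G.HOM_REF, G.HET)) == "COMP_UNIQUE"

    def test_eight_site_fixture_exact_assignment(self):
        cases = [
            (site(G.HET, G.HET), "CONCORDANT"),
            (site(G.HOM_ALT, G.HOM_ALT), "CONCORDANT"),
            (site(G.HET, G.HOM_ALT), "DISCORDANT"),
            (site(G.HET, G.HET, alt_e="G", alt_c="T"), "DISCORDANT"),
            (site(G.HOM_REF, G.HET), "COMP_UNIQUE"),
            (site(G.NO_CALL, G.HOM_ALT), "COMP_UNIQUE"),
            (site(G.HET, G.HOM_REF), "EVAL_UNIQUE"),
            (site(G.HOM_ALT, G.NO_CALL), "EVAL_UNIQUE"),
        ]
        for s, expected in cases:
            assert categorize_site(s, "4way") == expected

    def test_three_way_mapping(self):
        assert categorize_site(site(G.HET, G.HET), "3way") == "CONCORDANT"
        assert categorize_site(site(G.HOM_REF, G.HET), "3way") == "NRS_CONTRIBUTING"
        assert categorize_site(site(G.HET, G.HOM_ALT), "3way") == "NRD_CONTRIBUTING"
        assert categorize_site(site(G.HET, G.HOM_REF), "3way") == "NRD_CONTRIBUTING"


class TestSpectrum:
    def test_counts_and_proportions(self):
        sites = (
            [site(G.HET, G.HET, ref="C", alt_e="T", alt_c="T")] * 4
            + [site(G.HET, G.HET, ref="A", alt_e="G", alt_c="G")] * 2
            + [site(G.HET, G.HET, ref="G", alt_e="T", alt_c="T")] * 2
            + [site(G.HET, G.HET, ref="A", alt_e="C", alt_c="C")]
            + [site(G.HET, G.HET, ref="A", alt_e="T", alt_c="T")]
        )
        counts = spectrum([(s, "CONCORDANT") for s in sites])
        assert counts.loc["CONCORDANT", "C/T"] == 4
        props = counts.attrs["proportions"]
        assert props.loc["CONCORDANT", "C/T"] == pytest.approx(0.4)
        assert props.loc["CONCORDANT"].sum() == pytest.approx(1.0)

    def test_empty_category_all_zero_with_nan_proportions(self):
        counts = spectrum([])
        assert (counts.to_numpy() == 0).all()
        assert counts.attrs["proportions"].isna().all().all()

    def test_random_spectra_row_proportions_sum_to_one(self):
        rng = np.random.default_rng(5)
        cats = list(FOUR_WAY)
        categorized = []
        for _ in range(500):
            ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
            categorized.append(
                (site(G.HET, G.HET, ref=ref, alt_e=alt, alt_c=alt), cats[rng.integers(4)])
            )
        counts = spectrum(categorized)
        props = counts.attrs["proportions"]
        for cat in cats:
            if counts.loc[cat].sum() > 0:
                assert props.loc[cat].sum() == pytest.approx(1.0)


class TestFisherExact:
    def test_known_table_34_over_70(self):
        assert fisher_exact_2x2([[3, 1], [1, 3]]) == pytest.approx(34 / 70, rel=1e-9)

    def test_balanced_table_p_one(self):
        assert fisher_exact_2x2([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_zero_margin_returns_one(self):
        assert fisher_exact_2x2([[0, 0], [3, 4]]) == 1.0
        assert fisher_exact_2x2([[0, 3], [0, 4]]) == 1.0

    def test_against_exact_enumeration_oracle_on_random_tables(self):
        rng = np.random.default_rng(17)
        n_checked = 0
        while n_checked < 200:
            cells = rng.multinomial(int(rng.integers(4, 41)), [0.25] * 4)
            a, b, c, d = (int(x) for x in cells)
            p = fisher_exact_2x2([[a, b], [c, d]])
            assert p == pytest.approx(fisher_oracle(a, b, c, d), rel=1e-6)
            n_checked += 1

    def test_against_scipy_two_sided(self):
        rng = np.random.default_rng(29)
        for _ in range(50):
            t = rng.integers(0, 30, size=(2, 2))
            if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
                continue
            _, p_scipy = scipy.stats.fisher_exact(t, alternative="two-sided")
            assert fisher_exact_2x2(t) == pytest.approx(p_scipy, rel=1e-6)


class TestPairwiseBiasTest:
    @staticmethod
    def _counts(rows: dict[str, list[int]]) -> pd.DataFrame:
        return pd.DataFrame.from_dict(
            rows, orient="index", columns=list(COMBINATIONS), dtype=np.int64
        ).reindex(list(FOUR_WAY), fill_value=0)

    def test_identical_spectra_not_significant(self):
        row = [30, 60, 10, 10, 70, 20]
        counts = self._counts({c: list(row) for c in FOUR_WAY})
        for combo in COMBINATIONS:
            for r in pairwise_bias_test(counts, combo):
                assert r.p_adjusted == 1.0 and not r.significant

    def test_adjusted_p_bounded(self):
        rng = np.random.default_rng(3)
        counts = self._counts(
            {c: list(rng.integers(0, 50, size=6)) for c in FOUR_WAY}
        )
        report = bias_report(counts)
        assert (report.p_adjusted >= report.p_raw - 1e-12).all()
        assert (report.p_adjusted <= 1.0).all()

    def test_two_categories_single_pair_no_adjustment(self):
        counts = self._counts(
            {"CONCORDANT": [10, 20, 5, 5, 30, 10], "DISCORDANT": [5, 25, 5, 5, 30, 10]}
        )
        results = pairwise_bias_test(counts, "A/C")
        assert len(results) == 1
        assert results[0].p_adjusted == pytest.approx(
            min(1.0, results[0].p_raw), rel=1e-12
        )

    def test_inflated_cg_proportion_detected(self):
        """A 3-fold C/G inflation in one category at n = 2,000/category is
        flagged significant for every pair involving that category."""
        rng = np.random.default_rng(41)
        base = np.array([0.15, 0.30, 0.08, 0.06, 0.31, 0.10])
        inflated = base.copy()
        inflated[3] *= 3
        inflated /= inflated.sum()
        rows = {}
        for cat in FOUR_WAY:
            p = inflated if cat == "DISCORDANT" else base
            rows[cat] = list(rng.multinomial(2000, p))
        counts = self._counts(rows)
        results = pairwise_bias_test(counts, "C/G")
        for r in results:
            involves = "DISCORDANT" in (r.category_a, r.category_b)
            assert r.significant == involves

    def test_type_i_error_controlled_under_null(self):
        """Under a shared multinomial null, the fraction of simulated
        spectra with any significant pair anywhere in the report stays at
        or below the nominal level when the Bonferroni adjustment spans the
        whole report (pairs x combinations)."""
        rng = np.random.default_rng(99)
        p = np.array([0.15, 0.30, 0.08, 0.06, 0.31, 0.10])
        n_sig = 0
        n_sim = 300
        for _ in range(n_sim):
            rows = {cat: list(rng.multinomial(400, p)) for cat in FOUR_WAY}
            report = bias_report(
                self._counts(rows), bonferroni_scope="pairs_x_combinations"
            )
            if report.significant.any():
                n_sig += 1
        assert n_sig / n_sim <= 0.07
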