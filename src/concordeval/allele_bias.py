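"""Allele-spectrum bias analysis of SNP concordance categories.

Merged SNP sites are split into concordance categories (four when comparing
two sequencing callsets, three when validating against an array), the six
unordered ref/alt base combinations are tallied per category, and pairwise
two-sided Fisher exact tests — Bonferroni-corrected over the category pairs
within one combination — test whether a combination's proportion differs
between categories.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .concordance import MergedSite
from .formats_io import Genotype, VALID_BASES

__all__ = [
    "COMBINATIONS",
    "FOUR_WAY",
    "THREE_WAY",
    "allele_combination",
    "categorize_site",
    "categorize_sites",
    "spectrum",
    "fisher_exact_2x2",
    "pairwise_bias_test",
]

#: The six unordered ref/alt base combinations, canonical alphabetic order.
COMBINATIONS = ("A/C", "A/G", "A/T", "C/G", "C/T", "G/T")

FOUR_WAY = ("CONCORDANT", "COMP_UNIQUE", "DISCORDANT", "EVAL_UNIQUE")
THREE_WAY = ("CONCORDANT", "NRS_CONTRIBUTING", "NRD_CONTRIBUTING")


def allele_combination(ref: str, alt: str) -> str:
    """Canonical unordered base pair, e.g. (T, C) -> ``"C/T"``."""
    if ref not in VALID_BASES or alt not in VALID_BASES:
        raise ValueError(f"bases must be in ACGT, got {ref!r}/{alt!r}")
    if ref == alt:
        raise ValueError(f"ref == alt ({ref!r})")
    a, b = sorted((ref, alt))
    return f"{a}/{b}"


def categorize_site(site: MergedSite, mode: Literal["4way", "3way"] = "4way") -> str:
    """Assign one merged SNP site to its concordance category.

    4-way: CONCORDANT (both variant, same genotype and alt), COMP_UNIQUE
    (comparison variant, evaluation hom-ref/no-call; these reduce NRS),
    EVAL_UNIQUE (symmetric), DISCORDANT (both called variant-involving with
    unequal genotypes or alts; these contribute to NRD).

    3-way folds the same logic against an array comparison callset:
    NRS_CONTRIBUTING <- COMP_UNIQUE, NRD_CONTRIBUTING <- DISCORDANT or
    EVAL_UNIQUE (an evaluation-only variant is a called discordance against
    an array hom-ref genotype).
    """
    ev, cv = site.g_eval.is_variant, site.g_comp.is_variant
    if ev and cv:
        four = "CONCORDANT" if not site.genotypes_discordant else "DISCORDANT"
    elif cv:
        four = "COMP_UNIQUE"
    elif ev:
        four = "EVAL_UNIQUE"
    else:
        raise ValueError("merged site with no variant genotype")
    if mode == "4way":
        return four
    if mode == "3way":
        if four == "CONCORDANT":
            return "CONCORDANT"
        if four == "COMP_UNIQUE":
            return "NRS_CONTRIBUTING"
        return "NRD_CONTRIBUTING"
    raise ValueError(f"unknown mode {mode!r}")


def categorize_sites(
    merged: Iterable[MergedSite], mode: Literal["4way", "3way"] = "4way"
) -> list[tuple[MergedSite, str]]:
    return [
        (s, categorize_site(s, mode)) for s in merged if s.vclass == "SNP"
    ]


def spectrum(
    categorized: Sequence[tuple[MergedSite, str]],
    mode: Literal["4way", "3way"] = "4way",
) -> pd.DataFrame:
    """Category x combination count table (rows = categories).

    The returned frame has one row per category of the active mode and one
    column per combination; ``df.attrs["proportions"]`` holds the row-wise
    proportions (NaN rows where a category is empty).
    """
    categories = FOUR_WAY if mode == "4way" else THREE_WAY
    counts = pd.DataFrame(
        0, index=list(categories), columns=list(COMBINATIONS), dtype=np.int64
    )
    for site, cat in categorized:
        alt = site.alt_eval if site.alt_eval is not None else site.alt_comp
        combo = allele_combination(site.ref, alt)
        counts.loc[cat, combo] += 1
    totals = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        props = counts.div(totals.replace(0, np.nan), axis=0)
    counts.attrs["proportions"] = props
    return counts


# ---------------------------------------------------------------------------
# Fisher exact engine
# ---------------------------------------------------------------------------

_REL_TOL = 1e-7


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p-value for a 2x2 contingency table.

    Point-probability rule: p is the sum of hypergeometric probabilities of
    all tables with the same margins whose probability is <= that of the
    observed table, with a relative tolerance of 1e-7 on the comparison to
    guard floating-point ties.  A zero margin returns p = 1.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 non-negative")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    n = a + b + c + d
    row1, col1 = a + b, a + c
    if row1 == 0 or col1 == 0 or row1 == n or col1 == n:
        return 1.0
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n, col1, row1)
    p_obs = pmf[a - lo]
    return float(np.clip(pmf[pmf <= p_obs * (1.0 + _REL_TOL)].sum(), 0.0, 1.0))


@dataclass(frozen=True)
class PairwiseTestResult:
    combination: str
    category_a: str
    category_b: str
    table: tuple[tuple[int, int], tuple[int, int]]
    p_raw: float
    p_adjusted: float
    significant: bool


def pairwise_bias_test(
    counts: pd.DataFrame,
    combination: str,
    alpha: float = 0.05,
    bonferroni_scope: Literal["pairs", "pairs_x_combinations"] = "pairs",
) -> list[PairwiseTestResult]:
    """Pairwise Fisher tests of one combination's proportion across categories.

    For each unordered pair of categories with non-zero totals, the 2x2 table
    is [count of ``combination``, count of the other five combinations] by
    [category A, category B].  Raw p-values are Bonferroni-multiplied by the
    number of pairs tested (optionally also by the six combinations) and
    capped at 1; significance is judged at ``alpha``.
    """
    if combination not in counts.columns:
        raise ValueError(f"unknown combination {combination!r}")
    totals = counts.sum(axis=1)
    cats = [c for c in counts.index if totals[c] > 0]
    pairs = list(itertools.combinations(cats, 2))
    if not pairs:
        return []
    m = len(pairs)
    if bonferroni_scope == "pairs_x_combinations":
        m *= len(COMBINATIONS)
    results = []
    for ca, cb in pairs:
        xa = int(counts.loc[ca, combination])
        xb = int(counts.loc[cb, combination])
        table = ((xa, int(totals[ca]) - xa), (xb, int(totals[cb]) - xb))
        p = fisher_exact_2x2(table)
        p_adj = min(1.0, p * m)
        results.append(
            PairwiseTestResult(
                combination=combination,
                category_a=ca,
                category_b=cb,
                table=table,
                p_raw=p,
                p_adjusted=p_adj,
                significant=p_adj < alpha,
            )
        )
    return results


def bias_report(
    counts: pd.DataFrame,
    alpha: float = 0.05,
    bonferroni_scope: Literal["pairs", "pairs_x_combinations"] = "pairs",
) -> pd.DataFrame:
    """All-combination pairwise test table, one row per (combination, pair)."""
    rows = []
    for combo in COMBINATIONS:
        for r in pairwise_bias_test(counts, combo, alpha, bonferroni_scope):
            rows.append(
                {
                    "combination": r.combination,
                    "category_a": r.category_a,
                    "category_b": r.category_b,
                    "p_raw": r.p_raw,
                    "p_adjusted": r.p_adjusted,
                    "significant": r.significant,
                }
            )
    return pd.DataFrame(rows)
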