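"""Bootstrap read downsampling across a coverage ladder.

The design mirrors coverage-titration experiments on capture data: reads
with at least 1 bp of overlap with a capture target are retained, the read
count needed for a desired average target coverage C follows C = N x L / G
(L = read length, G = total target span), and B seeded replicates each draw
N reads without replacement.  "Bootstrap" here means repeated subsampling,
not with-replacement resampling.  Replicate metrics are summarized by their
median across replicates.

A deliberately minimal *recall model* converts per-site sampled depth into a
called genotype so the coverage ladder can be exercised end-to-end on
synthetic data; it is synthetic-only and never a stand-in on real callsets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .formats_io import Genotype, TargetInterval

__all__ = [
    "ReadPlacement",
    "DownsampleSpec",
    "reads_for_coverage",
    "filter_on_target",
    "replicate_seed",
    "bootstrap_downsample",
    "subset_read_pairs",
    "recall_model",
    "summarize_replicates",
    "coverage_ladder_experiment",
    "read_placement_table",
    "write_placement_table",
]


@dataclass(frozen=True)
class ReadPlacement:
    """One aligned read: 0-based half-open placement plus its pair id."""

    read_id: str
    chrom: str
    start: int
    end: int
    pair_id: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"read {self.read_id}: start >= end")


@dataclass(frozen=True)
class DownsampleSpec:
    """Coverage ladder design: fold coverages, read length L, target span G,
    replicate count B and the master seed all randomness flows from."""

    coverage_targets: tuple[float, ...]
    read_length: int
    target_span: int
    replicates: int = 100
    master_seed: int = 0

    def __post_init__(self) -> None:
        if any(c <= 0 for c in self.coverage_targets):
            raise ValueError("coverages must be > 0")
        if self.read_length <= 0 or self.target_span <= 0 or self.replicates < 1:
            raise ValueError("read_length, target_span > 0 and replicates >= 1")


def reads_for_coverage(coverage: float, target_span: int, read_length: int) -> int:
    """Reads needed for C-fold average target coverage: N = ceil(C x G / L)."""
    if coverage <= 0 or target_span <= 0 or read_length <= 0:
        raise ValueError("all arguments must be positive")
    return math.ceil(coverage * target_span / read_length)


def filter_on_target(
    reads: Iterable[ReadPlacement], targets: Sequence[TargetInterval]
) -> list[ReadPlacement]:
    """Keep reads overlapping a target by >= 1 base (half-open intervals).

    Abutting read/target pairs ([90,100) vs [100,200)) have zero overlap and
    are dropped.  ``targets`` must be normalized (sorted, merged).
    """
    import bisect

    by_chrom: dict[str, list[TargetInterval]] = {}
    for iv in targets:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    starts = {c: [iv.start for iv in ivs] for c, ivs in by_chrom.items()}
    kept = []
    for read in reads:
        ivs = by_chrom.get(read.chrom)
        if not ivs:
            continue
        # candidate: last interval starting before read.end
        i = bisect.bisect_left(starts[read.chrom], read.end) - 1
        if i >= 0 and ivs[i].end > read.start:
            kept.append(read)
    return kept


def replicate_seed(master_seed: int, replicate: int) -> np.random.SeedSequence:
    """Deterministic per-replicate seed derived from the master seed."""
    return np.random.SeedSequence([int(master_seed), int(replicate)])


def bootstrap_downsample(
    reads: Sequence[ReadPlacement], n: int, replicates: int, master_seed: int
) -> list[list[ReadPlacement]]:
    """B seeded subsamples of ``n`` reads each, without replacement.

    ``n`` greater than the available read count is capped (with the full set
    returned each replicate).  Identical inputs and master seed reproduce
    identical subsample families; read order within a replicate follows the
    input ordering.
    """
    n = min(n, len(reads))
    out = []
    for r in range(replicates):
        rng = np.random.Generator(np.random.PCG64(replicate_seed(master_seed, r)))
        idx = np.sort(rng.choice(len(reads), size=n, replace=False))
        out.append([reads[i] for i in idx])
    return out


def subset_read_pairs(
    total_pairs: int, n_pairs: int, seed: int
) -> np.ndarray:
    """Uniform sample of read-pair indices without replacement.

    Both mates travel together (pairs are the sampling unit); the returned
    indices preserve file order.
    """
    if not 0 <= n_pairs <= total_pairs:
        raise ValueError("need 0 <= n_pairs <= total_pairs")
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(int(seed))))
    return np.sort(rng.choice(total_pairs, size=n_pairs, replace=False))


def recall_model(
    depth: int,
    alt_reads: int,
    min_depth: int = 5,
    het_low: float = 0.2,
    het_high: float = 0.8,
) -> Genotype:
    """Minimal depth/allele-fraction genotype caller for synthetic reads.

    NO_CALL below ``min_depth`` (the depth floor mirrors the DP < 5 hard
    filter), HET for an alt fraction in [het_low, het_high], HOM_ALT above,
    HOM_REF below.  Synthetic-only: exercises the downsampling design, it is
    not a variant caller.
    """
    if not 0 <= alt_reads <= depth:
        raise ValueError("need 0 <= alt_reads <= depth")
    if depth < min_depth:
        return Genotype.NO_CALL
    frac = alt_reads / depth
    if frac > het_high:
        return Genotype.HOM_ALT
    if frac >= het_low:
        return Genotype.HET
    return Genotype.HOM_REF


def summarize_replicates(per_replicate: pd.DataFrame) -> pd.DataFrame:
    """Median and IQR of each metric across replicates per coverage level.

    ``per_replicate`` has columns coverage, replicate, plus metric columns
    (e.g. n_snps, n_indels, nrs, nrd).  Output: one row per (coverage,
    metric) with median, q1, q3, minimum, maximum.
    """
    metrics = [
        c for c in per_replicate.columns if c not in ("coverage", "replicate")
    ]
    rows = []
    for cov, grp in per_replicate.groupby("coverage", sort=True):
        for metric in metrics:
            v = grp[metric].dropna().to_numpy()
            if v.size == 0:
                continue
            q = np.quantile(v, [0.25, 0.5, 0.75])
            rows.append(
                {
                    "coverage": cov,
                    "metric": metric,
                    "median": q[1],
                    "q1": q[0],
                    "q3": q[2],
                    "min": v.min(),
                    "max": v.max(),
                    "n_replicates": v.size,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# End-to-end coverage-ladder experiment on synthetic reads
# ---------------------------------------------------------------------------


def coverage_ladder_experiment(
    reads: Sequence[ReadPlacement],
    truth_sites: pd.DataFrame,
    spec: DownsampleSpec,
    targets: Sequence[TargetInterval] | None = None,
) -> pd.DataFrame:
    """Run the full downsampling design on a synthetic read set.

    ``truth_sites`` has columns chrom, pos (1-based), vclass, g_true (the
    latent genotype name).  For each coverage level and replicate, N reads
    are drawn, per-site depth is the count of sampled reads covering the
    site, alt-supporting reads are drawn binomially at the genotype's allele
    fraction, the recall model assigns a genotype, and variant calls
    (HET/HOM_ALT) are counted.  Also reports per-site genotype concordance
    of called vs true genotypes as NRS/NRD-style fractions.

    Returns the per-replicate metric table consumed by
    :func:`summarize_replicates`.
    """
    if targets is not None:
        reads = filter_on_target(reads, targets)
    # a NO_CALL truth genotype carries no alt evidence: treated as hom-ref
    af = {"HOM_REF": 0.0, "HET": 0.5, "HOM_ALT": 1.0, "NO_CALL": 0.0}
    site_chrom = truth_sites["chrom"].to_numpy()
    site_pos = truth_sites["pos"].to_numpy()
    site_class = truth_sites["vclass"].to_numpy()
    site_af = np.array([af[g] for g in truth_sites["g_true"]])
    truth_variant = np.array(
        [g in ("HET", "HOM_ALT") for g in truth_sites["g_true"]]
    )

    read_chrom = np.array([r.chrom for r in reads])
    read_start = np.array([r.start for r in reads])
    read_end = np.array([r.end for r in reads])

    rows = []
    for cov in spec.coverage_targets:
        n = min(
            reads_for_coverage(cov, spec.target_span, spec.read_length), len(reads)
        )
        for rep in range(spec.replicates):
            seed = replicate_seed(
                spec.master_seed, int(cov * 1_000_003) % (2**31) + rep
            )
            rng = np.random.Generator(np.random.PCG64(seed))
            idx = rng.choice(len(reads), size=n, replace=False)
            depth = _site_depths(
                site_chrom, site_pos, read_chrom[idx], read_start[idx], read_end[idx]
            )
            alt = rng.binomial(depth, site_af)
            called = np.array(
                [recall_model(int(d), int(a)) for d, a in zip(depth, alt)]
            )
            called_variant = np.array(
                [g in (Genotype.HET, Genotype.HOM_ALT) for g in called]
            )
            snp = site_class == "SNP"
            row = {
                "coverage": cov,
                "replicate": rep,
                "n_snps": int((called_variant & snp).sum()),
                "n_indels": int((called_variant & ~snp).sum()),
            }
            # sensitivity against truth: truth is the comparison callset
            denom = truth_variant.sum()
            if denom:
                row["nrs"] = 100.0 * (called_variant & truth_variant).sum() / denom
            both_called = np.array([g is not Genotype.NO_CALL for g in called])
            true_g = truth_sites["g_true"].to_numpy()
            eligible = both_called & (truth_variant | called_variant)
            if eligible.sum():
                disc = np.array(
                    [g.name for g in called]
                ) != true_g
                row["nrd"] = 100.0 * (disc & eligible).sum() / eligible.sum()
            rows.append(row)
    return pd.DataFrame(rows)


def _site_depths(
    site_chrom: np.ndarray,
    site_pos: np.ndarray,
    read_chrom: np.ndarray,
    read_start: np.ndarray,
    read_end: np.ndarray,
) -> np.ndarray:
    """Depth per site = number of reads whose placement covers pos - 1."""
    depth = np.zeros(len(site_pos), dtype=np.int64)
    for chrom in np.unique(site_chrom):
        s_mask = site_chrom == chrom
        r_mask = read_chrom == chrom
        starts = np.sort(read_start[r_mask])
        ends = np.sort(read_end[r_mask])
        pos0 = site_pos[s_mask] - 1
        # reads with start <= pos0 minus reads with end <= pos0
        depth[s_mask] = np.searchsorted(starts, pos0, side="right") - np.searchsorted(
            ends, pos0, side="right"
        )
    return depth


# ---------------------------------------------------------------------------
# Read-placement table I/O (TSV: read_id, chrom, start, end, pair_id)
# ---------------------------------------------------------------------------


def read_placement_table(path) -> list[ReadPlacement]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "read_id": str, "pair_id": str})
    return [
        ReadPlacement(r.read_id, r.chrom, int(r.start), int(r.end), r.pair_id)
        for r in df.itertuples(index=False)
    ]


def write_placement_table(reads: Sequence[ReadPlacement], path) -> None:
    pd.DataFrame(
        [(r.read_id, r.chrom, r.start, r.end, r.pair_id) for r in reads],
        columns=["read_id", "chrom", "start", "end", "pair_id"],
    ).to_csv(path, sep="\t", index=False)
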