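"""GC content of capture targets and GC-binned coverage/concordance summaries.

Capture efficiency drops in GC-rich targets; this module quantifies that by
binning targets into quartiles of target GC% and summarizing median target
coverage and genotype-concordance metrics (NRS/NRD) per bin.

Quantiles use linear interpolation between order statistics; bin edges are
inclusive on the right (bin 1: gc <= Q1; bin 4: gc > Q3).  Both choices are
recorded in report metadata since bin membership near an edge depends on
them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import concordance as _conc
from .concordance import MergedSite
from .formats_io import TargetInterval, find_containing_interval

__all__ = [
    "TargetGC",
    "GCBinning",
    "gc_percent",
    "windowed_gc",
    "targets_gc",
    "quartile_bins",
    "per_bin_coverage",
    "per_bin_concordance",
]


@dataclass(frozen=True)
class TargetGC:
    interval: TargetInterval
    gc_percent: float | None  # None when every base is ambiguous
    n_ambiguous: int


@dataclass(frozen=True)
class GCBinning:
    """Quartile edges of target GC% plus the target -> bin assignment (1..4)."""

    edges: tuple[float, float, float]
    assignment: Mapping[TargetInterval, int]
    degenerate: bool = False  # all values equal: everything lands in bin 1

    def bin_of(self, gc: float) -> int:
        q1, q2, q3 = self.edges
        if gc <= q1:
            return 1
        if gc <= q2:
            return 2
        if gc <= q3:
            return 3
        return 4


def gc_percent(sequence: str) -> tuple[float | None, int]:
    """GC% of a sequence: 100 x (G+C)/(A+C+G+T), ambiguous bases excluded.

    Returns (gc, n_ambiguous); gc is ``None`` for an all-ambiguous sequence.
    """
    if not sequence:
        raise ValueError("empty sequence")
    s = sequence.upper()
    gc = s.count("G") + s.count("C")
    at = s.count("A") + s.count("T")
    n_amb = len(s) - gc - at
    if gc + at == 0:
        return None, n_amb
    return 100.0 * gc / (gc + at), n_amb


def windowed_gc(
    sequence: str, window: int = 10_000, step: int = 5_000
) -> pd.DataFrame:
    """GC% in sliding windows (default 10 kbp windows, 5 kbp overlap).

    Windows start at 0 and advance by ``step``.  A final partial window is
    retained when it spans at least ``step / 2`` bases, else dropped.
    Columns: start, end, gc_percent, n_ambiguous.
    """
    if window <= 0 or not 0 < step <= window:
        raise ValueError("need window > 0 and 0 < step <= window")
    rows = []
    start = 0
    n = len(sequence)
    while start < n:
        end = min(start + window, n)
        if end - start < window and end - start < step / 2:
            break
        gc, amb = gc_percent(sequence[start:end])
        rows.append((start, end, gc, amb))
        if end == n:
            break
        start += step
    return pd.DataFrame(rows, columns=["start", "end", "gc_percent", "n_ambiguous"])


def targets_gc(
    targets: Sequence[TargetInterval], reference: Mapping[str, str]
) -> list[TargetGC]:
    """GC% of each capture target from a chrom -> sequence mapping.

    ``reference`` can be a :class:`pyfaidx.Fasta` (string-slicing duck type)
    or a plain dict of sequences.
    """
    out = []
    for iv in targets:
        seq = str(reference[iv.chrom][iv.start : iv.end])
        gc, amb = gc_percent(seq)
        out.append(TargetGC(iv, gc, amb))
    return out


def quartile_bins(target_gcs: Sequence[TargetGC]) -> GCBinning:
    """Bin targets into four groups at the Q1/median/Q3 of target GC%.

    Requires >= 4 targets with defined GC.  When every value is equal the
    binning is flagged degenerate and all targets land in bin 1.
    """
    defined = [t for t in target_gcs if t.gc_percent is not None]
    if len(defined) < 4:
        raise ValueError("need at least 4 targets with defined GC%")
    values = np.array([t.gc_percent for t in defined])
    q1, q2, q3 = np.quantile(values, [0.25, 0.5, 0.75])  # linear interpolation
    binning = GCBinning(
        edges=(float(q1), float(q2), float(q3)),
        assignment={},
        degenerate=bool(values.min() == values.max()),
    )
    assignment = {t.interval: binning.bin_of(t.gc_percent) for t in defined}
    return GCBinning(binning.edges, assignment, binning.degenerate)


def per_bin_coverage(
    binning: GCBinning, coverage: pd.DataFrame
) -> pd.DataFrame:
    """Five-number summary of per-target median coverage in each GC bin.

    ``coverage`` has columns chrom, start, end, callset, median_coverage
    (one row per target per callset).  Output: one row per (callset, bin)
    with min/q1/median/q3/max and the target count; empty bins are absent.
    """
    cov = coverage.copy()
    key_to_bin = {
        (iv.chrom, iv.start, iv.end): b for iv, b in binning.assignment.items()
    }
    cov["bin"] = [
        key_to_bin.get((r.chrom, r.start, r.end))
        for r in cov.itertuples(index=False)
    ]
    cov = cov.dropna(subset=["bin"])
    rows = []
    for (callset, b), grp in cov.groupby(["callset", "bin"], sort=True):
        v = grp["median_coverage"].to_numpy()
        q = np.quantile(v, [0.0, 0.25, 0.5, 0.75, 1.0])
        rows.append(
            {
                "callset": callset,
                "bin": int(b),
                "n_targets": len(v),
                "min": q[0],
                "q1": q[1],
                "median": q[2],
                "q3": q[3],
                "max": q[4],
            }
        )
    return pd.DataFrame(rows)


def per_bin_concordance(
    binning: GCBinning,
    merged: Iterable[MergedSite],
    targets: Sequence[TargetInterval],
) -> pd.DataFrame:
    """NRS and NRD per GC bin per variant class.

    Each merged site is assigned to the bin of its containing target
    (half-open convention); sites outside every target are excluded and
    counted in ``df.attrs["n_off_target"]``.
    """
    by_bin: dict[tuple[int, str], list[MergedSite]] = {}
    n_off = 0
    for site in merged:
        iv = find_containing_interval(site.chrom, site.pos, targets)
        if iv is None or iv not in binning.assignment:
            n_off += 1
            continue
        by_bin.setdefault((binning.assignment[iv], site.vclass), []).append(site)
    rows = []
    for (b, vclass), sites in sorted(by_bin.items()):
        m = _conc.concordance_matrix(sites)
        rows.append(
            {
                "bin": b,
                "vclass": vclass,
                "n_sites": len(sites),
                "nrs": _conc.nrs(m),
                "nrd": _conc.nrd(m),
            }
        )
    df = pd.DataFrame(rows, columns=["bin", "vclass", "n_sites", "nrs", "nrd"])
    df.attrs["n_off_target"] = n_off
    return df
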