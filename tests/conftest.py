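"""Shared fixtures: small synthetic fixture families and record builders."""

from __future__ import annotations

import pytest

from concordeval.formats_io import Genotype, TargetInterval, VariantRecord
from concordeval.synthetic_data import SyntheticConfig, generate_targets


def make_snp(
    pos: int = 100,
    ref: str = "A",
    alt: str = "G",
    genotype: Genotype = Genotype.HET,
    chrom: str = "chr12",
    id_: str | None = None,
    depth: int = 100,
    mq0: int = 0,
    qual: float = 50.0,
    qd: float = 10.0,
    hrun: int = 2,
    sb: float = -0.5,
    filter_status: tuple[str, ...] = ("PASS",),
) -> VariantRecord:
    """A clean PASS SNP record; override any field per test."""
    return VariantRecord(
        chrom=chrom, pos=pos, ref=ref, alt=alt, genotype=genotype, id_=id_,
        qual=qual, depth=depth, mq0=mq0, qd=qd, hrun=hrun, sb=sb,
        filter_status=filter_status,
    )


def make_indel(
    pos: int = 200,
    ref: str = "A",
    alt: str = "AT",
    genotype: Genotype = Genotype.HET,
    chrom: str = "chr12",
    id_: str | None = None,
    depth: int = 50,
    mq0: int = 0,
    qual: float = 20.0,
    sb: float = -2.0,
    **kwargs,
) -> VariantRecord:
    """A clean PASS INDEL record."""
    return VariantRecord(
        chrom=chrom, pos=pos, ref=ref, alt=alt, genotype=genotype, id_=id_,
        qual=qual, depth=depth, mq0=mq0, sb=sb, **kwargs,
    )


@pytest.fixture(scope="session")
def small_fixture():
    """One small generated fixture family shared across tests."""
    cfg = SyntheticConfig(seed=42, n_snps=1200, n_indels=120, n_targets=40)
    targets, reference, gcs = generate_targets(cfg)
    return cfg, targets, reference, gcs
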