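# Methods

`concordeval` evaluates a pair of single-sample variant callsets over
capture targets. This note records the model, the conventions and numerical
choices the implementation commits to, what the synthetic generator does
and does not emulate, and the known limitations.

## Merging model and concordance metrics

Callsets are merged by coordinate. SNP sites are keyed by (chrom, pos):
when the two callsets disagree on the alternate allele at a shared
position, the site is kept once with both alts recorded and is treated as
genotype-discordant even when the genotype *states* coincide — a
coordinate-based intersection, with allele identity enforced only at the
discordance level. INDELs are keyed by (chrom, pos, ref, alt) exactly; no
left-normalization is applied, so representation differences between
callers surface as unique sites rather than silent matches. A reference
mismatch at a shared SNP key excludes the site and increments a conflict
counter.

A site absent from one callset is interpreted as an implicit hom-ref call
there (the caller saw the position and emitted nothing), while an explicit
`./.` record is a no-call. The distinction matters: both reduce NRS when
the other callset is variant, but only the no-call is excluded from NRD,
whose universe is sites *called* in both callsets. Sites hom-ref or
no-call in both callsets are never materialized, so the (hom-ref, hom-ref)
cell of the concordance matrix is structurally zero.

The 4×4 concordance matrix (evaluation × comparison genotype, order
hom-ref / het / hom-alt / no-call) carries one extra counter: the number of
diagonal-cell sites whose alternate alleles differ. NRS is computed from
the matrix alone; NRD adds that counter to the discordant numerator so the
matrix-based value equals a direct re-scan of the merged site list.

Ratios with empty denominators (NRS with no comparison-variant site, NRD
with nothing called in both, TsTv with zero transversions) are returned as
`None` — never 0 or 100 — and serialized as `null`.

## Hard filters

The SNP and INDEL filter expressions are applied with their inequalities
exactly as conventionally written: strict `<`/`>` everywhere, inclusive
`≥` on the strand-bias bound. Two deliberate choices where engines differ:

- A record missing an annotation skips that term (a missing value cannot
  fail a filter); skips are counted and reported.
- DP = 0 fails the depth term and skips the MQ0/DP fraction (division
  guard).

Thresholds are configurable (`FilterThresholds`), with the standard values
as defaults. Filtering is a pure function of the record, hence idempotent,
and weakening any single threshold can only move records from fail to pass
(per-term monotonicity, property-tested).

## Allele-spectrum bias testing

Merged SNP sites map to exactly one category. Four-way mode (callset vs
callset): concordant, comparison-unique (NRS-reducing), discordant
(NRD-contributing), evaluation-unique. Three-way mode (sequencing vs
array): concordant, NRS-contributing, NRD-contributing, where an
evaluation-only variant counts as NRD-contributing because the array's
hom-ref is a called genotype.

For each of the six unordered ref/alt combinations and each unordered pair
of non-empty categories, the 2×2 table is [this combination vs the other
five] × [category A vs category B]. The Fisher exact p-value is two-sided
by the point-probability rule — the sum of hypergeometric probabilities of
all tables with the observed margins whose probability is at most that of
the observed table — with a relative tolerance of 1e-7 on the comparison
to absorb floating-point ties; a zero margin returns p = 1. The engine is
cross-checked in the tests against an exact-arithmetic enumeration oracle
and against an independent library implementation.

Bonferroni scope: by default p-values are multiplied by the number of
category pairs within one combination (six in four-way mode), mirroring a
pairwise procedure applied per combination in succession. The alternative
scope multiplies additionally by the six combinations and is the
appropriate correction when asking whether *any* pair anywhere in the
report is significant; the whole-report null-calibration test uses it,
since the per-combination scope by construction does not control the
family-wise rate across combinations (~18% under the null versus ~3% with
the whole-report scope, measured by simulation).

## GC binning

Target GC% excludes ambiguous bases from the denominator; an
all-ambiguous sequence yields an undefined value. Windowed GC uses 10 kbp
windows advancing by 5 kbp; a final partial window is kept only when it
spans at least half a step. Quartile edges use linear interpolation
between order statistics (the common default), and bins are
right-inclusive: bin 1 is gc ≤ Q1, bin 4 is gc > Q3. Both choices are
recorded in the `gcbin` output metadata because membership of edge targets
depends on them. Per-target coverage is supplied as a table (from the
generator or external tooling); computing coverage from alignments is out
of scope.

## Downsampling design

The read count for a desired average target coverage follows
N = ceil(C·G/L) with G the total target span and L the single-read length
(101 bp by default; the equation counts reads, not pairs). Reads are kept
when they overlap a target by at least one base under half-open
coordinates, so abutment is zero overlap. Each replicate draws N reads
without replacement — "bootstrap" here means repeated subsampling, as when
downsampling an alignment file, not with-replacement resampling. Replicate
seeds derive deterministically from the master seed via seed sequences, so
identical inputs and master seed reproduce identical subsample families.
Read-pair subsetting samples pair indices uniformly without replacement,
keeping mates together and preserving file order.

To exercise the ladder end-to-end on synthetic data, a minimal recall
model converts sampled per-site depth and binomially drawn alt-supporting
reads into a genotype: no-call below depth 5 (the depth floor mirrors the
DP < 5 filter term), het for alt fractions in [0.2, 0.8], hom-alt above,
hom-ref below; thresholds configurable. It is synthetic-only and is never
applied to real callsets. Replicate metrics are summarized by median and
IQR per coverage level. Achieved coverage per replicate is reported rather
than asserted against a tolerance, since capture-efficiency variation
makes exact read-count matching unrealistic.

## SNP-array validation

Array markers enter validation when they lie inside a capture target and
meet the confidence criterion. The confidence direction defaults to
*at-most* 0.05 — Birdseed-style scores are better when lower — but is
exposed as a flag because conventions differ between tools. A/B calls are
oriented against the sequencing record's ref/alt, directly or after
reverse complementation; at markers without a sequencing record the
reference base is taken from the reference sequence when provided.
Complement-ambiguous A/T and C/G markers are excluded and counted rather
than strand-guessed, because an undetected strand flip would silently
convert concordance into discordance for exactly those combinations.
Validation then reuses the concordance engine with the array as the
comparison callset, plus the three-way allele spectrum.

## Synthetic generator

The generator's defaults emulate a chr12-scale custom-capture pair: 80
targets of 300–1500 bp with programmed GC drawn uniformly on 30–70%,
5,000 SNPs and 500 INDELs, mean target coverage 224×, SNP dbSNP fraction
98.6% with TsTv 2.43 (known) / 1.48 (novel), INDEL dbSNP fraction 34%,
and joint genotype distributions implying SNP NRS 99.63% / NRD 0.29% and
INDEL NRS 94.07% / NRD 10.7%.

`joint_from_concordance(nrs, nrd)` constructs a 4×4 joint genotype
distribution implying the requested metrics analytically: comparison-
variant mass is fixed, the NRS loss is split between evaluation hom-ref
and no-call (capped so the both-variant discordant mass stays
non-negative, with the remainder assigned to no-calls), and both-variant
plus evaluation-unique discordance is sized to hit the requested NRD.
`analytic_nrs`/`analytic_nrd` recover the implied values from any joint
matrix, which is what parameter-recovery tests compare pipeline estimates
against.

Design choices worth recording:

- Target sequences realize their programmed GC% by exact base-count
  construction (count, then shuffle), not i.i.d. draws, so realized GC sits
  within rounding of the programmed value even for short targets.
- `filter_fail_fraction` defaults to 0: randomly failing records would
  thin the PASS-only merge asymmetrically and bias NRS estimates away from
  the programmed joint distribution, making the truth unidentifiable.
  Filter behavior is exercised by configs that set the fraction explicitly;
  the truth table then records per-record pass flags. Records drawn to
  pass get annotations strictly inside the pass region (margins of one
  unit / 0.01) so filter counts are deterministic.
- Array discordance corruption applies to variant marker genotypes only,
  so the validation NRD converges to the programmed rate; corrupting
  hom-ref markers would add discordant sites outside the programmed
  universe and inflate NRD beyond the nominal rate.
- When a per-category allele spectrum is configured, ref/alt pairs are
  drawn from it with random orientation and may override the reference
  base at that position; the default TsTv-driven path always uses the
  reference base as ref.
- Latent truth (genotype pair, alleles, dbSNP status, GC bin, pass flags)
  is written alongside every fixture; tests compare estimates to truth
  rather than reverse-engineering generated files.

What the generator does **not** emulate: base-level read sequences and
sequencing error, alignment artifacts (mapping-quality structure is a
scalar annotation, not a model), WGA chimeras, linkage between adjacent
sites, multi-allelic sites, and indel representation ambiguity. Passing
tests therefore demonstrate that the *evaluation machinery* is correct and
that programmed statistical structure is recovered — not that any
particular laboratory protocol is unbiased.

## Numerical and I/O conventions

- VCF and array positions are 1-based; BED intervals 0-based half-open;
  one helper owns the conversion. Abutting BED intervals are not merged.
- Multi-allelic VCF records are split per alternate allele; records with
  non-ACGT alleles are skipped and counted.
- htslib stores QUAL and INFO floats in single precision, so the VCF
  reader and writer quantize float annotations to two decimals; the
  round-trip identity on domain fields is exact at that precision, which
  covers the precision real pipelines print.
- Annotation fields are read from INFO (the generator writes them there);
  missing annotations are `None` throughout.
- All randomness flows from explicit seeds through numpy seed sequences;
  every CLI run writes a manifest with config, input digests and seed.

## Problem sizes in the test suite

The suite runs the generator at 1,200–5,000 sites for structural checks,
50,000 SNP sites for the headline parameter-recovery check (3-binomial-SE
tolerance), 100 bootstrap replicates on a 25-target panel for the coverage
ladder, and 1,000 simulated spectra for the Fisher null calibration —
sizes chosen so each check's sampling error is well below its tolerance
while the whole suite stays around a minute.

## Limitations

- The whole-exome-scale NRS denominator reported by some published
  analyses cannot always be reproduced exactly from their printed counts;
  this implementation follows the definitional formula (comparison-variant
  sites in the denominator) and documents it, rather than matching any
  particular tool's internal site accounting.
- INDEL comparison is exact-allele; callsets from callers with different
  indel normalization conventions will show inflated unique fractions.
- The recall model is a deliberately minimal stand-in for a variant
  caller and is only meaningful on generator-produced depth tables.
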