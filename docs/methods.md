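# Methods

## Variant identity and storage

A variant is identified by `(chrom, pos, ref, alt)` with 1-based point
positions, chromosome names in the un-prefixed canonical set `1..22, X, Y`
("chr" dialects are normalized on ingest; output uses the un-prefixed form).
Genotype is excluded from identity: the same SNV is routinely carried het by
one donor and hom-alt by another, and every set operation (control
subtraction, cross-case intersection) must treat those as one variant.
Genotypes are stored as unordered diploid pairs drawn from `{ref, alt}`, with
at least one alt allele (a call asserts its variant). Male chrX calls are
stored diploid-coded like everything else — published variant tables print
diploid genotypes for male donors on chrX — so hemizygosity is handled only
at simulation time. Annotations (DP, QD, FS, MQ, HaplotypeScore, MQRankSum,
ReadPosRankSum) live in a mapping where absence is representable and distinct
from zero.

VCF reading uses cyvcf2 and writing uses pysam, so both ends are
htslib-compatible. Multi-allelic records are split into biallelic calls that
share the record's site-level annotations; a split call is emitted for each
ALT allele the genotype actually carries, and sibling-alt alleles are coded
as ref within a split call (each biallelic call can only describe its own
alt). Alleles outside ACGT (symbolic, spanning deletions) are dropped. The
read/write round trip preserves keys, genotypes, QUAL and annotations to six
significant digits (htslib stores INFO floats in 32-bit and prints `%g`).

## Hard filtering

The eight clauses use the GATK hard-filter convention: DP and QUAL are
pass-form requirements (`DP > 20`, `QUAL > 30`), the remainder fail-form
conditions (`QD < 2.0`, `FS > 60.0`, `MQ < 35.0`, `HaplotypeScore > 13.0`,
`MQRankSum < −12.5`, `ReadPosRankSum < −8.0`). All inequalities are strict,
so boundary values fail pass-form clauses (DP = 20 fails) and survive
fail-form clauses (QD = 2.0 passes). QUAL is applied as an ordinary clause
rather than a pre-selection; the two are indistinguishable in effect for a
single threshold, and treating it uniformly keeps the verdict record
complete.

Missing annotations are governed by a policy rather than an error: the
default `lenient` mode leaves a missing clause unevaluated (recorded in the
verdict's `missing_clauses`), matching how variant-filtration tools treat
absent annotations; `strict` mode fails it. HaplotypeScore in particular is a
legacy annotation that modern callers frequently omit, which is why it is
optional and why lenient is the default.

## Selection methods and their ordering guarantee

Methods A/B/C are described in the README. Two interpretation choices are
worth recording. "Absent in controls" means absent from the *union* of the
control callsets — in none of the controls — not absent pairwise. And method
C separates SNVs from indels before its raw-level subtraction, mirroring the
SNV/indel separation that precedes filtering in method A; the subtraction
therefore compares SNV keys on both sides.

The containment `C ⊆ B` (per sample and for the common set) is a theorem in
this algebra: a key in C passed the case-side filter and is outside the raw
control union; the filtered control union is a subset of the raw union, so
the key is outside it too, hence in B. The package property-tests this over
randomized cohorts, thresholds and missing policies rather than assuming it.
`B \ C` is exactly the keys present in some control's raw calls but filtered
out of every control — the "filter-order false negatives on the control
side" that become false case-specific positives; this characterization is
audited per key in the tests.

`genotype_concordance` compares unordered genotypes over an explicit key set
(e.g. brain- vs blood-derived callsets of one donor, where near-1
concordance argues a germline rather than somatic origin); an empty key set
or a key missing from either callset is a validation error, not a silent 0.

## Chromosome-burden statistics

The comparison unit is the percentage of a sample's SNVs per chromosome
(conserved to 100 by construction), which normalizes out per-sample yield;
raw-count contrasts are emitted alongside (`diff_count`) because a difference
of average counts is sometimes wanted. Group summaries use the arithmetic
mean and sample SD (n−1). The two-group test is Welch's two-sample t-test on
per-sample percentages, chosen as defensible for a 5-vs-3 design with
unequal variances summarized by SD error bars; Mann-Whitney is available as
an option but with n = 5 vs 3 its two-sided p cannot go below ~0.036, so it
cannot support an α = 0.001 claim at this design size. No multiple-testing
correction is applied by default (per-chromosome significance is reported as
such); a Bonferroni option across the 24 chromosomes exists. Groups of one
sample yield a missing p-value but still report the descriptive contrast.
Degenerate zero-variance-in-both-groups cases return p = 1 when the means
agree and p = 0 otherwise, rather than NaN. chrY is kept in every profile
(zero for females) so profiles are always 24-vector comparable;
sex-stratified comparisons (male cases vs male controls, cases by sex) are
the intended way to separate sex composition from group effects.

## Consequence classification

Codon changes are parsed from the printed convention (changed base uppercase,
context lowercase, `ref/alt` separated by a slash) and validated strictly:
exactly one differing position, the uppercase one in both codons, identical
lowercase context. Translation uses Biopython's standard genetic code. The
class follows from the amino-acid pair (synonymous / missense / stop_gained /
stop_lost), and notation is `L89*`-style, with the synonymous form printing
residue letter and index only (`G1026`). Strand and reading-frame resolution
is deliberately out of scope: codons are taken as printed, already oriented
to the coding strand, and are not recomputed from genomic ref/alt (several
table rows are on reverse-strand genes, where genomic alleles and codon bases
are complements). Rows without an annotated codon ("NA") classify as
not-applicable rather than erroring.

## The cohort simulator

The generator emulates raw single-sample caller output for the study-scale
design: 5 cases (sexes M,F,F,F,M) and 3 male controls by default, extensible.
Positions are drawn uniformly within GRCh37 chromosome lengths, weighted by
an approximate exome-target share per chromosome (autosomes proportional to
protein-coding gene counts; chrX fixed at 0.03, chrY at 0.002); ref/alt bases
are uniform and distinct; no reference sequence is consulted. Three disjoint
planted classes:

* **Background** polymorphisms (default 20,000 per cohort), each with a
  population allele frequency from Beta(0.8, 0.8) clipped to [0.01, 0.99].
  In `hw` mode samples carry them by Hardy-Weinberg draws (males hemizygous
  on the allosomes); in `shared` mode every sample carries them with a
  genotype drawn conditional on carriage — the clean regime in which exact
  recovery of the planted case-specific set is provable and tested.
* **Case-specific** variants (present in all cases, no control), good tier;
  `case_specific_chrX_fraction` forces that share onto chrX — the enrichment
  knob. Planted variants avoid chrY so mixed-sex cohorts can share them.
* **Borderline-shared** variants, good tier in every case and sub-threshold
  in every control: one uniformly chosen filter clause is forced past its
  threshold per control call, guaranteeing filter failure there. These are
  the calls that separate methods B and C.

Good-tier annotations are truncated into every clause's passing region:
DP ~ round(N(50, 10)) floored at 21 (matching the ~50x design coverage),
QUAL ~ N(200, 50) floored at 31, QD ~ N(15, 4) floored at 2, FS ~ Exp(3)
capped at 60, MQ ~ N(60, 2) floored at 35, HaplotypeScore ~ Exp(1.5) capped
at 13, rank-sums ~ N(0, 1) floored at their thresholds. The truncation puts a
small point mass at each bound; that is intentional — the good tier must
never fail a clause, or planted-truth recovery would be ill-posed.
HaplotypeScore, MQRankSum and ReadPosRankSum are independently dropped at
`missing_annotation_rate` (default 0.05; never the forced clause of a
borderline call). Male chrX/chrY genotypes are drawn hemizygously and
emitted diploid-coded as alt/alt. All draws flow through one
`numpy.random.default_rng(seed)`; identical configs reproduce byte-identical
cohorts and truth.

What the simulator does *not* model — and what passing tests therefore do not
show about real data: linkage/LD structure, sequencing-error and
allele-fraction models (no read-level simulation), somatic mosaicism
(variants are planted cohort-level, i.e. germline-like), realistic
within-chromosome position clustering, indels (the generator emits SNVs
only; indel handling is exercised by hand-written fixtures), and the true
per-chromosome exome variant proportions of any particular capture kit (the
weights are an approximation, not an acceptance surface).

## Verification scales and numerical choices

The filter is checked against an independent clause-by-clause oracle on 10⁴
randomized calls (boundary and missing values included, both policies); the
containment theorem over 1,000 randomized cohorts; planted-set recovery over
100 seeds (clean shared regime, 250 background / 15 planted per cohort);
borderline discrimination over 20 seeds at 50 borderline calls with a
per-key audit. The chrX-enrichment check simulates 20 cohorts at 20,000
background SNVs plus 600 chrX case-specific SNVs per case and requires Welch
chrX p < 0.001 in ≥90% of replicates; the null calibration runs 2,000
all-male no-signal replicates at 800 background SNVs and requires each
chromosome's α = 0.001 flag rate to stay within the binomial 99.9% quantile
at the nominal 0.001 rate (7 fires in 2,000). These problem sizes are the
package's chosen verification scales; all are seeded and deterministic.

Float comparisons in VCF round-trip tests use a 10⁻⁵ relative tolerance
(six-significant-digit storage). Sample ordering never affects results (set
semantics throughout; outputs are sorted karyotypically for determinism).

## Known limitations

* Gene names and codon context cannot be derived for simulated or novel
  variants (no annotation databases are consulted); report tables print "NA"
  there, and the packaged table carries its printed gene names verbatim.
* The Welch default is an assumption where the underlying analysis left the
  test unnamed; both tests are exposed and the choice is configurable.
* With every control female and a male-only case group, chrY background
  variants in `shared` mode cannot be vetoed by controls and would surface
  as case-specific; the default rosters avoid this, and planted variants
  avoid chrY entirely.
* Very small cohorts (one case) make the "common" set equal that case's
  selection; the algebra is well-defined but the cross-case intersection
  carries no replication evidence.
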