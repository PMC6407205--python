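# Methods

This note documents the models and procedures `canerv` implements, the
parameters that matter, what the synthetic-data generator does and does
not emulate, and the numerical choices made where the design was open.

## Coordinates and formats

All internal coordinates are 0-based half-open; conversion to 1-based
conventions (SAM, RepeatMasker `.out`, VCF) happens only in
`canerv.formats`. The exchange alignment format is a SAM subset (CIGAR
ops M/I/D/S, mapq 0–60); BAM/CRAM are out of scope. One exception to the
0-based rule: defect positions on the proviral consensus are reported
1-based from the consensus start (`DefectRecord.consensus_pos`), matching
how shared defects are conventionally cited (e.g. "bp 882"); the boundary
is explicit in the dataclass.

## The bundled read mapper

`canerv.mapping` is deliberately minimal plumbing: exact k-mer seeds
(k = 20, three offsets, both strands), mismatch-count scoring
(`len − 2·mm`), and a mapping-quality proxy
`min(60, −10·log₁₀(second_best/best))` (60 for unique hits, 0 for perfect
ties). It handles substitution errors but not indels within reads, which
matches the substitution-only read simulator. Any real mapper's SAM can
be substituted at every entry point.

## Non-reference insertion discovery

1. **Anchor pairs.** Pairs with exactly one reference-mapped mate whose
   other mate aligns to the LTR or internal consensus at ≥ 90% identity
   over ≥ 30 bp (defaults; full-read identity via edlib). The identity
   threshold is a configuration default, not a literature value.
2. **Clustering.** Single-linkage over anchor positions within 200 bp;
   ≥ 2 supporting pairs per emitted candidate; candidates within ±500 bp
   of an annotated element of the queried family are dropped with a
   recorded reason.
3. **Assembly.** Greedy overlap-layout-consensus over the candidate
   window's reads: repeatedly merge the highest-scoring suffix–prefix
   overlap (≥ 25 bp at ≥ 95% identity, reverse complements considered),
   consensus by per-column majority with alphabetical tie-break. Overlap
   search is seeded by exact 12-mers of the incoming contig's prefix, so
   an overlap whose first ~18 bp contain errors on both seed offsets can
   be missed — negligible at the 0.1% error rate the generator emulates.
   Ties break on contig consensus strings, making the result independent
   of input order. Input reads are deduplicated and, above 250, evenly
   subsampled in canonical order.
4. **Junction classification.** The LTR-derived span of a contig is
   delimited by the LTR's terminal 40-mers located with edlib (≤ 5
   edits); ≥ 30 bp of LTR-derived and of genomic sequence are required.
   Sides: `five_prime` (genome | LTR start), `three_prime` (LTR end |
   genome), `full_ltr` (both flanks around a complete LTR).
5. **Breakpoint and TSD.** Genomic spans are placed on the reference with
   the bundled mapper (unique placement, mapq ≥ 20). Junction boundaries
   are ambiguous wherever reference and LTR termini share bases
   (micro-homology), so the breakpoint is refined by scoring candidate
   positions (±6 bp around each placement-implied guess) against
   80-bp junction templates built from the reference and LTR consensus;
   the leftmost best-scoring candidate wins, and a candidate must fit
   every junction within 8% edit distance for the TSD to be reported.
   The reported breakpoint is always the leftmost TSD start on the
   forward strand, irrespective of element orientation. Loci with a
   single junction get a breakpoint but no TSD; inconsistent junctions
   are flagged (`tsd_mismatch`, `orientation_conflict`) and excluded
   from genotyping by default.

## Reference (unfixed) insertion detection

Library insert sizes are estimated from proper pairs (median and MAD;
≥ 200 pairs required). Pairs with both mates at mapq ≥ 20 and insert
size > median + 7×MAD support a deletion relative to the reference;
overlapping supports merge, the implied size is the median supporting
insert minus the expected insert, and only calls intersecting an
annotated element are kept, classified solo LTR (400–500 bp) or provirus
(7–9 kb). The median + k×MAD rule is the standard reading of a "MAD
score cutoff".

## Genotyping model

Alleles are rebuilt from ±600 bp of reference flank around the
breakpoint; the insertion allele duplicates the 5-bp TSD around the
element (reference loci invert the roles: the alternate allele is the
excision leaving one TSD copy). Elements with unresolved interiors are
filled from consensus and flagged `element_filled`.

Read pairs are support units, scored by summed best edlib placement on
each allele; ties are uninformative. Three guards remove non-informative
or misleading support: both mates must genuinely align to the supported
allele (≤ 10% edit distance — reads from outside the allele window
otherwise vote by alignment noise); pairs wholly inside the element's
internal (non-LTR) portion are dropped as non-specific; at least one
mate must overlap a discriminating junction by ≥ 1 base.

Per supporting pair with error probability ε = 10^(−mapq/10): the
matching homozygote contributes 1−ε, the opposite homozygote ε, and the
heterozygote ½ (the equal-weight mixture of the two homozygote terms).
Genotype is the maximum-likelihood class (no prior); zero informative
pairs yield a missing call which is excluded from that locus's
allele-frequency denominator. Short reads cannot distinguish a solo-LTR
from a proviral allele, and the package does not try.

## The molecular clock

`age = D/(L·μ)` with no factor of two: divergence is divided by a single
LTR length, treating the pair's combined accumulation as the per-site
divergence — the convention under which one change over 457 bp at
μ = 1.33 × 10⁻⁹ /site/year gives 1.64 My. The default rate is the canine
neutral rate written as 1.33e-9 (the value that reproduces the published
cluster ages; a 1.3e-9 rounding appears in some write-ups and is
accepted via `RunConfig`); presets for the mammalian-average (2.2e-9)
and mouse (4.5e-9) rates support sensitivity comparisons.

Change counting: pairwise global alignment (match +1, mismatch −1, gap
open −4, extend −0.5 — substitutions preferred over gaps), then
mismatched columns plus gap events, where runs of 1–2 gap columns count
one change per column and longer runs count once (a single
insertion/deletion event, e.g. a 43-bp internal duplication counts as
one change). The effective length is the ungapped 5′ LTR length.

Identical-LTR clusters (exact string match, size ≥ 2) are dated as
`1/(T·μ)` with `T` the concatenated member length — the waiting time for
one substitution across the cluster — which degenerates to the
single-change pair formula at one 457-bp member, keeping the two
estimators consistent.

The generator draws the total change count `D ~ Poisson(age·μ·L)` and
scatters changes uniformly over the pair, making it the exact inverse of
the dating formula; recovery is unbiased to within the small probability
of repeat hits at the same site (< 1% at the ages exercised).

## Depletion test

The statistic per window `w` is the number of insertions with ≥ 1 gene
model within `w` kb (window 0 = strict overlap). The null shuffles
insertion positions uniformly genome-wide, chromosomes chosen
proportional to length (per-chromosome count preservation is not
imposed; the merged gene intervals are fixed).
`p = #{permuted ≤ observed}/n_perm`, reported as `< 1/n_perm` when no
permutation is as extreme. Ties between permuted and observed counts
make the p-value mildly conservative and discrete; calibration is tested
at 100 insertions per dataset, where the granularity is far below the
Kolmogorov–Smirnov detection threshold used.

## Proviral annotation

The consensus is the per-column majority non-gap residue of a supplied
multiple alignment (ties alphabetical and logged; gap-majority columns
dropped). Gene intervals are annotation supplied alongside the
consensus, not inferred.

Each provirus is compared to the consensus by affine-gap global
alignment (match +1, mismatch −2, open −10, extend −0.5): affine costs
keep one biological indel as one gap run, where unit-cost (edit
distance) alignment would scatter it. Within each gene: indels are
classified frameshift (length mod 3 ≠ 0), in-frame, or large deletion
(≥ 100 bp, clipped to the gene); premature stops are in-frame stops of
the provirus's own gene sequence upstream of the consensus stop, read in
the consensus frame from the gene start. After a frameshift only the
first (abortive) stop is reported — downstream stops in a shifted frame
carry no further information. Shared defects group records identical in
kind, gene, and indel length within ±3 bp of the group anchor (the
tolerance absorbs alignment jitter near homopolymers); the recurrent
*env* deletion is recognized at 1073 ± 10 bp.

dN/dS follows Nei–Gojobori (1986): per-codon synonymous site fractions
by enumerating the nine single-base neighbors (mutations to stops count
as nonsynonymous), site counts averaged over the two sequences,
differences averaged over all minimal mutational pathways skipping those
through stop codons (all pathways used only if every one is blocked),
Jukes–Cantor correction `d = −¾·ln(1 − 4p/3)` (undefined and flagged at
p ≥ ¾). Significance uses a seedable codon bootstrap (default 1000
resamples) of `Z = (dN − dS)/se` against a normal reference — chosen
over the analytic-variance codon Z-test because it is assumption-light
and reproducible. A cohort average is the mean of pairwise ratios over
pairs where both rates are defined and dS > 0; excluded pairs are the
caller's to log.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the features the analysis logic depends on:
5-bp TSDs read from the reference at the breakpoint; solo-LTR versus
full-provirus alleles ('−' orientation elements reverse-complemented);
post-insertion LTR substitution accrual under the clock; diploid
Hardy–Weinberg cohorts with per-population insertion frequencies; FR
paired-end reads with Gaussian fragment sizes (400 ± 50 bp), uniform
substitution errors (0.1% default), and flat quality. Default study
conditions for the end-to-end validation: two 50-kb chromosomes, six
loci (~30% proviral), twelve samples in two populations, 20× coverage
per haplotype.

It does **not** emulate: indel or quality-profiled sequencing errors,
PCR duplicates, repetitive genomic background (reference chromosomes are
i.i.d.), segmental duplications, gene conversion between LTRs, CpG
hypermutability, or structural variants other than the ERV alleles.
Passing the round-trip tests therefore demonstrates the pipeline's logic
is correct under its stated assumptions — not that recall or genotype
concordance would reach the same values on real repetitive genomes with
real error profiles.

## Problem sizes and defaults used in validation

End-to-end validation runs 2 × 50 kb × 12 samples at 20×; clock
calibration uses 1000 replicate LTR pairs at 8 My; permutation
calibration 200 replicate null datasets of 100 insertions × 300
permutations; dN/dS is verified against exhaustive pathway enumeration
on all 61 × 61 sense-codon pairs. These sizes make every stage's
behavior measurable in seconds to minutes on one CPU while keeping
expected event counts (anchor support, junction coverage, Poisson change
counts) in the regimes the thresholds were designed for.

## Known limitations

- The anchor-mate identity threshold (90%/30 bp) is a configuration
  default; no published value exists for the equivalent filter.
- The greedy assembler is not a general-purpose assembler: it assumes a
  single locus per window and can be confused by windows containing two
  near-identical inserted sequences.
- Breakpoint refinement assumes the LTR consensus is within ~8% of the
  element's true termini; far more diverged families would need the
  divergence caps raised.
- The insert-size scan detects deletions only; it does not size
  insertions segregating in the sample but absent from the reference
  (those are the anchor-pair detector's job).
- dN/dS significance is per-pair; no correction is applied across pairs.
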