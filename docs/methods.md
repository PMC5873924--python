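# Methods

This note documents the models, estimators and design choices behind
splicedelta: what each statistic assumes, what the synthetic cohorts do and
do not emulate, and where genuinely open choices were resolved.

## Coordinate and annotation model

All public coordinates are 1-based inclusive (the GFF3/SAM convention);
half-open arithmetic is internal only. A gene is a set of transcripts, each
an ordered chain of non-overlapping exons; an intron is exactly the gap
between consecutive exons of one transcript. Because intron statistics are
computed per intron rather than per isoform, introns from all transcripts
of a gene are pooled and deduplicated by (start, end); each keeps a pointer
to its contributing transcript so "neighboring exons" are unambiguous. This
pooling is a choice (multi-isoform collapse is not forced by anything in
the data model) and is visible in output metadata through the
transcript-resolved flank coordinates. Genes failing the model invariants
are rejected into an explicit report, never silently dropped.

## Alignment acceptance filters

Records arrive pre-aligned; the two mapping stages of the emulated protocol
(a transcriptome pass and a genome pass) are represented by their
acceptance rules rather than by running aligners, because the rules — not
the aligner binaries — are the reproducible contract:

* transcriptome rule: identity strictly > 0.95 and exact terminal match
  runs ≥ 4 nt at **both** read ends (per record; in paired mode both mates
  must also map to the same transcript). Identity derives from NM (falling
  back to MD), terminal runs from MD capped by clipping/insertions.
* genome rule: any aligned block shorter than 8 nt rejects the record
  (a block of exactly 8 nt passes).

Both filters are pure predicates, so their application order is
irrelevant; per-rule rejection counts are logged for every replicate, as
filter attrition is the only mapping QC the pipeline performs. Duplicate
reads are not collapsed. Whether the 4-bp end rule should be applied per
mate or per pair in paired data is unknowable from the protocol statement;
it is applied per record here.

## Intron-retention test

The retention ratio of intron *i* in one replicate is the mean per-base
depth over the intron divided by the mean per-base depth over its two
flanking exons **pooled base-wise** (one average over all flank bases, not
the mean of two per-exon means; the alternative is available via
`pool_flanks=False` and differs only when flank lengths are unequal).
Replicates with zero flank depth yield an undefined ratio; any undefined
replicate excludes the intron from testing, with the reason recorded.

Group comparison is a two-sided Welch t-test. Two genuinely open choices
were resolved as follows:

* **Welch, not pooled-variance.** With n = 3 biological replicates there
  is no basis for assuming equal variances; Welch is the robust default
  and is used identically in every test in the package.
* **log₂ ratios by default** (`ir_use_log`, default true). Retention
  ratios are positive with approximately multiplicative noise; the log
  stabilizes variance across retention levels. This matters specifically
  at n = 3: when one group's variance dominates on the raw scale, the
  Welch–Satterthwaite degrees of freedom collapse toward 2 and the
  p < 0.01 criterion demands |t| ≳ 9.9, costing most of the test's power.
  The log scale balances the group variances and is consistent with the
  junction channels, which are tested on log ratios. The raw-scale test
  remains available (`ir_use_log=False`).

Calls additionally require a 2-fold gate on the **raw** group means:
IR when mutant ≥ 2× wild type, MES when ≤ ½×. The gate makes the test
conservative under the null.

## Junction-event tests

Candidates are junction-defined: an exon-skipping candidate exists for an
internal exon when at least one read joins its two flanking exons
directly; an alternative donor/acceptor candidate exists for every
observed junction over an annotated exon pair (both endpoints within the
flanking exons or the intron) that differs from the annotated boundaries.
Events with zero support everywhere are never candidates. Side labels are
strand-aware (the left genomic boundary is the donor on "+", the acceptor
on "−"); `alt_both` marks junctions where both boundaries differ.

The supporting/non-supporting convention: for skipping, supporting = skip
junction reads, non-supporting = junctions linking the skipped exon to
either flank; for alternative sites, supporting = the novel junction,
non-supporting = the annotated junction over the same exon pair. This
reading makes both ratios monotone in event usage; the underlying protocol
language admits other readings, so the convention is stated here rather
than attributed.

Both channels use pseudocount 1 before the log (keeping zero-count events
testable and the transform symmetric), and an event is reported only when
both Welch p-values pass — the expression-ratio channel protects against
AS-ratio shifts driven by denominator collapse. Classification
(enhanced/reduced) applies the 2-fold gate to the mean raw expression
ratio.

## Expression and DEG

Gene counts are reads unique to a gene: all blocks within the gene span
and overlapping no other gene (the conservative denominator; ambiguous
reads count toward per-gene totals only). TMM follows the published
definition — reference sample by closest scaled upper quartile, genes with
zero counts in either member excluded, 30%/5% double trim on M and A,
inverse-asymptotic-variance weights, factors rescaled to geometric mean 1 —
and agrees with the Bioconductor reference implementation to ~1e-12.
logCPM uses `log2((count + 0.5) / (effective lib + 1) * 1e6)`; RPKM is
`2^logCPM / (L/1000)` with L the exonic-union length of the gene.

DEGs are called on per-sample RPKM with Welch p < 0.01 and fold ≥ 2 (a
log₂-RPKM switch exists, `deg_log`). **No multiple-testing correction is
applied anywhere** — the emulated analysis convention uses raw p-value
thresholds throughout; at ~500 tested features and p < 0.01 this implies
roughly 5 expected false positives per family under the null, which the
fold gates largely absorb. Users porting these calls to larger genomes
should add FDR control.

## Reporter quantification

The reporter locus carries two overlapping introns with acceptors 3 nt
apart (defaults; both offsets configurable). Junction reads are classified
by exact matching of both boundaries, so a read can match at most one
variant and the 3-nt offset can never be mis-assigned; junctions matching
neither are tallied separately. Unspliced evidence is a contiguous read
spanning the canonical donor boundary with ≥ 8 nt on each side, mirroring
the block-credibility threshold — a declared proxy for "unspliced
transcript" from short-read data, since full-length evidence does not
exist in RNA-seq. Percentages are computed per replicate and then averaged
within condition; both levels are reported.

## The synthetic cohort

The generator emulates the study design the analyses assume: two
conditions × 3 replicates (configurable, ≥ 2 so t-tests have variance),
single-end 100-nt reads, multi-exon genes on one chromosome, and an
optional reporter locus on its own chromosome. Per gene, condition and
replicate, the fragment count is Poisson with a log-normal replicate
effect (sd 0.1 on log₂ — zero variance would make every t-test
degenerate); each fragment independently realizes exon skips, intron
retention and alternative-junction usage; starts are uniform along the
realized transcript. Reads carry NM/MD tags consistent with a perfect
alignment to the (random, fixed-seed) reference sequence; no downstream
stage reads sequence content or base qualities, and no sequencing-error or
insert-size model is included. Everything is deterministic given the
scenario: identical parameters produce byte-identical outputs, and the
annotation can be pinned (`annotation_seed`) independently of read seeds.

Default conditions: exons 200–400 nt, introns 200–300 nt (plant-like
element sizes, with introns in the upper half of that distribution so a
single intron's mean depth at ~50× coverage rests on enough independent
fragments for stable replicate ratios), baseline retention 0.2 per intron
— a partially retained intron class, the wild-type precondition without
which "more efficient splicing" would be unobservable — and 425 expected
fragments per gene, which yields ≈ 50× mean exon depth at 100-nt reads
for a two-exon gene after accounting for transcript-end coverage ramps.
Planted effects default to 5× retention shifts, 10%→60% alternative
junction usage, 5%→50% skip rates and 4× expression shifts.

Reporter fragments are junction-anchored: every reporter read is
diagnostic for its class (spliced classes span their junction, unspliced
reads span the canonical donor boundary, always with ≥ 8 nt overhang), so
class counts are exactly multinomial in the class proportions and the
quantifier's recovery error is purely binomial. Default proportions are
the reporter's observed variant shares: wild type 55/22/23
(unspliced / canonical / non-canonical), mutant ≈ 50.5/46.5/3.

What the generator does **not** emulate — and hence what green tests do
not establish about real data: mismatches and indels (filters are
exercised by constructed fixtures, not by an error model), paired-end
mates, fragment-length biases, positional/GC coverage bias, overlapping or
nested genes, multi-isoform expression mixtures, and novel junctions
outside annotated exon pairs.

## Numerical and procedural details

* Welch t-tests resolve degenerate inputs explicitly: both groups constant
  and equal → p = 1; both constant but different → p = 0.
* The depth-ratio estimator is mildly biased at desk scale: transcript-end
  coverage ramps deflate flank-exon means (inflating ratios a few percent
  when exons are short relative to the read length), and retained
  transcripts being longer than spliced ones deflates intron coverage per
  retained fragment by intron/transcript length. The recovery tests use
  geometries where these effects are small against sampling error; the
  fold-gated two-group comparison is unaffected to first order because
  both groups share the geometry.
* All result tables are sorted with explicit tie-breaks and carry the
  package version, a configuration hash and the seed, so reruns are
  byte-identical and diffs meaningful.
* Problem sizes used by the test-suite and acceptance cohorts: 500
  two-exon genes (500 introns) at ~50× exon depth for calibration and
  recovery, a 150-gene mixed-structure demo cohort, and ~1000–6000
  reporter fragments per replicate — desk-scale sizes chosen so a full
  run completes in minutes while every statistic still has 10–100
  informative reads per tested feature.

## Known limitations

* The exon-skipping channel requires the skip junction to be observed;
  at low coverage or very low skip rates candidates simply do not arise.
* The dual-test requirement (both p < 0.01 at n = 3) is deliberately
  stringent; moderately used alternative junctions can be missed, as the
  detection counts in the acceptance report show.
* "Unique read" gene counts undercount expression for genes overlapping
  neighbors; with the non-overlapping synthetic annotation this is
  invisible, on real compact genomes it is not.
* The exclusion-list mechanism models the removal of loci confounded by
  second-site splice-site mutations as simple interval masking; it does
  not model the variant calling that produces such a list.
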