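# Methods

## Coordinate conventions

All internal coordinates are 1-based and inclusive on both ends, the
GTF/GFF convention: an interval's length is `end − start + 1`, a single
base is `start == end`.  This is the only convention under which the
published *SCN1A* feature table is self-consistent (e.g. the 228-nt
cassette exon at chr2:166,060,640–166,060,867).  BED's 0-based half-open
convention appears only at the I/O boundary and the conversion is an
exact bijection (property-tested on random interval sets).  Three rows
of the shipped *SCN1A* table (features 3, 5 and 15) disagree with their
own printed lengths by 1–12 nt; they are carried verbatim with a
`length_discrepancy` flag rather than silently corrected.

Strand `.` (unstranded) is allowed for tracks but not for transcripts.
Exons within a transcript must be non-overlapping and on one chromosome;
a CDS span must start and end inside exons.

## Annotation delta

Given an old and a new annotation of the same genes (matched by
`gene_id`, no symbol aliasing), after removing retained-intron
transcripts (their exonic footprint blankets introns and would mask
genuine novelty):

* **Novel exon** — a new exon sharing zero bases with the union of old
  exons of the same gene.  Adjacency is not overlap under inclusive
  coordinates.  Each distinct interval is reported once with its
  supporting transcripts.  Genes absent from the old set go into a
  separate new-gene bucket.
* **Novel intron** — a new intron with no exact (chrom, start, end,
  strand) match among the gene's old introns.  Note that planting a
  cassette exon splits its host intron into two novel introns, and
  shifting a boundary moves the adjacent intron: the definitions
  overlap by construction, and the synthetic truth set records these
  induced introns so recovery tests can demand exact set equality.
* **Shifted splice junction** — a new exon overlapping an old exon with
  at least one *internal* boundary (a boundary adjoining an intron) at a
  different position.  Transcript ends are not splice sites; 5′/3′
  terminal extensions count only toward footprint gain.  When several
  old exons overlap, the comparison exon is the one with the largest
  base overlap, ties broken to the smaller start — the choice is
  arbitrary but deterministic.  Each changed boundary is reported with
  its shift in nt, extension/truncation direction, and donor/acceptor
  side derived from strand (plus-strand exon end = donor).

Novelty is evaluated within gene and strand: overlapping genes on the
opposite strand do not suppress a novel exon.  Whether the original
analysis pooled exons across genes or per gene is not documented;
per-gene is implemented here.  Footprint gain is the per-gene union of
new exonic bases not covered by old exonic bases (always ≥ 0 and
monotone in added exons); CDS gain restricts both unions to CDS
sub-intervals.

## Poison-exon calling (NMD rule)

The CDS is projected into spliced coordinates 5′→3′ (strand-aware); a
junction at offset *j* sits between spliced bases *j* and *j + 1*.  A
transcript is classified NMD when its stop codon ends more than
`ptc_distance` nt (default 50, configurable) upstream of the final
junction; junction-free transcripts are never NMD.  The 50-nt threshold
is the standard annotation rule; classification is monotone in the stop
position (moving a stop 5′ never flips NMD back to coding at fixed
junctions).

A cassette inclusion is classified by rebuilding the inclusion
transcript's junction set (the insertion junction splits in two; later
junctions shift by the exon length) and recomputing the stop, at three
precision levels:

1. **sequence** — host spliced mRNA and exon sequence available: scan
   codon-by-codon from the start codon for the first stop.  Checked
   against an independent Biopython-translation oracle on hundreds of
   random insertions.
2. **exon_scan** — exon sequence only: look for a stop inside the exon
   at the insertion frame; a frameshifting exon without an internal stop
   assumes a premature stop at the first opportunity downstream (the
   exon's 3′ end).
3. **frame_only** — no sequence: pure frame arithmetic with the same
   frameshift assumption.  A frame-preserving exon is assumed stop-free,
   so stop-carrying in-frame poison exons are *undercalled* in this
   mode; the file-level pipeline (GTF in, no FASTA) runs at this level
   and reports the mode alongside each call.

Hosts without an inferable CDS yield `processed_transcript`.
Selenocysteine recoding and stop-codon readthrough are not modelled.
Exon sequences are interpreted in transcript orientation (5′→3′ mRNA).

## Variant re-intersection

Two passes: (1) flag variants exonic in the new annotation but intronic
in the old; (2) demote flagged variants within `flank` nt (default 8) of
a splice site to `splice_proximal`, since their effect may act through
splicing disruption.  Distance is measured to the splice-site boundary
base, inclusive, on either side (the "within 8 bp" and "8-nt flanking
sequence" phrasings are reconciled as distance ≤ 8).  The flank test
uses boundaries from both annotation versions by default
(`splice_site_source="both"`); `"old"` restricts it to pre-existing
sites.  The reported per-call distance is always to the nearest old
splice site.  Indels intersect by their leftmost affected base
(VCF-style left alignment).  Every variant receives exactly one status
(`newly_exonic` / `splice_proximal` / `unchanged`), so the counts
partition the input; comparing an annotation with itself never yields
`newly_exonic`.

Amplicon-screen filters (all thresholds configurable via
`FilterThresholds`): positions with coverage < 5 or caller score < 30
are unsequenced (strict `<`, equality passes) and their variants are
masked; surviving cohort variants must have coverage > 7, GATK quality
> 50 (strict `>`), both callers (GATK and Samtools), no population-
database hit, homopolymer run ≤ 8 and no simple-repeat membership.  The
rules are conjunctive, hence order-independent (tested over all rule
permutations).  Diagnostic yield is 100·diagnosed/cohort rounded
half-up to one decimal (2/122 → 1.6 %).

## De novo enrichment

Disjoint features are concatenated to a region of length *L* with an
offset↔genomic map retained.  The expected count is

    λ = ploidy_factor · N · Σ_{pos, alt} μ(pos, alt)

with μ the per-site, per-allele de novo substitution probability per
generation per chromosome copy; positions missing from the table fall
back to a configurable default per-site rate.  `ploidy_factor` defaults
to 2 (μ per chromosome copy) and is an explicit parameter because
published mutability tables differ in convention; a genome-average
*diploid* rate (2.4 × 10⁻⁸/site) is therefore used with
`ploidy_factor=1`.  The p-value is the Poisson upper tail P(X ≥ k),
computed through the regularized incomplete gamma function
(`scipy.stats.poisson.sf`), which keeps full relative precision down to
λ ~ 10⁻⁹ where a naive `1 − CDF` would cancel; it is verified against
direct term-by-term series summation to < 10⁻¹⁰ relative error.
Bonferroni correction multiplies by the number of tests (default
18,000, the approximate exome-wide protein-coding gene count) and caps
at 1.  Rounding (2 significant figures) happens only at the reporting
layer.  Only the unweighted statistic is implemented; the
pathogenicity-weighted variant is out of scope.  Under the null the test
is conservative: its type-I error never exceeds the nominal level
(checked by seeded Monte-Carlo with 10,000 draws).

## Conservation and expression evidence

**Overlap fraction** is covered bases of the query's base-level union
divided by the union's size — invariant to how the query is split into
intervals.  The **permutation null** re-places every query interval
(length preserved) uniformly at random over the genome per replicate,
choosing the chromosome with probability proportional to its number of
valid start positions; placements are independent and may overlap,
which is unbiased and the simplest defensible null.  1000 replicates by
default; bit-identical for a fixed seed (a prefix-sum coverage index
keeps each replicate O(q log t)).  The significance summary is a
one-sample t-test of the replicate fractions against the observed
fraction as hypothesised mean, one-sided in the direction "replicates
below observed".  The original study's t-test formulation is ambiguous;
this convention is the package's own choice, documented here, and should
not be read as the published procedure's exact form.

**Junction expression**: raw junction read counts are normalised to
counts per million total mapped reads per sample.  Stage enrichment
compares the mean CPM over numerator-stage samples (foetal by default)
against `fold` × the mean over denominator-stage samples (infant;
fold = 5 by default, boundary inclusive); a zero denominator with a
positive numerator also flags.  The "all other samples combined" mode
pools raw reads and totals before normalising.  Whether the original
fivefold rule compared means, medians or pooled counts is unstated;
per-stage means of CPM are used and both the statistic and the fold are
configurable.  Read support: an intron is supported when its total
count across samples is ≥ `min_reads` (default 10, boundary inclusive);
a cumulative (threshold, fraction ≥ threshold) table is emitted for
plotting support curves.

## Synthetic data

The generator emulates the study's inputs at desk scale with full
ground truth.  Defaults mirror the study conditions where stated — 122
probands, 2 observed de novo variants, 36 junction samples in six
developmental stages, fivefold enrichment calls, a 5 % background
conservation density, a 1.2 × 10⁻⁸ per-copy per-site mutability
(2.4 × 10⁻⁸ diploid) — and otherwise use one fixed choice of realistic
gene scale: 8 genes (the size of the screened gene panel) of 6–10 exons
of 90–300 nt separated by 600–2000-nt introns, on both strands, with
30-nt UTR stubs and a frame-consistent CDS.  Per locus pair it plants 5
novel cassette exons (2 stop-carrying poison, 1 frameshifting poison, 2
benign), 3 exon-skipping novel introns, 4 junction shifts of 10–40 nt
and 2 retained-intron transcripts, reserving introns so features never
collide.  Poison exons are placed with ≥ 2 downstream junctions in
transcript order so the 50-nt rule is decisive; benign exon sequences
are built codon-by-codon so no codon touching the exon (including the
two spanning its boundaries) is a stop.  Variants are planted per
category plan: novel-exon interiors (> 8 nt from every boundary in both
versions), shift-extension flanks at 1–8 nt from the old boundary, deep
intronic and old-exonic controls, and one variant per quality-filter
rule crafted to fail exactly that rule.  Junction counts are Poisson
around a baseline CPM (5 by default, ≈ 10 reads/sample at the 2 × 10⁶
library size) with a 10-fold foetal boost on planted enriched introns
and a near-zero CPM class (fraction 0.2) to populate the unsupported
tail.  A negative-binomial noise model is not implemented; Poisson is
the minimal choice and the quantile tests only rely on means.

All randomness flows from one mandatory seed through named
`numpy.random.default_rng` streams (no global state); identical configs
give byte-identical output files.

What the generator does **not** emulate — and therefore what passing
tests do not show about real data: realistic sequence composition
(sequences are random apart from planted stops and frames), overlapping
genes and shared exons between paralogs, soft-clipped/mismapped
junction reads, batch effects or library-size variation across samples,
indel mutability, and the strong position-dependence of real per-site
mutation rates.  Truth-recovery results demonstrate correctness of the
definitions and plumbing, not robustness to alignment noise.

## Numerical and reporting choices

* Interval set arithmetic is exact integer arithmetic on sorted merged
  lists; no floating point touches coordinates.
* Writers sort deterministically (chrom, start, end, id); report JSON is
  key-sorted.
* Diagnostic yield uses decimal half-up rounding (so 1.55 → 1.6), not
  banker's rounding.
* Degenerate inputs fail loudly: empty query for overlap fractions,
  zero-variance permutation nulls, zero library sizes, overlapping
  concatenation features, CDS boundaries outside exons.
* Problem sizes in the test-suite and acceptance script — 8-gene loci,
  20 simulation replicates, 200 random classifier cases, 1000
  permutation replicates, 10,000 null draws — were chosen once as the
  smallest sizes at which the checked properties are sharp (exact set
  equality, 3-standard-error bands).

## Known limitations

* The headline full-release numbers (3550 transcripts, 674 kb footprint
  gain, 23 re-annotated clinical variants, the 19 %/12.7 %/47 %
  fractions) require the complete public annotation, variant and
  RNA-Seq releases and are out of scope at desk scale; the pipeline
  reproduces the definitions and the arithmetic, not those totals.
* Exact reproduction of the published unadjusted enrichment p-value
  (9.5 × 10⁻⁷) needs the study's per-site mutability table, supported
  as an optional input; with the genome-average rate the package lands
  within a factor of 2 (8.7 × 10⁻⁷).
* HGVS nomenclature, pathogenicity scoring, liftover between
  assemblies, splicing-efficiency prediction and conservation-score
  computation (tracks are inputs) are all out of scope.
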