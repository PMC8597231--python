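# Methods

## The problem

RNA editing (A-to-I deamination by ADAR enzymes, read as A>G on the coding
strand; C-to-U by APOBEC enzymes, read as C>T) creates RNA-specific
single-nucleotide variants: present in RNA-Seq reads, absent from the same
individual's DNA. Detecting coding editing sites reliably is dominated by
alignment artifacts — soft-clipped reads near splice junctions, reads
captured by intronless retro-copies (processed pseudogenes), and
reverse-transcription errors near homopolymers — so this package couples
an alignment-selection/refinement layer to the variant-calling layer and
ships a ground-truthed synthetic-data generator that reproduces each of
those failure modes.

## Competitive selection

Candidate alignments come from up to five mapper/database sources
(transcript database, alternate-exon fragments, a second transcript
annotation, and two genome mappers). Custom-database sequences are
forward-strand exon concatenations whose names encode the exon intervals,
so alignments against them are translated to spliced genomic coordinates
(splice operations of exactly the intron lengths) without consulting the
annotation again.

Per read mate, the best record is chosen by: mapped beats unmapped, then
more reference-matching bases, then fewer indel *events*. Ties go to pair
rules, in order: same chromosome; smaller `floor(log10(max(d,1)))` of the
leftmost-start distance `d`; forward-reverse orientation (upstream mate
forward, downstream reverse); same source; smallest source priority. A
final deterministic tie-break on the ordered priority pair makes selection
independent of candidate input order. Pair distance is measured between
leftmost starts (outer-span and inner-span conventions differ only within
a log10 bucket at this read scale). "Matches" are aligned bases minus
mismatches when mismatch information (reference or NM tag) is available;
otherwise aligned bases stand in and the fallback is noted in the record
stream.

## Refinement

Records of interest — unmapped, soft-clipped, gapped, or carrying a
mismatch with base quality ≥ 20 — are realigned inside a 100 kb window on
the forward-reverse-consistent side of the mate (or 100 kb on either side
of the original position when the mate is unmapped). Alignments are scored
`+1` per aligned base, `−1` per gap open, `−1` per gap-extend unit, `+5`
per splice shorter than 100 kb. The gap convention is: a gap of length L
costs `1 + L` (open plus one extend unit per gapped base); splices of
100 kb or more earn no bonus and no penalty (the built-in realigner never
proposes them). A realignment replaces the original only when it is an
improvement: originally unmapped; higher score; same score but the pair
goes cross-chromosome → same chromosome, or non-FR → FR; otherwise the
original stands.

The built-in realigner is exact seed-and-extend: three staggered 16-mer
seeds from each read end (one sequencing error can break at most two
overlapping seeds), gapless extension with mismatch counting, and an
exhaustive single-splice-point search between any left/right seed
placement pair (minimum anchor 12 bp, minimum intron 20 bp). Candidates
are ranked by score minus twice the mismatch count; a candidate below half
the read length in score is rejected. The realigner is pluggable — any
callable returning a scored candidate, e.g. parsed output of an external
spliced aligner, can be substituted.

Poly-A tails that splice onto genomic A-runs are soft-clipped afterwards:
a strand-aware 3′ run of at least 6 A's (T's at the stored-sequence start
for reverse-strand records) whose aligned span contains, or is immediately
preceded by, a splice is converted to soft clip and the splice removed.

## Editing-site calling

Pileup counting uses aligned (M) bases of non-duplicate reads with mapping
quality ≥ 1 and base quality ≥ 20; soft-clipped bases never count.
De novo candidates need ≥ 3 alt reads (the same count as the rescue rule;
the upstream caller's exact cutoffs are not recoverable, so the package
states its own). Candidates are then:

* subtracted against germline/somatic DNA variants and a public SNP table
  (position *and* allele by default; a position-only mode exists);
* restricted to coding sequence, taking the gene strand from the covering
  CDS; a site inside CDS of genes on both strands is kept with strand
  "unknown" plus a transcript-model flag rather than dropped;
* screened by artifact filters (below);
* classified (A>G/+ or T>C/− → A-to-I; C>T/+ or G>A/− → C-to-U; unknown
  strand classified by whichever orientation is canonical and marked
  ambiguous) and annotated with the worst coding consequence across
  transcripts (nonsense > stop-loss > missense > synonymous).

A call with an empty flag set is PASS. Note that at ≥3 alt reads a cohort
will still produce occasional error-coincidence false positives — the
manual-review step of the original procedure is automated here only as
flags plus a review table, so a small residue of de novo false calls is
expected and documented rather than hidden.

### Artifact filters

**Homopolymer.** Reverse-transcription slippage errors concentrate within
one base of the 3′ end of a homopolymer on the antisense strand. The
extracted description of the rule's geometry is ambiguous without the
original figure, and gene strand may be unknown when the filter runs, so
the filter is applied strand-agnostically: a variant within one
intervening base of either end of a run of ≥ 4 identical bases is flagged
(one of the two ends is the antisense-strand 3′ end whichever strand the
gene is on). This over-flags by at most a factor of two relative to a
strand-resolved rule; the review table preserves the flagged sites.

**Paralog suspect.** For each alt-supporting read, the filter looks for a
placement on any sequence of a paralog transcript database with at least
as many matching bases as the read's current placement *and* whose base at
the variant offset equals the alt allele — i.e. the "variant" is the
paralog's reference. If at least half the alt reads vote, the site is
flagged. Placement is a gapless best-match scan in both orientations
(numpy sliding windows) behind a pigeonhole pre-gate: a placement with at
most k mismatches must contain one of k+1 disjoint read chunks exactly, so
reads that cannot possibly tie are skipped in O(find).

**Transcript-model suspect.** Sites where ≥ 50% of alt-supporting reads
are soft-clipped within 5 bp of the site — the signature of reads that
belong to an exon missing from the transcript model.

### Known-site rescue

Editing sites from a curated database that de novo calling missed are
rescued when ≥ 3 mutant reads are observed in each of ≥ 2 cohort samples.
Rescued calls carry provenance `rescued_known`, disjoint from `de_novo`.

## Quantification

Per site and sample: coverage, mutant reads, VAF = mutant/coverage
(undefined at zero coverage). Third-allele bases count toward coverage
only. A site is **evaluable** at ≥ 10 reads. **High confidence** is
coverage-banded: > 100 reads → ≥ 3 mutant reads; 20–100 → ≥ 2; < 20 → ≥ 1.
The band edges place coverage exactly 100 in the middle band (the source
wording leaves 100 ambiguous between "20–99" and "above 100"; the rule
here resolves it downward and the tests pin that choice). The thresholds
are motivated by background error measured at **adjacent control sites**:
the nearest position within ±2 bp of an editing site with the same
reference allele (distance ties broken upstream). `estimate_background`
tabulates, per coverage bin and mutant-read threshold,
`TP = 1 − (control observations ≥ threshold)/(editing observations ≥ threshold)`;
empty denominators are flagged undefined. The estimator is exercised on
binomial simulations only — the exact denominator convention of the
original percentages is not recoverable from the text.

**Junction-corrected (spliced) levels** restrict counting to reads whose
record *or mate* contains a splice operation (orphan mates are judged by
their own operations). Overall vs spliced VAFs across samples are compared
per site with a two-sided Wilcoxon rank-sum test: exhaustive enumeration
of all C(n1+n2, n1) assignments on midranks (counting arrangements with
|U − μ| ≥ |observed|) when both groups have ≤ 10 values, else a normal
approximation with tie correction. The unpaired test follows the stated
procedure even though per-sample pairing exists; a paired signed-rank mode
is available behind a flag. Benjamini–Hochberg FDR is reported across
sites (the source shows a volcano plot without naming a correction).

## Cohort summaries

Per-sample burden counts high-confidence sites. Group expression is the
fraction of panel sites covered ≥ 10× in ≥ 3 samples of the group. Group
median VAFs run over positively edited (high-confidence, non-zero)
samples only, and a site is reported for a group only when ≥ 3 samples
cover it ≥ 10× (standard midpoint median). The specificity matrix divides
each cell's VAF by its row maximum over expressed cells (all samples, not
a thinned subset); cells under 10× coverage are a distinct NOT_EXPRESSED
sentinel (`NE` in the TSV export, NaN in memory) so renderers can keep the
unedited-vs-unexpressed distinction. Tumor-specific sites have ≥ 1
high-confidence tumor observation and none among evaluable normals; sites
with no evaluable normal are listed but marked low-power.

## Synthetic data

`simgen.make_reference` builds, deterministically per seed (one
`numpy` Philox stream per entity, keyed `(seed, stream_id)`):

* 5 genes on alternating strands, 3–5 exons of 150–300 bp, introns
  200–600 bp, each a complete stop-free ORF (`ATG … TAA`), CDS = exons;
* one intronless retro-copy of gene 0 on its own contig, annotated as a
  single-exon coding gene (the expressed-pseudogene trap), at 99.7%
  background identity plus 3 planted divergent bases near a designated
  junction of gene 0;
* a codon-aligned T-run (length 6) in gene 1 followed by a designated
  artifact site;
* 20 heterozygous germline SNPs and 30 editing sites (≈ 90% A-to-I,
  ≈ 10% C-to-U) with per-site rates uniform on [0.05, 0.5], placed ≥ 121 bp
  from transcript ends, away from each other, from SNPs, from homopolymer
  contexts, and outside the retro-reachable region of gene 0.

`simulate_reads` draws 101 bp read pairs per transcript at depth 50
(fragment length N(280, 40) truncated to [101, mean+4σ]), heterozygous
SNPs on one haplotype, each covering read carrying an edit independently
with the site's rate (a per-molecule mode couples mates), substitution
errors at 0.2%, and 2% duplicate fragments (flagged, never recounted).
`write_candidate_alignments` emits three of the five sources — transcript
database (priority 1, custom-entry coordinates), BWA-like genome
(priority 4, gapless; junction reads soft-clipped to their longest exonic
anchor), STAR-like genome (priority 5, spliced) — with two configured
degradations: 10% of junction-spanning reads are soft-clipped in the
genome sources and unmapped in the transcript source (exercising
refinement), and half of the fragments spanning the designated gene-0
junction are mis-placed whole onto the retro-copy (exercising the paralog
filter). The alternate-exon and second-annotation sources map nothing in a
simulation that expresses only annotated junctions and are therefore not
emitted by default; the module constant still declares all five sources.

The retro-copy identity (99.7%) is deliberately higher than the ~98% of
the motivating real-gene pair: in the real case intronic context resolves
the DNA mapping while the competitive match-count rules see transcripts
only, so a strongly divergent copy would never win selection and the trap
would be vacuous. Variant placement is excluded from the entire region of
gene 0 reachable by a retro-misplaced fragment so that genuine variants
cannot leak onto the retro contig as wrong-coordinate calls.

### What the generator does not emulate

Quality-by-cycle error profiles, GC and positional coverage bias,
expression-level variation between genes and samples, indel errors,
allele-specific expression, and per-patient genotype variation (one
germline VCF serves the whole cohort). Passing tests on this generator
demonstrate the *logic* of selection, refinement, filtering, and
quantification under controlled failure modes — not performance on real
libraries, where error structure and mapping ambiguity are richer.

## Problem sizes and numerical choices

The bundled study conditions are desk-scale by design: a ~14 kb genome,
10-sample cohorts, ~1,200 fragments per sample; the full discovery
pipeline over 10 samples runs in well under a minute. End-to-end checks
pool mutant/coverage counts per site across the cohort before comparing
against exact binomial 99% intervals of the true rate — per-sample
intervals at 30 sites × 10 samples would fail by multiplicity under a
correct implementation. Degenerate inputs are defined throughout: empty
candidate lists are contract violations; zero coverage yields undefined
VAF; empty background bins are flagged; rank-sum comparisons with fewer
than 3 defined values per group are undefined and flagged; ties in
control-site matching break upstream.

## Known limitations

* The de novo caller keeps error-coincidence false positives that the
  original procedure removed by manual review; they appear in the review
  table or as rare PASS calls (≥3 identical errors at one position).
* The paralog filter is gapless; paralogs diverging by indels would need
  the pluggable realigner.
* `estimate_background`'s true-positive fraction is a simulation-grade
  estimator, not a reproduction of any published percentage.
* The built-in realigner proposes at most one splice per read.
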