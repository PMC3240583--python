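# Methods

## The analysis model

The pipeline treats a CLIP experiment as a sample of short sense-strand RNA
fragments drawn from a transcriptome in proportion to transcript abundance,
with fragments overlapping a protein-binding motif over-represented. All
genomic coordinates are 0-based half-open (BED convention); tag sequences
are always transcribed-strand sequences (reverse complement of the genome
on the minus strand).

### k-mer enrichment

Every length-k window (windows containing N are skipped, never imputed) is
counted in three populations: deduplicated CLIP tags, the genome, and the
transcriptome. The genome background counts both strands, because the
genome is unstranded while binding is transcribed-strand specific; the
transcriptome background counts sense strands only, because tags are sense
sequences. Enrichment is the signed frequency difference
`f_CLIP − f_background` on the per-window probability scale; a ratio column
is emitted for reference but never drives the headline ranking. Ranks are
descending with lexicographic tie-breaks so output is reproducible.
Significance per k-mer is a Pearson χ² on the 2×2 table (k-mer windows vs
other windows) × (CLIP vs background), df = 1; tables with an expected cell
below 1 are flagged but still reported.

Duplicate removal precedes all counting: after sorting by (chrom, strand,
start, end), a greedy left-to-right scan per (chrom, strand) keeps a tag
only if it does not overlap the previously kept tag. Exact duplicates fall
out of the same rule and opposite strands never collide. The overlap rule
is a stated convention (only "duplicates including overlapping reads" is
specified by the procedure being reimplemented); the greedy scan is simple,
deterministic and idempotent.

### Anchored consensus

Tags are anchored at the first base of a GAA triplet, preferring the
strongest context present in the tag: leftmost AGAAGA match, else leftmost
AGAA, else leftmost GAA; tags without GAA are excluded and counted. The
priority encodes the finding that AGAA is the optimal core. Columns are
offsets relative to the anchor (default window −5..+7; the exact display
extent is a free choice and is configurable). Each column is normalized by
its own coverage, because short tags do not reach outer columns; exact
ties in the per-column argmax are rendered as IUPAC ambiguity codes rather
than an arbitrary base.

The GAAG-context statistic considers tags that contain GAA but no AGAA
anywhere and reports the fraction whose anchor is immediately followed by
G; an anchor at the last position counts as not-followed-by-G, and the
statistic is undefined (None) when no tag qualifies.

### Tag annotation

A tag overlapping a same-strand gene is assigned the feature class (5'UTR,
CDS, 3'UTR, intron) with the largest total overlap; exon subclasses beat
intron on exact ties (exonic binding is the signal of interest), and exon
subclasses tie-break in the fixed order 5'UTR > CDS > 3'UTR. Failing a
same-strand coding overlap, a same-strand ncRNA overlap gives ncRNA; an
opposite-strand gene or ncRNA overlap gives antisense; otherwise
intergenic. Whether the antisense slice counts as intragenic is a
reporting convention, so the summary carries both intragenic fractions.
Alternative-event assignment is by maximal overlap with the fixed
tie-break priority cassette > mutually exclusive > alt5 > alt3 > retained
intron.

### Conservation enrichment

Positions covered by any match of the top k-mer set (overlaps union) are
cross-tabulated against a per-position conservation mask, one trial per
nucleotide (per-match-site counting is not the default because the
hypothesis concerns nucleotide positions). The Fisher exact test is
two-sided by the point-probability convention — the sum of hypergeometric
probabilities of all fixed-margin tables no more probable than the
observed one — computed in log space (gammaln) so large exons are safe; a
relative tolerance of 1e-7 on the log scale absorbs floating-point error
in the "no more probable" comparison. The χ² test is the closed-form 2×2
Pearson statistic with optional Yates correction. Both are implemented
here and cross-checked against scipy in the test suite.

### ESE scanning and mutation design

Octamer z-score tables are user-supplied files (published score tables are
not redistributed; the generator fabricates tables for testing). Octamers
absent from the table score 0 (neutral) and are counted in a log message;
a strict mode raises instead. Default thresholds are z ≥ +4 for enhancers
(z around 4 is already enhancer territory) and z ≤ −4 for silencers; both
are configurable, as the strong/moderate boundary is not fixed. Calls are
maximal runs of threshold-crossing windows with their extents unioned.

Mutation design searches all single-base substitutions inside a called
enhancer (mirroring experimental point mutants; double mutants are out of
scope). A plan is valid iff every window of the target enhancer falls
below the enhancer threshold after mutation and no affected window (the ≤8
windows containing the mutated position; all others are provably
unchanged) would be called a silencer, i.e. none scores at or below the
silencer threshold. Plans are returned sorted by post-mutation enhancer
peak, ascending; an empty list means no single substitution suffices.

### Splice quantification

PSI defaults to molar length-correction of band intensities (longer RT-PCR
products bind more dye), `100·(I_inc/L_inc)/(I_inc/L_inc + I_skip/L_skip)`;
whether published intensity data are length-corrected is a convention, so
the uncorrected ratio is available via a flag. Group comparison is Welch's
unequal-variance t-test (the safer default when only "independent
two-sample t-test" is specified), with an explicit guard returning
(t=0, p=1) for identical zero-variance groups. qPCR quantification follows
the standard-curve procedure — OLS of Ct on log10(concentration),
`quantify(ct) = 10^((ct−intercept)/slope)`, `efficiency = 10^(−1/slope)` —
not ΔΔCt; duplicate measurements are averaged by arithmetic mean before
reference-gene normalization. Mapping reports render percentages rounded
to two decimals.

## The synthetic-data generator

`SimConfig` defaults are the study conditions: mean tag length 40 nt
(truncated Poisson on [20, 80] — only the mean is specified, Poisson is a
stand-in), planted hexamer AGAAGA, enrichment factor 10, 10,000 tags,
antisense rate 7.5%, duplicate rate 10% (a generator choice; CLIP
libraries are PCR-duplicated to varying degrees), uniform expression
weights. Genes occupy the central 70% of equal slots on a 1 Mb chromosome
(100 genes, alternating strands), each with exons separated by introns of
twice the exon length and the concatenated exonic run labelled
20% 5'UTR / 60% CDS / 20% 3'UTR; the middle exon of gene *i* carries
alternative-event class *i* mod 5, and one ncRNA per five genes sits in
intergenic gaps.

Tags are sampled from full gene spans (pre-mRNA: tags land in introns as
well as exons, as in real CLIP data), with per-window weight equal to the
transcript's expression weight times the enrichment factor when the window
fully contains the planted k-mer. Planting by up-weighting — not by
rewriting genome sequence — keeps the background k-mer frequencies exactly
interpretable, and makes enrichment_factor = 1 an exact null: with uniform
weights, tag windows are then uniform over transcribed windows, matching
the unweighted transcriptome background.

The genome size matters: a transcriptome small enough that reads saturate
the planted loci destroys enrichment after overlapping-read deduplication
(each binding site collapses to ~1 kept tag however strongly it was
sampled). The 1 Mb / 100-gene default keeps read coverage of the
transcribed space around 0.6×, as in a real library where most binding
sites remain sparsely covered. Conservation masks are independent
Bernoulli(conserved_fraction) per position, with the odds multiplied by
motif_bias inside planted-motif matches (bias 1 gives a mask independent
of sequence — the null for the conservation test; with bias > 1 the
overall conserved fraction slightly exceeds the baseline). Quantification
readouts are molar abundances psi_true : (100−psi_true) times product
length (defaults 714/438 bp) with multiplicative lognormal noise.

A single integer seed drives everything; sub-streams use fixed offsets
(genome 0, tags 1, conservation 2, quantification 3, octamer tables 4), so
tags can be resampled from one genome under many seeds, and identical
configs give byte-identical FASTA/BED/TSV output.

What the generator does **not** emulate: sequencing errors,
crosslink-induced deletions/mutations, non-uniform fragmentation,
transcript splicing (tags are sampled from pre-mRNA, so spliced-junction
tags do not occur), multiple transcripts per gene, and realistic k-mer
composition (the background is i.i.d. uniform, so genome and transcriptome
frequencies coincide in expectation — real genomes differ, which is why
both corrections are computed). Passing tests therefore demonstrate
correctness of the counting, ranking, annotation and testing machinery and
calibration of the statistics under the generator's assumptions — not that
the pipeline is robust to the full messiness of real CLIP libraries.

## Numerical and design notes

- Ranks, tie-breaks and consensus codes are all deterministic
  (lexicographic / fixed priority orders) so repeated runs agree exactly.
- Frequencies from any k-mer table sum to 1 within 1e-12; column
  frequencies of the PFM likewise per covered column.
- χ² on tables with an expected cell < 1 is flagged, not suppressed.
- The Fisher implementation agrees with exact rational enumeration for
  small tables (verified to total ≤ 24 in the tests) and with scipy for
  large ones.
- Degenerate inputs raise: empty tag sets, zero-window k-mer tables,
  zero-margin χ² tables, both-zero isoform intensities, non-positive or
  constant dilution series, mapping counts that do not sum.

## Problem sizes used in the checks

The end-to-end checks run 100 simulated experiments at the full study
conditions (10,000 tags each) for planted-motif recovery; null calibration
uses one 2 Mb / 200-gene genome with 400 tag-sampling seeds (300 in the
acceptance script) for the χ² test, 400 conservation masks over a 10 kb
exon for the Fisher test, and 1000 replicate pairs for the t-test; these
sizes give binomial standard errors around 0.01 on the rejection rates.
Oracle-equivalence checks use randomized inputs up to 10 kb, where
brute-force recomputation is fast and exact.
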