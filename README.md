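# clipmotif

Motif discovery and splicing-regulation analysis for CLIP-seq binding-site
data, built around the analysis of an SR-like splicing activator (Tra2β)
that binds AGAA-rich exonic enhancers.

CLIP (UV crosslinking-immunoprecipitation followed by sequencing) recovers
short RNA fragments ("tags", ~40 nt) bound by a protein of interest. This
package implements the downstream computational pipeline for such data:

- **k-mer enrichment** — count every k-mer in the tag population and in
  genome/transcriptome backgrounds, then rank by the background-corrected
  frequency `f_CLIP − f_background` (per-window probability scale), with a
  Pearson χ² test per k-mer, GAA/AGA core-motif classification, and the
  fraction of tags containing each k-mer. Duplicate and overlapping reads
  are removed first (greedy left-to-right scan per chromosome and strand).
- **Anchored consensus** — anchor each tag on its GAA core (preferring an
  AGAAGA context, then AGAA, then bare GAA), stack into a position
  frequency matrix relative to the anchor, and emit an IUPAC consensus.
- **Tag annotation** — assign each tag to exon (5'UTR/CDS/3'UTR), intron,
  ncRNA, antisense or intergenic by majority overlap, and to
  alternative-splicing event classes (cassette, mutually exclusive,
  alt 5'/3' splice site, retained intron).
- **Conservation enrichment** — test whether positions covered by matches
  of a top k-mer set are preferentially conserved, with self-implemented
  two-sided Fisher exact and 2×2 χ² tests on the per-nucleotide
  (covered × conserved) table.
- **ESE scanning and mutation design** — slide an octamer z-score table
  over an exon, call enhancer/silencer regions above/below thresholds
  (default z ≥ 4 / z ≤ −4), and exhaustively search single-base
  substitutions that abolish an enhancer without creating a silencer.
- **Splice quantification** — percent spliced in,
  `PSI = 100·(I_inc/L_inc) / (I_inc/L_inc + I_skip/L_skip)` (molar
  length-correction of band intensities, switchable), Welch two-sample
  t-tests between replicate groups, qPCR standard curves (OLS of Ct on
  log10 concentration, `efficiency = 10^(−1/slope)`), reference-gene
  normalization, and read-mapping report summaries.
- **Synthetic data** — a generator producing toy genomes, gene models,
  conservation masks, motif-planted CLIP tags (windows containing the
  planted hexamer are up-weighted rather than rewriting the genome) and
  simulated RT-PCR readouts, so the whole pipeline is testable without
  external downloads.

## Worked example

```python
import clipmotif as cm
from clipmotif.simulate import SimConfig, generate_dataset

ds = generate_dataset(SimConfig(seed=1))        # 10,000 tags, AGAAGA planted
df = cm.analyze_tags(ds.tags, ds.genome.values(),
                     ds.transcript_sequences(), k=6)
top = df.sort_values("rank_corrected").iloc[0]
print(top.kmer, f"{top.corrected_genome:.5f}", f"{top.chi2_p:.2e}")

pfm = cm.consensus_from_tags(ds.tags)
print(pfm.consensus_slice(-1, 4))
```

prints

```
AGAAGA 0.00049 1.27e-34
AGAAGA
```

i.e. the planted hexamer is the top genome-corrected 6-mer (its CLIP window
frequency exceeds the genome background by 0.00049, χ² p ≈ 1e-34), and the
GAA-anchored consensus over offsets −1..+4 reads back the planted AGAAGA.

The same stages are available from the shell:

```bash
clipmotif simulate --n-tags 10000 --seed 1 --outdir sim_out
clipmotif kmers --tags-bed sim_out/tags.bed --tags-fasta sim_out/tags.fa \
    --genome-fasta sim_out/genome.fa --transcriptome-fasta tx.fa --k 6
clipmotif map-report --processed 297070 --aligned 177457 \
    --failed 74476 --suppressed 45137
```

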