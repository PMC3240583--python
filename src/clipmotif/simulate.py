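"""Synthetic genomes, gene models, CLIP tags, conservation masks and
quantification readouts.

The generator emulates the statistical structure of a testis CLIP
experiment: ~40-nt tags sampled from transcribed regions with expression
weighting, a planted enriched hexamer (AGAAGA by default) realized by
up-weighting motif-bearing windows rather than rewriting the genome (so
background k-mer frequencies stay interpretable), exact-duplicate and
antisense read fractions, and per-position conservation masks whose odds
of conservation are boosted inside planted-motif matches.

Coordinates are 0-based half-open throughout.  A single integer seed
drives all randomness; sub-streams are derived with fixed offsets so each
stage is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .annotate import EVENT_CLASSES, GeneModelSet
from .kmers import ClipTag, reverse_complement

__all__ = [
    "SimConfig",
    "SyntheticDataset",
    "generate_genome",
    "generate_clip_tags",
    "generate_dataset",
    "generate_conservation",
    "generate_quant_readouts",
    "random_octamer_table",
]

_BASES = np.array(list("ACGT"))

# fixed sub-stream offsets off the user seed
_STREAM_GENOME = 0
_STREAM_TAGS = 1
_STREAM_CONSERVATION = 2
_STREAM_QUANT = 3
_STREAM_OCTAMER = 4


@dataclass
class SimConfig:
    """Study conditions for one synthetic CLIP experiment.

    Defaults mirror the experiment being emulated: mean tag length 40 nt,
    planted hexamer AGAAGA at 10x window up-weighting, 10,000 tags, a 7.5%
    antisense read fraction, and a 10% exact-duplicate fraction.  The 1 Mb
    genome with 100 genes keeps the transcribed space well below read
    saturation (~0.6x coverage), as in a real CLIP library where
    overlapping-read deduplication leaves most binding sites represented;
    see the methods note for these generator choices.
    """

    genome_length: int = 1_000_000
    n_genes: int = 100
    exons_per_gene: int = 3
    expression_weights: Optional[Sequence[float]] = None  # None -> uniform
    planted_kmer: str = "AGAAGA"
    enrichment_factor: float = 10.0
    n_tags: int = 10_000
    tag_length_mean: int = 40
    duplicate_rate: float = 0.10
    antisense_rate: float = 0.075
    seed: int = 0

    #: tag lengths are truncated-Poisson around the mean, clipped to this range
    tag_length_range: tuple = (20, 80)

    def __post_init__(self):
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        if self.enrichment_factor < 1:
            raise ValueError("enrichment_factor must be >= 1")
        for name in ("duplicate_rate", "antisense_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0,1]")
        if self.tag_length_mean <= 0 or self.n_tags < 0 or self.n_genes < 0:
            raise ValueError("lengths and counts must be positive")
        if set(self.planted_kmer) - set("ACGT"):
            raise ValueError("planted_kmer must be over ACGT")
        if self.expression_weights is not None:
            w = np.asarray(self.expression_weights, dtype=float)
            if len(w) != self.n_genes or (w < 0).any() or w.sum() == 0:
                raise ValueError(
                    "expression_weights must be nonnegative, length n_genes, not all zero"
                )


@dataclass
class SimTruth:
    """Ground truth recorded at generation time."""

    planted_kmer: str
    enrichment_factor: float
    motif_positions: list  # (chrom, genomic start, strand of the transcribed copy)
    category_fractions: dict = field(default_factory=dict)
    tag_categories: list = field(default_factory=list)


@dataclass
class SyntheticDataset:
    genome: dict  # chrom -> sequence string
    gene_models: GeneModelSet
    config: SimConfig
    tags: list = field(default_factory=list)
    truth: SimTruth = None

    def transcript_sequences(self) -> list[str]:
        """Sense-strand pre-mRNA sequences (full gene spans)."""
        out = []
        for gene in self.gene_models.genes.itertuples():
            seq = self.genome[gene.chrom][gene.start : gene.end]
            out.append(seq if gene.strand == "+" else reverse_complement(seq))
        return out


def _random_genome(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def generate_genome(config: SimConfig) -> SyntheticDataset:
    """Uniform random genome plus a templated, non-overlapping gene layout.

    Genes occupy the central 70% of equal slots along one chromosome and
    alternate strands.  Each gene is exons_per_gene exons separated by
    introns twice the exon length; the concatenated exonic sequence is
    partitioned 20% 5'UTR / 60% CDS / 20% 3'UTR.  The middle exon of gene i
    is labelled with alternative-event class i mod 5.  One ncRNA per five
    genes is placed in intergenic gaps.
    """
    rng = np.random.default_rng([config.seed, _STREAM_GENOME])
    chrom = "chrSim"
    genome = {chrom: _random_genome(rng, config.genome_length)}

    gene_rows, feat_rows, nc_rows, event_rows = [], [], [], []
    n = config.n_genes
    if n > 0:
        slot = config.genome_length // n
        span = int(slot * 0.7)
        n_units = 3 * config.exons_per_gene - 2  # exon=1 unit, intron=2 units
        exon_len = span // n_units
        if exon_len < 10:
            raise ValueError(
                "genome too short to place the requested genes/exons "
                f"(exon length would be {exon_len} nt)"
            )
        for i in range(n):
            gstart = i * slot + (slot - span) // 2
            gend = gstart + span
            strand = "+" if i % 2 == 0 else "-"
            gene_id = f"gene{i}"
            gene_rows.append(dict(chrom=chrom, start=gstart, end=gend,
                                  strand=strand, gene_id=gene_id))
            exons = []
            pos = gstart
            for j in range(config.exons_per_gene):
                exons.append((pos, pos + exon_len))
                pos += exon_len + 2 * exon_len  # exon then intron
            exons[-1] = (exons[-1][0], gend)  # last exon absorbs the slack
            # label exonic run: first 20% 5UTR, last 20% 3UTR, middle CDS
            total_ex = sum(e - s for s, e in exons)
            b1, b2 = int(total_ex * 0.2), int(total_ex * 0.8)
            if strand == "-":
                b1, b2 = total_ex - b2, total_ex - b1  # template in sense order
            cum = 0
            for (s, e) in exons:
                for seg_s, seg_e, feat in _split_exon(s, e, cum, b1, b2, strand):
                    feat_rows.append(dict(chrom=chrom, start=seg_s, end=seg_e,
                                          strand=strand, gene_id=gene_id,
                                          transcript_id=f"{gene_id}.t1",
                                          feature=feat))
                cum += e - s
            mid = exons[len(exons) // 2]
            event_rows.append(dict(chrom=chrom, start=mid[0], end=mid[1],
                                   strand=strand,
                                   event_class=EVENT_CLASSES[i % len(EVENT_CLASSES)]))
        for i in range(n // 5):
            # ncRNA in the gap after every 5th gene
            gap_start = (5 * i) * slot + (slot - span) // 2 + span + 10
            if gap_start + 300 <= min(config.genome_length, (5 * i + 1) * slot):
                nc_rows.append(dict(chrom=chrom, start=gap_start,
                                    end=gap_start + 300, strand="+",
                                    ncrna_id=f"ncRNA{i}"))

    models = GeneModelSet(
        genes=pd.DataFrame(gene_rows, columns=["chrom", "start", "end", "strand", "gene_id"]),
        exon_subfeatures=pd.DataFrame(
            feat_rows,
            columns=["chrom", "start", "end", "strand", "gene_id", "transcript_id", "feature"],
        ),
        ncRNAs=pd.DataFrame(nc_rows, columns=["chrom", "start", "end", "strand", "ncrna_id"]),
        alt_events=pd.DataFrame(event_rows, columns=["chrom", "start", "end", "strand", "event_class"]),
    )
    return SyntheticDataset(genome=genome, gene_models=models, config=config)


def _split_exon(s, e, cum_before, b1, b2, strand):
    """Split one exon's genomic interval into UTR/CDS segments.

    cum_before is the exonic length preceding this exon in genomic order;
    b1/b2 are the UTR/CDS breakpoints on the genomic-order exonic run (for
    minus-strand genes the 5'UTR sits at the genomic right, handled by the
    caller flipping b1/b2 and the label order here).
    """
    labels = ("5UTR", "CDS", "3UTR") if strand == "+" else ("3UTR", "CDS", "5UTR")
    bounds = [0, b1, b2, b2 + (e - s) + cum_before + 1]  # last sentinel large
    out = []
    for li, (lo, hi) in enumerate(zip(bounds[:-1], bounds[1:])):
        seg_s = max(s, s + lo - cum_before)
        seg_e = min(e, s + hi - cum_before)
        if seg_e > seg_s:
            out.append((seg_s, seg_e, labels[li]))
    return out


def _truncated_poisson(rng, mean, lo, hi, size):
    draws = rng.poisson(mean, size=size)
    return np.clip(draws, lo, hi)


def _motif_start_intervals(match_positions, tag_len, k, n_starts):
    """Start positions s (as merged intervals) whose window [s, s+tag_len)
    fully contains a motif match: s in [m - tag_len + k, m]."""
    ivals = []
    for m in match_positions:
        lo = max(0, m - tag_len + k)
        hi = min(m, n_starts - 1)
        if hi >= lo:
            ivals.append((lo, hi))
    merged = []
    for lo, hi in sorted(ivals):
        if merged and lo <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    return merged


def _find_all(seq: str, motif: str) -> list[int]:
    out, i = [], seq.find(motif)
    while i != -1:
        out.append(i)
        i = seq.find(motif, i + 1)
    return out


def _classify_by_truth(gene, subfeatures, introns, start, end):
    """Generator-side majority-overlap category (independent bookkeeping,
    same rule as the annotation module but computed by linear scan)."""
    totals = {"5UTR": 0, "CDS": 0, "3UTR": 0, "intron": 0}
    for s, e, feat in subfeatures:
        totals[feat] += max(0, min(end, e) - max(start, s))
    for s, e in introns:
        totals["intron"] += max(0, min(end, e) - max(start, s))
    order = ["5UTR", "CDS", "3UTR", "intron"]
    best = max(order, key=lambda f: (totals[f], -order.index(f)))
    return "intron" if best == "intron" else f"exon_{best}"


def _gene_info(dataset: SyntheticDataset, planted_kmer: str) -> list:
    """Per-gene (gene row, sense sequence, motif matches, exon subfeatures,
    introns), cached on the dataset so tags can be resampled from one genome
    under many seeds without re-deriving bookkeeping."""
    cached = getattr(dataset, "_gene_info_cache", None)
    if cached is not None and cached[0] == planted_kmer:
        return cached[1]
    feats_by_gene = {
        gid: [(r.start, r.end, r.feature) for r in sub.itertuples()]
        for gid, sub in dataset.gene_models.exon_subfeatures.groupby("gene_id")
    }
    introns_by_gene = {
        gid: [(r.start, r.end) for r in sub.itertuples()]
        for gid, sub in dataset.gene_models.introns.groupby("gene_id")
    }
    gene_info = []
    for gene in dataset.gene_models.genes.itertuples():
        seq = dataset.genome[gene.chrom][gene.start : gene.end]
        sense = seq if gene.strand == "+" else reverse_complement(seq)
        matches = _find_all(sense, planted_kmer)
        gene_info.append((gene, sense, matches,
                          feats_by_gene.get(gene.gene_id, []),
                          introns_by_gene.get(gene.gene_id, [])))
    dataset._gene_info_cache = (planted_kmer, gene_info)
    return gene_info


def generate_clip_tags(dataset: SyntheticDataset, config: SimConfig = None) -> list[ClipTag]:
    """Sample CLIP tags from transcribed regions.

    Per tag: length ~ truncated Poisson around tag_length_mean; source gene
    chosen with probability proportional to expression weight x number of
    start positions; start chosen so that windows containing the planted
    k-mer carry enrichment_factor times the weight of plain windows.  A
    duplicate_rate fraction of reads are exact re-emissions; an
    antisense_rate fraction are strand-flipped.  Tags are stored on
    ``dataset.tags`` and per-tag truth on ``dataset.truth``.
    """
    config = config or dataset.config
    if config.enrichment_factor < 1:
        raise ValueError("enrichment_factor must be >= 1")
    rng = np.random.default_rng([config.seed, _STREAM_TAGS])
    genome = dataset.genome
    genes = dataset.gene_models.genes
    k = len(config.planted_kmer)

    n_dup = int(round(config.n_tags * config.duplicate_rate))
    n_core = config.n_tags - n_dup
    lengths = _truncated_poisson(rng, config.tag_length_mean,
                                 *config.tag_length_range, size=n_core)

    tags: list[ClipTag] = []
    truth = SimTruth(planted_kmer=config.planted_kmer,
                     enrichment_factor=config.enrichment_factor,
                     motif_positions=[])

    if len(genes) == 0:
        # no transcripts: intergenic sampling from the raw genome, plus strand
        chrom = next(iter(genome))
        gseq = genome[chrom]
        for i in range(n_core):
            L = int(lengths[i])
            s = int(rng.integers(0, len(gseq) - L + 1))
            tags.append(ClipTag(chrom, s, s + L, "+", f"tag{i}", gseq[s : s + L]))
            truth.tag_categories.append("intergenic")
    else:
        weights = (np.ones(len(genes)) if config.expression_weights is None
                   else np.asarray(config.expression_weights, dtype=float))
        gene_info = _gene_info(dataset, config.planted_kmer)
        for gene, sense, matches, feats, intrs in gene_info:
            for m in matches:
                gstart = (gene.start + m if gene.strand == "+"
                          else gene.end - m - k)
                truth.motif_positions.append((gene.chrom, gstart, gene.strand))
        span_lens = (genes["end"] - genes["start"]).to_numpy()
        gene_probs = weights * np.maximum(span_lens - config.tag_length_mean + 1, 1)
        gene_probs = gene_probs / gene_probs.sum()
        gene_draws = rng.choice(len(genes), size=n_core, p=gene_probs)
        flip = rng.random(n_core) < config.antisense_rate

        for i in range(n_core):
            gene, sense, matches, feats, intrs = gene_info[gene_draws[i]]
            L = int(min(lengths[i], gene.end - gene.start))
            n_starts = len(sense) - L + 1
            s = _sample_start(rng, matches, L, k, n_starts, config.enrichment_factor)
            # map sense-coordinate start to genomic coordinates
            if gene.strand == "+":
                gstart = gene.start + s
            else:
                gstart = gene.end - s - L
            gend = gstart + L
            strand = gene.strand
            seq = sense[s : s + L]
            category = _classify_by_truth(gene, feats, intrs, gstart, gend)
            if flip[i]:
                strand = "-" if strand == "+" else "+"
                seq = reverse_complement(seq)
                category = "antisense"
            tags.append(ClipTag(gene.chrom, int(gstart), int(gend), strand,
                                f"tag{i}", seq))
            truth.tag_categories.append(category)

    if n_dup > 0 and tags:
        dup_idx = rng.integers(0, len(tags), size=n_dup)
        for j, idx in enumerate(dup_idx):
            t = tags[idx]
            tags.append(ClipTag(t.chrom, t.start, t.end, t.strand,
                                f"dup{j}", t.sequence))
            truth.tag_categories.append(truth.tag_categories[idx])

    cats = pd.Series(truth.tag_categories)
    truth.category_fractions = (cats.value_counts(normalize=True)).to_dict()
    dataset.tags = tags
    dataset.truth = truth
    return tags


def _sample_start(rng, matches, L, k, n_starts, enrichment):
    """One start position with motif-bearing windows up-weighted."""
    if not matches or enrichment == 1.0:
        return int(rng.integers(0, n_starts))
    ivals = _motif_start_intervals(matches, L, k, n_starts)
    c = sum(hi - lo + 1 for lo, hi in ivals)
    if c == 0:
        return int(rng.integers(0, n_starts))
    w_motif = enrichment * c
    w_plain = n_starts - c
    if rng.random() < w_motif / (w_motif + w_plain):
        # uniform over the union of motif-bearing start intervals
        r = int(rng.integers(0, c))
        for lo, hi in ivals:
            if r < hi - lo + 1:
                return lo + r
            r -= hi - lo + 1
    # uniform over plain starts: rejection against the merged intervals
    while True:
        s = int(rng.integers(0, n_starts))
        if not any(lo <= s <= hi for lo, hi in ivals):
            return s


def generate_dataset(config: SimConfig) -> SyntheticDataset:
    """Genome + gene models + tags in one call."""
    ds = generate_genome(config)
    generate_clip_tags(ds, config)
    return ds


def generate_conservation(
    exon_sequence: str,
    conserved_fraction: float,
    motif_bias: float = 1.0,
    seed: int = 0,
    motif: str = "AGAAGA",
) -> np.ndarray:
    """Per-position boolean conservation mask.

    Each position is conserved with probability conserved_fraction; positions
    inside matches of ``motif`` have their odds of conservation multiplied by
    motif_bias.  With motif_bias = 1 the mask is independent of the sequence
    (the null for the conservation-enrichment test).
    """
    if not 0 <= conserved_fraction <= 1:
        raise ValueError("conserved_fraction must lie in [0,1]")
    if motif_bias < 1:
        raise ValueError("motif_bias must be >= 1")
    rng = np.random.default_rng([seed, _STREAM_CONSERVATION])
    n = len(exon_sequence)
    p = np.full(n, float(conserved_fraction))
    if motif_bias > 1 and 0 < conserved_fraction < 1:
        odds = conserved_fraction / (1 - conserved_fraction) * motif_bias
        p_motif = odds / (1 + odds)
        for m in _find_all(exon_sequence.upper(), motif):
            p[m : m + len(motif)] = p_motif
    return rng.random(n) < p


def generate_quant_readouts(
    psi_true: float,
    n_replicates: int,
    noise_sd: float,
    seed: int = 0,
    inclusion_length: int = 714,
    skip_length: int = 438,
) -> pd.DataFrame:
    """Simulated two-isoform RT-PCR intensity table.

    Molar abundances are psi_true : (100 - psi_true); measured intensities
    are molar abundance x product length with multiplicative lognormal noise
    (exp of a zero-mean Gaussian with sd noise_sd).  Default product lengths
    are the 714-nt inclusion and 438-nt skip products of the experiment the
    generator emulates.
    """
    if not 0 <= psi_true <= 100:
        raise ValueError("psi_true must lie in [0,100]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng([seed, _STREAM_QUANT])
    inc_molar = psi_true / 100.0
    skip_molar = 1.0 - inc_molar
    noise = np.exp(rng.normal(0.0, noise_sd, size=(n_replicates, 2))) if noise_sd > 0 \
        else np.ones((n_replicates, 2))
    return pd.DataFrame(
        {
            "replicate": np.arange(n_replicates),
            "inclusion_intensity": inc_molar * inclusion_length * noise[:, 0],
            "skip_intensity": skip_molar * skip_length * noise[:, 1],
            "inclusion_length": inclusion_length,
            "skip_length": skip_length,
        }
    )


def random_octamer_table(
    n_scored: int,
    seed: int = 0,
    score_scale: float = 6.0,
) -> dict[str, float]:
    """Fabricated octamer z-score table for testing the ESE scanner."""
    rng = np.random.default_rng([seed, _STREAM_OCTAMER])
    scores: dict[str, float] = {}
    while len(scores) < n_scored:
        octamer = "".join(_BASES[rng.integers(0, 4, size=8)])
        scores[octamer] = float(rng.normal(0.0, score_scale))
    return scores
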