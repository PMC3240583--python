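"""Genomic-feature annotation of CLIP tags.

Each tag is assigned to exactly one category — exon_5UTR, exon_CDS,
exon_3UTR, intron, ncRNA, antisense or intergenic — by majority overlap
against a gene-model set, and optionally to an alternative-splicing event
class (cassette, mutually exclusive, alt 5'/3' splice site, retained
intron).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .kmers import ClipTag

__all__ = [
    "GeneModelSet",
    "AnnotationSummary",
    "annotate_tag",
    "summarize_annotation",
    "assign_alt_event",
    "CATEGORIES",
    "EVENT_CLASSES",
]

CATEGORIES = (
    "exon_5UTR",
    "exon_CDS",
    "exon_3UTR",
    "intron",
    "ncRNA",
    "antisense",
    "intergenic",
)

EXON_FEATURES = ("5UTR", "CDS", "3UTR")

#: tie-break priority for alternative-event assignment (highest first)
EVENT_CLASSES = ("cassette", "mutually_exclusive", "alt5", "alt3", "retained_intron")


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


@dataclass
class GeneModelSet:
    """Gene models used for tag annotation.

    All tables use 0-based half-open coordinates.

    genes: columns chrom, start, end, strand, gene_id
    exon_subfeatures: columns chrom, start, end, strand, gene_id,
        transcript_id, feature (5UTR/CDS/3UTR)
    ncRNAs: columns chrom, start, end, strand, ncrna_id
    alt_events: columns chrom, start, end, strand, event_class
    introns are derived: the within-gene complement of the exon subfeatures.
    """

    genes: pd.DataFrame
    exon_subfeatures: pd.DataFrame
    ncRNAs: pd.DataFrame
    alt_events: pd.DataFrame
    introns: pd.DataFrame = field(default=None)  # derived if None

    def __post_init__(self):
        if self.introns is None:
            self.introns = self._derive_introns()
        self._gene_trees = self._build_trees(self.genes, ("gene_id",))
        self._feature_trees = self._build_trees(
            self.exon_subfeatures, ("gene_id", "feature")
        )
        self._intron_trees = self._build_trees(self.introns, ("gene_id",))
        self._ncrna_trees = self._build_trees(self.ncRNAs, ("ncrna_id",))
        self._event_trees = self._build_trees(self.alt_events, ("event_class",))

    def _derive_introns(self) -> pd.DataFrame:
        rows = []
        if len(self.genes) == 0:
            return pd.DataFrame(columns=["chrom", "start", "end", "strand", "gene_id"])
        exons = self.exon_subfeatures
        for gene in self.genes.itertuples():
            sub = exons[exons["gene_id"] == gene.gene_id].sort_values("start")
            cursor = gene.start
            for ex in sub.itertuples():
                if ex.start > cursor:
                    rows.append(
                        dict(chrom=gene.chrom, start=cursor, end=ex.start,
                             strand=gene.strand, gene_id=gene.gene_id)
                    )
                cursor = max(cursor, ex.end)
            if cursor < gene.end:
                rows.append(
                    dict(chrom=gene.chrom, start=cursor, end=gene.end,
                         strand=gene.strand, gene_id=gene.gene_id)
                )
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "gene_id"])

    @staticmethod
    def _build_trees(df: pd.DataFrame, payload_cols: tuple) -> dict:
        trees: dict = {}
        if df is None or len(df) == 0:
            return trees
        stranded = "strand" in df.columns
        for row in df.itertuples():
            strand = row.strand if stranded else "."
            key = (row.chrom, strand)
            trees.setdefault(key, IntervalTree())
            payload = tuple(getattr(row, c) for c in payload_cols)
            if row.end > row.start:
                trees[key].addi(row.start, row.end, payload)
        return trees

    def _query(self, trees: dict, chrom: str, start: int, end: int, strand=None):
        hits = []
        for (c, s), tree in trees.items():
            if c != chrom:
                continue
            if strand is not None and s != strand:
                continue
            for iv in tree.overlap(start, end):
                hits.append((iv.begin, iv.end, iv.data))
        return hits

    def chroms(self) -> set:
        out = set()
        for df in (self.genes, self.ncRNAs):
            if df is not None and len(df):
                out.update(df["chrom"].unique())
        return out


def annotate_tag(tag: ClipTag, models: GeneModelSet) -> str:
    """Assign one category to a tag by majority overlap.

    Same-strand protein-coding assignment first: the feature class (5UTR,
    CDS, 3UTR, intron) with the largest total overlap wins; exon subclasses
    beat intron on exact ties, and exon subclasses tie-break in the fixed
    order 5UTR > CDS > 3UTR.  Failing that, a same-strand ncRNA overlap
    gives ncRNA; an opposite-strand gene or ncRNA overlap gives antisense;
    otherwise intergenic.
    """
    if models.chroms() and tag.chrom not in models.chroms():
        warnings.warn(f"tag chromosome {tag.chrom!r} absent from gene models; "
                      "annotating as intergenic", stacklevel=2)
        return "intergenic"
    sense_genes = models._query(models._gene_trees, tag.chrom, tag.start, tag.end,
                                strand=tag.strand)
    if sense_genes:
        totals = {f: 0 for f in EXON_FEATURES}
        totals["intron"] = 0
        for s, e, (gene_id, feature) in models._query(
            models._feature_trees, tag.chrom, tag.start, tag.end, strand=tag.strand
        ):
            totals[feature] += _overlap(tag.start, tag.end, s, e)
        for s, e, _ in models._query(
            models._intron_trees, tag.chrom, tag.start, tag.end, strand=tag.strand
        ):
            totals["intron"] += _overlap(tag.start, tag.end, s, e)
        # exon subclasses listed before intron: ties go to exons
        order = ["5UTR", "CDS", "3UTR", "intron"]
        best = max(order, key=lambda f: (totals[f], -order.index(f)))
        if totals[best] > 0:
            return "intron" if best == "intron" else f"exon_{best}"
        # overlaps the gene span but no derived feature (degenerate model)
        return "intron"
    if models._query(models._ncrna_trees, tag.chrom, tag.start, tag.end,
                     strand=tag.strand):
        return "ncRNA"
    opposite = "-" if tag.strand == "+" else "+"
    if models._query(models._gene_trees, tag.chrom, tag.start, tag.end,
                     strand=opposite) or models._query(
        models._ncrna_trees, tag.chrom, tag.start, tag.end, strand=opposite
    ):
        return "antisense"
    return "intergenic"


@dataclass
class AnnotationSummary:
    counts: dict
    fractions: dict
    n_tags: int
    intragenic_fraction: float          # sense intragenic only
    intragenic_fraction_incl_antisense: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "category": list(CATEGORIES),
                "count": [self.counts[c] for c in CATEGORIES],
                "fraction": [self.fractions[c] for c in CATEGORIES],
            }
        )


def summarize_annotation(tags: Sequence[ClipTag], models: GeneModelSet) -> AnnotationSummary:
    """Category counts and fractions over all tags (tags should be deduplicated).

    Because whether the antisense slice counts as intragenic is a convention,
    both intragenic fractions are reported.
    """
    if not tags:
        raise ValueError("empty tag set")
    counts = {c: 0 for c in CATEGORIES}
    for tag in tags:
        counts[annotate_tag(tag, models)] += 1
    n = len(tags)
    fractions = {c: counts[c] / n for c in CATEGORIES}
    sense_intragenic = 1.0 - fractions["intergenic"] - fractions["antisense"]
    return AnnotationSummary(
        counts=counts,
        fractions=fractions,
        n_tags=n,
        intragenic_fraction=sense_intragenic,
        intragenic_fraction_incl_antisense=sense_intragenic + fractions["antisense"],
    )


def assign_alt_event(tag: ClipTag, models: GeneModelSet) -> Optional[str]:
    """Alternative-event class with maximal overlap, or None.

    Exact overlap ties break by the fixed priority
    cassette > mutually_exclusive > alt5 > alt3 > retained_intron.
    Event intervals are matched regardless of strand if the event table has
    no strand column; with strands, same-strand events only.
    """
    best_class, best_len = None, 0
    stranded = "strand" in models.alt_events.columns if len(models.alt_events) else True
    strand = tag.strand if stranded else None
    hits = models._query(models._event_trees, tag.chrom, tag.start, tag.end,
                         strand=strand)
    totals: dict = {}
    for s, e, (event_class,) in hits:
        totals[event_class] = totals.get(event_class, 0) + _overlap(tag.start, tag.end, s, e)
    for cls in EVENT_CLASSES:
        if totals.get(cls, 0) > best_len:
            best_class, best_len = cls, totals[cls]
    return best_class
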