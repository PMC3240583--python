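"""Readers and writers for the plain-text formats the pipeline exchanges.

FASTA via Biopython; BED6 and the gene-model/alt-event/conservation/octamer
tables as TSV via pandas.  Tag sets travel as a BED6 file paired with a
name-matched FASTA of tag sequences.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotate import GeneModelSet
from .kmers import ClipTag

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_tags",
    "write_tags",
    "read_gene_models",
    "write_gene_models",
    "read_conservation_mask",
    "write_conservation_mask",
    "read_octamer_table",
    "write_octamer_table",
]

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def write_tags(tags: Sequence[ClipTag], bed_path, fasta_path) -> None:
    """BED6 of tag intervals plus a name-matched FASTA of tag sequences."""
    df = pd.DataFrame(
        {
            "chrom": [t.chrom for t in tags],
            "start": [t.start for t in tags],
            "end": [t.end for t in tags],
            "name": [t.tag_id for t in tags],
            "score": 0,
            "strand": [t.strand for t in tags],
        }
    )
    df.to_csv(bed_path, sep="\t", header=False, index=False)
    write_fasta({t.tag_id: t.sequence for t in tags}, fasta_path)


def read_tags(bed_path, fasta_path) -> list[ClipTag]:
    bed = pd.read_csv(bed_path, sep="\t", header=None, names=BED6_COLUMNS)
    seqs = read_fasta(fasta_path)
    tags = []
    for row in bed.itertuples():
        try:
            seq = seqs[str(row.name)]
        except KeyError:
            raise ValueError(f"tag {row.name!r} present in BED but absent from FASTA")
        tags.append(ClipTag(row.chrom, int(row.start), int(row.end),
                            row.strand, str(row.name), seq))
    return tags


GENE_MODEL_COLUMNS = ["gene_id", "transcript_id", "feature", "chrom", "start", "end", "strand"]
ALT_EVENT_COLUMNS = ["event_class", "chrom", "start", "end", "strand"]


def write_gene_models(models: GeneModelSet, features_path, alt_events_path=None) -> None:
    """Gene-model TSV: one row per exon subfeature or ncRNA.

    Columns: gene_id, transcript_id, feature (5UTR/CDS/3UTR/ncRNA), chrom,
    start, end, strand.  Gene spans are recovered on read as the extent of
    each gene's features.  Alternative events go to a second TSV.
    """
    rows = models.exon_subfeatures[
        ["gene_id", "transcript_id", "feature", "chrom", "start", "end", "strand"]
    ].copy()
    if len(models.ncRNAs):
        nc = models.ncRNAs.rename(columns={"ncrna_id": "gene_id"}).copy()
        nc["transcript_id"] = nc["gene_id"] + ".t1"
        nc["feature"] = "ncRNA"
        rows = pd.concat([rows, nc[GENE_MODEL_COLUMNS]], ignore_index=True)
    rows.to_csv(features_path, sep="\t", index=False)
    if alt_events_path is not None:
        models.alt_events[ALT_EVENT_COLUMNS].to_csv(alt_events_path, sep="\t", index=False)


def read_gene_models(features_path, alt_events_path=None, gene_spans=None) -> GeneModelSet:
    """Rebuild a GeneModelSet from the TSV dialect of :func:`write_gene_models`.

    Gene intervals are taken as the per-gene extent of the non-ncRNA
    features unless explicit ``gene_spans`` (DataFrame with chrom, start,
    end, strand, gene_id) are given.
    """
    df = pd.read_csv(features_path, sep="\t")
    nc_rows = df[df["feature"] == "ncRNA"]
    feat_rows = df[df["feature"] != "ncRNA"]
    if gene_spans is None:
        if len(feat_rows):
            gene_spans = (
                feat_rows.groupby(["gene_id", "chrom", "strand"], as_index=False)
                .agg(start=("start", "min"), end=("end", "max"))
            )[["chrom", "start", "end", "strand", "gene_id"]]
        else:
            gene_spans = pd.DataFrame(columns=["chrom", "start", "end", "strand", "gene_id"])
    ncRNAs = nc_rows.rename(columns={"gene_id": "ncrna_id"})[
        ["chrom", "start", "end", "strand", "ncrna_id"]
    ] if len(nc_rows) else pd.DataFrame(columns=["chrom", "start", "end", "strand", "ncrna_id"])
    if alt_events_path is not None:
        alt = pd.read_csv(alt_events_path, sep="\t")
    else:
        alt = pd.DataFrame(columns=ALT_EVENT_COLUMNS)
    return GeneModelSet(
        genes=gene_spans.reset_index(drop=True),
        exon_subfeatures=feat_rows[
            ["chrom", "start", "end", "strand", "gene_id", "transcript_id", "feature"]
        ].reset_index(drop=True),
        ncRNAs=ncRNAs.reset_index(drop=True),
        alt_events=alt,
    )


def write_conservation_mask(mask: Iterable, path) -> None:
    vals = [int(bool(v)) for v in mask]
    pd.DataFrame({"position": range(len(vals)), "conserved": vals}).to_csv(
        path, sep="\t", index=False
    )


def read_conservation_mask(path):
    import numpy as np

    df = pd.read_csv(path, sep="\t").sort_values("position")
    return np.asarray(df["conserved"].to_numpy(), dtype=bool)


def write_octamer_table(scores: dict, path) -> None:
    pd.DataFrame({"octamer": list(scores), "z": list(scores.values())}).to_csv(
        path, sep="\t", index=False
    )


def read_octamer_table(path) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["octamer"], df["z"].astype(float)))
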