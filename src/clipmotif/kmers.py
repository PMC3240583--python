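"""k-mer counting and background-corrected enrichment for CLIP tags.

The core analysis: count every k-mer in the CLIP tag population and in
genome/transcriptome backgrounds, subtract the background frequency from
the CLIP frequency (per-window probability scale), rank the corrected
frequencies, classify GAA/AGA core motifs, and attach a chi-squared test
of enrichment plus the fraction of tags containing each k-mer.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2 as _chi2_dist

__all__ = [
    "ClipTag",
    "KmerTable",
    "count_kmers",
    "deduplicate_tags",
    "correct_background",
    "classify_core_motif",
    "chi_squared_enrichment",
    "tag_fraction_containing",
    "tag_fraction_all",
    "rank_recovery_curve",
    "analyze_tags",
]

_BASES = "ACGT"
# A,C,G,T -> 0..3; N -> 4; anything else -> 255 (rejected)
_ENCODE_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(_BASES):
    _ENCODE_LUT[ord(_b)] = _i
_ENCODE_LUT[ord("N")] = 4

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class ClipTag:
    """One CLIP read: a stranded genomic interval plus its (sense) sequence.

    Coordinates are 0-based half-open (BED convention).  The sequence is the
    transcribed-strand sequence, i.e. the reverse complement of the genome
    for minus-strand tags.
    """

    chrom: str
    start: int
    end: int
    strand: str
    tag_id: str
    sequence: str

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"tag {self.tag_id}: end must exceed start")
        if self.strand not in ("+", "-"):
            raise ValueError(f"tag {self.tag_id}: strand must be + or -")
        if len(self.sequence) != self.end - self.start:
            raise ValueError(
                f"tag {self.tag_id}: sequence length {len(self.sequence)} "
                f"!= interval length {self.end - self.start}"
            )
        if self.sequence != self.sequence.upper():
            raise ValueError(f"tag {self.tag_id}: sequence must be uppercase")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a nucleotide string to uint8 codes (A,C,G,T,N -> 0..4)."""
    arr = _ENCODE_LUT[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        bad = sorted({c for c in seq.upper() if c not in "ACGTN"})
        raise ValueError(f"non-nucleotide characters in sequence: {bad}")
    return arr


def window_codes(arr: np.ndarray, k: int) -> np.ndarray:
    """Integer codes of all N-free length-k windows of an encoded sequence."""
    n = len(arr) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    codes = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for j in range(k):
        b = arr[j : j + n]
        codes = codes * 4 + (b & 3)
        valid &= b != 4
    return codes[valid]


def kmer_string(index: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(_BASES[index & 3])
        index >>= 2
    return "".join(reversed(out))


def kmer_index(kmer: str) -> int:
    idx = 0
    for c in kmer:
        idx = idx * 4 + _BASES.index(c)
    return idx


def all_kmers(k: int) -> list[str]:
    return ["".join(p) for p in itertools.product(_BASES, repeat=k)]


@dataclass
class KmerTable:
    """Counts of every k-mer over a set of sequences.

    ``counts`` is a dense int64 vector of length 4**k indexed by the
    lexicographic k-mer code (A<C<G<T).  Windows containing N are skipped.
    """

    k: int
    counts: np.ndarray = field(repr=False)

    def __post_init__(self):
        if len(self.counts) != 4**self.k:
            raise ValueError("counts vector must have length 4**k")

    @property
    def total_windows(self) -> int:
        return int(self.counts.sum())

    def frequencies(self) -> np.ndarray:
        total = self.total_windows
        if total == 0:
            raise ValueError("empty k-mer table has no frequencies")
        return self.counts / total

    def as_dict(self, nonzero_only: bool = True) -> dict[str, int]:
        items = {}
        for idx in np.nonzero(self.counts)[0] if nonzero_only else range(4**self.k):
            items[kmer_string(int(idx), self.k)] = int(self.counts[idx])
        return items

    def __getitem__(self, kmer: str) -> int:
        return int(self.counts[kmer_index(kmer)])


def count_kmers(sequences: Iterable[str], k: int) -> KmerTable:
    """Count every N-free length-k window across ``sequences``.

    Sequences shorter than k contribute no windows; that is not an error.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    counts = np.zeros(4**k, dtype=np.int64)
    for seq in sequences:
        codes = window_codes(encode_sequence(seq), k)
        if len(codes):
            counts += np.bincount(codes, minlength=4**k)
    return KmerTable(k=k, counts=counts)


def deduplicate_tags(tags: Sequence[ClipTag]) -> list[ClipTag]:
    """Remove duplicate and overlapping reads.

    Tags are sorted by (chrom, strand, start, end); within each
    (chrom, strand) group a greedy left-to-right scan keeps a tag only if it
    does not overlap the previously kept tag.  Exact duplicates fall out of
    the same rule.  Opposite strands never collide.
    """
    kept: list[ClipTag] = []
    ordered = sorted(tags, key=lambda t: (t.chrom, t.strand, t.start, t.end))
    last_key = None
    last_end = -1
    for tag in ordered:
        key = (tag.chrom, tag.strand)
        if key != last_key:
            last_key = key
            last_end = -1
        if tag.start >= last_end:
            kept.append(tag)
            last_end = tag.end
    return kept


def classify_core_motif(kmer: str) -> str:
    """GAA if the k-mer contains GAA, else AGA if it contains AGA, else other."""
    if "GAA" in kmer:
        return "GAA"
    if "AGA" in kmer:
        return "AGA"
    return "other"


class Chi2Result(NamedTuple):
    statistic: float
    pvalue: float
    low_expected: bool


def chi_squared_enrichment(
    clip_count, clip_total, background_count, background_total
):
    """Pearson chi-squared on the 2x2 table (k-mer vs other) x (CLIP vs background).

    Accepts scalars or numpy arrays (vectorized over k-mers).  One degree of
    freedom; p from the chi-squared survival function.  If any expected cell
    is below 1 the result carries ``low_expected=True`` but is still returned.
    """
    a = np.asarray(clip_count, dtype=float)
    b = np.asarray(clip_total, dtype=float) - a
    c = np.asarray(background_count, dtype=float)
    d = np.asarray(background_total, dtype=float) - c
    if np.any(np.asarray(clip_total) <= 0) or np.any(np.asarray(background_total) <= 0):
        raise ValueError("totals must be positive")
    if np.any(a < 0) or np.any(b < 0) or np.any(c < 0) or np.any(d < 0):
        raise ValueError("counts must be between 0 and their totals")
    n = a + b + c + d
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    stat = np.where((c1 == 0) | (c2 == 0), 0.0, stat)
    p = _chi2_dist.sf(stat, df=1)
    expected_min = np.minimum.reduce(
        [r1 * c1 / n, r1 * c2 / n, r2 * c1 / n, r2 * c2 / n]
    )
    low = expected_min < 1
    if stat.ndim == 0:
        return Chi2Result(float(stat), float(p), bool(low))
    return Chi2Result(stat, p, low)


def _descending_rank(values: np.ndarray) -> np.ndarray:
    """Ranks 1..len(values), descending by value, ties broken by index
    (lexicographic k-mer order, since the vector is code-indexed)."""
    order = np.argsort(-values, kind="stable")
    ranks = np.empty(len(values), dtype=np.int64)
    ranks[order] = np.arange(1, len(values) + 1)
    return ranks


def correct_background(
    clip: KmerTable, genome: KmerTable, transcriptome: KmerTable
) -> pd.DataFrame:
    """Background-corrected enrichment table, one row per k-mer (all 4**k).

    Corrected values are signed frequency differences
    (CLIP frequency minus background frequency).  Ranks are assigned
    descending by raw CLIP frequency, genome-corrected and
    transcriptome-corrected frequency; ties break lexicographically.
    A ratio column (CLIP/genome frequency) is included for reference but is
    never used for the headline ranking.  The chi-squared columns test each
    k-mer's CLIP count against the genome background.  ``tag_fraction`` is
    left NaN here (this function never sees the tags); ``analyze_tags``
    fills it.
    """
    if not (clip.k == genome.k == transcriptome.k):
        raise ValueError("all tables must share k")
    k = clip.k
    f_clip = clip.frequencies()
    f_gen = genome.frequencies()
    f_tx = transcriptome.frequencies()
    corrected_genome = f_clip - f_gen
    corrected_tx = f_clip - f_tx
    chi2_res = chi_squared_enrichment(
        clip.counts, clip.total_windows, genome.counts, genome.total_windows
    )
    kmers = all_kmers(k)
    df = pd.DataFrame(
        {
            "kmer": kmers,
            "freq_clip": f_clip,
            "freq_genome": f_gen,
            "freq_transcriptome": f_tx,
            "corrected_genome": corrected_genome,
            "corrected_transcriptome": corrected_tx,
            "ratio_genome": np.where(f_gen > 0, f_clip / np.where(f_gen > 0, f_gen, 1), np.inf),
            "rank_raw": _descending_rank(f_clip),
            "rank_corrected": _descending_rank(corrected_genome),
            "rank_corrected_transcriptome": _descending_rank(corrected_tx),
            "core_class": [classify_core_motif(m) for m in kmers],
            "chi2_stat": chi2_res.statistic,
            "chi2_p": chi2_res.pvalue,
            "chi2_low_expected": chi2_res.low_expected,
            "tag_fraction": np.nan,
        }
    )
    return df


def tag_fraction_containing(tags: Sequence[ClipTag], kmer_set: Iterable[str]) -> float:
    """Fraction of tags whose sequence contains at least one k-mer of the set."""
    kmer_set = list(kmer_set)
    if not tags:
        raise ValueError("empty tag set")
    if not kmer_set:
        return 0.0
    hits = sum(1 for t in tags if any(m in t.sequence for m in kmer_set))
    return hits / len(tags)


def tag_fraction_all(tags: Sequence[ClipTag], k: int) -> np.ndarray:
    """Per-k-mer fraction of tags containing it, for all 4**k k-mers at once.

    Equivalent to calling :func:`tag_fraction_containing` with each singleton
    set, but vectorized: unique (tag, window-code) pairs are counted with one
    bincount.
    """
    if not tags:
        raise ValueError("empty tag set")
    pair_keys = []
    for i, tag in enumerate(tags):
        codes = window_codes(encode_sequence(tag.sequence), k)
        if len(codes):
            pair_keys.append(codes + np.int64(i) * 4**k)
    if not pair_keys:
        return np.zeros(4**k)
    uniq = np.unique(np.concatenate(pair_keys))
    counts = np.bincount(uniq % (4**k), minlength=4**k)
    return counts / len(tags)


def rank_recovery_curve(records: pd.DataFrame, rank_column: str = "rank_corrected") -> pd.DataFrame:
    """(rank, tag_fraction) pairs per k-mer, ordered by rank.

    Carries the GAA-core flag for plotting (GAA-containing k-mers are the
    red series in the canonical plot).  Tag fractions are taken from the
    records; they need not be monotone in rank.
    """
    out = records.loc[:, ["kmer", rank_column, "tag_fraction", "core_class"]].copy()
    out = out.rename(columns={rank_column: "rank"})
    out["is_gaa"] = out["core_class"] == "GAA"
    return out.sort_values("rank").reset_index(drop=True)


def analyze_tags(
    tags: Sequence[ClipTag],
    genome_sequences: Iterable[str],
    transcriptome_sequences: Iterable[str],
    k: int = 6,
    dedupe: bool = True,
) -> pd.DataFrame:
    """Full enrichment pipeline: dedupe, count, correct, test, tag fractions.

    The genome background counts both strands (the genome is unstranded);
    the transcriptome background counts the sense strand only, because tags
    are sense transcript sequences.
    """
    if dedupe:
        tags = deduplicate_tags(tags)
    clip = count_kmers((t.sequence for t in tags), k)
    genome_seqs = list(genome_sequences)
    genome = count_kmers(
        itertools.chain(genome_seqs, (reverse_complement(s) for s in genome_seqs)), k
    )
    transcriptome = count_kmers(transcriptome_sequences, k)
    df = correct_background(clip, genome, transcriptome)
    df["tag_fraction"] = tag_fraction_all(tags, k)
    return df
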