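"""GAA-anchored consensus building.

Tags are anchored on a GAA core (preferring the strongest context available
in each tag: AGAAGA, then AGAA, then bare GAA, leftmost within each class),
stacked into a position frequency matrix relative to the anchor, and
summarized as an IUPAC consensus string.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .kmers import ClipTag

__all__ = ["AnchoredPFM", "anchor_tags", "build_pfm", "gaag_context_stat"]

_BASES = "ACGT"

# IUPAC codes for base sets (used for consensus ties)
_IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("GC"): "S", frozenset("AT"): "W",
    frozenset("GT"): "K", frozenset("AC"): "M",
    frozenset("CGT"): "B", frozenset("AGT"): "D", frozenset("ACT"): "H", frozenset("ACG"): "V",
    frozenset("ACGT"): "N",
}

# anchor priority: (pattern, offset of the GAA triplet within the pattern)
_ANCHOR_PATTERNS = (("AGAAGA", 1), ("AGAA", 1), ("GAA", 0))


@dataclass
class AnchoredPFM:
    """Position frequency matrix of tags aligned on their GAA anchor.

    Column 0 is the first base of the GAA triplet; offsets run from
    ``window[0]`` to ``window[1]`` inclusive.  Frequencies are normalized
    per column by the number of tags actually covering that column.
    """

    offsets: np.ndarray
    counts: pd.DataFrame   # rows A,C,G,T x columns offsets
    freqs: pd.DataFrame
    consensus: str
    n_tags_used: int
    n_tags_excluded: int

    def consensus_slice(self, start_offset: int, end_offset: int) -> str:
        """Consensus over offset columns start..end inclusive."""
        offs = list(self.offsets)
        return "".join(
            self.consensus[offs.index(o)] for o in range(start_offset, end_offset + 1)
        )


def _choose_anchor(sequence: str) -> Optional[int]:
    for pattern, gaa_offset in _ANCHOR_PATTERNS:
        i = sequence.find(pattern)
        if i != -1:
            return i + gaa_offset
    return None


def anchor_tags(tags: Sequence[ClipTag]) -> tuple[list[tuple[ClipTag, int]], int]:
    """Anchor each tag at the first base of its chosen GAA triplet.

    Priority: leftmost AGAAGA match, else leftmost AGAA, else leftmost GAA.
    Returns (anchored pairs, number of tags excluded for lacking GAA).
    """
    anchored, excluded = [], 0
    for tag in tags:
        a = _choose_anchor(tag.sequence)
        if a is None:
            excluded += 1
        else:
            anchored.append((tag, a))
    return anchored, excluded


def build_pfm(
    anchored: Sequence[tuple[ClipTag, int]],
    window: tuple[int, int] = (-5, 7),
    n_excluded: int = 0,
) -> AnchoredPFM:
    """Stack anchored tags into a PFM over offset columns window[0]..window[1].

    Columns a tag does not cover (anchor too close to a sequence end) simply
    do not contribute; each column is normalized by its own coverage.
    Consensus per column is the argmax base, with exact ties rendered as the
    IUPAC ambiguity code and zero-coverage columns as N.
    """
    if not anchored:
        raise ValueError("no anchored tags to build a PFM from")
    lo, hi = window
    offsets = np.arange(lo, hi + 1)
    counts = np.zeros((4, len(offsets)), dtype=np.int64)
    for tag, a in anchored:
        seq = tag.sequence
        for ci, off in enumerate(offsets):
            pos = a + off
            if 0 <= pos < len(seq):
                b = _BASES.find(seq[pos])
                if b >= 0:
                    counts[b, ci] += 1
    coverage = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = np.where(coverage > 0, counts / np.where(coverage > 0, coverage, 1), 0.0)
    consensus = []
    for ci in range(len(offsets)):
        if coverage[ci] == 0:
            consensus.append("N")
            continue
        col = counts[:, ci]
        best = col.max()
        tied = frozenset(_BASES[i] for i in range(4) if col[i] == best)
        consensus.append(_IUPAC[tied])
    cols = [int(o) for o in offsets]
    return AnchoredPFM(
        offsets=offsets,
        counts=pd.DataFrame(counts, index=list(_BASES), columns=cols),
        freqs=pd.DataFrame(freqs, index=list(_BASES), columns=cols),
        consensus="".join(consensus),
        n_tags_used=len(anchored),
        n_tags_excluded=n_excluded,
    )


def consensus_from_tags(
    tags: Sequence[ClipTag], window: tuple[int, int] = (-5, 7)
) -> AnchoredPFM:
    """Anchor + PFM in one call."""
    anchored, excluded = anchor_tags(tags)
    return build_pfm(anchored, window=window, n_excluded=excluded)


def gaag_context_stat(tags: Sequence[ClipTag]) -> Optional[float]:
    """Fraction of GAA-only tags whose anchor is immediately followed by G.

    Considers tags containing GAA but no AGAA anywhere; the anchor is the
    leftmost GAA (the priority rule reduces to that here).  An anchor at the
    very end of the sequence counts as not followed by G.  Returns None when
    no tag qualifies.
    """
    n_qual = n_g = 0
    for tag in tags:
        seq = tag.sequence
        if "AGAA" in seq or "GAA" not in seq:
            continue
        a = seq.find("GAA")
        n_qual += 1
        if a + 3 < len(seq) and seq[a + 3] == "G":
            n_g += 1
    if n_qual == 0:
        return None
    return n_g / n_qual
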