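"""Conservation-position enrichment of predicted binding sites.

Tests whether positions of an exon covered by matches of a top k-mer set
are preferentially conserved: per-nucleotide 2x2 cross-tabulation of
(covered x conserved) with self-implemented Fisher exact and chi-squared
tests.  Per-nucleotide counting is the default (each position is one
trial); per-match-site counting is exposed as an option.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy.special import gammaln
from scipy.stats import chi2 as _chi2_dist

__all__ = [
    "ContingencyTable2x2",
    "kmer_coverage_mask",
    "build_contingency",
    "fisher_exact",
    "chi2_2x2",
    "conserved_fraction",
    "conservation_enrichment",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Rows: position covered / not covered; columns: conserved / not."""

    a: int  # covered & conserved
    b: int  # covered & not conserved
    c: int  # not covered & conserved
    d: int  # not covered & not conserved

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be nonnegative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def odds_ratio(self) -> float:
        if self.b * self.c == 0:
            return float("inf") if self.a * self.d > 0 else float("nan")
        return (self.a * self.d) / (self.b * self.c)

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


def kmer_coverage_mask(sequence: str, kmer_set: Iterable[str]) -> np.ndarray:
    """Boolean mask: position i is True iff it lies inside any match window.

    All k-mers must share one length; overlapping matches union.
    """
    kmer_set = list(kmer_set)
    n = len(sequence)
    mask = np.zeros(n, dtype=bool)
    if not kmer_set:
        return mask
    ks = {len(m) for m in kmer_set}
    if len(ks) != 1:
        raise ValueError("k-mers must share one length")
    k = ks.pop()
    seq = sequence.upper()
    for m in kmer_set:
        i = seq.find(m)
        while i != -1:
            mask[i : i + k] = True
            i = seq.find(m, i + 1)
    return mask


def build_contingency(coverage_mask, conservation_mask) -> ContingencyTable2x2:
    """Per-nucleotide cross-tabulation of covered x conserved."""
    cov = np.asarray(coverage_mask, dtype=bool)
    con = np.asarray(conservation_mask, dtype=bool)
    if cov.shape != con.shape:
        raise ValueError("masks must have equal length")
    return ContingencyTable2x2(
        a=int(np.sum(cov & con)),
        b=int(np.sum(cov & ~con)),
        c=int(np.sum(~cov & con)),
        d=int(np.sum(~cov & ~con)),
    )


def _log_hypergeom_pmf(avals, r1, r2, c1, n):
    """log P(A = a) under the hypergeometric with fixed margins."""
    return (
        gammaln(r1 + 1) - gammaln(avals + 1) - gammaln(r1 - avals + 1)
        + gammaln(r2 + 1) - gammaln(c1 - avals + 1) - gammaln(r2 - (c1 - avals) + 1)
        - (gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1))
    )


def fisher_exact(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p-value.

    Standard two-sided convention: the sum of hypergeometric point
    probabilities (over all tables with the observed margins) that do not
    exceed the observed table's point probability.  Computed in log space so
    large margins are safe.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, r2 = a + b, c + d
    c1 = a + c
    n = table.total
    if n == 0:
        return 1.0
    amin = max(0, c1 - r2)
    amax = min(r1, c1)
    avals = np.arange(amin, amax + 1)
    logp = _log_hypergeom_pmf(avals.astype(float), r1, r2, c1, n)
    log_obs = logp[a - amin]
    # relative tolerance absorbs floating error in "<= observed probability"
    include = logp <= log_obs + 1e-7
    p = float(np.exp(logp[include]).sum())
    return min(p, 1.0)


def chi2_2x2(table: ContingencyTable2x2, continuity_correction: bool = False):
    """Pearson chi-squared (optionally Yates-corrected) on a 2x2 table, df=1."""
    a, b, c, d = (float(x) for x in (table.a, table.b, table.c, table.d))
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("chi-squared undefined: a margin is zero")
    diff = abs(a * d - b * c)
    if continuity_correction:
        diff = max(0.0, diff - n / 2)
    stat = n * diff**2 / (r1 * r2 * c1 * c2)
    p = float(_chi2_dist.sf(stat, df=1))
    return float(stat), p


def conserved_fraction(mask) -> float:
    """Mean of a boolean conservation mask."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        raise ValueError("empty conservation mask")
    return float(mask.mean())


def conservation_enrichment(
    sequence: str,
    kmer_set: Iterable[str],
    conservation_mask,
    continuity_correction: bool = False,
) -> dict:
    """End-to-end: coverage mask -> contingency -> both tests.

    Returns a dict with the table, odds ratio, Fisher and chi-squared
    p-values, and the exon's conserved fraction.
    """
    cov = kmer_coverage_mask(sequence, kmer_set)
    table = build_contingency(cov, conservation_mask)
    stat, chi_p = chi2_2x2(table, continuity_correction=continuity_correction)
    return {
        "table": table,
        "odds_ratio": table.odds_ratio(),
        "fisher_p": fisher_exact(table),
        "chi2_stat": stat,
        "chi2_p": chi_p,
        "conserved_fraction": conserved_fraction(conservation_mask),
        "covered_fraction": float(cov.mean()) if len(cov) else 0.0,
    }
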