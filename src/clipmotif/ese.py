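"""Exonic splicing enhancer/silencer scanning and mutation design.

An exon is scanned with a table of octamer z-scores (positive scores
predict enhancers, negative scores silencers); maximal runs of windows
beyond the thresholds are called as ESE/ESS regions; and single-base
substitutions are searched exhaustively for mutations that abolish an ESE
without creating an ESS anywhere nearby.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

__all__ = [
    "OctamerScoreTable",
    "ZScoreProfile",
    "RegionCall",
    "MutationPlan",
    "zscore_profile",
    "call_regions",
    "design_disrupting_mutation",
    "apply_mutation",
]

logger = logging.getLogger(__name__)

K = 8  # octamer window


@dataclass
class OctamerScoreTable:
    """Octamer -> splicing-regulatory z-score, with call thresholds.

    Octamers absent from the table score 0 (neutral) by default; with
    ``missing_is_error`` an unknown octamer raises instead.  The default
    thresholds treat z >= 4 as enhancer territory (z around 4 is a moderate
    ESE) and z <= -4 as silencer territory.
    """

    scores: Mapping[str, float]
    ese_threshold: float = 4.0
    ess_threshold: float = -4.0
    missing_is_error: bool = False

    def __post_init__(self):
        if not (self.ese_threshold > 0 > self.ess_threshold):
            raise ValueError("need ese_threshold > 0 > ess_threshold")
        for octamer in self.scores:
            if len(octamer) != K or set(octamer) - set("ACGT"):
                raise ValueError(f"bad octamer key {octamer!r}")

    def score(self, octamer: str) -> float:
        try:
            return float(self.scores[octamer])
        except KeyError:
            if self.missing_is_error:
                raise
            return 0.0


@dataclass(frozen=True)
class RegionCall:
    kind: str  # "ESE" or "ESS"
    start: int  # sequence coordinates, half-open; union of window extents
    end: int
    peak: float  # max (ESE) / min (ESS) window score in the run


@dataclass
class ZScoreProfile:
    sequence: str
    values: np.ndarray  # one score per window start, length len(sequence)-7
    n_unknown: int = 0
    calls: list = field(default_factory=list)


def zscore_profile(sequence: str, table: OctamerScoreTable) -> ZScoreProfile:
    """Sliding step-1 octamer score lookup over the sequence."""
    seq = sequence.upper()
    if len(seq) < K:
        raise ValueError(f"sequence shorter than {K} nt")
    n = len(seq) - K + 1
    values = np.empty(n)
    n_unknown = 0
    for i in range(n):
        octamer = seq[i : i + K]
        if octamer not in table.scores:
            n_unknown += 1
        values[i] = table.score(octamer)
    if n_unknown:
        logger.info("%d/%d octamer windows absent from score table (scored 0)",
                    n_unknown, n)
    return ZScoreProfile(sequence=seq, values=values, n_unknown=n_unknown)


def _runs(flags: np.ndarray):
    """(start, end) half-open index runs of consecutive True."""
    out = []
    i = 0
    n = len(flags)
    while i < n:
        if flags[i]:
            j = i
            while j < n and flags[j]:
                j += 1
            out.append((i, j))
            i = j
        else:
            i += 1
    return out


def call_regions(profile: ZScoreProfile, table: OctamerScoreTable) -> list[RegionCall]:
    """Merge threshold-crossing window runs into ESE/ESS intervals.

    Each maximal run of consecutive windows with score >= ese_threshold
    becomes one ESE whose extent is the union of its windows; symmetric for
    ESS at <= ess_threshold.  Calls are stored on the profile and returned
    sorted by start.
    """
    calls = []
    for i, j in _runs(profile.values >= table.ese_threshold):
        calls.append(RegionCall("ESE", i, (j - 1) + K, float(profile.values[i:j].max())))
    for i, j in _runs(profile.values <= table.ess_threshold):
        calls.append(RegionCall("ESS", i, (j - 1) + K, float(profile.values[i:j].min())))
    calls.sort(key=lambda c: (c.start, c.kind))
    profile.calls = calls
    return calls


def apply_mutation(sequence: str, position: int, alt_base: str) -> str:
    return sequence[:position] + alt_base + sequence[position + 1 :]


@dataclass
class MutationPlan:
    """One candidate single-base substitution disrupting an ESE.

    ``before``/``after`` hold the scores of the (at most 8) windows that
    contain the mutated position, keyed by window start.  A plan is valid
    iff every window of the target ESE scores below the ESE threshold after
    mutation AND no affected window drops below the ESS threshold.
    """

    position: int
    ref_base: str
    alt_base: str
    before: dict
    after: dict
    ese_peak_after: float
    valid: bool


def design_disrupting_mutation(
    sequence: str,
    ese_interval: RegionCall,
    table: OctamerScoreTable,
    valid_only: bool = False,
) -> list[MutationPlan]:
    """Exhaustively search single-base substitutions within an ESE.

    For every position in the called ESE interval and every alternative
    base, the affected windows (exactly those containing the position) are
    rescored.  A plan is valid iff all windows of the target ESE fall below
    the ESE threshold and no affected window falls below the ESS threshold.
    Plans are returned sorted by post-mutation ESE peak score ascending;
    with ``valid_only`` only valid plans are returned.
    """
    seq = sequence.upper()
    n_windows = len(seq) - K + 1
    ese_windows = range(ese_interval.start, ese_interval.end - K + 1)
    plans = []
    for pos in range(ese_interval.start, ese_interval.end):
        ref = seq[pos]
        affected = [w for w in range(max(0, pos - K + 1), min(n_windows, pos + 1))]
        before = {w: table.score(seq[w : w + K]) for w in affected}
        for alt in "ACGT":
            if alt == ref:
                continue
            mutated = apply_mutation(seq, pos, alt)
            after = {w: table.score(mutated[w : w + K]) for w in affected}
            ese_after = [
                after[w] if w in after else table.score(mutated[w : w + K])
                for w in ese_windows
            ]
            peak = max(ese_after) if ese_after else float("-inf")
            valid = all(v < table.ese_threshold for v in ese_after) and all(
                v > table.ess_threshold for v in after.values()
            )
            plans.append(
                MutationPlan(
                    position=pos,
                    ref_base=ref,
                    alt_base=alt,
                    before=before,
                    after=after,
                    ese_peak_after=peak,
                    valid=valid,
                )
            )
    if valid_only:
        plans = [p for p in plans if p.valid]
    plans.sort(key=lambda p: (p.ese_peak_after, p.position, p.alt_base))
    return plans
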