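"""Splice-isoform quantification: PSI, group comparison, qPCR standard
curves, and sequencing/mapping report summaries."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as _stats

__all__ = [
    "IsoformIntensities",
    "StandardCurve",
    "MappingReport",
    "compute_psi",
    "compare_psi",
    "fit_standard_curve",
    "normalize_to_reference",
    "mapping_report",
]


@dataclass(frozen=True)
class IsoformIntensities:
    """Band intensities of the inclusion and skip RT-PCR products.

    Lengths are the product sizes in bp; intensities are arbitrary units.
    """

    inclusion_intensity: float
    skip_intensity: float
    inclusion_length: int
    skip_length: int

    def __post_init__(self):
        if self.inclusion_intensity < 0 or self.skip_intensity < 0:
            raise ValueError("intensities must be nonnegative")
        if self.inclusion_intensity == 0 and self.skip_intensity == 0:
            raise ValueError("both isoform intensities are zero: PSI undefined")
        if self.inclusion_length <= 0 or self.skip_length <= 0:
            raise ValueError("product lengths must be positive")


def compute_psi(data: IsoformIntensities, molar_correction: bool = True) -> float:
    """Percent spliced in.

    With molar correction (default) intensities are divided by product
    length before taking the ratio, because longer products bind more dye:
    PSI = 100 * (I_inc/L_inc) / (I_inc/L_inc + I_skip/L_skip).  Without it
    the raw intensity ratio is used.
    """
    if molar_correction:
        inc = data.inclusion_intensity / data.inclusion_length
        skip = data.skip_intensity / data.skip_length
    else:
        inc, skip = data.inclusion_intensity, data.skip_intensity
    return 100.0 * inc / (inc + skip)


def compare_psi(group_a: Sequence[float], group_b: Sequence[float]):
    """Independent two-sample t-test between PSI replicate groups.

    Welch's unequal-variance variant, two-sided.  Identical groups (zero
    pooled variance, zero mean difference) return (0, 1) rather than NaN.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 replicates")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float("inf") * np.sign(a.mean() - b.mean()), 0.0
    t, p = _stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


@dataclass(frozen=True)
class StandardCurve:
    """Linear fit of Ct versus log10(concentration) for qPCR quantification."""

    slope: float
    intercept: float
    r_squared: float

    @property
    def efficiency(self) -> float:
        """Per-cycle amplification factor, 10**(-1/slope); 2 is perfect doubling."""
        return 10.0 ** (-1.0 / self.slope)

    def quantify(self, ct: float) -> float:
        """Invert the curve: concentration of an unknown from its Ct."""
        return 10.0 ** ((ct - self.intercept) / self.slope)


def fit_standard_curve(concentrations: Sequence[float], ct_values: Sequence[float]) -> StandardCurve:
    """Ordinary least squares of Ct on log10(concentration)."""
    conc = np.asarray(concentrations, dtype=float)
    ct = np.asarray(ct_values, dtype=float)
    if len(conc) < 3 or len(conc) != len(ct):
        raise ValueError("need >= 3 matched dilution points")
    if (conc <= 0).any():
        raise ValueError("concentrations must be positive")
    x = np.log10(conc)
    if np.allclose(x, x[0]):
        raise ValueError("degenerate dilution series: all concentrations equal")
    res = _stats.linregress(x, ct)
    return StandardCurve(slope=float(res.slope), intercept=float(res.intercept),
                         r_squared=float(res.rvalue**2))


def normalize_to_reference(target_quantity, reference_quantity) -> float:
    """Target/reference quantity ratio (e.g. normalization to Gapdh).

    Scalars or replicate sequences are accepted; duplicate measurements are
    averaged by arithmetic mean before the ratio is taken.
    """
    t = float(np.mean(np.asarray(target_quantity, dtype=float)))
    r = float(np.mean(np.asarray(reference_quantity, dtype=float)))
    if r <= 0:
        raise ValueError("reference quantity must be positive")
    return t / r


@dataclass(frozen=True)
class MappingReport:
    """Read-mapping summary: aligned / failed / multi-hit-suppressed counts
    with percentages rounded to 2 decimals as rendered in reports."""

    processed: int
    aligned: int
    failed: int
    suppressed: int
    pct_aligned: float
    pct_failed: float
    pct_suppressed: float

    def render(self) -> str:
        return (
            f"{self.processed} reads processed; "
            f"{self.aligned} ({self.pct_aligned:.2f}%) aligned; "
            f"{self.failed} ({self.pct_failed:.2f}%) failed to align; "
            f"{self.suppressed} ({self.pct_suppressed:.2f}%) suppressed (multiple hits)"
        )


def mapping_report(processed: int, aligned: int, failed: int, suppressed: int) -> MappingReport:
    if min(processed, aligned, failed, suppressed) < 0:
        raise ValueError("counts must be nonnegative")
    if aligned + failed + suppressed != processed:
        raise ValueError(
            f"aligned+failed+suppressed = {aligned + failed + suppressed} "
            f"!= processed = {processed}"
        )
    if processed == 0:
        raise ValueError("no reads processed")
    return MappingReport(
        processed=processed,
        aligned=aligned,
        failed=failed,
        suppressed=suppressed,
        pct_aligned=round(100.0 * aligned / processed, 2),
        pct_failed=round(100.0 * failed / processed, 2),
        pct_suppressed=round(100.0 * suppressed / processed, 2),
    )
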