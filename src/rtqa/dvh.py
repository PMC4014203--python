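"""Dose-volume histograms, homogeneity/conformity indices, and deviation
statistics between a reconstructed delivery and the treatment plan.

DVHs are exact voxel-list (unbinned) cumulative histograms.  Dose-at-volume
queries (Dx%) interpolate linearly between order statistics: the i-th hottest
voxel (i = 1..n) is placed at cumulative fraction (i - 0.5)/n and the dose is
interpolated between neighbouring voxels, clamping to the extreme voxel doses
at the ends.  Volume-at-dose queries (Vd) are exact counting fractions with an
inclusive boundary ('received at least dose d').

Homogeneity index: HI = (D2% - D98%) / D50% (0 for a perfectly uniform dose).
Conformity index:  CI = (PTV95%/PTV) x (PTV95%/V95%), i.e. coverage x
selectivity, where PTV95% is the target sub-volume receiving >= 95% of the
prescription and V95% the total evaluated volume receiving >= 95%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import DoseGrid, Prescription

__all__ = [
    "DVHCurve",
    "MetricSet",
    "DeviationSummary",
    "cumulative_dvh",
    "dose_at_volume",
    "volume_at_dose",
    "compute_metrics",
    "homogeneity_index",
    "conformity_index",
    "relative_deviation",
    "deviation_summary",
]


@dataclass
class DVHCurve:
    """Exact cumulative DVH of one structure.

    ``doses`` holds every voxel dose (cGy) sorted descending; all voxels share
    one volume weight.  The cumulative curve V(d) = fraction of the structure
    receiving >= d is monotone non-increasing, 1 at d = 0 and 0 above the
    maximum voxel dose.
    """

    structure: str
    doses: np.ndarray           # sorted descending, cGy
    voxel_volume_cc: float

    @property
    def n(self) -> int:
        return len(self.doses)

    @property
    def total_volume_cc(self) -> float:
        return self.n * self.voxel_volume_cc

    @property
    def mean_dose(self) -> float:
        return float(np.mean(self.doses))

    def volume_fraction(self, dose: np.ndarray | float) -> np.ndarray | float:
        """V(d): exact counting fraction receiving >= d (inclusive)."""
        d = np.asarray(dose, dtype=float)
        asc = self.doses[::-1]
        frac = 1.0 - np.searchsorted(asc, d, side="left") / self.n
        return float(frac) if np.isscalar(dose) else frac


@dataclass
class MetricSet:
    """Point DVH metrics of one structure (doses cGy, volumes fractional)."""

    structure: str
    d2: float
    d50: float
    d95: float
    d98: float
    dmean: float
    v100: float | None = None
    v95: float | None = None
    hi: float | None = None
    ci: float | None = None


@dataclass
class DeviationSummary:
    """Plan-vs-reconstruction deviations over a case batch, with a one-sample
    t-test of mean zero (two-sided)."""

    deviations: np.ndarray
    minimum: float
    maximum: float
    mean: float
    std: float
    t: float
    df: int
    p: float
    degenerate: bool = False


def cumulative_dvh(dose: DoseGrid, mask: np.ndarray, structure: str = "") -> DVHCurve:
    """Exact voxel-list cumulative DVH of ``dose`` within ``mask``."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != dose.shape:
        raise ValueError("mask shape does not match dose grid")
    vals = dose.values[mask]
    if vals.size == 0:
        raise ValueError(f"structure {structure!r} has an empty mask")
    return DVHCurve(structure, np.sort(vals)[::-1], dose.voxel_volume_cc)


def dose_at_volume(curve: DVHCurve, v: float) -> float:
    """Dose covering the hottest fraction ``v`` of the structure (Dv).

    Linear interpolation between order statistics: the i-th hottest voxel sits
    at cumulative fraction (i - 0.5)/n.  v = 1 returns the minimum voxel dose.
    """
    if not (0.0 < v <= 1.0):
        raise ValueError(f"v must be in (0, 1], got {v}")
    n = curve.n
    # fractional order-statistic index; doses[0] is the hottest voxel
    i = v * n + 0.5
    if i <= 1.0:
        return float(curve.doses[0])
    if i >= n:
        return float(curve.doses[-1])
    k = int(np.floor(i))
    w = i - k
    return float((1.0 - w) * curve.doses[k - 1] + w * curve.doses[k])


def volume_at_dose(curve: DVHCurve, d: float, *, percent: bool = False,
                   prescription: float | None = None) -> float:
    """Fraction of the structure receiving at least dose ``d`` (Vd).

    With ``percent=True`` the dose is a percentage of ``prescription``
    (e.g. V95% = volume_at_dose(curve, 95, percent=True, prescription=Rx)).
    """
    if percent:
        if prescription is None:
            raise ValueError("percent dose queries require a prescription dose")
        d = d / 100.0 * prescription
    if d < 0:
        raise ValueError("dose must be >= 0")
    return float(curve.volume_fraction(d))


def homogeneity_index(metrics: MetricSet) -> float:
    """HI = (D2% - D98%) / D50%; 0 means a perfectly uniform target dose."""
    if metrics.d50 <= 0:
        raise ValueError("D50% must be > 0 to form the homogeneity index")
    return (metrics.d2 - metrics.d98) / metrics.d50


def conformity_index(dose: DoseGrid, ptv_mask: np.ndarray,
                     prescription: float,
                     eval_mask: np.ndarray | None = None) -> float:
    """CI = (PTV95%/PTV) x (PTV95%/V95%), coverage times selectivity.

    ``eval_mask`` restricts the V95% volume (e.g. to the body contour); by
    default the whole grid is evaluated.  If no voxel anywhere reaches 95% of
    the prescription, CI is defined as 0 with a warning.
    """
    ptv_mask = np.asarray(ptv_mask, dtype=bool)
    if not ptv_mask.any():
        raise ValueError("PTV mask is empty")
    if prescription <= 0:
        raise ValueError("prescription must be > 0")
    level = 0.95 * prescription
    hot = dose.values >= level
    if eval_mask is not None:
        hot = hot & np.asarray(eval_mask, dtype=bool)
    ptv95 = float(np.sum(hot & ptv_mask))
    v95 = float(np.sum(hot))
    ptv = float(np.sum(ptv_mask))
    if v95 == 0:
        warnings.warn("no voxel reaches 95% of the prescription; CI set to 0",
                      stacklevel=2)
        return 0.0
    return (ptv95 / ptv) * (ptv95 / v95)


def compute_metrics(dose: DoseGrid, mask: np.ndarray, structure: str,
                    prescription: Prescription | None = None,
                    eval_mask: np.ndarray | None = None,
                    *, target: bool = False) -> MetricSet:
    """All point metrics of one structure; HI/CI only for targets with a
    prescription entry."""
    curve = cumulative_dvh(dose, mask, structure)
    ms = MetricSet(
        structure=structure,
        d2=dose_at_volume(curve, 0.02),
        d50=dose_at_volume(curve, 0.50),
        d95=dose_at_volume(curve, 0.95),
        d98=dose_at_volume(curve, 0.98),
        dmean=curve.mean_dose,
    )
    if prescription is not None and structure in prescription.doses:
        rx = prescription[structure]
        ms.v100 = volume_at_dose(curve, 100, percent=True, prescription=rx)
        ms.v95 = volume_at_dose(curve, 95, percent=True, prescription=rx)
        if target:
            ms.hi = homogeneity_index(ms)
            ms.ci = conformity_index(dose, mask, rx, eval_mask)
    return ms


def relative_deviation(reconstructed: float, planned: float) -> float:
    """Percent deviation of the reconstruction from the plan,
    100 x (reconstructed - planned) / planned."""
    if planned == 0:
        raise ValueError("planned value is zero; relative deviation undefined")
    return 100.0 * (reconstructed - planned) / planned


def deviation_summary(deviations) -> DeviationSummary:
    """Range, mean +/- sample std, and a two-sided one-sample t-test of mean
    zero over per-case percent deviations.

    Zero-variance samples: p = 1 exactly when the mean is also 0; otherwise t
    is undefined and the summary is flagged degenerate (p = NaN) with a
    warning.
    """
    dev = np.asarray(list(deviations), dtype=float)
    if dev.size < 2:
        raise ValueError("need at least 2 deviations for a t-test")
    n = dev.size
    mean = float(np.mean(dev))
    s = float(np.std(dev, ddof=1))
    df = n - 1
    if s == 0.0:
        if mean == 0.0:
            return DeviationSummary(dev, float(dev.min()), float(dev.max()),
                                    mean, s, 0.0, df, 1.0)
        warnings.warn("zero variance with nonzero mean: t undefined",
                      stacklevel=2)
        return DeviationSummary(dev, float(dev.min()), float(dev.max()),
                                mean, s, np.nan, df, np.nan, degenerate=True)
    t = mean / (s / np.sqrt(n))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return DeviationSummary(dev, float(dev.min()), float(dev.max()),
                            mean, s, float(t), df, p)
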