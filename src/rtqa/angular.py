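"""Per-detector gantry-angle response correction for 2D ion-chamber arrays.

Plane-parallel chambers under-respond when the beam arrives obliquely, worst
near lateral incidence (90 deg / 270 deg, beam parallel to the detector
plane).  A single correction-factor table is measured for the *central*
chamber over a calibration sweep of gantry angles; every other chamber in a
row sees the beam at a slightly different incident angle because it is offset
from the rotation axis.  For a chamber at signed in-plane offset d (mm) from
the array center and gantry angle theta, the incident angle is

    phi = atan2(d + SAD*sin(theta), SAD*cos(theta))  mapped to [0, 360),

with SAD the source-axis distance.  Correction factors are looked up at phi
by linear interpolation (periodic across 360 -> 0) and applied
multiplicatively per detector.  Detectors offset only along the rotation axis
keep phi = theta: out-of-plane offsets do not change incidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import PlanarDose

__all__ = [
    "CorrectionTable",
    "calibration_angles",
    "incident_angle",
    "build_correction_table",
    "correction_factor_at",
    "apply_correction",
]


def calibration_angles() -> np.ndarray:
    """The calibration sampling grid: 0-360 deg in 5 deg steps, refined to
    1 deg steps within 90 +/- 5 deg and 270 +/- 5 deg."""
    coarse = np.arange(0, 360, 5)
    fine = np.concatenate([np.arange(85, 96), np.arange(265, 276)])
    return np.unique(np.concatenate([coarse, fine])).astype(float)


@dataclass
class CorrectionTable:
    """Gantry-angle -> response-correction-factor samples.

    Angles are strictly increasing in [0, 360); interpolation wraps around
    360 -> 0.  The factor at 0 deg is exactly 1 by construction (factors are
    normalized to the zero-degree response).
    """

    angles: np.ndarray
    factors: np.ndarray
    sad: float = 1000.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        self.factors = np.asarray(self.factors, dtype=float)
        if self.angles.shape != self.factors.shape or self.angles.ndim != 1:
            raise ValueError("angles and factors must be matching 1D arrays")
        if np.any(np.diff(self.angles) <= 0):
            raise ValueError("angles must be strictly increasing")
        if self.angles[0] < 0 or self.angles[-1] >= 360:
            raise ValueError("angles must lie in [0, 360)")
        if np.any(self.factors <= 0):
            raise ValueError("all correction factors must be > 0")
        i0 = np.flatnonzero(self.angles == 0.0)
        if len(i0) == 0 or not np.isclose(self.factors[i0[0]], 1.0):
            raise ValueError("table must contain angle 0 with factor 1")


def incident_angle(d, theta, sad: float):
    """Incident angle phi (deg in [0, 360)) of a detector at in-plane offset
    ``d`` mm for gantry angle ``theta`` deg and source-axis distance ``sad``.

    Quadrant-correct via the two-argument arctangent; at theta = 90 deg the
    denominator vanishes and phi = 90 deg for any offset with positive
    numerator.  d = 0 gives phi = theta identically.
    """
    if sad <= 0:
        raise ValueError("SAD must be > 0")
    th = np.deg2rad(np.asarray(theta, dtype=float))
    num = np.asarray(d, dtype=float) + sad * np.sin(th)
    den = sad * np.cos(th)
    phi = np.rad2deg(np.arctan2(num, den)) % 360.0
    if np.isscalar(theta) and np.isscalar(d):
        return float(phi)
    return phi


def build_correction_table(angles, measured, calculated,
                           sad: float = 1000.0,
                           metadata: dict | None = None) -> CorrectionTable:
    """Build a correction table from a paired calibration series.

    At each gantry angle the central detector's measured dose is compared to
    the planning-system calculation as a ratio, then normalized to the
    zero-degree ratio:

        factor(theta) = [calculated(theta)/measured(theta)]
                        / [calculated(0)/measured(0)]

    so a chamber that under-responds at an angle gets a factor > 1 there.
    """
    angles = np.asarray(angles, dtype=float) % 360.0
    measured = np.asarray(measured, dtype=float)
    calculated = np.asarray(calculated, dtype=float)
    if not (len(angles) == len(measured) == len(calculated)):
        raise ValueError("angles, measured and calculated must have equal length")
    if np.any(measured <= 0) or np.any(calculated <= 0):
        raise ValueError("all calibration doses must be > 0")
    order = np.argsort(angles)
    angles, measured, calculated = angles[order], measured[order], calculated[order]
    if np.any(np.diff(angles) == 0):
        raise ValueError("duplicate calibration angles")
    i0 = np.flatnonzero(angles == 0.0)
    if len(i0) == 0:
        raise ValueError("calibration series must contain a 0 degree entry")
    ratio = calculated / measured
    factors = ratio / ratio[i0[0]]
    return CorrectionTable(angles, factors, sad=sad, metadata=metadata or {})


def correction_factor_at(table: CorrectionTable, phi):
    """Correction factor at incident angle ``phi`` by periodic linear
    interpolation between the bracketing sample angles."""
    phi = np.asarray(phi, dtype=float) % 360.0
    # close the circle: append the 0-degree sample at 360
    ang = np.concatenate([table.angles, [table.angles[0] + 360.0]])
    fac = np.concatenate([table.factors, [table.factors[0]]])
    # angles below the first sample wrap from the last sample
    lo = table.angles[0]
    phi_w = np.where(phi < lo, phi + 360.0, phi)
    out = np.interp(phi_w, ang, fac)
    if out.ndim == 0:
        return float(out)
    return out


def apply_correction(measurement: PlanarDose, table: CorrectionTable,
                     sad: float | None = None,
                     row_offsets: np.ndarray | None = None) -> PlanarDose:
    """Apply per-detector angular correction to a planar measurement.

    ``row_offsets`` gives each detector's signed in-plane offset d (mm) from
    the array center along the row (gantry-rotation-plane) direction; by
    default it is the u-axis coordinate of each element, so detectors sharing
    a row offset share a factor.  The measurement must carry its gantry angle.
    """
    if measurement.gantry_angle is None:
        raise ValueError("measurement has no gantry angle; cannot correct")
    sad = float(sad if sad is not None else table.sad)
    if row_offsets is None:
        u = measurement.axis_coords(0)
        row_offsets = np.broadcast_to(u[:, None], measurement.shape)
    else:
        row_offsets = np.broadcast_to(np.asarray(row_offsets, dtype=float),
                                      measurement.shape)
    phi = incident_angle(row_offsets, measurement.gantry_angle, sad)
    factors = correction_factor_at(table, phi)
    vals = measurement.values * factors
    return measurement.like(vals)
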