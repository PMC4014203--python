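"""Gamma-index comparison of dose distributions.

The gamma index combines a dose-difference criterion (a percentage of a
normalization dose) with a distance-to-agreement (DTA) criterion.  For a
reference point r with dose Dr(r), against an evaluated distribution De,

    gamma(r) = min over positions r' of
               sqrt( |r' - r|^2 / dta^2 + (De(r') - Dr(r))^2 / dD^2 ),

with dD = dose_tolerance% of the normalization dose.  A point passes when
gamma <= 1 (boundary inclusive).  The evaluated dose is continuously
(bi/tri-linearly) interpolated during the minimization, which is carried out
over a displacement lattice of step ``search_step_mm`` (default dta/10)
within ``search_radius_mm`` (default 3*dta); the residual quantization error
of that lattice is bounded by :func:`lattice_bound`.

Counting conventions follow clinical 3D anatomical verification practice:
globally, only reference points whose planned dose exceeds the low-dose
threshold (default 20 cGy) are counted; per-structure pass rates count every
voxel inside the structure contour regardless of the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import DoseGrid, PlanarDose

__all__ = [
    "GammaCriteria",
    "GammaResult",
    "compute_gamma",
    "gamma_oracle",
    "pass_rate",
    "lattice_bound",
]

NORMALIZATION_MODES = ("global_reference_max", "prescription", "local")


@dataclass
class GammaCriteria:
    """Gamma acceptance criteria.

    dose_tolerance : percent of the normalization dose (default 3)
    dta : distance to agreement in mm (default 3)
    normalization : 'global_reference_max' (default for planar pairs),
        'prescription' (a dose supplied by the caller; default for 3D pairs
        in the report layer), or 'local' (percent of the local reference
        dose).
    low_dose_threshold : cGy; reference points at or below it are excluded
        from global counting (strictly 'higher than' passes the gate).
    """

    dose_tolerance: float = 3.0
    dta: float = 3.0
    normalization: str = "global_reference_max"
    low_dose_threshold: float = 20.0

    def __post_init__(self) -> None:
        if self.dose_tolerance <= 0:
            raise ValueError("dose_tolerance must be > 0")
        if self.dta <= 0:
            raise ValueError("dta must be > 0")
        if self.low_dose_threshold < 0:
            raise ValueError("low_dose_threshold must be >= 0")
        if self.normalization not in NORMALIZATION_MODES:
            raise ValueError(
                f"normalization must be one of {NORMALIZATION_MODES}")


@dataclass
class GammaResult:
    """Per-point gamma values on the reference geometry.

    gamma : array aligned to the reference; NaN where not computable
        (inactive detector, or reference point outside the evaluated extent).
    valid_mask : gamma is finite here.
    evaluated_mask : points counted in *global* mode — valid and above the
        low-dose threshold.
    """

    gamma: np.ndarray
    valid_mask: np.ndarray
    evaluated_mask: np.ndarray
    criteria: GammaCriteria
    normalization_dose: float | None
    search_step_mm: float
    search_radius_mm: float


def _as_points(dist):
    """Reference coordinates (N, dim), doses (N,), validity mask, shape."""
    if isinstance(dist, DoseGrid):
        cs = dist.coords()
        mesh = np.meshgrid(*cs, indexing="ij")
        pts = np.column_stack([m.ravel() for m in mesh])
        vals = dist.values.ravel()
        valid = np.isfinite(vals)
        return pts, vals, valid, dist.shape
    if isinstance(dist, PlanarDose):
        cs = dist.coords()
        mesh = np.meshgrid(*cs, indexing="ij")
        pts = np.column_stack([m.ravel() for m in mesh])
        vals = np.where(dist.active, dist.values, np.nan).ravel()
        valid = np.isfinite(vals)
        return pts, vals, valid, dist.shape
    raise TypeError(f"unsupported dose type {type(dist).__name__}")


def _resolve_normalization(criteria, ref_vals, valid, normalization_dose):
    if normalization_dose is not None:
        if normalization_dose <= 0:
            raise ValueError("normalization dose must be > 0")
        return float(normalization_dose)
    if criteria.normalization == "global_reference_max":
        m = float(np.max(ref_vals[valid])) if valid.any() else 0.0
        if m <= 0:
            raise ValueError("global reference maximum is zero; cannot normalize")
        return m
    if criteria.normalization == "prescription":
        raise ValueError(
            "normalization='prescription' requires an explicit normalization_dose")
    return None  # local mode


def _offset_lattice(dim: int, step: float, radius: float):
    """Displacement lattice within ``radius``, sorted by distance."""
    n = int(np.floor(radius / step))
    ax = step * np.arange(-n, n + 1)
    mesh = np.meshgrid(*([ax] * dim), indexing="ij")
    offs = np.column_stack([m.ravel() for m in mesh])
    d2 = np.einsum("ij,ij->i", offs, offs)
    keep = d2 <= radius * radius + 1e-12
    offs, d2 = offs[keep], d2[keep]
    order = np.argsort(d2, kind="stable")
    return offs[order], d2[order]


def compute_gamma(
    reference,
    evaluated,
    criteria: GammaCriteria | None = None,
    *,
    normalization_dose: float | None = None,
    search_step_mm: float | None = None,
    search_radius_mm: float | None = None,
    max_points_per_chunk: int = 4_000_000,
) -> GammaResult:
    """Compute the gamma map of ``evaluated`` against ``reference``.

    Both inputs must share dimensionality (two DoseGrids or two PlanarDoses)
    and a common physical frame.  The minimization runs over displacement
    shells of increasing radius with per-point early termination: once the
    distance term alone exceeds a point's current best gamma, no farther
    displacement can improve it.
    """
    criteria = criteria or GammaCriteria()
    if type(reference) is not type(evaluated):
        raise TypeError("reference and evaluated must have the same dimensionality")
    pts, ref_vals, valid, shape = _as_points(reference)
    dim = pts.shape[1]
    norm = _resolve_normalization(criteria, ref_vals, valid, normalization_dose)

    if norm is not None:
        delta = np.full(ref_vals.shape, criteria.dose_tolerance / 100.0 * norm)
    else:  # local normalization: dD scales with the local reference dose
        delta = criteria.dose_tolerance / 100.0 * np.abs(ref_vals)
        valid = valid & (delta > 0)

    step = search_step_mm if search_step_mm is not None else criteria.dta / 10.0
    radius = (search_radius_mm if search_radius_mm is not None
              else 3.0 * criteria.dta)
    if step <= 0 or radius <= 0:
        raise ValueError("search step and radius must be > 0")

    interp = evaluated.interpolator(fill_value=np.nan)
    offs, d2 = _offset_lattice(dim, step, radius)
    # group offsets into shells of equal quantized distance
    shell_ids = np.floor(np.sqrt(d2) / step + 1e-9).astype(int)
    boundaries = np.flatnonzero(np.diff(shell_ids)) + 1
    shells = np.split(np.arange(len(offs)), boundaries)

    idx = np.flatnonzero(valid)
    P = pts[idx]
    Dr = ref_vals[idx]
    dl = delta[idx]
    best2 = np.full(len(idx), np.inf)
    dta2 = criteria.dta ** 2

    for sh in shells:
        shell_min2 = d2[sh[0]] / dta2
        improvable = best2 > shell_min2
        if not improvable.any():
            break
        ai = np.flatnonzero(improvable)
        O = offs[sh]
        # chunk reference points so the (points x offsets) block stays bounded
        rows = max(1, max_points_per_chunk // max(1, len(O)))
        for s in range(0, len(ai), rows):
            a = ai[s:s + rows]
            cand = P[a][:, None, :] + O[None, :, :]
            De = interp(cand.reshape(-1, dim)).reshape(len(a), len(O))
            g2 = d2[sh][None, :] / dta2 + \
                ((De - Dr[a][:, None]) / dl[a][:, None]) ** 2
            with np.errstate(invalid="ignore"):
                g2 = np.where(np.isnan(g2), np.inf, g2)
            best2[a] = np.minimum(best2[a], g2.min(axis=1))

    gamma = np.full(ref_vals.shape, np.nan)
    finite = np.isfinite(best2)
    gamma[idx[finite]] = np.sqrt(best2[finite])
    valid_out = np.isfinite(gamma)
    thresh = valid_out & (ref_vals > criteria.low_dose_threshold)
    return GammaResult(
        gamma=gamma.reshape(shape),
        valid_mask=valid_out.reshape(shape),
        evaluated_mask=thresh.reshape(shape),
        criteria=criteria,
        normalization_dose=norm,
        search_step_mm=step,
        search_radius_mm=radius,
    )


def gamma_oracle(
    reference,
    evaluated,
    criteria: GammaCriteria | None = None,
    fine_factor: int = 10,
    *,
    normalization_dose: float | None = None,
    search_radius_mm: float | None = None,
) -> GammaResult:
    """Brute-force gamma by exhaustive lattice minimization.

    Evaluates every displacement on a lattice of step dta/(10*fine_factor)
    within the search radius, with no pruning — an independent check for
    :func:`compute_gamma` on small inputs (every axis <= 64 points).
    """
    criteria = criteria or GammaCriteria()
    pts, ref_vals, valid, shape = _as_points(reference)
    if max(shape) > 64:
        raise ValueError("gamma_oracle refuses inputs larger than 64 points per axis")
    dim = pts.shape[1]
    norm = _resolve_normalization(criteria, ref_vals, valid, normalization_dose)
    if norm is not None:
        delta = np.full(ref_vals.shape, criteria.dose_tolerance / 100.0 * norm)
    else:
        delta = criteria.dose_tolerance / 100.0 * np.abs(ref_vals)
        valid = valid & (delta > 0)

    step = criteria.dta / 10.0 / int(fine_factor)
    radius = (search_radius_mm if search_radius_mm is not None
              else 3.0 * criteria.dta)
    interp = evaluated.interpolator(fill_value=np.nan)
    offs, d2 = _offset_lattice(dim, step, radius)
    dta2 = criteria.dta ** 2

    gamma = np.full(ref_vals.shape, np.nan)
    idx = np.flatnonzero(valid)
    # plain per-point exhaustive scan, chunked over offsets only for memory
    for i in idx:
        cand = pts[i][None, :] + offs
        De = interp(cand)
        with np.errstate(invalid="ignore"):
            g2 = d2 / dta2 + ((De - ref_vals[i]) / delta[i]) ** 2
        g2 = np.where(np.isnan(g2), np.inf, g2)
        m = g2.min()
        if np.isfinite(m):
            gamma[i] = np.sqrt(m)
    valid_out = np.isfinite(gamma)
    thresh = valid_out & (ref_vals > criteria.low_dose_threshold)
    return GammaResult(
        gamma=gamma.reshape(shape),
        valid_mask=valid_out.reshape(shape),
        evaluated_mask=thresh.reshape(shape),
        criteria=criteria,
        normalization_dose=norm,
        search_step_mm=step,
        search_radius_mm=radius,
    )


def lattice_bound(evaluated, criteria: GammaCriteria,
                  step: float, normalization_dose: float) -> float:
    """Upper bound on the gamma error due to lattice quantization.

    The gamma integrand is Lipschitz in the displacement with constant
    L <= sqrt(1/dta^2 + (G/dD)^2), G the maximum dose-gradient magnitude of
    the interpolated evaluated distribution.  The nearest lattice point to
    the continuum minimizer is at most step*sqrt(dim)/2 away, so the lattice
    minimum exceeds the continuum minimum by at most L*step*sqrt(dim)/2.
    """
    if isinstance(evaluated, PlanarDose):
        vals = np.where(evaluated.active, evaluated.values, np.nan)
        spac = evaluated.pitch
    else:
        vals = evaluated.values
        spac = evaluated.spacing
    dim = vals.ndim
    g2 = 0.0
    for a in range(dim):
        d = np.abs(np.diff(vals, axis=a)) / spac[a]
        if d.size:
            g2 += float(np.nanmax(d)) ** 2
    G = np.sqrt(g2)
    dD = criteria.dose_tolerance / 100.0 * normalization_dose
    L = np.sqrt(1.0 / criteria.dta ** 2 + (G / dD) ** 2)
    return float(L * step * np.sqrt(dim) / 2.0)


def pass_rate(result: GammaResult, mask: np.ndarray | None = None,
              structure_name: str = "") -> float:
    """Fraction of counted points with gamma <= 1 (boundary inclusive).

    Without a mask: global mode — counts points above the low-dose threshold.
    With a mask: structure mode — counts every valid point inside the mask,
    ignoring the threshold.
    """
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != result.gamma.shape:
            raise ValueError("mask shape does not match the gamma map")
        counted = result.valid_mask & mask
    else:
        counted = result.evaluated_mask
    n = int(counted.sum())
    if n == 0:
        label = f" for structure {structure_name!r}" if structure_name else ""
        raise ValueError(f"no points to count{label}: empty evaluation set")
    return float(np.sum(result.gamma[counted] <= 1.0)) / n
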