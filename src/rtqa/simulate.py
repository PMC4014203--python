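"""Synthetic phantom data with known ground truth.

Generates everything the verification pipeline consumes: a phantom dose grid
sized like a MULTICube-class QA phantom (31.4 x 34 x 22 cm, default 3 mm
grid), a nasopharynx-like structure template with nested targets
(PTVnx within PTV1 within PTV2, built by exact Euclidean dilation so the
nesting is guaranteed), serial organs at risk (brainstem, spinal cord, optic
nerves, chiasm) and parallel ones (parotid glands), an analytic conformal
planned dose (prescription-weighted target indicators blurred by a Gaussian
penumbra), controlled delivery perturbations (rigid shift, global output
scale, penumbra broadening, additive noise — applied in that fixed order),
a 32 x 32 ion-chamber-array sampling with 7.62 mm pitch and 1020 active
elements, and a smooth angular response model with dips at lateral incidence
(90 and 270 deg).

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .angular import incident_angle
from .core import DoseGrid, PlanarDose, Prescription, StructureSet

__all__ = [
    "PerturbationSpec",
    "ResponseModel",
    "make_phantom",
    "make_npc_structures",
    "default_prescription",
    "make_planned_dose",
    "perturb_dose",
    "sample_detector_array",
    "matrixx_active_mask",
    "simulate_angular_response",
]

#: MULTICube-class phantom exterior dimensions in cm (x = LR, y = AP, z = SI).
PHANTOM_DIMS_CM = (31.4, 34.0, 22.0)

#: MatriXX-class array layout: 32 x 32 lattice, 7.62 mm pitch, 1020 active.
ARRAY_SHAPE = (32, 32)
ARRAY_PITCH_MM = 7.62


@dataclass
class PerturbationSpec:
    """Delivery-error model applied to a planned dose.

    shift_mm : rigid displacement vector (x, y, z) of the delivered dose.
    scale : global output factor (1.0 = nominal, must be > 0).
    penumbra_broadening_mm : extra Gaussian sigma added to the falloff.
    noise_pct : std of additive Gaussian noise, percent of the normalization
        dose (requires a reference dose when > 0).
    seed : RNG seed; identical specs with identical seeds reproduce outputs
        bit for bit.
    """

    shift_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    scale: float = 1.0
    penumbra_broadening_mm: float = 0.0
    noise_pct: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be > 0")
        if self.penumbra_broadening_mm < 0:
            raise ValueError("penumbra broadening must be >= 0")
        if self.noise_pct < 0:
            raise ValueError("noise must be >= 0")

    @property
    def is_identity(self) -> bool:
        return (tuple(self.shift_mm) == (0.0, 0.0, 0.0) and self.scale == 1.0
                and self.penumbra_broadening_mm == 0.0 and self.noise_pct == 0.0)


@dataclass
class ResponseModel:
    """Smooth angular response of a plane-parallel chamber, R(0 deg) = 1.

    Gaussian dips of amplitude ``dip_amplitude`` and width ``dip_width_deg``
    centred at 90 and 270 deg (beam parallel to the detector plane) plus a
    small 2-cycle ripple; the whole curve is renormalized so R(0) = 1 exactly
    and must stay positive everywhere.
    """

    dip_amplitude: float = 0.2
    dip_width_deg: float = 10.0
    ripple_amplitude: float = 0.01

    def __post_init__(self) -> None:
        if self.dip_amplitude >= 1.0:
            raise ValueError("dip amplitude must be < 1 (response stays positive)")
        if self.dip_width_deg <= 0:
            raise ValueError("dip width must be > 0")
        if self.ripple_amplitude < 0:
            raise ValueError("ripple amplitude must be >= 0")

    def _raw(self, phi):
        phi = np.asarray(phi, dtype=float) % 360.0
        r = np.ones_like(phi)
        for center in (90.0, 270.0):
            # circular angular distance to the dip center
            dd = np.abs((phi - center + 180.0) % 360.0 - 180.0)
            r = r - self.dip_amplitude * np.exp(-dd ** 2 / (2 * self.dip_width_deg ** 2))
        r = r + self.ripple_amplitude * 0.5 * (1.0 - np.cos(2 * np.deg2rad(phi)))
        return r

    def __call__(self, phi):
        out = self._raw(phi) / self._raw(0.0)
        if np.any(out <= 0):
            raise ValueError("response model went non-positive")
        if np.ndim(phi) == 0:
            return float(out)
        return out


def make_phantom(spacing_mm: float = 3.0,
                 dims_cm: tuple[float, float, float] = PHANTOM_DIMS_CM,
                 frame: str = "phantom") -> DoseGrid:
    """Empty dose grid covering the phantom box, centred on the origin.

    The voxel count per axis is ceil(extent_mm / spacing); default spacing
    3 mm matches a typical planning grid.
    """
    if spacing_mm <= 0:
        raise ValueError("spacing must be > 0")
    dims_mm = np.asarray(dims_cm, dtype=float) * 10.0
    if np.any(dims_mm <= 0):
        raise ValueError("phantom dimensions must be > 0")
    shape = tuple(int(np.ceil(d / spacing_mm)) for d in dims_mm)
    origin = tuple(-(n - 1) * spacing_mm / 2.0 for n in shape)
    return DoseGrid(np.zeros(shape), (spacing_mm,) * 3, origin, frame)


def _ellipsoid(grid: DoseGrid, center, semi_axes) -> np.ndarray:
    xs, ys, zs = grid.coords()
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    cx, cy, cz = center
    ax, ay, az = semi_axes
    return ((gx - cx) / ax) ** 2 + ((gy - cy) / ay) ** 2 + ((gz - cz) / az) ** 2 <= 1.0


def _cylinder_z(grid: DoseGrid, center_xy, radius, z_range) -> np.ndarray:
    xs, ys, zs = grid.coords()
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    cx, cy = center_xy
    return (((gx - cx) ** 2 + (gy - cy) ** 2 <= radius ** 2)
            & (gz >= z_range[0]) & (gz <= z_range[1]))


def _cylinder_x(grid: DoseGrid, center_yz, radius, x_range) -> np.ndarray:
    xs, ys, zs = grid.coords()
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    cy, cz = center_yz
    return (((gy - cy) ** 2 + (gz - cz) ** 2 <= radius ** 2)
            & (gx >= x_range[0]) & (gx <= x_range[1]))


def _dilate_mm(mask: np.ndarray, margin_mm: float, spacing) -> np.ndarray:
    """Exact Euclidean dilation of a mask by a ball of radius ``margin_mm``,
    via the distance transform of the complement with anisotropic sampling."""
    dist = ndimage.distance_transform_edt(~mask, sampling=spacing)
    return dist <= margin_mm


def make_npc_structures(grid: DoseGrid, seed: int = 0,
                        jitter_mm: float = 0.0,
                        ptv1_margin_mm: float = 5.0,
                        ptv2_margin_mm: float = 10.0) -> StructureSet:
    """Nasopharynx-like structure template on ``grid``.

    PTVnx is a central ellipsoid; PTV1 and PTV2 are exact Euclidean dilations
    of it by the given margins, so PTVnx <= PTV1 <= PTV2 holds voxelwise by
    construction.  Serial OARs (brainstem, spinal cord) are posterior
    z-cylinders, optic nerves are thin x-cylinders meeting a small chiasm,
    and the parotid glands are lateral ellipsoids.  ``jitter_mm`` adds a
    seeded uniform perturbation to the template centres.
    """
    rng = np.random.default_rng(seed)
    jit = lambda: rng.uniform(-jitter_mm, jitter_mm, size=3) if jitter_mm > 0 \
        else np.zeros(3)

    ext = grid.extent()
    span = [hi - lo for lo, hi in ext]
    if min(span) < 100.0:
        raise ValueError("grid too small for the structure template (needs >= 10 cm)")

    c0 = np.array([0.0, -10.0, 0.0]) + jit()
    ptvnx = _ellipsoid(grid, c0, (25.0, 20.0, 20.0))
    ptv1 = _dilate_mm(ptvnx, ptv1_margin_mm, grid.spacing)
    ptv2 = _dilate_mm(ptvnx, ptv2_margin_mm, grid.spacing)

    cbs = np.array([0.0, 20.0, 25.0]) + jit()
    brainstem = _cylinder_z(grid, cbs[:2], 8.0, (cbs[2] - 30.0, cbs[2] + 30.0))
    ccd = np.array([0.0, 26.0, -20.0]) + jit()
    cord = _cylinder_z(grid, ccd[:2], 5.0, (ccd[2] - 40.0, ccd[2] + 40.0))

    cch = np.array([0.0, -32.0, 24.0]) + jit()
    chiasm = _ellipsoid(grid, cch, (7.0, 4.0, 3.5))
    nerve_l = _cylinder_x(grid, (cch[1], cch[2]), 3.5, (-26.0 + cch[0], -5.0 + cch[0]))
    nerve_r = _cylinder_x(grid, (cch[1], cch[2]), 3.5, (5.0 + cch[0], 26.0 + cch[0]))

    cpl = np.array([-40.0, 2.0, 0.0]) + jit()
    cpr = np.array([40.0, 2.0, 0.0]) + jit()
    parotid_l = _ellipsoid(grid, cpl, (8.0, 13.0, 16.0))
    parotid_r = _ellipsoid(grid, cpr, (8.0, 13.0, 16.0))

    masks = {
        "PTVnx": ptvnx,
        "PTV1": ptv1,
        "PTV2": ptv2,
        "Brainstem": brainstem,
        "SpinalCord": cord,
        "OpticChiasm": chiasm,
        "OpticNerve_L": nerve_l,
        "OpticNerve_R": nerve_r,
        "Parotid_L": parotid_l,
        "Parotid_R": parotid_r,
    }
    for name, m in masks.items():
        if not m.any():
            raise ValueError(f"template structure {name!r} fell outside the grid")
    return StructureSet(masks, grid)


def default_prescription() -> Prescription:
    """Synthetic three-level simultaneous-integrated-boost prescription
    (7000/6600/6000 cGy); clinical plans vary, these are labelled defaults."""
    return Prescription(
        doses={"PTVnx": 7000.0, "PTV1": 6600.0, "PTV2": 6000.0},
        normalization=7000.0,
    )


def make_planned_dose(structures: StructureSet,
                      prescription: Prescription,
                      penumbra_sigma_mm: float = 4.0,
                      targets: tuple[str, ...] = ("PTVnx", "PTV1", "PTV2"),
                      ) -> DoseGrid:
    """Analytic conformal planned dose: the voxelwise maximum over targets of
    prescription x Gaussian-blurred target indicator.

    The blur sigma (mm) models the beam penumbra and must be > 0.  Inside a
    large target the blurred indicator saturates to 1, so the dose approaches
    the prescription; the falloff outside is Gaussian-smooth.  Deterministic.
    """
    if penumbra_sigma_mm <= 0:
        raise ValueError("penumbra sigma must be > 0")
    grid = structures.grid
    dose = np.zeros(grid.shape)
    for t in targets:
        if t not in prescription.doses:
            raise ValueError(f"no prescription for target {t!r}")
        if t not in structures:
            raise ValueError(f"structure set has no target {t!r}")
        sig_vox = [penumbra_sigma_mm / s for s in grid.spacing]
        blurred = ndimage.gaussian_filter(
            structures[t].astype(float), sigma=sig_vox, mode="constant")
        dose = np.maximum(dose, prescription[t] * blurred)
    return grid.like(dose)


def perturb_dose(dose: DoseGrid, spec: PerturbationSpec,
                 normalization_dose: float | None = None) -> DoseGrid:
    """Apply a delivery perturbation: rigid shift (trilinear), global scale,
    extra penumbra blur, then seeded Gaussian noise — in that order.

    The identity spec returns a bitwise-equal copy.  Noise std is
    ``noise_pct`` percent of ``normalization_dose`` (required when noise > 0);
    noisy doses are clipped at 0 so the result remains a valid dose grid.
    """
    if spec.is_identity:
        return dose.like(dose.values.copy())
    vals = dose.values
    if tuple(spec.shift_mm) != (0.0, 0.0, 0.0):
        shift_vox = [s / sp for s, sp in zip(spec.shift_mm, dose.spacing)]
        vals = ndimage.shift(vals, shift_vox, order=1, mode="constant", cval=0.0)
    if spec.scale != 1.0:
        vals = vals * spec.scale
    if spec.penumbra_broadening_mm > 0:
        sig_vox = [spec.penumbra_broadening_mm / s for s in dose.spacing]
        vals = ndimage.gaussian_filter(vals, sigma=sig_vox, mode="constant")
    if spec.noise_pct > 0:
        if normalization_dose is None:
            raise ValueError("noise_pct > 0 requires a normalization dose")
        rng = np.random.default_rng(spec.seed)
        vals = vals + rng.normal(
            0.0, spec.noise_pct / 100.0 * normalization_dose, size=vals.shape)
    return dose.like(np.clip(vals, 0.0, None))


def matrixx_active_mask(shape: tuple[int, int] = ARRAY_SHAPE) -> np.ndarray:
    """Active-element mask: full lattice minus the 4 corner elements
    (1020 active on 32 x 32)."""
    active = np.ones(shape, dtype=bool)
    for i in (0, -1):
        for j in (0, -1):
            active[i, j] = False
    return active


def sample_detector_array(plane: PlanarDose,
                          pitch_mm: float = ARRAY_PITCH_MM,
                          shape: tuple[int, int] = ARRAY_SHAPE,
                          center: tuple[float, float] = (0.0, 0.0),
                          gantry_angle: float | None = None) -> PlanarDose:
    """Sample a planar dose field at an ion-chamber-array lattice.

    Bilinear sampling at a ``shape`` lattice of ``pitch_mm`` spacing centred
    at ``center``; the 4 corner elements are inactive (1020 active for the
    default 32 x 32 layout).  Raises if the array extends beyond the field.
    """
    n0, n1 = shape
    u0 = center[0] - (n0 - 1) * pitch_mm / 2.0
    v0 = center[1] - (n1 - 1) * pitch_mm / 2.0
    us = u0 + pitch_mm * np.arange(n0)
    vs = v0 + pitch_mm * np.arange(n1)
    pu, pv = plane.coords()
    if us[0] < pu[0] - 1e-9 or us[-1] > pu[-1] + 1e-9 \
            or vs[0] < pv[0] - 1e-9 or vs[-1] > pv[-1] + 1e-9:
        raise ValueError("detector array extent falls outside the dose field")
    interp = plane.interpolator(fill_value=np.nan)
    gu, gv = np.meshgrid(us, vs, indexing="ij")
    vals = interp(np.column_stack([gu.ravel(), gv.ravel()])).reshape(shape)
    active = matrixx_active_mask(shape)
    vals = np.where(active, vals, 0.0)
    return PlanarDose(vals, (pitch_mm, pitch_mm), (u0, v0), active, gantry_angle)


def simulate_angular_response(frame: PlanarDose, theta: float,
                              model: ResponseModel, sad: float = 1000.0,
                              row_offsets: np.ndarray | None = None) -> PlanarDose:
    """Apply an angular response R(phi) to a true beam frame.

    Each detector's value is multiplied by R evaluated at its own incident
    angle phi(d, theta, SAD), with d the detector's in-plane (u-axis) offset
    from the array center by default.  The returned frame carries ``theta``
    as its gantry angle.
    """
    if row_offsets is None:
        u = frame.axis_coords(0)
        row_offsets = np.broadcast_to(u[:, None], frame.shape)
    else:
        row_offsets = np.broadcast_to(np.asarray(row_offsets, dtype=float),
                                      frame.shape)
    phi = incident_angle(row_offsets, theta, sad)
    vals = frame.values * model(phi)
    return PlanarDose(vals, frame.pitch, frame.origin, frame.active.copy(), theta)
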