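"""Shared geometric data types for dose-verification analysis.

Conventions
-----------
All geometry lives in a right-handed millimetre frame with the DICOM patient
axes: x = left-right, y = anterior-posterior, z = superior-inferior.  Voxel
positions refer to voxel *centers*; indices are 0-based.  Dose is carried in
cGy throughout; unit conversion happens only at the I/O boundary.

A :class:`DoseGrid` stores a 3D dose array indexed ``values[ix, iy, iz]`` with
per-axis spacing and the position of the first voxel center.  A
:class:`PlanarDose` is the 2D analogue used for ion-chamber-array measurements
and extracted planes; its two in-plane axes are called u and v.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RegularGridInterpolator

AXES = ("x", "y", "z")

__all__ = [
    "DoseGrid",
    "PlanarDose",
    "StructureSet",
    "Prescription",
    "rasterize_contours",
    "resample_to_grid",
    "extract_plane",
    "points_in_polygon",
]


@dataclass
class DoseGrid:
    """A 3D absorbed-dose distribution on a regular grid.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Absorbed dose in cGy; must be finite and non-negative.
    spacing : tuple of float
        Voxel size per axis in mm, all > 0.
    origin : tuple of float
        Position of the center of voxel (0, 0, 0) in mm.
    frame : str
        Free-text frame-of-reference label (e.g. a DICOM FoR UID).
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    frame: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"dose array must be 3D, got ndim={self.values.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("spacing and origin must have 3 components")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"all spacings must be > 0, got {self.spacing}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("dose values must be finite")
        if np.any(self.values < 0):
            raise ValueError("dose values must be >= 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_cc(self) -> float:
        """Volume of one voxel in cubic centimetres."""
        return float(np.prod(self.spacing)) / 1000.0

    def axis_coords(self, axis: int) -> np.ndarray:
        """Physical coordinates (mm) of the voxel centers along one axis."""
        n = self.values.shape[axis]
        return self.origin[axis] + self.spacing[axis] * np.arange(n)

    def coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(self.axis_coords(i) for i in range(3))

    def extent(self) -> list[tuple[float, float]]:
        """Per-axis (min, max) voxel-center coordinates in mm."""
        return [
            (c[0], c[-1]) for c in self.coords()
        ]

    def interpolator(self, fill_value: float | None = np.nan) -> RegularGridInterpolator:
        """Trilinear interpolator over the voxel-center lattice."""
        return RegularGridInterpolator(
            self.coords(), self.values, method="linear",
            bounds_error=False, fill_value=fill_value,
        )

    def like(self, values: np.ndarray) -> "DoseGrid":
        """A new grid with the same geometry and different values."""
        return DoseGrid(values, self.spacing, self.origin, self.frame)


@dataclass
class PlanarDose:
    """A 2D dose plane: an array measurement or an extracted grid plane.

    ``active`` marks physical detector elements; for MatriXX-like arrays the
    active count is 1020 on a 32x32 lattice (four corner elements absent).
    ``gantry_angle`` is the nominal beam angle in degrees, [0, 360), or None
    for composite/extracted planes.
    """

    values: np.ndarray
    pitch: tuple[float, float]
    origin: tuple[float, float] = (0.0, 0.0)
    active: np.ndarray | None = None
    gantry_angle: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("planar dose must be 2D")
        self.pitch = tuple(float(p) for p in self.pitch)
        self.origin = tuple(float(o) for o in self.origin)
        if any(p <= 0 for p in self.pitch):
            raise ValueError(f"pitch must be > 0, got {self.pitch}")
        if self.active is None:
            self.active = np.ones(self.values.shape, dtype=bool)
        else:
            self.active = np.asarray(self.active, dtype=bool)
            if self.active.shape != self.values.shape:
                raise ValueError("active mask shape must match values")
        if not np.all(np.isfinite(self.values[self.active])):
            raise ValueError("dose values must be finite where active")
        if self.gantry_angle is not None:
            self.gantry_angle = float(self.gantry_angle) % 360.0

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def axis_coords(self, axis: int) -> np.ndarray:
        n = self.values.shape[axis]
        return self.origin[axis] + self.pitch[axis] * np.arange(n)

    def coords(self) -> tuple[np.ndarray, np.ndarray]:
        return self.axis_coords(0), self.axis_coords(1)

    def interpolator(self, fill_value: float | None = np.nan) -> RegularGridInterpolator:
        """Bilinear interpolator; inactive elements contribute NaN."""
        vals = np.where(self.active, self.values, np.nan)
        return RegularGridInterpolator(
            self.coords(), vals, method="linear",
            bounds_error=False, fill_value=fill_value,
        )

    def like(self, values: np.ndarray) -> "PlanarDose":
        return PlanarDose(values, self.pitch, self.origin,
                          self.active.copy(), self.gantry_angle)


@dataclass
class StructureSet:
    """Named binary voxel masks sharing one DoseGrid geometry."""

    masks: dict[str, np.ndarray]
    grid: DoseGrid
    empty_structures: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name, m in self.masks.items():
            m = np.asarray(m, dtype=bool)
            if m.shape != self.grid.shape:
                raise ValueError(
                    f"mask {name!r} shape {m.shape} != grid shape {self.grid.shape}")
            self.masks[name] = m

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    def names(self) -> list[str]:
        return list(self.masks)

    @property
    def volumes(self) -> dict[str, float]:
        """Structure volumes in cc (voxel count x voxel volume)."""
        vv = self.grid.voxel_volume_cc
        return {n: float(m.sum()) * vv for n, m in self.masks.items()}


@dataclass
class Prescription:
    """Prescribed dose per target and the dose defining '100%'.

    ``doses`` maps structure name -> prescribed dose in cGy.
    ``normalization`` is the dose treated as 100% for global gamma
    normalization and percent-of-prescription DVH queries.
    """

    doses: dict[str, float]
    normalization: float

    def __post_init__(self) -> None:
        if self.normalization <= 0:
            raise ValueError("normalization dose must be > 0")
        for name, d in self.doses.items():
            if d <= 0:
                raise ValueError(f"prescription for {name!r} must be > 0")

    def __getitem__(self, name: str) -> float:
        return self.doses[name]


def points_in_polygon(points: np.ndarray, polygon: np.ndarray) -> np.ndarray:
    """Even-odd (ray-casting) point-in-polygon test, vectorized.

    ``points`` is (N, 2); ``polygon`` is (M, 2) and treated as closed
    (an explicit repeated final vertex is tolerated).  Points exactly on an
    edge are not guaranteed a particular side.
    """
    pts = np.asarray(points, dtype=float)
    poly = np.asarray(polygon, dtype=float)
    if poly.shape[0] >= 2 and np.allclose(poly[0], poly[-1]):
        poly = poly[:-1]
    x, y = pts[:, 0], pts[:, 1]
    inside = np.zeros(len(pts), dtype=bool)
    x1, y1 = poly[:, 0], poly[:, 1]
    x2, y2 = np.roll(x1, -1), np.roll(y1, -1)
    for i in range(len(poly)):
        cond = (y1[i] > y) != (y2[i] > y)
        if not cond.any():
            continue
        # x-coordinate where the edge crosses the horizontal ray
        xi = x1[i] + (y[cond] - y1[i]) * (x2[i] - x1[i]) / (y2[i] - y1[i])
        sub = inside[cond]
        sub ^= x[cond] < xi
        inside[cond] = sub
    return inside


def rasterize_contours(
    contours: dict[str, list[tuple[float, np.ndarray]]],
    grid: DoseGrid,
) -> StructureSet:
    """Rasterize per-slice closed polygons into voxel masks.

    Parameters
    ----------
    contours : dict
        Structure name -> list of ``(z_mm, polygon)`` where ``polygon`` is an
        (M, 2) array of in-plane (x, y) vertices in mm with the first vertex
        repeated at the end (explicitly closed).
    grid : DoseGrid
        Target geometry; masks share its shape.

    A voxel is included iff its center lies inside an odd number of that
    slice's polygons (even-odd rule), so disjoint polygons union and nested
    polygons carve holes.  Contour slices outside the grid's z extent are
    ignored with a warning.  Structures that end up empty are kept but listed
    in ``StructureSet.empty_structures``.
    """
    xs, ys, zs = grid.coords()
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel()])

    masks: dict[str, np.ndarray] = {}
    empty: list[str] = []
    sz = grid.spacing[2]
    for name, slices in contours.items():
        mask = np.zeros(grid.shape, dtype=bool)
        for z, poly in slices:
            poly = np.asarray(poly, dtype=float)
            if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 4 \
                    or not np.allclose(poly[0], poly[-1], atol=1e-6):
                raise ValueError(
                    f"structure {name!r}: polygon at z={z} mm is not closed "
                    "(first vertex must repeat at the end)")
            iz = (z - grid.origin[2]) / sz
            k = int(round(iz))
            if k < 0 or k >= grid.shape[2] or abs(iz - k) > 0.5 + 1e-9:
                warnings.warn(
                    f"structure {name!r}: contour slice z={z} mm outside "
                    "grid extent; ignored", stacklevel=2)
                continue
            inside = points_in_polygon(pts, poly).reshape(gx.shape)
            mask[:, :, k] ^= inside
        if not mask.any():
            empty.append(name)
        masks[name] = mask
    return StructureSet(masks, grid, empty_structures=empty)


def resample_to_grid(
    dose: DoseGrid, target: DoseGrid
) -> tuple[DoseGrid, np.ndarray]:
    """Trilinearly resample a dose grid onto another geometry.

    Returns the resampled :class:`DoseGrid` (on ``target``'s geometry) and a
    boolean mask of target voxels that fell inside the source extent.  Outside
    the source extent the dose is set to 0 rather than extrapolated — dose
    beyond the calculated/measured extent is unknown.

    Raises ``ValueError`` if the extents do not overlap at all.
    """
    src_ext = dose.extent()
    tgt_ext = target.extent()
    for a in range(3):
        if tgt_ext[a][0] > src_ext[a][1] or tgt_ext[a][1] < src_ext[a][0]:
            raise ValueError(
                f"target grid does not overlap source extent on axis {AXES[a]}")
    interp = dose.interpolator(fill_value=np.nan)
    cx, cy, cz = target.coords()
    gx, gy, gz = np.meshgrid(cx, cy, cz, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    vals = interp(pts).reshape(target.shape)
    inside = np.isfinite(vals)
    vals = np.where(inside, vals, 0.0)
    return target.like(vals), inside


def extract_plane(dose: DoseGrid, axis: str, coordinate: float) -> PlanarDose:
    """Extract a bilinearly interpolated planar dose at a fixed coordinate.

    ``axis`` is one of 'x', 'y', 'z'; ``coordinate`` is in mm and must lie
    within the grid's voxel-center extent along that axis.  The plane's (u, v)
    axes are the two remaining grid axes in x, y, z order and inherit their
    spacings.
    """
    if axis not in AXES:
        raise ValueError(f"axis must be one of {AXES}, got {axis!r}")
    ia = AXES.index(axis)
    c = dose.axis_coords(ia)
    if coordinate < c[0] - 1e-9 or coordinate > c[-1] + 1e-9:
        raise ValueError(
            f"coordinate {coordinate} mm outside {axis} extent "
            f"[{c[0]}, {c[-1]}] mm")
    # fractional layer index and linear weight between bracketing layers
    f = (coordinate - c[0]) / dose.spacing[ia]
    k0 = int(np.clip(np.floor(f), 0, len(c) - 1))
    k1 = min(k0 + 1, len(c) - 1)
    w = f - k0
    lo = np.take(dose.values, k0, axis=ia)
    hi = np.take(dose.values, k1, axis=ia)
    vals = (1.0 - w) * lo + w * hi
    keep = [a for a in range(3) if a != ia]
    pitch = (dose.spacing[keep[0]], dose.spacing[keep[1]])
    origin = (dose.origin[keep[0]], dose.origin[keep[1]])
    return PlanarDose(vals, pitch, origin)
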