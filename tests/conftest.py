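"""Shared fixtures: small geometries and analytic dose fields."""

import numpy as np
import pytest

from rtqa.core import DoseGrid, PlanarDose


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def circle_polygon(cx, cy, r, n=180):
    """Closed polygon approximating a circle (first vertex repeated)."""
    t = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    pts = np.column_stack([cx + r * np.cos(t), cy + r * np.sin(t)])
    return np.vstack([pts, pts[0]])


def sphere_contours(radius, spacing, center=(0.0, 0.0, 0.0)):
    """Per-slice circle contours of a sphere, one per grid z-layer."""
    cx, cy, cz = center
    zs = np.arange(-radius, radius + 1e-9, spacing)
    slices = []
    for z in zs:
        r2 = radius ** 2 - z ** 2
        if r2 <= 0:
            continue
        slices.append((cz + z, circle_polygon(cx, cy, np.sqrt(r2))))
    return slices


def gradient_pair(shift_mm=3.0, slope_pct_per_mm=1.0, d0=1000.0,
                  n=81, pitch=1.0, width=21):
    """1D linear-gradient slab and a rigidly shifted copy (planar).

    The reference rises ``slope_pct_per_mm`` percent of ``d0`` per mm along
    the first axis; the evaluated field is the same slab shifted by
    ``shift_mm``.  The interior gamma for (3%, 3 mm) criteria with
    normalization d0 has the closed form sqrt((r^2 + (r-shift)^2))/3 minimized
    over r, = sqrt(2)/2 for a 3 mm shift of a 1 %/mm gradient.
    """
    x = np.arange(n) * pitch
    prof = d0 * (0.5 + slope_pct_per_mm / 100.0 * (x - x.mean()))
    ref = PlanarDose(np.repeat(prof[:, None], width, axis=1), (pitch, pitch))
    prof_s = d0 * (0.5 + slope_pct_per_mm / 100.0 * (x - x.mean() - shift_mm))
    ev = PlanarDose(np.repeat(prof_s[:, None], width, axis=1), (pitch, pitch))
    return ref, ev


def smooth_random_plane(rng, shape=(20, 20), pitch=3.0, base=100.0,
                        amp=50.0, sigma=2.0):
    """A smooth positive random planar dose (Gaussian-filtered noise)."""
    from scipy.ndimage import gaussian_filter
    a = gaussian_filter(rng.normal(0.0, 1.0, shape), sigma)
    a = base + amp * a / np.abs(a).max()
    return PlanarDose(a, (pitch, pitch))


@pytest.fixture
def small_scenario():
    """Reduced phantom scenario used for end-to-end runs in tests."""
    return {"phantom": {"spacing_mm": 4.0, "dims_cm": [26.0, 26.0, 14.0]}}


def uniform_grid(value=100.0, shape=(8, 8, 8), spacing=(2.0, 2.0, 2.0)):
    return DoseGrid(np.full(shape, float(value)), spacing)
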