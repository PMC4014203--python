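"""Synthetic phantom, plan, perturbation, and detector-array generators."""

import numpy as np
import pytest
from scipy import ndimage

from rtqa.core import PlanarDose
from rtqa.simulate import (PerturbationSpec, ResponseModel, default_prescription,
                           make_npc_structures, make_phantom, make_planned_dose,
                           matrixx_active_mask, perturb_dose,
                           sample_detector_array)


def small_structures(spacing=4.0, dims=(26.0, 26.0, 14.0), seed=0):
    return make_npc_structures(make_phantom(spacing, dims), seed=seed)


class TestPhantom:
    def test_default_grid_shape(self):
        g = make_phantom()
        assert g.shape == (105, 114, 74)  # ceil(314/3), ceil(340/3), ceil(220/3)
        assert g.spacing == (3.0, 3.0, 3.0)

    def test_coarse_grid_shape_and_centering(self):
        g = make_phantom(10.0)
        assert g.shape == (32, 34, 22)
        xs, ys, zs = g.coords()
        assert xs[0] == -xs[-1] and ys[0] == -ys[-1] and zs[0] == -zs[-1]

    def test_invalid_spacing(self):
        with pytest.raises(ValueError):
            make_phantom(0.0)
        with pytest.raises(ValueError):
            make_phantom(-3.0)


class TestStructures:
    def test_targets_nested_voxelwise(self):
        ss = small_structures()
        assert np.all(ss["PTVnx"] <= ss["PTV1"])
        assert np.all(ss["PTV1"] <= ss["PTV2"])
        assert ss["PTV1"].sum() > ss["PTVnx"].sum()
        assert ss["PTV2"].sum() > ss["PTV1"].sum()

    def test_template_names_present(self):
        ss = small_structures()
        expect = {"PTVnx", "PTV1", "PTV2", "Brainstem", "SpinalCord",
                  "OpticChiasm", "OpticNerve_L", "OpticNerve_R",
                  "Parotid_L", "Parotid_R"}
        assert set(ss.masks) == expect
        assert all(m.any() for m in ss.masks.values())

    def test_seeded_jitter_deterministic(self):
        g = make_phantom(4.0, (26.0, 26.0, 14.0))
        a = make_npc_structures(g, seed=7, jitter_mm=3.0)
        b = make_npc_structures(g, seed=7, jitter_mm=3.0)
        c = make_npc_structures(g, seed=8, jitter_mm=3.0)
        for name in a.masks:
            assert np.array_equal(a[name], b[name])
        assert any(not np.array_equal(a[n], c[n]) for n in a.masks)

    def test_dilation_matches_binary_dilation_oracle(self):
        # 5 mm margin on a 2 mm grid = dilation by a discrete Euclidean
        # ball of radius 2.5 voxels
        g = make_phantom(2.0, (12.0, 12.0, 12.0))
        ss = make_npc_structures(g)
        r_vox = 5.0 / 2.0
        span = np.arange(-2, 3)
        i, j, k = np.meshgrid(span, span, span, indexing="ij")
        ball = i ** 2 + j ** 2 + k ** 2 <= r_vox ** 2
        expect = ndimage.binary_dilation(ss["PTVnx"], structure=ball)
        assert np.array_equal(ss["PTV1"], expect)

    def test_too_small_grid_rejected(self):
        g = make_phantom(4.0, (8.0, 8.0, 8.0))
        with pytest.raises(ValueError, match="10 cm"):
            make_npc_structures(g)


class TestPlannedDose:
    def test_boost_center_reaches_prescription(self):
        ss = small_structures()
        rx = default_prescription()
        dose = make_planned_dose(ss, rx)
        center = np.unravel_index(
            np.argmax(ss["PTVnx"] * dose.values), dose.shape)
        assert dose.values[center] == pytest.approx(7000.0, rel=1e-3)

    def test_dose_bounded_by_highest_prescription(self):
        ss = small_structures()
        dose = make_planned_dose(ss, default_prescription())
        assert dose.values.max() <= 7000.0 + 1e-9
        assert dose.values.min() >= 0.0

    def test_narrow_penumbra_approaches_indicator(self):
        ss = small_structures()
        rx = default_prescription()
        dose = make_planned_dose(ss, rx, penumbra_sigma_mm=0.2)
        inside = ss["PTVnx"] & ~_boundary(ss["PTVnx"])
        assert np.allclose(dose.values[inside], 7000.0, rtol=1e-6)
        far = ~_boundary(ss["PTV2"]) & ~ss["PTV2"]
        assert np.all(dose.values[far] < 1.0)

    def test_parameter_validation(self):
        ss = small_structures()
        rx = default_prescription()
        with pytest.raises(ValueError, match="sigma"):
            make_planned_dose(ss, rx, penumbra_sigma_mm=0.0)
        with pytest.raises(ValueError, match="target"):
            make_planned_dose(ss, rx, targets=("PTVnx", "Nonexistent"))


def _boundary(mask):
    return mask ^ ndimage.binary_erosion(mask, iterations=2)


class TestPerturbation:
    def dose(self):
        ss = small_structures()
        return make_planned_dose(ss, default_prescription())

    def test_identity_bitwise(self):
        d = self.dose()
        out = perturb_dose(d, PerturbationSpec())
        assert np.array_equal(out.values, d.values)
        assert out.values is not d.values

    def test_pure_scale_is_exact_multiplication(self):
        d = self.dose()
        out = perturb_dose(d, PerturbationSpec(scale=1.02))
        assert np.allclose(out.values, 1.02 * d.values, rtol=1e-12)

    def test_noise_requires_normalization(self):
        d = self.dose()
        with pytest.raises(ValueError, match="normalization"):
            perturb_dose(d, PerturbationSpec(noise_pct=0.5))

    def test_noise_deterministic_in_seed(self):
        d = self.dose()
        spec = PerturbationSpec(noise_pct=0.5, seed=3)
        a = perturb_dose(d, spec, normalization_dose=7000.0)
        b = perturb_dose(d, spec, normalization_dose=7000.0)
        c = perturb_dose(d, PerturbationSpec(noise_pct=0.5, seed=4),
                         normalization_dose=7000.0)
        assert np.array_equal(a.values, b.values)
        assert not np.array_equal(a.values, c.values)
        assert a.values.min() >= 0.0  # clipped to a valid dose

    def test_small_shift_moves_the_distribution(self):
        d = self.dose()
        out = perturb_dose(d, PerturbationSpec(shift_mm=(4.0, 0.0, 0.0)))
        # a +4 mm shift on a 4 mm grid is exactly a one-voxel roll (interior)
        assert np.allclose(out.values[1:], d.values[:-1], atol=1e-9)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            PerturbationSpec(scale=0.0)
        with pytest.raises(ValueError):
            PerturbationSpec(noise_pct=-1.0)
        with pytest.raises(ValueError):
            PerturbationSpec(penumbra_broadening_mm=-0.5)


class TestDetectorArray:
    def wide_plane(self, values):
        return PlanarDose(values, (3.0, 3.0),
                          origin=(-150.0, -150.0))

    def test_uniform_field_sampled_exactly(self):
        plane = self.wide_plane(np.full((101, 101), 123.0))
        arr = sample_detector_array(plane)
        assert arr.shape == (32, 32)
        assert int(arr.active.sum()) == 1020
        assert np.allclose(arr.values[arr.active], 123.0)
        assert np.all(arr.values[~arr.active] == 0.0)

    def test_linear_ramp_bilinear_exact(self):
        xs = np.arange(101) * 3.0 - 150.0
        vals = np.broadcast_to(100.0 + xs[:, None], (101, 101)).copy()
        arr = sample_detector_array(self.wide_plane(vals))
        us = arr.axis_coords(0)
        expect = 100.0 + us
        mid = arr.values[:, 16]
        assert np.allclose(mid, expect, atol=1e-9)

    def test_array_larger_than_field_rejected(self):
        small = PlanarDose(np.full((10, 10), 5.0), (3.0, 3.0))
        with pytest.raises(ValueError, match="extent"):
            sample_detector_array(small)

    def test_gantry_angle_carried(self):
        plane = self.wide_plane(np.full((101, 101), 1.0))
        arr = sample_detector_array(plane, gantry_angle=135.0)
        assert arr.gantry_angle == 135.0


class TestResponseModel:
    def test_normalized_to_unity_at_zero(self):
        m = ResponseModel()
        assert m(0.0) == 1.0

    def test_lateral_dip_value(self):
        # 1 - dip(0.2) + full ripple(0.01), renormalized by R_raw(0) ~= 1
        m = ResponseModel(0.2, 10.0, 0.01)
        assert m(90.0) == pytest.approx(0.81, abs=1e-12)
        assert m(270.0) == pytest.approx(0.81, abs=1e-12)

    def test_symmetric_about_lateral_axes(self):
        m = ResponseModel()
        for delta in (3.0, 7.5, 20.0):
            assert m(90.0 - delta) == pytest.approx(m(90.0 + delta), abs=1e-12)

    def test_validation(self):
        with pytest.raises(ValueError):
            ResponseModel(dip_amplitude=1.0)
        with pytest.raises(ValueError):
            ResponseModel(dip_width_deg=0.0)
        with pytest.raises(ValueError):
            ResponseModel(ripple_amplitude=-0.1)
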