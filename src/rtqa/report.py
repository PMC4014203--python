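"""End-to-end verification batches over simulated cases.

A scenario config (dict, typically loaded from YAML) describes one phantom,
one structure template, a prescription, gamma criteria, an angular response
model, a beam-angle set, and a list of cases, each with its own delivery
perturbation.  :func:`run_batch` pushes every case through the full
pipeline — planar verification at a single gantry angle (SGAC) and as a
multi-gantry-angle composite (MGAC, corrected and uncorrected), volumetric
gamma analysis (global and per structure), and DVH/HI/CI deviations — and
collects per-case rows plus across-case deviation summaries with one-sample
t-tests.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import angular, dvh, gamma, simulate
from .core import DoseGrid, Prescription, StructureSet, extract_plane

__all__ = ["CaseResult", "VerificationReport", "default_scenario", "run_batch"]

TARGETS = ("PTVnx", "PTV1", "PTV2")

#: DVH metrics reported per structure, mirroring a clinical deviation table.
METRIC_PLAN = {
    "PTVnx": ("d98", "d2", "d95", "v100"),
    "PTV1": ("d98", "d2", "d95", "v95"),
    "PTV2": ("d98", "d2", "d95", "v95"),
    "Brainstem": ("d2",),
    "SpinalCord": ("d2",),
    "OpticChiasm": ("d2",),
    "OpticNerve_L": ("d2",),
    "OpticNerve_R": ("d2",),
    "Parotid_L": ("dmean",),
    "Parotid_R": ("dmean",),
}

INDEX_PLAN = {"PTVnx": ("hi",), "PTV1": ("ci",), "PTV2": ("ci",)}


def default_scenario() -> dict:
    """A complete scenario config with synthetic defaults.

    The phantom box and detector array match a MULTICube/MatriXX-class QA
    setup; the three perturbation cases emulate a small setup shift, an
    output-scale error with a shift, and penumbra broadening with noise.
    """
    return {
        "phantom": {"spacing_mm": 3.0, "dims_cm": list(simulate.PHANTOM_DIMS_CM)},
        "structures_seed": 1,
        "jitter_mm": 0.0,
        "penumbra_sigma_mm": 4.0,
        "prescription": {"PTVnx": 7000.0, "PTV1": 6600.0, "PTV2": 6000.0,
                         "normalization": 7000.0},
        "criteria": {"dose_tolerance": 3.0, "dta": 3.0,
                     "low_dose_threshold": 20.0},
        "gamma_search": {"step_mm_2d": 0.3, "radius_mm_2d": 9.0,
                         "step_mm_3d": 1.0, "radius_mm_3d": 9.0},
        "sad_mm": 1000.0,
        "response": {"dip_amplitude": 0.1, "dip_width_deg": 12.0,
                     "ripple_amplitude": 0.01},
        "beam_angles": [0.0, 40.0, 100.0, 180.0, 260.0, 320.0],
        "isocenter_plane_z_mm": 0.0,
        "cases": [
            {"label": "case_shift", "shift_mm": [1.5, 0.0, 0.0], "scale": 1.0,
             "penumbra_broadening_mm": 0.0, "noise_pct": 0.0, "seed": 11},
            {"label": "case_scale", "shift_mm": [0.5, -0.5, 0.0], "scale": 1.02,
             "penumbra_broadening_mm": 0.0, "noise_pct": 0.3, "seed": 12},
            {"label": "case_blur", "shift_mm": [0.0, 1.0, 0.5], "scale": 0.99,
             "penumbra_broadening_mm": 1.0, "noise_pct": 0.3, "seed": 13},
        ],
    }


@dataclass
class CaseResult:
    """All verification outputs of one simulated case."""

    label: str
    sgac_pass: float
    mgac_pass_uncorrected: float
    mgac_pass_corrected: float
    global_3d_pass: float
    structure_pass: dict[str, float]
    metric_deviations: dict[tuple[str, str], float]  # (structure, metric) -> %


@dataclass
class VerificationReport:
    """Per-case rows plus across-case deviation summaries."""

    cases: list[CaseResult]
    criteria: gamma.GammaCriteria
    config: dict = field(default_factory=dict)

    def case_frame(self) -> pd.DataFrame:
        """One row per case: planar and volumetric pass rates (percent)."""
        rows = []
        for c in self.cases:
            row = {
                "case": c.label,
                "sgac_pass_pct": 100.0 * c.sgac_pass,
                "mgac_uncorrected_pass_pct": 100.0 * c.mgac_pass_uncorrected,
                "mgac_corrected_pass_pct": 100.0 * c.mgac_pass_corrected,
                "global_3d_pass_pct": 100.0 * c.global_3d_pass,
            }
            for s, p in c.structure_pass.items():
                row[f"{s}_pass_pct"] = 100.0 * p
            rows.append(row)
        return pd.DataFrame(rows)

    def summary_frame(self) -> pd.DataFrame:
        """Across-case deviation statistics per (structure, metric):
        range, mean +/- std, and the two-sided one-sample t-test p-value."""
        keys = sorted({k for c in self.cases for k in c.metric_deviations})
        rows = []
        for structure, metric in keys:
            devs = [c.metric_deviations.get((structure, metric), np.nan)
                    for c in self.cases]
            devs = [d for d in devs if np.isfinite(d)]
            if len(devs) < 2:
                continue
            s = dvh.deviation_summary(devs)
            rows.append({
                "structure": structure,
                "metric": metric.upper(),
                "n": len(devs),
                "min_pct": s.minimum,
                "max_pct": s.maximum,
                "mean_pct": s.mean,
                "std_pct": s.std,
                "p": s.p,
            })
        return pd.DataFrame(rows)

    def write_csv(self, cases_path, summary_path) -> None:
        self.case_frame().to_csv(cases_path, index=False, float_format="%.4f")
        self.summary_frame().to_csv(summary_path, index=False,
                                    float_format="%.6f")


def _build_world(config: dict):
    ph = config["phantom"]
    grid = simulate.make_phantom(ph.get("spacing_mm", 3.0),
                                 tuple(ph.get("dims_cm", simulate.PHANTOM_DIMS_CM)))
    structures = simulate.make_npc_structures(
        grid, seed=int(config.get("structures_seed", 0)),
        jitter_mm=float(config.get("jitter_mm", 0.0)))
    rx_cfg = dict(config["prescription"])
    norm = float(rx_cfg.pop("normalization"))
    prescription = Prescription({k: float(v) for k, v in rx_cfg.items()}, norm)
    plan = simulate.make_planned_dose(
        structures, prescription,
        penumbra_sigma_mm=float(config.get("penumbra_sigma_mm", 4.0)))
    return grid, structures, prescription, plan


def _planar_pass(ref_array, eval_array, criteria, search) -> float:
    res = gamma.compute_gamma(
        ref_array, eval_array, criteria,
        search_step_mm=search.get("step_mm_2d"),
        search_radius_mm=search.get("radius_mm_2d"))
    return gamma.pass_rate(res)


def run_case(case_cfg: dict, grid: DoseGrid, structures: StructureSet,
             prescription: Prescription, plan: DoseGrid,
             config: dict) -> CaseResult:
    """Run the full verification pipeline for one perturbed delivery."""
    criteria = gamma.GammaCriteria(
        normalization="prescription", **config.get("criteria", {}))
    search = config.get("gamma_search", {})
    sad = float(config.get("sad_mm", 1000.0))
    model = simulate.ResponseModel(**config.get("response", {}))
    angles = [float(a) for a in config.get("beam_angles", [0.0])]
    z_iso = float(config.get("isocenter_plane_z_mm", 0.0))

    spec = simulate.PerturbationSpec(
        shift_mm=tuple(case_cfg.get("shift_mm", (0, 0, 0))),
        scale=float(case_cfg.get("scale", 1.0)),
        penumbra_broadening_mm=float(case_cfg.get("penumbra_broadening_mm", 0.0)),
        noise_pct=float(case_cfg.get("noise_pct", 0.0)),
        seed=int(case_cfg.get("seed", 0)),
    )
    rdd = simulate.perturb_dose(plan, spec, prescription.normalization)

    # --- volumetric gamma: global (low-dose threshold) and per structure
    res3d = gamma.compute_gamma(
        plan, rdd, criteria, normalization_dose=prescription.normalization,
        search_step_mm=search.get("step_mm_3d"),
        search_radius_mm=search.get("radius_mm_3d"))
    global_pass = gamma.pass_rate(res3d)
    structure_pass = {
        name: gamma.pass_rate(res3d, structures[name], structure_name=name)
        for name in structures.names()
    }

    # --- planar verification at the isocenter plane
    planar_criteria = gamma.GammaCriteria(
        dose_tolerance=criteria.dose_tolerance, dta=criteria.dta,
        normalization="global_reference_max",
        low_dose_threshold=criteria.low_dose_threshold)
    ref_plane = extract_plane(plan, "z", z_iso)
    rdd_plane = extract_plane(rdd, "z", z_iso)
    ref_array = simulate.sample_detector_array(ref_plane)
    delivered = simulate.sample_detector_array(rdd_plane)

    # SGAC: every beam delivered at 0 deg, no angular response error
    sgac_pass = _planar_pass(ref_array, delivered, planar_criteria, search)

    # MGAC: the delivered composite split evenly over the planned beam
    # angles; each frame picks up the per-detector angular response
    table = angular.build_correction_table(
        angular.calibration_angles(),
        measured=100.0 * model(angular.calibration_angles()),
        calculated=np.full(angular.calibration_angles().shape, 100.0),
        sad=sad)
    nb = len(angles)
    frame_true = delivered.like(delivered.values / nb)
    uncorr = np.zeros(delivered.shape)
    corr = np.zeros(delivered.shape)
    for theta in angles:
        measured = simulate.simulate_angular_response(frame_true, theta, model, sad)
        uncorr += measured.values
        corr += angular.apply_correction(measured, table, sad).values
    mgac_uncorr = _planar_pass(
        ref_array, delivered.like(uncorr), planar_criteria, search)
    mgac_corr = _planar_pass(
        ref_array, delivered.like(corr), planar_criteria, search)

    # --- DVH / HI / CI deviations, plan vs reconstruction
    deviations: dict[tuple[str, str], float] = {}
    for name in structures.names():
        is_target = name in TARGETS
        m_plan = dvh.compute_metrics(plan, structures[name], name,
                                     prescription, target=is_target)
        m_rdd = dvh.compute_metrics(rdd, structures[name], name,
                                    prescription, target=is_target)
        wanted = METRIC_PLAN.get(name, ()) + INDEX_PLAN.get(name, ())
        for metric in wanted:
            p, r = getattr(m_plan, metric), getattr(m_rdd, metric)
            if p is None or r is None or p == 0:
                deviations[(name, metric)] = np.nan
            else:
                deviations[(name, metric)] = dvh.relative_deviation(r, p)

    return CaseResult(
        label=str(case_cfg.get("label", "case")),
        sgac_pass=sgac_pass,
        mgac_pass_uncorrected=mgac_uncorr,
        mgac_pass_corrected=mgac_corr,
        global_3d_pass=global_pass,
        structure_pass=structure_pass,
        metric_deviations=deviations,
    )


def run_batch(config: dict | None = None) -> VerificationReport:
    """Run every case of a scenario config through the pipeline."""
    cfg = copy.deepcopy(default_scenario())
    if config:
        cfg.update(copy.deepcopy(config))
    grid, structures, prescription, plan = _build_world(cfg)
    cases = [run_case(c, grid, structures, prescription, plan, cfg)
             for c in cfg["cases"]]
    criteria = gamma.GammaCriteria(
        normalization="prescription", **cfg.get("criteria", {}))
    return VerificationReport(cases, criteria, cfg)
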