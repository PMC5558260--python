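"""End-to-end study orchestration: cohort -> resistivity -> montage ->
FEM solve -> target dose -> mixed-model tables, with manifest tracking.

One linear solve is performed per (subject, configuration, site) at a 1 mA
reference current; other intensities follow exactly by linearity (a config
flag forces independent solves for verification).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import analytic, fem, montage as mt, stats, target
from .phantom import (CohortSpec, HeadPhantom, MRITriplet, cohort_manifest_rows,
                      generate_cohort, save_phantom_nifti)
from .resistivity import (ResistivityParams, combine_mri,
                          conductivity_from_resistivity,
                          resistivity_from_intensity)

log = logging.getLogger("tesdose")


@dataclass(frozen=True)
class SolverOptions:
    tol: float = 1e-8
    max_iter: int = 20000
    preconditioner: str = "jacobi"


@dataclass(frozen=True)
class RunConfig:
    cohort: CohortSpec = field(default_factory=CohortSpec)
    resistivity: ResistivityParams = field(default_factory=ResistivityParams)
    solver: SolverOptions = field(default_factory=SolverOptions)
    electrode_radius_mm: float = mt.DEFAULT_ELECTRODE_RADIUS_MM
    ring_distance_mm: float = mt.DEFAULT_RING_DISTANCE_MM
    target_diameter_mm: float = 10.0
    intensities_mA: tuple[float, ...] = mt.INTENSITIES_MA
    reference_intensity_mA: float = 1.0
    independent_solves: bool = False
    write_nifti: bool = False
    out_dir: str = "tesdose_output"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        if "cohort" in kwargs:
            c = dict(kwargs["cohort"])
            if "variability" in c:
                from .phantom import VariabilitySpec
                c["variability"] = VariabilitySpec(**c["variability"])
            if "sex_assignment" in c and c["sex_assignment"] is not None:
                c["sex_assignment"] = tuple(c["sex_assignment"])
            if "grid_shape" in c:
                c["grid_shape"] = tuple(c["grid_shape"])
            kwargs["cohort"] = CohortSpec(**c)
        if "resistivity" in kwargs:
            kwargs["resistivity"] = ResistivityParams(**kwargs["resistivity"])
        if "solver" in kwargs:
            kwargs["solver"] = SolverOptions(**kwargs["solver"])
        if "intensities_mA" in kwargs:
            kwargs["intensities_mA"] = tuple(kwargs["intensities_mA"])
        return cls(**kwargs)


def _sha256(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()


def subject_forward(phantom: HeadPhantom, triplet: MRITriplet,
                    config: RunConfig) -> list[dict]:
    """All 18 dose rows for one subject (one solve per configuration/site)."""
    v = combine_mri(triplet)
    R = resistivity_from_intensity(v, config.resistivity)
    sigma = conductivity_from_resistivity(R, phantom.label_volume,
                                          phantom.voxel_size_mm)
    system = fem.assemble(sigma)
    sites = mt.place_1020_sites(phantom)
    spheres = {s: target.locate_target(sites[s], phantom,
                                       config.target_diameter_mm)
               for s in mt.SITES}

    rows = []
    for cfg in mt.CONFIGURATIONS:
        for site in mt.SITES:
            ref_I = config.reference_intensity_mA
            ref_dose = _solve_dose(cfg, site, ref_I, sites, phantom,
                                   system, spheres[site], config)
            for intensity in config.intensities_mA:
                if config.independent_solves:
                    dose = _solve_dose(cfg, site, intensity, sites, phantom,
                                       system, spheres[site], config)
                else:
                    dose = dataclasses.replace(
                        ref_dose,
                        mean_J=ref_dose.mean_J * (intensity / ref_I),
                        sd_J=ref_dose.sd_J * (intensity / ref_I),
                        min_J=ref_dose.min_J * (intensity / ref_I),
                        max_J=ref_dose.max_J * (intensity / ref_I))
                rows.append({
                    "subject_id": phantom.subject_id, "sex": phantom.sex,
                    "configuration": cfg, "site": site,
                    "intensity_mA": intensity,
                    "dose_uA_cm2": dose.mean_J, "sd_uA_cm2": dose.sd_J,
                    "min_uA_cm2": dose.min_J, "max_uA_cm2": dose.max_J,
                    "n_target_voxels": dose.n_voxels})
    return rows


def _solve_dose(cfg, site, intensity, sites, phantom, system, sphere,
                config: RunConfig):
    spec = mt.StimulationSpec(configuration=cfg, site=site,
                              intensity_mA=intensity)
    m = mt.build_montage(spec, sites, phantom,
                         radius_mm=config.electrode_radius_mm,
                         ring_distance_mm=config.ring_distance_mm)
    load = fem.montage_load(system, m)
    phi = fem.solve_potential(system, load, tol=config.solver.tol,
                              max_iter=config.solver.max_iter,
                              preconditioner=config.solver.preconditioner)
    J = fem.compute_current_density(phi)
    return target.dose_summary(J, sphere,
                               tags={"configuration": cfg, "site": site,
                                     "intensity_mA": intensity})


def run_full_study(config: RunConfig) -> dict:
    """Run the complete study analog; returns the output bundle in memory
    and writes CSV/JSON (optionally NIfTI) artifacts under out_dir."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": _config_echo(config), "stages": {},
                      "seed": config.cohort.seed}

    t0 = time.perf_counter()
    cohort = generate_cohort(config.cohort)
    manifest["stages"]["cohort"] = {
        "seconds": round(time.perf_counter() - t0, 3),
        "n_subjects": len(cohort),
        "water_fraction_sha256": [
            _sha256(p.water_fraction_volume) for p, _ in cohort]}
    pd.DataFrame(cohort_manifest_rows(config.cohort, cohort)).to_csv(
        out_dir / "cohort.csv", index=False)
    if config.write_nifti:
        for phantom, triplet in cohort:
            save_phantom_nifti(phantom, out_dir / "volumes", triplet)

    rows = []
    t0 = time.perf_counter()
    for i, (phantom, triplet) in enumerate(cohort):
        t_subj = time.perf_counter()
        try:
            rows.extend(subject_forward(phantom, triplet, config))
        except Exception as err:
            raise RuntimeError(
                f"forward stage failed for subject {phantom.subject_id}"
            ) from err
        log.info("subject %s: forward stage done in %.1fs",
                 phantom.subject_id, time.perf_counter() - t_subj)
    manifest["stages"]["forward"] = {
        "seconds": round(time.perf_counter() - t0, 3), "n_rows": len(rows)}

    table = stats.assemble_measurements(rows)
    table.to_csv(out_dir / "doses.csv", index=False)
    manifest["stages"]["doses"] = {
        "sha256": hashlib.sha256(
            table.to_csv(index=False).encode()).hexdigest()}

    t0 = time.perf_counter()
    main_fit = stats.fit_mixed_model(table, include_interactions=False)
    inter_fit = stats.fit_mixed_model(table, include_interactions=True)
    cells = stats.summarize_cells(table)
    corr = (stats.cross_site_correlation(table, intensity_mA=2.0)
            if table["subject_id"].nunique() >= 3 else None)
    manifest["stages"]["stats"] = {
        "seconds": round(time.perf_counter() - t0, 3)}

    cells.to_csv(out_dir / "table1_cells.csv", index=False)
    main_fit.terms.to_csv(out_dir / "table2_main_effects.csv")
    inter_fit.terms.to_csv(out_dir / "table3_interactions.csv")
    if corr is not None:
        corr.drop(columns=["c3_doses", "f3_doses"]).to_csv(
            out_dir / "cross_site_correlations.csv")
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)

    return {"table": table, "main_fit": main_fit, "interaction_fit": inter_fit,
            "cells": cells, "correlations": corr, "manifest": manifest,
            "cohort": cohort}


def _config_echo(config: RunConfig) -> dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (tuple, list)):
            return [enc(v) for v in obj]
        if isinstance(obj, np.generic):
            return obj.item()
        return obj

    return enc(config)


# ---------------------------------------------------------------------------
# solver validation against the analytic oracles

def validate_solver(slab_shape=(25, 25, 25), slab_voxel_mm: float = 2.0,
                    sphere_radius_mm: float = 20.0, sphere_grid_n: int = 48,
                    tol: float = 1e-10) -> dict:
    """Slab and homogeneous-sphere oracle comparisons plus conservation
    residuals. Returns a report dict with a boolean 'passed'."""
    report = {}

    # --- uniform slab: exact discrete solution is linear in depth
    sigma = analytic.uniform_slab_conductivity(slab_shape,
                                               voxel_size_mm=slab_voxel_mm)
    system = fem.assemble(sigma)
    load = analytic.slab_face_load(system, current_mA=1.0)
    phi = fem.solve_potential(system, load, tol=tol)
    expected_phi = analytic.slab_expected_potential(system, current_mA=1.0)
    scale = np.abs(expected_phi).max()
    report["slab_phi_max_rel_error"] = float(
        np.abs(phi.phi - expected_phi).max() / scale)

    J = fem.compute_current_density(phi)
    expected_J = analytic.slab_expected_J_magnitude(slab_shape, slab_voxel_mm)
    report["slab_J_max_rel_error"] = float(
        np.abs(J.J_magnitude - expected_J).max() / expected_J)

    # current is injected at the top face, so it flows in -z: compare |flux|
    fluxes = [fem.plane_flux_mA(J, axis=2, index=k)
              for k in range(1, slab_shape[2] - 1)]
    report["slab_flux_max_rel_error"] = float(
        max(abs(abs(fl) - 1.0) for fl in fluxes))
    report["conservation_residual"] = phi.relative_residual

    # --- homogeneous sphere vs Legendre series
    report.update(_sphere_oracle(sphere_radius_mm, sphere_grid_n))

    report["passed"] = bool(
        report["slab_phi_max_rel_error"] < 1e-6
        and report["slab_J_max_rel_error"] < 1e-6
        and report["slab_flux_max_rel_error"] < 1e-3
        and report["sphere_rms_rel_error"] < 0.02)
    return report


def _sphere_oracle(radius_mm: float, grid_n: int) -> dict:
    sigma = analytic.sphere_conductivity(radius_mm, grid_n)
    system = fem.assemble(sigma)
    h = sigma.voxel_size_mm
    c = grid_n * h / 2.0

    # two surface point electrodes, 90 degrees apart
    anode_dir = np.array([0.0, 0.0, 1.0])
    cathode_dir = np.array([1.0, 0.0, 0.0])
    load = np.zeros(system.n_nodes)
    for direction, current in ((anode_dir, 1.0), (cathode_dir, -1.0)):
        p = c + direction * (radius_mm - 1.5 * h)
        ijk = tuple(int(q // h) for q in p)
        node = system.node_id[ijk]
        if node < 0:
            raise fem.SolverError("electrode node outside the sphere domain")
        load[node] += current
    phi = fem.solve_potential(system, load, tol=1e-10)

    # compare on interior voxel centers away from the electrodes
    inside = ~sigma.air_mask
    vox = np.argwhere(inside)
    centers = (vox + 0.5) * h - c
    r = np.linalg.norm(centers, axis=1)
    anode_mm = anode_dir * (radius_mm - 1.5 * h)
    cathode_mm = cathode_dir * (radius_mm - 1.5 * h)
    d_a = np.linalg.norm(centers - anode_mm, axis=1)
    d_c = np.linalg.norm(centers - cathode_mm, axis=1)
    sel = (r <= 0.8 * radius_mm) & (d_a > 0.35 * radius_mm) \
        & (d_c > 0.35 * radius_mm)

    series = analytic.sphere_two_electrode_potential(
        centers[sel], radius_mm, float(sigma.sigma[inside][0]),
        anode_mm, cathode_mm, current_mA=1.0)

    # voxel-center FEM potential = corner average
    grid = phi.node_grid()
    corners = vox[sel][:, None, :] + fem.CORNER_OFFSETS[None, :, :]
    fem_phi = grid[corners[..., 0], corners[..., 1], corners[..., 2]].mean(1)

    series = series - series.mean()
    fem_phi = fem_phi - fem_phi.mean()
    rms_err = float(np.sqrt(np.mean((fem_phi - series) ** 2))
                    / np.sqrt(np.mean(series ** 2)))
    return {"sphere_rms_rel_error": rms_err,
            "sphere_n_compared": int(sel.sum()),
            "sphere_iterations": phi.iterations}
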