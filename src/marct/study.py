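"""End-to-end study orchestration.

``run_study`` executes, for each requested metal configuration: phantom
construction, the metal scan and the metal-free scan, MAR correction,
ground-truth substitution, HU-to-density conversion, beam-angle selection
and fluence optimization on the *uncorrected* image for each PTV, dose
recomputation with fixed fluence on uncorrected / corrected / ground-truth
volumes, and metric assembly into a deterministic report.

Seeds: every stochastic stage derives its seed from the master seed by
fixed offsets (configuration index * 1000 + scan kind), so a study is fully
reproducible from ``(config, master_seed)``.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np

from . import dosimetry as dosim
from . import evaluation as ev
from .ct_sim import ScanGeometry, acquire
from .io import RunConfig, sha256_of, write_volume
from .mar import MarConfig, mar_pipeline
from .materials import load_attenuation_table, load_spectrum
from .phantom import (GridSpec, build_phantom, body_mask, configuration_spec,
                      make_ground_truth, metal_slot_mask, ptv_preset)

CONFIG_METALS = {1: "titanium", 2: "cerrobend"}
CONFIG_NAMES = {1: "low_z", 2: "high_z"}


def run_study(config: RunConfig, logger=None) -> dict:
    """Run the full study; returns the report dict (see evaluate_study).

    When ``config.output_dir`` is set, volumes, the report (JSON), the
    accuracy table (CSV) and a manifest with SHA-256 hashes are written
    there.
    """
    log = logger or (lambda *_: None)
    t_start = time.time()
    table = load_attenuation_table()
    spectrum = load_spectrum()
    grid = GridSpec(config.n_xy, config.spacing_mm, config.n_slices,
                    config.slice_thickness_mm)
    geometry = ScanGeometry.for_grid(config.n_xy, config.spacing_mm,
                                     n_views=config.n_views)
    mar_cfg = MarConfig(**config.mar)
    out_dir = Path(config.output_dir) if config.output_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": config.config_hash(), "artifacts": []}

    def save(volume, name):
        if out_dir:
            volume.meta.setdefault("config_hash", config.config_hash())
            path = write_volume(volume, out_dir / f"{name}.nrrd")
            manifest["artifacts"].append(
                {"name": name, "path": path.name, "sha256": sha256_of(path)})

    artifacts: dict = {}
    for cfg_idx in config.configurations:
        metal_name = CONFIG_METALS[cfg_idx]
        config_name = CONFIG_NAMES[cfg_idx]
        seed_scan = config.master_seed + 1000 * cfg_idx
        seed_gt = config.master_seed + 1000 * cfg_idx + 500
        log(f"[{config_name}] acquiring scans (seed {seed_scan})")

        labels = build_phantom(configuration_spec(cfg_idx, grid=grid))
        labels_sw = build_phantom(configuration_spec(3, grid=grid))
        counts, uncorrected = acquire(labels, spectrum, geometry, config.n0,
                                      seed_scan, table)
        _, solid_water_img = acquire(labels_sw, spectrum, geometry, config.n0,
                                     seed_gt, table)
        gt = make_ground_truth(
            solid_water_img, labels,
            [("A", table.material(metal_name)), ("B", table.material(metal_name))],
            table, spectrum.reference_energy_kev)

        log(f"[{config_name}] running MAR")
        mar_cfg_run = MarConfig(**{**config.mar,
                                   "metal_material": metal_name})
        result = mar_pipeline(counts, uncorrected, mar_cfg_run,
                              spectrum=spectrum, table=table,
                              return_diagnostics=True)
        corrected = result.corrected

        metal = metal_slot_mask(labels)
        body = body_mask(labels)
        body_no_metal_mask = body.mask & ~metal.mask \
            & ~result.segmentation.mask.mask
        body_no_metal = ev.StructureMask("body_no_metal", body_no_metal_mask,
                                         body.spacing, body.origin)

        curve = dosim.default_calibration(table, spectrum.reference_energy_kev)
        densities = {
            "uncorrected": dosim.hu_to_density(uncorrected, curve),
            "corrected": dosim.hu_to_density(corrected, curve),
            "gt": dosim.hu_to_density(gt, curve),
        }
        for name, img in (("uncorrected", uncorrected),
                          ("corrected", corrected), ("gt", gt)):
            save(img, f"{config_name}_{name}")

        plans: dict = {}
        for ptv_name in config.ptvs:
            ptv = ptv_preset(ptv_name, uncorrected)
            angles, flag = dosim.select_beam_angles(range(360), metal, ptv)
            log(f"[{config_name}] {ptv_name}: angles {angles} ({flag})")
            plan = dosim.PlanSpec(angles, ptv,
                                  prescription_gy=config.prescription_gy,
                                  beamlet_width_mm=config.beamlet_width_mm,
                                  beam_energy_mev=config.beam_energy_mev)
            fluence = dosim.optimize_fluence(densities["uncorrected"], plan,
                                             table, body=body)
            if out_dir:
                plan_path = out_dir / f"{config_name}_{ptv_name}_plan.txt"
                plan_path.write_text(dosim.fluence_to_text(fluence, plan))
                manifest["artifacts"].append(
                    {"name": plan_path.stem, "path": plan_path.name,
                     "sha256": sha256_of(plan_path)})
            doses = dosim.recompute_plans(
                fluence, plan, densities, table, mode=config.engine,
                seed=config.master_seed + 1000 * cfg_idx,
                histories=config.histories)
            for name, dose in doses.items():
                save(dose, f"{config_name}_{ptv_name}_dose_{name}")
            plans[ptv_name] = {"mask": ptv, "doses": doses,
                               "angles": angles, "flag": flag}

        artifacts[config_name] = {
            "images": {"uncorrected": uncorrected, "corrected": corrected,
                       "gt": gt},
            "body": body_no_metal,
            "body_full": body,
            "plans": plans,
            "provenance": {
                "seed_scan": seed_scan, "seed_gt": seed_gt,
                "metal": metal_name,
                "config_hash": config.config_hash(),
                "segmentation_voxels": int(
                    result.segmentation.mask.voxel_count),
            },
        }

    report = ev.evaluate_study(artifacts)
    report["provenance"] = {
        "master_seed": config.master_seed,
        "config_hash": config.config_hash(),
        "config": config.scientific_dict(),
    }
    report["_artifacts"] = artifacts  # in-memory only, stripped on save

    if out_dir:
        serializable = {k: v for k, v in report.items() if k != "_artifacts"}
        report_path = out_dir / "report.json"
        report_path.write_text(ev.report_to_json(serializable))
        table_path = out_dir / "accuracy_table.csv"
        ev.accuracy_table(report).to_csv(table_path, index=False)
        for path in (report_path, table_path):
            manifest["artifacts"].append(
                {"name": path.stem, "path": path.name,
                 "sha256": sha256_of(path)})
        (out_dir / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True))
    log(f"study complete in {time.time() - t_start:.1f}s")
    return report
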