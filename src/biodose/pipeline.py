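"""End-to-end pipeline: phantom → biological maps → prescription → plan → report.

Stages mirror the planning workflow: FMISO normalization and pO2 conversion,
HTV segmentation, FDG-based (or uniform fallback) clonogen-density mapping,
TCP-targeted ideal dose and its collapse to contour prescriptions, emulated
delivery, and radiobiological/dosimetric evaluation. Any stage failure is
re-raised as a StageError naming the stage.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cellkill import eqd2, tcp
from .config import RunConfig
from .density import normalize_fdg, uniform_density, uptake_to_density
from .errors import StageError
from .evaluation import (characterize_volumes, check_constraints,
                         conformity_homogeneity, dose_at_volume, mean_dose)
from .grid import StructureSet, subtarget_masks
from .oxygen import normalize_fmiso, segment_htv, uptake_to_po2
from .phantom import emulate_plan, generate_phantom
from .prescription import contour_prescription, ideal_dose_map

log = logging.getLogger(__name__)


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise StageError(name, exc) from exc
            log.info("stage %s: done in %.2f s", name, time.perf_counter() - self.t0)
    return _Ctx()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow on a generated phantom; returns the report.

    Deterministic for a given config (the phantom seed is the only source of
    randomness).
    """
    with _stage("phantom"):
        ph = generate_phantom(config.phantom, seed=config.seed,
                              oxy=config.oxygen, cd=config.density)
        structures: StructureSet = ph["structures"]
        grid = structures.grid

    with _stage("oxymap"):
        fmiso_n = normalize_fmiso(ph["fmiso"], structures["muscle"], config.oxygen)
        po2 = uptake_to_po2(fmiso_n, config.oxygen)
        htv = segment_htv(po2, structures["TV2"], config.oxygen)
        structures.add("HTV", htv)

    with _stage("cellmap"):
        if config.use_fdg:
            fdg_n = normalize_fdg(ph["fdg"], structures["muscle"])
            density = uptake_to_density(fdg_n, config.density)
            density_mode = "fdg"
        else:
            fdg_n = None
            density = uniform_density(structures["TV2"], grid, config.density)
            density_mode = "uniform fallback"

    with _stage("prescribe"):
        tv2 = structures["TV2"]
        ideal = ideal_dose_map(density, po2, tv2,
                               config.radiobiology, config.prescription)
        subtargets = subtarget_masks(structures)
        prescriptions = contour_prescription(ideal, subtargets, config.prescription)

    with _stage("emulate"):
        plan = emulate_plan(prescriptions, subtargets, structures["TV1"],
                            grid, config.emulator)

    with _stage("evaluate"):
        n_fx = config.radiobiology.n_fractions
        ab_t = config.fractionation.ab_tumor
        plan_eqd2_t = eqd2(plan, n_fx, ab_t)
        vois = dict(subtargets)
        vois["TV2"] = tv2
        tcp_by_voi, metrics = {}, {}
        for name, mask in vois.items():
            if not mask.any():
                continue
            tcp_by_voi[name] = tcp(plan, density, po2, mask, config.radiobiology)
            metrics[name] = {
                "mean_eqd2_Gy": mean_dose(plan_eqd2_t, mask),
                "d2pct_eqd2_Gy": dose_at_volume(plan_eqd2_t, mask, 0.02),
                "voxels": int(np.count_nonzero(mask)),
            }
        indices = {}
        for p in prescriptions:
            ci, hi = conformity_homogeneity(plan, vois[p.name], p.homogeneous_dose)
            indices[p.name] = {"conformity": ci, "homogeneity": hi}
        constraints = check_constraints(plan, structures, None,
                                        config.fractionation, n_fx)
        fdg_for_bio = fdg_n if fdg_n is not None else ph["fdg"]
        bio = characterize_volumes(po2, fdg_for_bio, tv2, htv)

    report = {
        "schema_version": 1,
        "package_version": __version__,
        "config": config.to_dict(),
        "density_mode": density_mode,
        "prescriptions": [
            {
                "name": p.name,
                "mean_dose_Gy": round(p.mean_dose, 4),
                "sd_dose_Gy": round(p.sd_dose, 4),
                "homogeneous_dose_Gy": round(p.homogeneous_dose, 4),
                "homogeneous_eqd2_Gy": round(
                    eqd2(p.homogeneous_dose, n_fx, ab_t), 4),
                "voxel_count": p.voxel_count,
            }
            for p in prescriptions
        ],
        "tcp": {k: round(v, 6) for k, v in tcp_by_voi.items()},
        "target_metrics": {k: {m: (round(v, 4) if isinstance(v, float) else v)
                               for m, v in d.items()}
                           for k, d in metrics.items()},
        "indices": {k: {m: round(v, 4) for m, v in d.items()}
                    for k, d in indices.items()},
        "constraints": [c.as_dict() for c in constraints],
        "biological_volumes": {k: round(v, 4) for k, v in bio.items()},
    }
    return report


def write_report(report: dict, path) -> None:
    """Write the report as JSON, with a CSV twin of the tabular fields."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")

    rows = []
    for name, val in report.get("tcp", {}).items():
        rows.append({"section": "tcp", "structure": name, "metric": "TCP",
                     "value": val})
    for name, d in report.get("target_metrics", {}).items():
        for m, v in d.items():
            rows.append({"section": "target_metrics", "structure": name,
                         "metric": m, "value": v})
    for c in report.get("constraints", []):
        rows.append({"section": "constraints",
                     "structure": f"{c['structure']}:{c['metric']}",
                     "metric": f"limit {c['limit_Gy']} Gy",
                     "value": "NA" if c["value_Gy"] is None else c["value_Gy"]})
    for k, v in report.get("biological_volumes", {}).items():
        rows.append({"section": "biological_volumes", "structure": "TV2",
                     "metric": k, "value": v})
    pd.DataFrame(rows).to_csv(path.with_suffix(".csv"), index=False)
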