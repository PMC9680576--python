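"""End-to-end run: phantom -> DRRs -> aperture search -> plan -> delivery
simulation -> error summary, with per-stage logging and artifacts written
under a run directory stamped with the config hash."""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import io as bio
from .apertures import build_imaging_plan
from .config import RunConfig
from .motion import (
    DeliveryConfig,
    evaluate_errors,
    make_motion_trace,
    simulate_delivery,
)
from .phantom import generate_skull_phantom, remove_bb_region
from .projection import control_points_from_arcs

log = logging.getLogger("bevroi")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: RunConfig, outdir, save_volumes: bool = False) -> dict:
    """Execute the full workflow; returns the summary dict (also written
    to ``summary.json``).  Partial outputs are preserved on failure."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    config.to_yaml(outdir / "config.yaml")
    summary: dict = {"config_hash": chash}

    def stage(name):
        log.info("stage %s ...", name)
        return time.time()

    try:
        t0 = stage("phantom")
        volume = generate_skull_phantom(config.phantom)
        reference = remove_bb_region(volume, fill_hu=config.phantom.fill_hu)
        if save_volumes:
            bio.save_volume(volume, outdir / "phantom.nii.gz")
        log.info("stage phantom done in %.1fs (shape %s)", time.time() - t0, volume.shape)
    except Exception as exc:  # noqa: BLE001
        raise StageError("phantom", exc) from exc

    try:
        t0 = stage("control_points")
        cps = control_points_from_arcs(
            config.arcs, panel_pitch_mm=config.detector.panel_pitch_mm
        )
        summary["n_control_points"] = len(cps)
        log.info("%d control points", len(cps))
    except Exception as exc:  # noqa: BLE001
        raise StageError("control_points", exc) from exc

    try:
        t0 = stage("plan")
        plan = build_imaging_plan(
            cps,
            reference,
            config.threshold,
            config.search,
            detector_px=config.detector.pixels,
            mu_water=config.mu_water,
            progress=lambda i, n: log.info("  control point %d/%d", i + 1, n),
        )
        plan.provenance["config_hash"] = chash
        (outdir / "plan.json").write_text(plan.to_json())
        log.info("stage plan done in %.1fs", time.time() - t0)
    except Exception as exc:  # noqa: BLE001
        raise StageError("plan", exc) from exc

    try:
        t0 = stage("simulate")
        trace = make_motion_trace(
            config.trace.kind, config.trace.magnitude_mm, cps, config.trace.onset
        )
        dconf = DeliveryConfig(
            detector_px=config.detector.pixels,
            mu_water=config.mu_water,
            bound_mm=config.registration.bound_mm,
            bins=config.registration.bins,
            seed=config.seed,
        )
        rec_bb = simulate_delivery(volume, plan, trace, "bb", dconf)
        rec_an = simulate_delivery(
            volume, plan, trace, "anatomy", dconf, reference_volume=reference
        )
        rows = []
        for r, method in [(x, "bb") for x in rec_bb] + [(x, "anatomy") for x in rec_an]:
            rows.append(
                {
                    "control_point": r.index,
                    "gantry": r.geometry.gantry_deg,
                    "couch": r.geometry.couch_deg,
                    "method": method,
                    "dx_mm": r.bev_mm[0],
                    "dy_mm": r.bev_mm[1],
                    "dLat_mm": r.shift.lat_mm,
                    "dLng_mm": r.shift.lng_mm,
                    "dVrt_mm": r.shift.vrt_mm,
                    "ok": r.ok,
                    "note": r.note,
                }
            )
        pd.DataFrame(rows).to_csv(outdir / "delivery.csv", index=False)
        log.info("stage simulate done in %.1fs", time.time() - t0)
    except Exception as exc:  # noqa: BLE001
        raise StageError("simulate", exc) from exc

    try:
        stage("evaluate")
        es = evaluate_errors(rec_an, rec_bb)
        summary.update(
            {
                "trace": config.trace.kind,
                "threshold": config.threshold,
                "median_3d_error_mm": es.median_3d_mm,
                "mean_3d_error_mm": es.mean_3d_mm,
                "median_2d_error_mm": es.median_2d_mm,
                "frac_2d_lt_1mm": es.frac_2d_lt_1mm,
                "n_points": es.n_points,
                "n_flagged": es.n_flagged,
            }
        )
        (outdir / "summary.json").write_text(
            json.dumps(summary, indent=1, sort_keys=True)
        )
    except Exception as exc:  # noqa: BLE001
        raise StageError("evaluate", exc) from exc

    return summary
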