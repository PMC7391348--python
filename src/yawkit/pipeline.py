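"""End-to-end pipeline: calibrate → derive → metrics → turns → dives → stats.

Each stage logs rows in/out; a JSON manifest records the config hash,
package/library versions, seed and per-stage row counts.  The manifest and
all outputs are deterministic for a fixed config and seed (no wall-clock
content), so reruns are byte-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .dive_segmentation import (
    association_stats,
    classify_flat_u,
    detect_dives,
    dives_to_frame,
    per_dive_summary,
)
from .errors import ConfigError, YawkitError
from .logger_io import read_tag_csv, write_metrics_csv
from .magcal import EllipsoidFit, fit_ellipsoid
from .rotation_metrics import compute_metrics
from .turn_analysis import cuhe, turn_coverage

logger = logging.getLogger(__name__)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage on every configured input; returns the manifest dict."""
    if not config.inputs:
        raise ConfigError("no inputs configured")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: list[dict] = []
    all_dives = []

    def record(stage, rows_in, rows_out):
        logger.info("stage %-10s rows in=%d out=%d", stage, rows_in, rows_out)
        stages.append({"stage": stage, "rows_in": int(rows_in), "rows_out": int(rows_out)})

    for item in config.inputs:
        animal = item.get("animal_id", Path(item["raw"]).stem)
        try:
            raw = read_tag_csv(
                item["raw"], schema=config.schema, rate_hz=config.rate_hz, animal_id=animal
            )

            # -- calibrate ----------------------------------------------------
            if item.get("cal"):
                cal = read_tag_csv(item["cal"], schema=config.schema, rate_hz=config.rate_hz)
                fit = fit_ellipsoid(cal.mag)
            else:
                fit = EllipsoidFit.identity(
                    mean_radius=float(np.median(np.linalg.norm(raw.mag, axis=1)))
                )
            (out / f"{animal}.fit.json").write_text(fit.to_json())
            record("calibrate", len(raw), len(raw))

            # -- derive + metrics ---------------------------------------------
            metrics = compute_metrics(
                raw,
                fit=fit,
                window_s=config.window_s,
                subsample_n=config.subsample_n,
                scales=config.avey_scales,
            )
            record("derive", len(raw), len(metrics))
            write_metrics_csv(metrics, out / f"{animal}.metrics.csv")
            record("metrics", len(metrics), len(metrics))

            # -- turns + CuHe -------------------------------------------------
            turns = {
                thr: turn_coverage(
                    metrics.t, metrics.avey_1, thr, reset=config.turn_reset
                )
                for thr in config.turn_thresholds
            }
            ch = cuhe(metrics.t, metrics.heading, bin_deg=config.cuhe_bin_deg)
            turn_frame = pd.DataFrame({"time": metrics.t})
            for thr, cov in turns.items():
                turn_frame[f"percent_{int(thr)}"] = cov.percent
                turn_frame[f"events_{int(thr)}"] = cov.events
            turn_frame["cuhe_percent"] = ch.percent
            turn_frame["cuhe_revolutions"] = ch.revolutions
            write_metrics_csv(turn_frame, out / f"{animal}.turns.csv")
            record("turns", len(metrics), len(turn_frame))

            # -- dives --------------------------------------------------------
            sub_depth = None if raw.depth is None else raw.depth[:: config.subsample_n]
            dives = []
            if sub_depth is not None:
                dives = detect_dives(
                    metrics.t,
                    sub_depth,
                    surface_threshold=config.surface_threshold_m,
                    min_depth=config.min_depth_m,
                    bottom_fraction=config.bottom_fraction,
                    animal_id=animal,
                )
                for dv in dives:
                    classify_flat_u(
                        dv,
                        flatness_max=config.flatness_max,
                        min_bottom_s=config.min_bottom_s,
                    )
                dives = [
                    d
                    for d in dives
                    if d.is_flat_u and per_dive_summary(d, metrics, turns, ch) is not None
                ]
            record("dives", len(metrics), len(dives))
            all_dives.extend(dives)
        except YawkitError as exc:
            raise YawkitError(f"stage failed for input {animal!r}: {exc}") from exc

    dive_frame = dives_to_frame(all_dives)
    write_metrics_csv(dive_frame, out / "dives.csv")

    # -- stats (needs enough animals/dives; otherwise recorded as skipped) -----
    stats_result = None
    try:
        report = association_stats(dive_frame)
        stats_result = report.to_dict()
        (out / "stats.json").write_text(json.dumps(stats_result, indent=2))
        record("stats", len(dive_frame), 1)
    except ValueError as exc:
        logger.warning("stats stage skipped: %s", exc)
        record("stats", len(dive_frame), 0)
        stats_result = {"skipped": str(exc)}

    manifest = {
        "yawkit_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "seed": config.seed,
        "stages": stages,
        "n_dives": len(all_dives),
        "stats": stats_result,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
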