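"""End-to-end pipeline: simulate/load -> label -> trim -> bin -> model -> Δgaze.

Every stage writes its table under the run's output directory, and a manifest
records the configuration hash, seed, per-stage row counts and trim
percentages.  Identical configurations produce identical manifests (and
byte-identical tables), which is the package's reproducibility contract.
"""

from __future__ import annotations

import logging

import pandas as pd

from . import aoi, delta, io, models, preprocess, simulate

log = logging.getLogger(__name__)

STAGES = ("acquire", "label", "trim", "bin", "model", "delta")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: io.RunConfig) -> dict:
    """Execute the full pipeline and return the run manifest."""
    from pathlib import Path

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": config.hash(), "seed": config.seed,
                      "stages": {}, "trim": {}}

    # -- acquire ----------------------------------------------------------
    stage = "acquire"
    try:
        if config.simulation is not None:
            sim = config.simulation.replace(seed=config.seed)
            trials, gaze = simulate.simulate_study(sim)
            viewports = sim.viewports()
        else:
            gaze = io.read_gaze_table(config.gaze_path)
            trials = io.read_trial_table(config.trials_path)
            viewports = (io.read_viewport_table(config.viewports_path)
                         if config.viewports_path else None)
        io.write_table(trials, out / "trials.csv")
        manifest["stages"][stage] = {"trials": len(trials), "gaze": len(gaze)}
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # -- label ------------------------------------------------------------
    stage = "label"
    try:
        labeled = aoi.label_stream(gaze, trials, viewports)
        manifest["stages"][stage] = {
            "samples": len(labeled),
            "discarded": int(labeled["discarded"].sum()),
        }
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # -- trim -------------------------------------------------------------
    stage = "trim"
    try:
        if config.trim_timestamps:
            labeled, ts_report = preprocess.trim_timestamps(labeled)
        else:
            ts_report = {"n_input": len(labeled), "n_removed": 0,
                         "fraction_removed": 0.0}
        if config.trim_rts:
            trials_trimmed, rt_report = preprocess.trim_rts(trials)
        else:
            trials_trimmed, rt_report = trials, {
                "n_input": len(trials), "n_removed": 0,
                "fraction_removed": 0.0}
        manifest["trim"] = {"timestamps": ts_report, "rts": rt_report}
        manifest["stages"][stage] = {"samples": len(labeled),
                                     "trials": len(trials_trimmed)}
        log.info("trimmed %.1f%% of the eye data, %.1f%% of the RT data",
                 100 * ts_report["fraction_removed"],
                 100 * rt_report["fraction_removed"])
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # -- bin --------------------------------------------------------------
    stage = "bin"
    try:
        bincells = preprocess.bin_gaze(
            labeled, trials, bin_width_ms=config.bin_width_ms,
            window_ms=config.window_ms, denominator=config.denominator)
        io.write_table(bincells, out / "bincells.csv")
        manifest["stages"][stage] = {"cells": len(bincells)}
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # -- model ------------------------------------------------------------
    stage = "model"
    try:
        analysis = bincells[bincells["structure"] != "filler"]
        pwa_trials = trials[trials["group"] == "pwa"]
        fits: dict = {}
        if pwa_trials["accurate"].nunique() > 1:
            fits["accuracy"] = models.fit_accuracy(
                pwa_trials, random_effects=config.random_effects)
        rt_ready = preprocess.transform_rt(
            trials_trimmed[trials_trimmed["structure"] != "filler"])
        fits["rt"] = models.fit_rt(rt_ready,
                                   random_effects=config.random_effects)
        bw = models.BinwiseGazeModel(factors=("group", "modality")).fit(analysis)
        contr = models.binwise_contrasts(bw, factor="group",
                                         a="pwa", b="control")
        io.write_table(contr, out / "contrasts_group.csv")
        for name, fit in fits.items():
            io.write_table(fit.table, out / f"model_{name}.csv")
        windows = models.significant_windows(contr)
        io.write_table(windows, out / "windows_group.csv")
        manifest["stages"][stage] = {
            "models": sorted(fits) + ["binwise"],
            "gaze_dispersion": bw.dispersion_,
        }
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # -- delta ------------------------------------------------------------
    stage = "delta"
    try:
        dseries = delta.compute_delta(analysis)
        io.write_table(dseries, out / "delta.csv")
        dfit = delta.fit_delta_model(dseries)
        io.write_table(dfit.table, out / "model_delta.csv")
        report = delta.lag_report(dseries, bin_width_ms=config.bin_width_ms,
                                  max_lag_bins=config.max_lag_bins)
        (out / "lag_report.txt").write_text(report + "\n", encoding="utf-8")
        est = delta.estimate_lag(delta.delta_series(dseries, "lab"),
                                 delta.delta_series(dseries, "web"),
                                 method=config.lag_method,
                                 max_lag_bins=config.max_lag_bins,
                                 bin_width_ms=config.bin_width_ms)
        manifest["stages"][stage] = {"cells": len(dseries),
                                     "lag_method": est.method,
                                     "lag_ms": est.lag_ms}
    except Exception as exc:
        raise StageError(stage, exc) from exc

    manifest["n_stages_completed"] = len(manifest["stages"])
    io.write_manifest(manifest, out / "manifest.json")
    return manifest
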