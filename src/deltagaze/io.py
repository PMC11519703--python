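"""Readers, writers, and run configuration.

All tables are plain comma-separated text with a header row (UTF-8).  Readers
validate mandatory columns by name, coerce numeric columns, and report
malformed rows by file line number; unknown columns are preserved.  The run
configuration round-trips losslessly through YAML, and a manifest records the
configuration hash, seed, and per-stage row counts so that byte-identical
reruns can be verified.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .simulate import SimulationConfig

GAZE_COLUMNS = ("participant", "modality", "trial_id", "t_ms")
TRIAL_COLUMNS = ("participant", "group", "modality", "trial_id", "structure",
                 "target_side", "disamb_ms", "rt_ms", "accurate")
VIEWPORT_COLUMNS = ("participant", "width_px", "height_px")
BIN_COLUMNS = ("participant", "modality", "trial_id", "bin",
               "n_target", "n_foil", "n", "proportion")


def _validate(df: pd.DataFrame, mandatory, numeric, path) -> pd.DataFrame:
    missing = [c for c in mandatory if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s) {missing}")
    for col in numeric:
        if col not in df.columns:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            lines = (df.index[bad] + 2).tolist()[:10]  # +2: header + 1-based
            raise ValueError(
                f"{path}: malformed numeric value(s) in column {col!r} "
                f"at line(s) {lines}")
        df[col] = coerced
    return df


def read_gaze_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    return _validate(df, GAZE_COLUMNS, ("t_ms", "x_px", "y_px"), path)


def read_trial_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df = _validate(df, TRIAL_COLUMNS, ("disamb_ms", "rt_ms"), path)
    if df["accurate"].dtype == object:
        df["accurate"] = df["accurate"].map(
            {"True": True, "False": False, "1": True, "0": False}).astype(bool)
    else:
        df["accurate"] = df["accurate"].astype(bool)
    return df


def read_viewport_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    return _validate(df, VIEWPORT_COLUMNS, ("width_px", "height_px"), path)


def read_bin_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    return _validate(df, BIN_COLUMNS,
                     ("bin", "n_target", "n_foil", "n", "proportion",
                      "rel_bin", "disamb_ms"), path)


def write_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, encoding="utf-8", lineterminator="\n",
              float_format="%.6g")
    return path


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Everything a reproducible pipeline run needs."""

    simulation: SimulationConfig | None = None
    gaze_path: str | None = None
    trials_path: str | None = None
    viewports_path: str | None = None
    out_dir: str = "out"
    bin_width_ms: float = 100.0
    window_ms: tuple = (0.0, 12000.0)
    trim_timestamps: bool = True
    trim_rts: bool = True
    denominator: str = "aoi_only"
    lag_method: str = "xcorr"
    max_lag_bins: int = 20
    random_effects: bool = True
    seed: int = 0
    verbosity: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["window_ms"] = list(d["window_ms"])
        if self.simulation is not None:
            d["simulation"] = self.simulation.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("simulation") is not None:
            d["simulation"] = SimulationConfig.from_dict(d["simulation"])
        if "window_ms" in d:
            d["window_ms"] = tuple(d["window_ms"])
        return cls(**d)

    def hash(self) -> str:
        """Hash of the analysis-relevant configuration (where outputs go and
        how chatty the log is do not change the result)."""
        d = self.to_dict()
        d.pop("out_dir", None)
        d.pop("verbosity", None)
        payload = json.dumps(d, sort_keys=True, default=float)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_config(config: RunConfig | SimulationConfig, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(config.to_dict(), sort_keys=True),
                    encoding="utf-8")
    return path


def read_config(path) -> RunConfig:
    d = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    return RunConfig.from_dict(d)


def read_simulation_config(path) -> SimulationConfig:
    d = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    return SimulationConfig.from_dict(d)


def write_manifest(manifest: dict, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True,
                               default=str) + "\n", encoding="utf-8")
    return path
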