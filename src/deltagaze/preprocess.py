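"""Trimming rules and 100-ms binning of labeled gaze streams.

Three cleaning rules precede modeling:

* **Timestamp trim** — within each trial, gaze estimations whose timestamp
  lies more than two sample standard deviations (n−1 denominator) from the
  trial's mean timestamp are removed; trials with fewer than three samples or
  zero spread pass through untouched.
* **RT trim** — inaccurate trials are dropped, then, within each participant
  and session (one modality visit), trials whose reaction time lies more than
  two SDs from the session mean.  Accuracy itself is never trimmed.
* **Binning** — surviving target/foil samples are counted into half-open
  100-ms bins over the 0–12,000 ms trial window and converted to a per-trial,
  per-bin target proportion; bins with no target/foil samples are removed.
  ``none``-labeled samples are excluded from the denominator by default
  (they are "discarded"), with an ``"all"`` switch that counts them.

Each trim is applied exactly once: the rules are not idempotent (re-trimming
trimmed data can remove more), so a provenance flag in ``DataFrame.attrs``
guards against double application.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

log = logging.getLogger(__name__)

TRIAL_KEY = ["participant", "modality", "trial_id"]


def _two_sd_keep(values: pd.Series, by: pd.core.groupby.SeriesGroupBy) -> pd.Series:
    """Keep-mask for the two-sample-SD rule within each group.

    Groups with fewer than 3 values or zero spread are kept whole (the SD is
    undefined or degenerate there).
    """
    mean = by.transform("mean")
    sd = by.transform("std")  # ddof=1
    n = by.transform("size")
    return (n < 3) | sd.isna() | (sd == 0) | ((values - mean).abs() <= 2.0 * sd)


def trim_timestamps(samples: pd.DataFrame, group_cols=TRIAL_KEY):
    """Apply the per-trial 2-SD timestamp trim.

    Returns ``(filtered, report)`` where ``report`` maps ``n_input``,
    ``n_removed``, ``fraction_removed``.
    """
    if samples.attrs.get("timestamps_trimmed"):
        raise ValueError("timestamp trim already applied to this table")
    by = samples.groupby([c for c in group_cols if c in samples.columns],
                         observed=True)["t_ms"]
    keep = _two_sd_keep(samples["t_ms"], by)
    out = samples[keep].copy()
    out.attrs["timestamps_trimmed"] = True
    report = {
        "n_input": int(len(samples)),
        "n_removed": int((~keep).sum()),
        "fraction_removed": float((~keep).mean()) if len(samples) else 0.0,
    }
    log.info("timestamp trim removed %.1f%% of the eye data",
             100.0 * report["fraction_removed"])
    return out, report


def trim_rts(trials: pd.DataFrame, session_cols=("participant", "modality")):
    """Drop inaccurate trials, then 2-SD RT outliers per participant-session.

    Returns ``(filtered, report)``; the report distinguishes the two steps
    and gives the overall removed fraction.  Participants who lose every
    trial to step 1 are logged as a warning.
    """
    if trials.attrs.get("rts_trimmed"):
        raise ValueError("RT trim already applied to this table")
    n_input = len(trials)
    accurate = trials[trials["accurate"].astype(bool)].copy()
    exhausted = set(trials["participant"].unique()) - set(
        accurate["participant"].unique())
    if exhausted:
        log.warning("participants lost all trials to the accuracy filter: %s",
                    sorted(exhausted))

    by = accurate.groupby(list(session_cols), observed=True)["rt_ms"]
    keep = _two_sd_keep(accurate["rt_ms"], by)
    out = accurate[keep].copy()
    out.attrs["rts_trimmed"] = True
    report = {
        "n_input": int(n_input),
        "n_inaccurate_removed": int(n_input - len(accurate)),
        "n_outlier_removed": int((~keep).sum()),
        "n_removed": int(n_input - len(out)),
        "fraction_removed": float((n_input - len(out)) / n_input) if n_input else 0.0,
    }
    log.info("RT trim removed %.1f%% of the RT data "
             "(including outliers and incorrect trials)",
             100.0 * report["fraction_removed"])
    return out, report


def transform_rt(trials: pd.DataFrame) -> pd.DataFrame:
    """Add a ``sqrt_rt`` column (square root of RT in ms) for normality."""
    if (trials["rt_ms"] <= 0).any():
        raise ValueError("nonpositive RT encountered; RTs must be > 0")
    out = trials.copy()
    out["sqrt_rt"] = np.sqrt(out["rt_ms"].to_numpy(dtype=float))
    return out


def bin_gaze(
    labeled: pd.DataFrame,
    trials: pd.DataFrame,
    bin_width_ms: float = 100.0,
    window_ms: tuple = (0.0, 12000.0),
    denominator: str = "aoi_only",
) -> pd.DataFrame:
    """Count labeled samples into time bins and compute target proportions.

    Bin ``k`` covers ``[window_start + k*width, window_start + (k+1)*width)``;
    the default window and width give bins 0–100 through 11,900–12,000 ms
    (120 bins).  ``rel_bin`` re-indexes each bin relative to the bin holding
    the trial's disambiguation point.

    Parameters
    ----------
    labeled
        Gaze table carrying a ``label`` column in {target, foil, none}.
    trials
        Trial table supplying group/structure/target-side/disambiguation.
    denominator
        ``"aoi_only"`` (default): proportion = target / (target + foil),
        bins with no target/foil samples removed.  ``"all"``: none-labeled
        samples count in the denominator.

    Returns
    -------
    BinCell table: one row per (participant, modality, trial, bin) with
    counts, ``proportion`` and ``rel_bin``.
    """
    w0, w1 = float(window_ms[0]), float(window_ms[1])
    width = float(bin_width_ms)
    if width <= 0 or (w1 - w0) <= 0:
        raise ValueError("window and bin width must be positive")
    n_bins = (w1 - w0) / width
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError(
            f"bin width {width} does not evenly divide window {window_ms}")
    if denominator not in ("aoi_only", "all"):
        raise ValueError("denominator must be 'aoi_only' or 'all'")

    df = labeled[(labeled["t_ms"] >= w0) & (labeled["t_ms"] < w1)].copy()
    df["bin"] = ((df["t_ms"].to_numpy(float) - w0) // width).astype(np.int64)

    counts = (
        df.groupby(TRIAL_KEY + ["bin"], observed=True)["label"]
        .value_counts()
        .unstack("label", fill_value=0)
        .reindex(columns=["target", "foil", "none"], fill_value=0)
        .rename(columns={"target": "n_target", "foil": "n_foil", "none": "n_none"})
        .reset_index()
    )
    counts.columns.name = None

    if denominator == "aoi_only":
        counts["n"] = counts["n_target"] + counts["n_foil"]
    else:
        counts["n"] = counts["n_target"] + counts["n_foil"] + counts["n_none"]
    counts = counts[counts["n"] > 0].copy()
    counts["proportion"] = counts["n_target"] / counts["n"]

    meta_cols = [c for c in ("group", "structure", "target_side", "disamb_ms")
                 if c in trials.columns]
    meta = trials[TRIAL_KEY + meta_cols].drop_duplicates(TRIAL_KEY)
    merged = counts.merge(meta, on=TRIAL_KEY, how="left", validate="m:1")
    if "disamb_ms" in merged.columns:
        missing = merged["disamb_ms"].isna()
        if missing.any():
            bad = merged.loc[missing, TRIAL_KEY].drop_duplicates().head(10)
            raise KeyError(
                f"binned cells reference trials absent from the trial table:\n{bad}")
        disamb_bin = ((merged["disamb_ms"].to_numpy(float) - w0) // width).astype(
            np.int64)
        merged["rel_bin"] = merged["bin"].to_numpy() - disamb_bin
    return merged


# ---------------------------------------------------------------------------
# sklearn-style facades


class TimestampTrimmer(TransformerMixin, BaseEstimator):
    """Transformer wrapping :func:`trim_timestamps`; report in ``report_``."""

    def __init__(self, group_cols=tuple(TRIAL_KEY)):
        self.group_cols = group_cols

    def fit(self, X, y=None):
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        out, self.report_ = trim_timestamps(X, group_cols=list(self.group_cols))
        return out


class RTTrimmer(TransformerMixin, BaseEstimator):
    """Transformer wrapping :func:`trim_rts`; report in ``report_``."""

    def __init__(self, session_cols=("participant", "modality")):
        self.session_cols = session_cols

    def fit(self, X, y=None):
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        out, self.report_ = trim_rts(X, session_cols=self.session_cols)
        return out


class GazeBinner(TransformerMixin, BaseEstimator):
    """Transformer wrapping :func:`bin_gaze` against a fixed trial table."""

    def __init__(self, trials=None, bin_width_ms=100.0,
                 window_ms=(0.0, 12000.0), denominator="aoi_only"):
        self.trials = trials
        self.bin_width_ms = bin_width_ms
        self.window_ms = window_ms
        self.denominator = denominator

    def fit(self, X, y=None):
        if self.trials is None:
            raise ValueError("GazeBinner requires a trial table")
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        self.fit(X)
        return bin_gaze(X, self.trials, self.bin_width_ms,
                        self.window_ms, self.denominator)
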