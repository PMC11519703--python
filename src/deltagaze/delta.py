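"""Δgaze: control-minus-PWA difference series and web-vs-lab lag estimation.

For each time bin, structure type, and tracking modality, the mean target
gaze proportion of the PWA group is subtracted from the control group's mean,
yielding a difference series (Δgaze) whose shape isolates the *timing* of
group effects: if the webcam stream reports gaze late, the web Δgaze curve is
a time-shifted copy of the lab curve, and the shift is the recording lag.

Three lag estimators are provided: the peak and dip locations of the two
curves (the field's narrated comparison — "Δgaze on the web peaked around
bin 45 whereas lab differences peaked around 3800 ms"), and, as a more
robust extension, the lag maximizing the normalized cross-correlation of the
two series over a bounded search window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


def compute_delta(
    bincells: pd.DataFrame,
    by: tuple = ("structure", "modality"),
    participant_mean_first: bool = False,
    exclude_structures: tuple = ("filler",),
    min_cells: int = 5,
) -> pd.DataFrame:
    """Per-(bin, structure, modality) control − PWA mean proportion.

    Trial-level bin proportions are averaged within each group with equal
    weight per trial cell (``participant_mean_first=True`` averages within
    participants first, then across them).  Cells where either group is
    missing — or, with ``min_cells`` > 1, where either group mean rests on
    fewer than ``min_cells`` trial cells, as happens in late bins once most
    trials have ended — are omitted with a log entry; a modality entirely
    missing one group raises.

    Returns columns ``bin``, *by*, ``delta``, ``n_control_cells``,
    ``n_pwa_cells``.
    """
    df = bincells[~bincells["structure"].isin(exclude_structures)].copy()
    for mod in df["modality"].unique():
        groups = set(df.loc[df["modality"] == mod, "group"].unique())
        if not {"control", "pwa"} <= groups:
            raise ValueError(
                f"modality {mod!r} lacks one group entirely: has {sorted(groups)}")

    keys = ["bin", *by]
    if participant_mean_first:
        per_part = df.groupby(keys + ["group", "participant"], observed=True)[
            "proportion"].mean().reset_index()
        g = per_part.groupby(keys + ["group"], observed=True)["proportion"]
    else:
        g = df.groupby(keys + ["group"], observed=True)["proportion"]
    stats_ = g.agg(["mean", "size"]).reset_index()
    wide = stats_.pivot_table(index=keys, columns="group",
                              values=["mean", "size"], observed=True)
    have_both = (
        (wide[("size", "control")].fillna(0) >= max(min_cells, 1))
        & (wide[("size", "pwa")].fillna(0) >= max(min_cells, 1))
    )
    n_dropped = int((~have_both).sum())
    if n_dropped:
        log.info("Δgaze: dropped %d cells missing one group or with fewer "
                 "than %d trial cells", n_dropped, min_cells)
    wide = wide[have_both]
    out = wide.index.to_frame(index=False)
    out["delta"] = (wide[("mean", "control")] - wide[("mean", "pwa")]).to_numpy()
    out["n_control_cells"] = wide[("size", "control")].to_numpy(int)
    out["n_pwa_cells"] = wide[("size", "pwa")].to_numpy(int)
    return out.sort_values(keys).reset_index(drop=True)


def delta_series(delta: pd.DataFrame, modality: str,
                 structure: str | None = None) -> pd.Series:
    """Extract one Δgaze series (indexed by bin) for a modality.

    Without ``structure`` the per-structure deltas are averaged per bin.
    """
    df = delta[delta["modality"] == modality]
    if structure is not None:
        df = df[df["structure"] == structure]
    if df.empty:
        raise ValueError(f"no Δgaze cells for modality {modality!r}")
    return df.groupby("bin")["delta"].mean().sort_index()


def fit_delta_model(delta: pd.DataFrame):
    """Linear regression of Δgaze on bin x modality (bin numeric).

    The Δgaze points are averages, so the model is deliberately fit without
    random effects; serial correlation across bins is not modeled (a caveat
    for interpreting its p-values).  Returns a :class:`~.models.ModelFit`
    whose key term is the ``bin : modality`` interaction — a positive
    web-vs-lab interaction means group differences persist later on the web.
    """
    import statsmodels.formula.api as smf

    from .models import ModelFit, _coef_table

    if delta.groupby("modality", observed=True)["bin"].nunique().min() < 2:
        raise ValueError("Δgaze model needs at least 2 bins per modality")
    if float(delta["delta"].std(ddof=0)) == 0.0:
        log.warning("constant Δgaze series: slopes will be exactly 0")
    res = smf.ols("delta ~ bin * C(modality)", delta).fit()
    table = _coef_table(res.params.index, res.params.to_numpy(),
                        res.bse.to_numpy(), res.df_resid)
    return ModelFit(table=table, method="delta-ols", n_obs=int(res.nobs),
                    extra={"r2": float(res.rsquared)})


# ---------------------------------------------------------------------------
# lag estimation


@dataclass
class LagEstimate:
    """A web-vs-lab lag estimate: positive = web lags the lab."""

    method: str
    lag_bins: int
    lag_ms: float
    diagnostics: dict = field(default_factory=dict)


def _align(lab: pd.Series, web: pd.Series) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Put both series on the common integer bin grid, linearly
    interpolating missing interior bins.  Bins outside a series' own support
    are NaN — never extrapolated."""
    lo = int(min(lab.index.min(), web.index.min()))
    hi = int(max(lab.index.max(), web.index.max()))
    grid = np.arange(lo, hi + 1)

    def interp(s: pd.Series) -> np.ndarray:
        s = s.sort_index()
        idx = s.index.to_numpy(float)
        v = np.interp(grid, idx, s.to_numpy(float))
        v[(grid < idx.min()) | (grid > idx.max())] = np.nan
        return v

    return grid, interp(lab), interp(web)


def _xcorr_profile(lab: np.ndarray, web: np.ndarray, max_lag: int):
    """Normalized cross-correlation of the overlapping segments per lag."""
    lags = np.arange(-max_lag, max_lag + 1)
    r = np.full(lags.shape, np.nan)
    n = len(lab)
    for i, k in enumerate(lags):
        if k >= 0:
            a, b = web[k:], lab[: n - k]
        else:
            a, b = web[: n + k], lab[-k:]
        ok = np.isfinite(a) & np.isfinite(b)
        if ok.sum() < 5:
            continue
        a = a[ok] - a[ok].mean()
        b = b[ok] - b[ok].mean()
        denom = np.sqrt(np.sum(a * a) * np.sum(b * b))
        if denom > 0:
            r[i] = np.sum(a * b) / denom
    return lags, r


def _smooth(x: np.ndarray, window: int = 3) -> np.ndarray:
    kernel = np.ones(window) / window
    pad = window // 2
    xp = np.pad(x, pad, mode="edge")
    return np.convolve(xp, kernel, mode="valid")


def estimate_lag(
    lab: pd.Series,
    web: pd.Series,
    method: str = "xcorr",
    max_lag_bins: int = 20,
    bin_width_ms: float = 100.0,
    smooth: bool = False,
) -> LagEstimate:
    """Estimate the web-vs-lab temporal lag between two Δgaze series.

    Parameters
    ----------
    lab, web
        Δgaze values indexed by integer bin (see :func:`delta_series`).
    method
        ``"peak"``: lag = argmax(web) − argmax(lab), ties broken toward the
        earliest bin.  ``"dip"``: the same with argmin.  ``"xcorr"``: the lag
        maximizing the normalized cross-correlation over ±``max_lag_bins``,
        ties broken toward the smallest |lag|.
    smooth
        Apply a centered 3-bin moving average before locating peaks/dips
        (off by default; peaks are read from the raw series).
    """
    for name, s in (("lab", lab), ("web", web)):
        if len(s) < 5:
            raise ValueError(f"series too short: {name} has {len(s)} bins (< 5)")
    grid, lab_v, web_v = _align(lab, web)
    if smooth:
        lab_v, web_v = _smooth(lab_v), _smooth(web_v)

    diagnostics: dict = {"grid": grid}
    if method in ("peak", "dip"):
        pick = np.nanargmax if method == "peak" else np.nanargmin
        i_lab = int(pick(lab_v))  # argmax/argmin return the earliest tie
        i_web = int(pick(web_v))
        lag = int(grid[i_web] - grid[i_lab])
        diagnostics.update({"lab_bin": int(grid[i_lab]),
                            "web_bin": int(grid[i_web])})
    elif method == "xcorr":
        lags, r = _xcorr_profile(lab_v, web_v, max_lag_bins)
        if np.all(np.isnan(r)):
            raise ValueError("no lag with sufficient overlap")
        best = np.nanmax(r)
        cand = lags[np.isclose(r, best, rtol=0, atol=1e-12)]
        lag = int(cand[np.lexsort((cand, np.abs(cand)))][0])
        diagnostics.update({"lags": lags, "correlation": r})
    else:
        raise ValueError(f"unknown method {method!r}")
    return LagEstimate(method=method, lag_bins=lag,
                       lag_ms=lag * bin_width_ms, diagnostics=diagnostics)


def lag_report(delta: pd.DataFrame, methods=("peak", "dip", "xcorr"),
               bin_width_ms: float = 100.0, max_lag_bins: int = 20) -> str:
    """Plain-text summary of peak/dip bins and lag per method."""
    lab = delta_series(delta, "lab")
    web = delta_series(delta, "web")
    lines = ["Δgaze lag summary (positive lag = web later than lab)", ""]
    for mod, s in (("lab", lab), ("web", web)):
        pk, dp = int(s.idxmax()), int(s.idxmin())
        lines.append(
            f"  {mod}: peak bin {pk} ({pk * bin_width_ms:.0f}-"
            f"{(pk + 1) * bin_width_ms:.0f} ms), dip bin {dp} "
            f"({dp * bin_width_ms:.0f}-{(dp + 1) * bin_width_ms:.0f} ms)")
    lines.append("")
    for method in methods:
        est = estimate_lag(lab, web, method=method,
                           max_lag_bins=max_lag_bins,
                           bin_width_ms=bin_width_ms)
        lines.append(f"  {method:>5}: lag {est.lag_bins:+d} bins "
                     f"({est.lag_ms:+.0f} ms)")
    return "\n".join(lines)
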