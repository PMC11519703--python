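"""Viewport-proportional areas of interest (AOIs) and gaze-sample assignment.

Webcam gaze estimators report raw x/y screen coordinates, so the two picture
AOIs of a sentence-picture matching display are reconstructed post hoc as
fixed proportions of each participant's viewport: the left picture occupies
15%-45% of the screen width, the right picture 55%-85%, and both span the
middle half of the screen height starting at 22.5% (y 243-783 px on a
1080-px-tall screen).  A sample is assigned to the *target* AOI
when it falls in the box on the trial's target side, to the *foil* AOI when it
falls in the other box, and to *none* otherwise (samples labeled none are
flagged as discarded for proportion denominators downstream).

Coordinates are screen pixels with the origin at the top-left corner and y
increasing downward (the convention of both acquisition systems).  Box
membership uses half-open intervals [start, end) on both axes so that every
point maps to exactly one of {target, foil, none}.

Lab exports arrive pre-labeled (label mode) and pass through unchanged: in-lab
AOIs are drawn in the acquisition software around pictures plus response
letters and are not reconstructed here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from sklearn.base import BaseEstimator, TransformerMixin

# Default AOI proportions of the viewport: each box is 30% of the width,
# and the shared y-range starts at 22.5% of the height and spans 50% of it
# (on 1920x1080: x 288-864 / 1056-1632, y 243-783).
LEFT_X = (0.15, 0.45)
RIGHT_X = (0.55, 0.85)
Y_RANGE = (0.225, 0.725)

LABELS = ("target", "foil", "none")


@dataclass(frozen=True)
class Viewport:
    """Browser viewport (or screen) size in pixels."""

    width_px: int
    height_px: int

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError(
                f"invalid viewport: {self.width_px} x {self.height_px}"
            )


@dataclass(frozen=True)
class AoiBox:
    """Axis-aligned rectangle in screen pixels, origin top-left.

    Membership is half-open: ``x_start <= x < x_end`` and
    ``y_start <= y < y_end``.
    """

    x_start_px: float
    x_end_px: float
    y_start_px: float
    y_end_px: float

    def __post_init__(self) -> None:
        if not (self.x_start_px < self.x_end_px and self.y_start_px < self.y_end_px):
            raise ValueError("degenerate AOI box")

    def contains(self, x: float, y: float) -> bool:
        return (
            self.x_start_px <= x < self.x_end_px
            and self.y_start_px <= y < self.y_end_px
        )


@dataclass(frozen=True)
class AoiPair:
    """Left/right picture AOIs sharing a y-range, separated by a gap."""

    left: AoiBox
    right: AoiBox

    def __post_init__(self) -> None:
        if self.left.x_end_px > self.right.x_start_px:
            raise ValueError("left and right AOIs overlap")
        if (self.left.y_start_px, self.left.y_end_px) != (
            self.right.y_start_px,
            self.right.y_end_px,
        ):
            raise ValueError("left/right AOIs must share y extents")


def compute_aois(viewport: Viewport) -> AoiPair:
    """Build the left/right AOI pair for a viewport.

    On a 1920x1080 screen the left AOI spans x 288-864 px and y 243-783 px;
    the right AOI spans x 1056-1632 px with the same y-range.
    """
    w, h = float(viewport.width_px), float(viewport.height_px)
    y0, y1 = Y_RANGE[0] * h, Y_RANGE[1] * h
    left = AoiBox(LEFT_X[0] * w, LEFT_X[1] * w, y0, y1)
    right = AoiBox(RIGHT_X[0] * w, RIGHT_X[1] * w, y0, y1)
    return AoiPair(left=left, right=right)


def assign_sample(x: float, y: float, aois: AoiPair, target_side: str) -> str:
    """Assign one coordinate-mode sample to target / foil / none.

    ``target_side`` is ``"left"`` or ``"right"``: the box on that side is the
    target, the other box the foil; points in neither box map to ``"none"``.
    """
    if target_side not in ("left", "right"):
        raise ValueError(f"target_side must be 'left' or 'right', got {target_side!r}")
    if aois.left.contains(x, y):
        side = "left"
    elif aois.right.contains(x, y):
        side = "right"
    else:
        return "none"
    return "target" if side == target_side else "foil"


def assign_xy(
    x: np.ndarray, y: np.ndarray, aois: AoiPair, target_left: np.ndarray
) -> np.ndarray:
    """Vectorized sample assignment.

    Parameters
    ----------
    x, y
        Coordinate arrays in pixels.
    aois
        The AOI pair for this participant's viewport.
    target_left
        Boolean array, True where the trial's target picture is on the left.

    Returns
    -------
    Array of labels from {"target", "foil", "none"}.
    """
    codes = _assign_codes(x, y, aois, target_left)
    return np.array(LABELS, dtype=object)[codes]


def _assign_codes(
    x: np.ndarray, y: np.ndarray, aois: AoiPair, target_left: np.ndarray
) -> np.ndarray:
    """Vectorized assignment to label codes 0=target, 1=foil, 2=none."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    in_y = (aois.left.y_start_px <= y) & (y < aois.left.y_end_px)
    in_left = in_y & (aois.left.x_start_px <= x) & (x < aois.left.x_end_px)
    in_right = in_y & (aois.right.x_start_px <= x) & (x < aois.right.x_end_px)
    target_left = np.asarray(target_left, dtype=bool)

    out = np.full(x.shape, 2, dtype=np.int8)
    out[(in_left & target_left) | (in_right & ~target_left)] = 0
    out[(in_left & ~target_left) | (in_right & target_left)] = 1
    return out


class AoiLabeler(TransformerMixin, BaseEstimator):
    """Transformer labeling a gaze-sample table against trial metadata.

    Coordinate-mode samples (web exports) are assigned by viewport-proportional
    AOI geometry; label-mode samples (lab exports) pass through verbatim.

    Parameters
    ----------
    trials : DataFrame
        Trial table with ``participant``, ``trial_id``, ``target_side``.
    viewports : DataFrame, Viewport, or None
        Per-participant viewports (columns ``participant``, ``width_px``,
        ``height_px``) or one viewport shared by all participants.  Required
        when any sample is in coordinate mode.

    Attributes
    ----------
    aois_ : dict
        Mapping participant id -> :class:`AoiPair`, built during ``fit``.
    """

    def __init__(self, trials: pd.DataFrame | None = None, viewports=None):
        self.trials = trials
        self.viewports = viewports

    def fit(self, X: pd.DataFrame, y=None) -> "AoiLabeler":
        if self.trials is None:
            raise ValueError("AoiLabeler requires a trial table")
        self.aois_ = {} if self.viewports is None else _as_aoi_map(X, self.viewports)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "aois_"):
            self.fit(X)
        return label_stream(X, self.trials, self.aois_)


def _as_aoi_map(samples: pd.DataFrame, viewports) -> dict:
    if isinstance(viewports, dict):
        return viewports
    if isinstance(viewports, Viewport):
        shared = compute_aois(viewports)
        return {p: shared for p in samples["participant"].unique()}
    if isinstance(viewports, pd.DataFrame):
        return {
            row.participant: compute_aois(Viewport(int(row.width_px), int(row.height_px)))
            for row in viewports.itertuples(index=False)
        }
    raise TypeError(f"unsupported viewport specification: {type(viewports)!r}")


def label_stream(
    samples: pd.DataFrame, trials: pd.DataFrame, viewports
) -> pd.DataFrame:
    """Label every sample in a mixed-mode gaze table.

    Parameters
    ----------
    samples
        Gaze table with ``participant``, ``trial_id``, ``t_ms`` and either
        ``aoi_label`` (label mode) or ``x_px``/``y_px`` (coordinate mode)
        populated per row.
    trials
        Trial table carrying ``target_side`` per (participant, trial_id).
    viewports
        Per-participant viewports: a dict of participant -> AoiPair, a
        viewport table, or a single :class:`Viewport`.

    Returns
    -------
    Copy of ``samples`` with a ``label`` column in {target, foil, none} and a
    boolean ``discarded`` column (True where label == none).

    Raises
    ------
    KeyError
        If any sample references a (participant, trial_id) absent from the
        trial table; the message lists the offending ids.
    """
    key = ["participant", "trial_id"]
    trial_side = trials.drop_duplicates(key).set_index(key)["target_side"]
    sample_key = pd.MultiIndex.from_frame(samples[key])
    missing = ~sample_key.isin(trial_side.index)
    if missing.any():
        bad = sorted(set(sample_key[missing]))[:10]
        raise KeyError(f"gaze samples reference unknown trials: {bad}")

    out = samples.copy()
    side = trial_side.reindex(sample_key).to_numpy()

    # label codes: 0=target, 1=foil, 2=none
    codes = np.full(len(out), 2, dtype=np.int8)
    if "aoi_label" in out.columns:
        al = out["aoi_label"]
        if isinstance(al.dtype, pd.CategoricalDtype):
            cats = list(al.cat.categories)
            bad = set(cats) - set(LABELS)
            if bad:
                raise ValueError(f"unknown AOI labels in input: {sorted(bad)}")
            lut = np.array([LABELS.index(c) for c in cats], dtype=np.int8)
            raw = al.cat.codes.to_numpy()
            has_label = raw >= 0
            codes[has_label] = lut[raw[has_label]]
        else:
            has_label = al.notna().to_numpy()
            vals = al.to_numpy(dtype=object)[has_label]
            bad = set(vals) - set(LABELS)
            if bad:
                raise ValueError(f"unknown AOI labels in input: {sorted(bad)}")
            codes[has_label] = np.array(
                [LABELS.index(v) for v in vals], dtype=np.int8)
    else:
        has_label = np.zeros(len(out), dtype=bool)

    coord = ~has_label
    if coord.any():
        if not {"x_px", "y_px"} <= set(out.columns):
            raise ValueError("coordinate-mode samples lack x_px/y_px columns")
        aoi_map = _as_aoi_map(out, viewports)
        x = out["x_px"].to_numpy(dtype=float)
        y = out["y_px"].to_numpy(dtype=float)
        target_left = np.asarray(side) == "left"
        pids = np.asarray(out["participant"])
        for pid in pd.unique(pids[coord]):
            if pid not in aoi_map:
                raise KeyError(f"no viewport for participant {pid!r}")
            sel = coord & (pids == pid)
            codes[sel] = _assign_codes(x[sel], y[sel], aoi_map[pid],
                                       target_left[sel])

    out["label"] = pd.Categorical.from_codes(codes, list(LABELS))
    out["discarded"] = codes == 2
    return out
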