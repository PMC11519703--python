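"""Synthetic dual-modality visual-world studies with known ground truth.

Emulates a two-group (control vs. PWA — persons with aphasia), two-modality
(lab EyeLink-style vs. webcam WebGazer-style) sentence-picture matching study:
a 65-trial design (15 active, 15 passive, 15 locative, 20 filler), 50/50
target-side balance, and per-trial gaze streams whose probability of landing
in the target AOI sits at the 0.5 chance baseline until the sentence's
disambiguation point, then ramps logistically to a group- and structure-
specific asymptote.  The webcam stream is additionally sampled an order of
magnitude more sparsely, with heavy-tailed timing jitter, and can carry an
injectable recording lag — the quantity the downstream Δgaze analysis is
designed to recover.

Every stochastic element is driven by one integer seed through documented
``numpy.random.SeedSequence`` splitting, so an identical configuration yields
bit-identical output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

GROUPS = ("control", "pwa")
MODALITIES = ("lab", "web")
ANALYSIS_STRUCTURES = ("active", "passive", "locative")
DESIGN_STRUCTURES = ("active", "passive", "locative", "filler_decl", "filler_wh")
DESIGN_COUNTS = {"active": 15, "passive": 15, "locative": 15,
                 "filler_decl": 10, "filler_wh": 10}

#: recording continues this long past the button press
POST_RESPONSE_MS = 300.0


def collapse_structure(structure: str) -> str:
    """Map the five design structures onto the four trial-table classes."""
    return structure if structure in ANALYSIS_STRUCTURES else "filler"


def _per_group(control: float, pwa: float) -> dict:
    return {"control": control, "pwa": pwa}


def _per_group_structure(control: dict, pwa: dict) -> dict:
    return {"control": dict(control), "pwa": dict(pwa)}


@dataclass
class SimulationConfig:
    """All tunable parameters of the synthetic study.

    Timing parameters are in milliseconds.  Sampling intervals follow a
    shifted lognormal matched exactly to the configured mean and SD (the
    empirical webcam interval distribution is strongly right-skewed —
    SD 162.2 ms against a 49 ms mean — and lab trackers show rare long gaps
    against a ~2 ms hardware tick).

    The gaze model: before ``disambiguation + ramp_onset_delay_ms[group]
    (+ web_lag_ms on the web)`` the per-sample probability of the target AOI
    is 0.5; it then rises logistically with time constant
    ``ramp_scale_ms[group]`` (the ramp rate is its reciprocal; 0 means an
    instantaneous step) to ``asymptote[group][structure]``.  Optionally,
    controls decay back toward 0.5 after ``late_decay_onset_ms`` while PWA
    persist, reproducing the late PWA > control crossover; off by default.
    """

    n_control: int = 16
    n_pwa: int = 16

    # sampling clocks
    lab_interval_ms: float = 2.3
    lab_interval_sd_ms: float = 13.91
    lab_interval_min_ms: float = 1.8
    web_interval_ms: float = 49.0
    web_interval_sd_ms: float = 162.2
    web_interval_min_ms: float = 15.0
    web_lag_ms: float = 600.0

    # gaze time course
    ramp_onset_delay_ms: dict = field(default_factory=lambda: _per_group(250.0, 1250.0))
    ramp_scale_ms: dict = field(default_factory=lambda: _per_group(350.0, 450.0))
    asymptote: dict = field(default_factory=lambda: _per_group_structure(
        {"active": 0.87, "passive": 0.84, "locative": 0.85, "filler": 0.88},
        {"active": 0.78, "passive": 0.70, "locative": 0.73, "filler": 0.80},
    ))
    late_decay_onset_ms: float | None = None
    late_decay_tau_ms: float = 1500.0

    # behavior
    accuracy_logit: dict = field(default_factory=lambda: _per_group_structure(
        {"active": 4.5, "passive": 4.5, "locative": 4.0, "filler": 4.5},
        {"active": 1.8, "passive": 0.8, "locative": 1.2, "filler": 2.2},
    ))
    rt_median_ms: dict = field(default_factory=lambda: _per_group_structure(
        {"active": 4300.0, "passive": 4500.0, "locative": 5200.0, "filler": 3900.0},
        {"active": 6300.0, "passive": 7000.0, "locative": 6800.0, "filler": 5800.0},
    ))
    rt_web_ratio: dict = field(default_factory=lambda: _per_group(0.80, 0.72))
    rt_log_sd: float = 0.25

    # between-participant / between-item heterogeneity.  The gaze term
    # multiplies (asymptote - 0.5) by exp(eps), so it vanishes exactly when
    # the asymptote sits at the 0.5 chance baseline (a null configuration
    # has genuinely exchangeable trials).
    gaze_participant_sd: float = 0.20
    rt_participant_log_sd: float = 0.10
    rt_item_log_sd: float = 0.04
    accuracy_participant_sd: float = 0.40

    # spatial model (web coordinate mode)
    spatial_noise_px: dict = field(default_factory=lambda: {"lab": 0.0, "web": 40.0})
    dropout_prob: dict = field(default_factory=lambda: {"lab": 0.02, "web": 0.08})
    viewport_width_px: int = 1920
    viewport_height_px: int = 1080

    # design / timeline
    trial_duration_ms: float = 12000.0
    disamb_window_ms: dict = field(default_factory=lambda: {
        "active": (1800.0, 2600.0), "passive": (1800.0, 2600.0),
        "locative": (1600.0, 2200.0),
        "filler_decl": (1400.0, 2200.0), "filler_wh": (1400.0, 2200.0),
    })
    audio_tail_ms: tuple = (800.0, 1600.0)

    modalities: tuple = ("lab", "web")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control < 0 or self.n_pwa < 0:
            raise ValueError("participant counts must be nonnegative")
        for name in ("lab_interval_ms", "web_interval_ms", "trial_duration_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not (0 < self.lab_interval_min_ms < self.lab_interval_ms):
            raise ValueError("lab_interval_min_ms must lie in (0, lab_interval_ms)")
        if not (0 < self.web_interval_min_ms < self.web_interval_ms):
            raise ValueError("web_interval_min_ms must lie in (0, web_interval_ms)")
        if self.web_lag_ms < 0:
            raise ValueError("web_lag_ms must be nonnegative")
        for g in GROUPS:
            if self.ramp_scale_ms[g] < 0:
                raise ValueError("ramp_scale_ms must be nonnegative")
            if self.ramp_onset_delay_ms[g] < 0:
                raise ValueError("ramp_onset_delay_ms must be nonnegative")
            for s, a in self.asymptote[g].items():
                if not (0.5 <= a <= 1.0):
                    raise ValueError(f"asymptote[{g}][{s}]={a} outside [0.5, 1]")
        for m, p in self.dropout_prob.items():
            if not (0.0 <= p < 1.0):
                raise ValueError(f"dropout_prob[{m}]={p} outside [0, 1)")
        for m in self.modalities:
            if m not in MODALITIES:
                raise ValueError(f"unknown modality {m!r}")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["audio_tail_ms"] = list(d["audio_tail_ms"])
        d["modalities"] = list(d["modalities"])
        d["disamb_window_ms"] = {k: list(v) for k, v in d["disamb_window_ms"].items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "audio_tail_ms" in d:
            d["audio_tail_ms"] = tuple(d["audio_tail_ms"])
        if "modalities" in d:
            d["modalities"] = tuple(d["modalities"])
        if "disamb_window_ms" in d:
            d["disamb_window_ms"] = {
                k: tuple(v) for k, v in d["disamb_window_ms"].items()
            }
        return cls(**d)

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)

    def participants(self) -> pd.DataFrame:
        ids = [f"C{i + 1:02d}" for i in range(self.n_control)] + [
            f"P{i + 1:02d}" for i in range(self.n_pwa)
        ]
        groups = ["control"] * self.n_control + ["pwa"] * self.n_pwa
        return pd.DataFrame({"participant": ids, "group": groups})

    def viewports(self) -> pd.DataFrame:
        p = self.participants()
        return pd.DataFrame({
            "participant": p["participant"],
            "width_px": self.viewport_width_px,
            "height_px": self.viewport_height_px,
        })


# ---------------------------------------------------------------------------
# study design


def build_design(
    seed: int | np.random.SeedSequence,
    disamb_window_ms: dict | None = None,
    audio_tail_ms: tuple = (800.0, 1600.0),
) -> pd.DataFrame:
    """Build the 65-trial design.

    15 active, 15 passive, 15 locative, 10 declarative fillers and 10
    wh-question fillers, with the target picture on the left in half of the
    trials of each type (8/7 for the odd 15-trial types, which side gets the
    extra trial being decided by the seed).  Disambiguation times — the noun
    onset for actives/passives, the first-preposition onset for locatives —
    are drawn uniformly inside per-structure windows that start after the
    300 ms fixation cross and 700 ms picture apprehension phase.

    Returns a DataFrame with columns ``trial_id``, ``structure`` (five design
    levels), ``structure_class`` (fillers collapsed), ``target_side``,
    ``disamb_ms``, ``audio_end_ms``.
    """
    rng = np.random.default_rng(seed)
    windows = disamb_window_ms or SimulationConfig().disamb_window_ms

    rows = []
    for structure in DESIGN_STRUCTURES:
        n = DESIGN_COUNTS[structure]
        n_left = n // 2 + (int(rng.integers(2)) if n % 2 else 0)
        sides = np.array(["left"] * n_left + ["right"] * (n - n_left))
        rng.shuffle(sides)
        lo, hi = windows[structure]
        if not lo > 1000.0:
            raise ValueError(
                f"disambiguation window for {structure} must start after the "
                "1000 ms fixation + apprehension phase"
            )
        disamb = rng.uniform(lo, hi, size=n)
        tail = rng.uniform(*audio_tail_ms, size=n)
        for i in range(n):
            rows.append((structure, sides[i], disamb[i], disamb[i] + tail[i]))

    design = pd.DataFrame(rows, columns=["structure", "target_side",
                                         "disamb_ms", "audio_end_ms"])
    order = rng.permutation(len(design))
    design = design.iloc[order].reset_index(drop=True)
    design.insert(0, "trial_id", [f"t{i + 1:02d}" for i in range(len(design))])
    design["structure_class"] = design["structure"].map(collapse_structure)
    return design


# ---------------------------------------------------------------------------
# gaze model


def _lognormal_params(mean: float, sd: float, shift: float) -> tuple[float, float]:
    """Parameters of a shifted lognormal with the given mean and SD."""
    m = mean - shift
    sigma2 = np.log1p((sd / m) ** 2)
    mu = np.log(m) - sigma2 / 2.0
    return mu, np.sqrt(sigma2)


def _interval_spec(config: SimulationConfig, modality: str):
    if modality == "lab":
        mean, sd, shift = (config.lab_interval_ms, config.lab_interval_sd_ms,
                           config.lab_interval_min_ms)
    else:
        mean, sd, shift = (config.web_interval_ms, config.web_interval_sd_ms,
                           config.web_interval_min_ms)
    mu, sigma = _lognormal_params(mean, sd, shift)
    return mean, shift, mu, sigma


def target_probability(
    t_ms: np.ndarray,
    disamb_ms,
    config: SimulationConfig,
    group: str,
    structure,
    modality: str,
    asymptote_scale: float = 1.0,
) -> np.ndarray:
    """Probability that a gaze sample at ``t_ms`` lands in the target AOI.

    ``structure`` may be a scalar or an array aligned with ``t_ms``'s first
    axis; ``disamb_ms`` likewise.  ``asymptote_scale`` multiplies the
    asymptote's distance from the 0.5 baseline (participant heterogeneity).
    """
    t = np.asarray(t_ms, dtype=float)
    if np.isscalar(structure) or isinstance(structure, str):
        asym = config.asymptote[group][collapse_structure(structure)]
    else:
        amap = {s: config.asymptote[group][collapse_structure(s)]
                for s in np.unique(structure)}
        asym = np.vectorize(amap.get)(structure).astype(float)
        asym = np.reshape(asym, (-1,) + (1,) * (t.ndim - 1))
    asym = np.minimum(0.5 + (asym - 0.5) * asymptote_scale, 1.0)
    mid = (np.reshape(np.asarray(disamb_ms, dtype=float), (-1,) + (1,) * (t.ndim - 1))
           if np.ndim(disamb_ms) else float(disamb_ms))
    mid = mid + config.ramp_onset_delay_ms[group]
    if modality == "web":
        mid = mid + config.web_lag_ms
    scale = config.ramp_scale_ms[group]
    if scale <= 0:
        ramp = (t >= mid).astype(float)
    else:
        ramp = expit((t - mid) / scale)
    p = 0.5 + (asym - 0.5) * ramp
    if config.late_decay_onset_ms is not None and group == "control":
        age = np.maximum(t - config.late_decay_onset_ms, 0.0)
        p = 0.5 + (p - 0.5) * np.exp(-age / config.late_decay_tau_ms)
    return p


def draw_participant_effects(config: SimulationConfig,
                             rng: np.random.Generator,
                             design: pd.DataFrame):
    """Per-participant and per-item random effects.

    Returns ``(participant_effects, item_rt_factor)``: a DataFrame indexed by
    participant with columns ``gaze_scale`` (multiplier on asymptote − 0.5),
    ``rt_factor`` and ``acc_offset`` (logit shift), and a Series of RT
    multipliers indexed by trial id.  One draw per participant, shared across
    that participant's two sessions.
    """
    parts = config.participants()
    n = len(parts)
    eff = pd.DataFrame({
        "gaze_scale": np.exp(rng.normal(0.0, config.gaze_participant_sd, n)),
        "rt_factor": np.exp(rng.normal(0.0, config.rt_participant_log_sd, n)),
        "acc_offset": rng.normal(0.0, config.accuracy_participant_sd, n),
    }, index=parts["participant"])
    item = pd.Series(
        np.exp(rng.normal(0.0, config.rt_item_log_sd, len(design))),
        index=design["trial_id"], name="rt_item_factor")
    return eff, item


def _gen_label_matrix(rng, config, modality, group, structures, disamb,
                      durations, asymptote_scale=1.0):
    """Sample timestamps and AOI outcomes for a batch of trials at once.

    Every inter-sample interval is at least the configured shift, so
    ``duration / shift + 1`` draws per trial are guaranteed to overshoot the
    recording window; the surplus is masked off.  Returns per-trial lists of
    (timestamps, outcome codes) where 0=target, 1=foil, 2=none.
    """
    _, shift, mu, sigma = _interval_spec(config, modality)
    durations = np.asarray(durations, dtype=float)
    n_trials = len(durations)
    n_cap = int(np.ceil(durations.max() / shift)) + 1
    intervals = shift + rng.lognormal(mu, sigma, size=(n_trials, n_cap))
    t = np.cumsum(intervals, axis=1)
    mask = t < durations[:, None]

    p = target_probability(t, disamb, config, group, structures, modality,
                           asymptote_scale)
    on_target = rng.random((n_trials, n_cap)) < p
    dropped = rng.random((n_trials, n_cap)) < config.dropout_prob[modality]
    code = np.where(dropped, 2, np.where(on_target, 0, 1)).astype(np.int8)
    return t, code, mask


def simulate_trial_gaze(
    trial,
    config: SimulationConfig,
    group: str,
    modality: str,
    rng: np.random.Generator,
    duration_ms: float | None = None,
    asymptote_scale: float = 1.0,
) -> pd.DataFrame:
    """Gaze stream for a single trial (a row of the design table).

    Lab streams are emitted in label mode (``aoi_label`` set); web streams in
    coordinate mode (``x_px``/``y_px`` set): on-AOI samples sit at the center
    of the assigned box plus isotropic Gaussian noise, dropout samples land in
    the inter-AOI gap well above both boxes.
    """
    duration = float(duration_ms if duration_ms is not None
                     else config.trial_duration_ms)
    if duration <= 0:
        raise ValueError("trial duration must be positive")
    t, code, mask = _gen_label_matrix(
        rng, config, modality, group,
        trial.structure, float(trial.disamb_ms), np.array([duration]),
        asymptote_scale,
    )
    t, code = t[0][mask[0]], code[0][mask[0]]
    df = pd.DataFrame({"t_ms": t})
    df["trial_id"] = trial.trial_id
    df["modality"] = modality
    if modality == "lab":
        df["aoi_label"] = np.array(["target", "foil", "none"], dtype=object)[code]
        df["x_px"] = np.nan
        df["y_px"] = np.nan
    else:
        x, y = _coordinates_for_codes(code, trial.target_side, config, rng)
        df["aoi_label"] = None
        df["x_px"] = x
        df["y_px"] = y
    return df[["trial_id", "modality", "t_ms", "x_px", "y_px", "aoi_label"]]


def _coordinates_for_codes(code, target_side, config, rng):
    """Map outcome codes to pixel coordinates (web coordinate mode)."""
    w, h = config.viewport_width_px, config.viewport_height_px
    centers_x = {"left": 0.30 * w, "right": 0.70 * w}
    if np.isscalar(target_side) or isinstance(target_side, str):
        target_side = np.full(code.shape, target_side, dtype=object)
    tgt_left = np.asarray(target_side) == "left"
    # code 0 = target box, 1 = foil box, 2 = neither
    in_left = ((code == 0) & tgt_left) | ((code == 1) & ~tgt_left)
    x = np.where(in_left, centers_x["left"], centers_x["right"]).astype(float)
    y = np.full(code.shape, 0.5 * h, dtype=float)
    noise = config.spatial_noise_px["web"]
    if noise > 0:
        x = x + rng.normal(0.0, noise, size=code.shape)
        y = y + rng.normal(0.0, noise, size=code.shape)
    # dropout: deterministic off-AOI point in the top gap region
    x = np.where(code == 2, 0.5 * w, x)
    y = np.where(code == 2, 0.05 * h, y)
    return x, y


# ---------------------------------------------------------------------------
# whole-study simulation


def simulate_trials(
    config: SimulationConfig,
    design: pd.DataFrame,
    rng: np.random.Generator,
    effects: pd.DataFrame | None = None,
    item_effects: pd.Series | None = None,
) -> pd.DataFrame:
    """Behavioral table: one row per participant x modality x trial.

    Accuracy is Bernoulli from the configured group-structure logits
    (infinite logits give deterministic ceiling performance); RT from the
    trial's onset is lognormal around a group-structure median, scaled by the
    per-group web ratio on the web, and floored just past the audio end
    (the response window only opens when the audio recording finishes).
    """
    parts = config.participants()
    frames = []
    for prow in parts.itertuples(index=False):
        for modality in config.modalities:
            df = design[["trial_id", "structure_class", "target_side",
                         "disamb_ms", "audio_end_ms"]].copy()
            df = df.rename(columns={"structure_class": "structure"})
            df.insert(0, "participant", prow.participant)
            df.insert(1, "group", prow.group)
            df.insert(2, "modality", modality)
            logits = df["structure"].map(
                config.accuracy_logit[prow.group]).to_numpy(float)
            if effects is not None:
                logits = logits + effects.loc[prow.participant, "acc_offset"]
            p_acc = expit(logits)
            df["accurate"] = rng.random(len(df)) < p_acc
            med = df["structure"].map(config.rt_median_ms[prow.group]).to_numpy(float)
            if modality == "web":
                med = med * config.rt_web_ratio[prow.group]
            if effects is not None:
                med = med * effects.loc[prow.participant, "rt_factor"]
            if item_effects is not None:
                med = med * item_effects.reindex(df["trial_id"]).to_numpy(float)
            rt = np.exp(np.log(med) + rng.normal(0.0, config.rt_log_sd, len(df)))
            rt = np.maximum(rt, df["audio_end_ms"].to_numpy(float) + 200.0)
            df["rt_ms"] = rt
            df["session"] = f"{prow.participant}-{modality}"
            frames.append(df)
    return pd.concat(frames, ignore_index=True)


def simulate_study(
    config: SimulationConfig,
    design: pd.DataFrame | None = None,
    structures: tuple | None = None,
    return_gaze: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Simulate a complete study: behavioral trial table plus gaze streams.

    Recording in each trial lasts ``min(rt + 300 ms, trial_duration_ms)`` —
    trial durations vary with response speed, as in a real session where the
    trial ends 300 ms after the button press.

    Parameters
    ----------
    config
        Study parameters; ``config.seed`` fully determines the output.
    design
        Optional pre-built design table (defaults to :func:`build_design`
        seeded from the study seed).
    structures
        Optional subset of design ``structure_class`` values to simulate
        (e.g. ``("active", "passive", "locative")`` to skip fillers).
    return_gaze
        When False only the trial table is produced (cheap).

    Returns
    -------
    (trials, gaze)
        ``gaze`` is None when ``return_gaze`` is False.  Lab gaze rows are in
        label mode, web rows in coordinate mode.
    """
    if config.n_control + config.n_pwa == 0:
        raise ValueError("empty study: n_control + n_pwa must be positive")
    root = np.random.SeedSequence(config.seed)
    n_streams = (config.n_control + config.n_pwa) * len(config.modalities)
    children = root.spawn(3 + n_streams)
    if design is None:
        design = build_design(children[0], config.disamb_window_ms,
                              config.audio_tail_ms)
    if structures is not None:
        design = design[design["structure_class"].isin(structures)].reset_index(drop=True)

    effects, item_effects = draw_participant_effects(
        config, np.random.default_rng(children[1]), design)
    trials = simulate_trials(config, design, np.random.default_rng(children[2]),
                             effects, item_effects)
    if not return_gaze:
        return trials, None

    rt_lookup = trials.set_index(["participant", "modality", "trial_id"])["rt_ms"]
    parts = config.participants()

    part_cats = list(parts["participant"])
    mod_cats = list(config.modalities)
    trial_cats = list(design["trial_id"])
    trial_codes_per_design = np.arange(len(design), dtype=np.int32)

    cols: dict[str, list] = {k: [] for k in
                             ("participant", "modality", "trial_id", "t_ms",
                              "x_px", "y_px", "aoi_label")}
    stream_i = 3
    for pi, prow in enumerate(parts.itertuples(index=False)):
        for mi, modality in enumerate(config.modalities):
            rng = np.random.default_rng(children[stream_i])
            stream_i += 1
            rts = rt_lookup.loc[prow.participant, modality].reindex(
                design["trial_id"]).to_numpy(float)
            durations = np.minimum(rts + POST_RESPONSE_MS, config.trial_duration_ms)
            t, code, mask = _gen_label_matrix(
                rng, config, modality, prow.group,
                design["structure"].to_numpy(),
                design["disamb_ms"].to_numpy(float), durations,
                float(effects.loc[prow.participant, "gaze_scale"]),
            )
            counts = mask.sum(axis=1)
            t_flat = t[mask]
            code_flat = code[mask]
            cols["participant"].append(
                np.full(t_flat.size, pi, dtype=np.int16))
            cols["modality"].append(np.full(t_flat.size, mi, dtype=np.int8))
            cols["trial_id"].append(
                np.repeat(trial_codes_per_design, counts))
            cols["t_ms"].append(t_flat)
            if modality == "lab":
                cols["aoi_label"].append(code_flat)
                cols["x_px"].append(np.full(t_flat.size, np.nan))
                cols["y_px"].append(np.full(t_flat.size, np.nan))
            else:
                sides = np.repeat(design["target_side"].to_numpy(), counts)
                x, y = _coordinates_for_codes(code_flat, sides, config, rng)
                cols["aoi_label"].append(np.full(t_flat.size, -1, dtype=np.int8))
                cols["x_px"].append(x)
                cols["y_px"].append(y)

    gaze = pd.DataFrame({
        "participant": pd.Categorical.from_codes(
            np.concatenate(cols["participant"]), part_cats),
        "modality": pd.Categorical.from_codes(
            np.concatenate(cols["modality"]), mod_cats),
        "trial_id": pd.Categorical.from_codes(
            np.concatenate(cols["trial_id"]), trial_cats),
        "t_ms": np.concatenate(cols["t_ms"]),
        "x_px": np.concatenate(cols["x_px"]),
        "y_px": np.concatenate(cols["y_px"]),
        "aoi_label": pd.Categorical.from_codes(
            np.concatenate(cols["aoi_label"]), ["target", "foil", "none"]),
    })
    return trials, gaze
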