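import numpy as np
import pandas as pd
import pytest

import deltagaze as dg


@pytest.fixture(scope="session")
def small_study():
    """A small web-only study reused across read-only tests."""
    cfg = dg.SimulationConfig(n_control=3, n_pwa=3, modalities=("web",),
                              trial_duration_ms=4000.0, seed=11)
    trials, gaze = dg.simulate_study(cfg)
    return cfg, trials, gaze


@pytest.fixture(scope="session")
def small_bincells(small_study):
    cfg, trials, gaze = small_study
    labeled = dg.label_stream(gaze, trials, cfg.viewports())
    trimmed, _ = dg.trim_timestamps(labeled)
    return dg.bin_gaze(trimmed, trials, window_ms=(0.0, 4000.0))


def flat_structure_map(value):
    return {"active": value, "passive": value, "locative": value,
            "filler": value}


def null_config(seed, n_per_group=6, duration=4000.0):
    """All group effects zeroed: both groups statistically exchangeable."""
    return dg.SimulationConfig(
        seed=seed, n_control=n_per_group, n_pwa=n_per_group,
        modalities=("web",), trial_duration_ms=duration, web_lag_ms=0.0,
        asymptote={"control": flat_structure_map(0.5),
                   "pwa": flat_structure_map(0.5)},
        rt_median_ms={"control": flat_structure_map(4000.0),
                      "pwa": flat_structure_map(4000.0)},
        rt_web_ratio={"control": 1.0, "pwa": 1.0},
        accuracy_logit={"control": flat_structure_map(3.0),
                        "pwa": flat_structure_map(3.0)},
        ramp_onset_delay_ms={"control": 0.0, "pwa": 0.0},
    )
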