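# deltagaze

Lab vs. webcam eye tracking for clinical visual-world studies: a tested,
reusable analysis pipeline for sentence–picture matching gaze data, plus a
synthetic-study generator that makes every stage verifiable against known
ground truth.

## The problem

Webcam gaze estimation (WebGazer-style) promises to take visual-world
paradigms out of the lab — important for clinical groups such as persons
with aphasia (PWA), for whom lab visits are a real barrier.  But webcam
streams differ from lab trackers in three ways that matter for inference:
sparse sampling (~49 ms between estimations vs. ~2.3 ms), heavy timing
jitter, and a systematic *recording lag* of several hundred milliseconds.
This package implements the comparison analysis end to end:

1. **AOI geometry** — rectangular areas of interest reconstructed as
   viewport proportions (left picture: 15–45 % of width; right: 55–85 %;
   both spanning half the screen height from 22.5 %), with raw x/y gaze
   samples assigned to *target* / *foil* / *none* by half-open rectangle
   membership.  Lab exports arrive pre-labeled and pass through.
2. **Preprocessing** — per-trial 2-SD timestamp trimming; accuracy filtering
   plus per-session 2-SD reaction-time trimming; square-root RT transform;
   and aggregation of labeled samples into half-open 100-ms bins
   (0–100 … 11,900–12,000 ms), giving per-trial, per-bin target-gaze
   proportions `n_target / (n_target + n_foil)`.
3. **Models** — accuracy: binomial mixed-effects logistic regression
   (structure × modality, participant and item intercepts); RT: linear
   mixed model on √RT (group × structure × modality); gaze: *quasibinomial*
   (overdispersed logit) regression of bin proportions, weighted by the
   sample count behind each proportion, with dispersion `φ = Pearson χ²/df`
   and all standard errors scaled by `√φ`.  The omnibus bin × predictor
   model yields per-bin group contrasts and contiguous significance windows
   ("PWA diverge from controls from bin *k* to bin *m*").
4. **Δgaze lag analysis** — the per-bin difference
   `Δgaze(b) = mean control proportion − mean PWA proportion`, computed per
   structure and modality.  If the webcam merely reports gaze late, the web
   Δgaze curve is a time-shifted copy of the lab curve; the shift is
   estimated from peak/dip locations and (more robustly) by maximizing the
   normalized cross-correlation between the two series.

A synthetic-data module simulates complete two-group, two-modality studies —
65-trial design (15 active / 15 passive / 15 locative / 20 filler),
disambiguation-locked logistic gaze ramps with group-specific delay and
asymptote, modality-specific sampling clocks, and an injectable web lag — so
parameter recovery can be demonstrated for every stage.

## Worked example

```python
import deltagaze as dg

cfg = dg.SimulationConfig(seed=1, web_lag_ms=600.0, trial_duration_ms=9000.0)
trials, gaze = dg.simulate_study(cfg)          # 4160 trials, 5,510,386 samples
labeled = dg.label_stream(gaze, trials, cfg.viewports())
trimmed, rep = dg.trim_timestamps(labeled)     # removed 0.05% of the eye data
cells = dg.bin_gaze(trimmed, trials, window_ms=(0, 9000))   # 187,549 bin cells

from deltagaze.models import BinwiseGazeModel, binwise_contrasts, significant_windows
bw = BinwiseGazeModel(factors=("group", "modality")).fit(cells[cells.structure != "filler"])
contr = binwise_contrasts(bw, "group", "pwa", "control")     # dispersion 1.401
print(significant_windows(contr))              # PWA deficit window: bins 17-63

d = dg.compute_delta(cells)
print(dg.lag_report(d))
```

```
Δgaze lag summary (positive lag = web later than lab)

  lab: peak bin 28 (2800-2900 ms), dip bin 4 (400-500 ms)
  web: peak bin 35 (3500-3600 ms), dip bin 64 (6400-6500 ms)

   peak: lag +7 bins (+700 ms)
    dip: lag +60 bins (+6000 ms)
  xcorr: lag +6 bins (+600 ms)
```

The cross-correlation estimate recovers the injected 600-ms webcam lag
exactly; the peak estimate is close (+700 ms); the dip comparison is
uninformative here because the simulated difference curve has no genuine
dip (see `docs/methods.md`).  The quasibinomial dispersion of 1.401 reflects
the between-participant variability the generator injects.

The same pipeline runs from the shell, one subcommand per stage:

```bash
deltagaze simulate --config sim.yaml --seed 1 --out data/
deltagaze label --gaze data/gaze.csv --trials data/trials.csv --viewports data/viewports.csv --out labeled.csv
deltagaze trim --gaze labeled.csv --trials data/trials.csv --out trimmed/
deltagaze bin --gaze trimmed/gaze_trimmed.csv --trials data/trials.csv --window 0:9000 --out bins.csv
deltagaze model --bins bins.csv --out models/
deltagaze delta --bins bins.csv --lag-method xcorr --out delta/
deltagaze run --seed 1 --out out/        # everything, with a manifest
```

## Layout

| module | contents |
| --- | --- |
| `deltagaze.simulate` | `SimulationConfig`, study design, gaze/trial generators |
| `deltagaze.aoi` | viewport AOIs, sample assignment, `AoiLabeler` |
| `deltagaze.preprocess` | 2-SD trims, √RT, 100-ms binning, transformers |
| `deltagaze.models` | `QuasibinomialGLM` (IRLS), `BinwiseGazeModel`, contrasts, mixed models |
| `deltagaze.delta` | Δgaze series, its linear model, lag estimators |
| `deltagaze.io` / `pipeline` / `cli` | CSV schemas, YAML configs, manifests, CLI |

Statistical background and design choices are documented in
`docs/methods.md`.
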