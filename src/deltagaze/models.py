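"""Accuracy, reaction-time, and per-bin gaze-proportion models.

Three model families mirror the analysis stages of a lab-vs-web visual-world
comparison:

* **Accuracy** — binomial mixed-effects logistic regression (structure x
  modality fixed effects, participant and item random intercepts), fit on the
  clinical group only when controls are at ceiling.
* **Reaction time** — linear mixed model on square-root RT with group x
  structure x modality fixed effects and crossed participant/item random
  intercepts; marginal and conditional variance-explained summaries included.
* **Gaze proportions** — quasibinomial (overdispersed logit) regression of
  per-trial per-bin target proportions, weighted by the number of gaze
  samples behind each proportion.  Random effects are deliberately absent
  from this family.  The fitting path is an iteratively reweighted least
  squares (IRLS) routine written here, with the dispersion estimated as
  Pearson chi-square over residual degrees of freedom and all standard
  errors scaled by its square root.

The per-bin engine (:class:`BinwiseGazeModel`) fits the omnibus
bin-by-predictor interaction model in its saturated cell-means
parameterization — one logit per (bin x factor-combination) cell — which
makes the per-bin contrast machinery exact and fast: contrasts are linear
combinations of cell logits with covariance ``dispersion / (w p (1-p))``
per cell.

The effect-size column ``d`` is computed as ``2 t / sqrt(df)``; this is an
approximation from the test statistic, not a standardized mean difference
computed from raw data.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from patsy import dmatrices
from scipy import stats
from scipy.special import expit, logit
from sklearn.base import BaseEstimator

log = logging.getLogger(__name__)


def effect_size_d(t: np.ndarray, df: np.ndarray) -> np.ndarray:
    """Approximate Cohen's d from a t statistic: ``d = 2 t / sqrt(df)``."""
    df = np.asarray(df, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        return 2.0 * np.asarray(t, dtype=float) / np.sqrt(df)


def _coef_table(names, est, se, df, use_t=True, ci_level=0.95) -> pd.DataFrame:
    est = np.asarray(est, float)
    se = np.asarray(se, float)
    df_arr = np.broadcast_to(np.asarray(df, float), est.shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = est / se
    if use_t:
        p = 2.0 * stats.t.sf(np.abs(stat), df_arr)
        crit = stats.t.ppf(0.5 + ci_level / 2.0, df_arr)
    else:
        p = 2.0 * stats.norm.sf(np.abs(stat))
        crit = np.full_like(est, stats.norm.ppf(0.5 + ci_level / 2.0))
    return pd.DataFrame({
        "term": list(names),
        "estimate": est,
        "se": se,
        "df": df_arr,
        "stat": stat,
        "p": p,
        "d": effect_size_d(stat, df_arr),
        "ci_low": est - crit * se,
        "ci_high": est + crit * se,
    })


@dataclass
class ModelFit:
    """A fitted model: coefficient table plus fit-level metadata."""

    table: pd.DataFrame
    method: str
    n_obs: int
    converged: bool = True
    dispersion: float | None = None
    extra: dict = field(default_factory=dict)

    def coef(self, term: str) -> pd.Series:
        rows = self.table[self.table["term"] == term]
        if rows.empty:
            raise KeyError(f"no term {term!r}; available: "
                           f"{list(self.table['term'])}")
        return rows.iloc[0]

    def __repr__(self) -> str:  # pragma: no cover
        return (f"<ModelFit {self.method}: {len(self.table)} terms, "
                f"n={self.n_obs}, converged={self.converged}>")


# ---------------------------------------------------------------------------
# quasibinomial IRLS


class QuasibinomialGLM(BaseEstimator):
    """Overdispersed logistic regression of proportions via IRLS.

    The response is a proportion in [0, 1]; each observation may carry a
    prior weight (the count of gaze samples behind the proportion).  Point
    estimates are the binomial maximum-likelihood estimates; inference uses
    the quasibinomial dispersion ``sum(w (y-mu)^2 / (mu(1-mu))) / (n - p)``
    (Pearson chi-square over residual df), multiplying the binomial
    covariance by the dispersion.  Tests are t-tests on ``n - p`` df.

    Parameters
    ----------
    formula : str
        Model formula, e.g. ``"proportion ~ C(bin) * group"``.
    weight_col : str or None
        Column of prior weights; None fits unweighted.
    """

    def __init__(self, formula: str = "proportion ~ 1",
                 weight_col: str | None = "n",
                 max_iter: int = 100, tol: float = 1e-12):
        self.formula = formula
        self.weight_col = weight_col
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, data: pd.DataFrame, y=None) -> "QuasibinomialGLM":
        ymat, X = dmatrices(self.formula, data, return_type="dataframe")
        yv = ymat.to_numpy(float).ravel()
        if not ((yv >= 0) & (yv <= 1)).all():
            raise ValueError("response must be a proportion in [0, 1]")
        Xv = X.to_numpy(float)
        if self.weight_col is not None:
            w = data.loc[X.index, self.weight_col].to_numpy(float)
        else:
            w = np.ones_like(yv)
        beta, cov_unit, mu, n_iter, converged = _irls_logit(
            Xv, yv, w, self.max_iter, self.tol)

        n, p = Xv.shape
        if n < p:
            raise ValueError("more parameters than observations")
        pearson = np.sum(w * (yv - mu) ** 2 / np.clip(mu * (1 - mu), 1e-12, None))
        # saturated fit: dispersion inestimable, covariance left unscaled
        self.dispersion_ = pearson / (n - p) if n > p else np.nan
        self.df_resid_ = n - p
        self.n_obs_ = n
        self.n_iter_ = n_iter
        self.converged_ = converged
        self.feature_names_ = list(X.columns)
        self.params_ = pd.Series(beta, index=self.feature_names_)
        self.cov_params_ = (cov_unit * self.dispersion_
                            if np.isfinite(self.dispersion_) else cov_unit)
        self.bse_ = pd.Series(np.sqrt(np.diag(self.cov_params_)),
                              index=self.feature_names_)
        self._design_info = X.design_info
        return self

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        from patsy import dmatrix
        X = dmatrix(self._design_info, data, return_type="dataframe")
        return expit(X.to_numpy(float) @ self.params_.to_numpy())

    def result(self) -> ModelFit:
        table = _coef_table(self.feature_names_, self.params_.to_numpy(),
                            self.bse_.to_numpy(), self.df_resid_)
        return ModelFit(table=table, method="quasibinomial-irls",
                        n_obs=self.n_obs_, converged=self.converged_,
                        dispersion=self.dispersion_,
                        extra={"n_iter": self.n_iter_})


def _irls_logit(X, y, w, max_iter=100, tol=1e-12):
    """Weighted logistic IRLS.  Returns (beta, unit covariance, mu, iters, ok)."""
    n, p = X.shape
    beta = np.zeros(p)
    eta = X @ beta
    dev_old = np.inf
    converged = False
    xtwx = None
    for it in range(1, max_iter + 1):
        mu = np.clip(expit(eta), 1e-10, 1 - 1e-10)
        var = mu * (1 - mu)
        W = w * var
        z = eta + (y - mu) / var
        XtW = X.T * W
        xtwx = XtW @ X
        try:
            beta = np.linalg.solve(xtwx, XtW @ z)
        except np.linalg.LinAlgError:
            beta = np.linalg.lstsq(xtwx, XtW @ z, rcond=None)[0]
        eta = X @ beta
        mu = np.clip(expit(eta), 1e-10, 1 - 1e-10)
        with np.errstate(divide="ignore", invalid="ignore"):
            dev = 2.0 * np.sum(w * (
                np.where(y > 0, y * np.log(y / mu), 0.0)
                + np.where(y < 1, (1 - y) * np.log((1 - y) / (1 - mu)), 0.0)))
        if abs(dev - dev_old) < tol * (abs(dev) + 0.1):
            converged = True
            break
        dev_old = dev
    try:
        cov_unit = np.linalg.inv(xtwx)
    except np.linalg.LinAlgError:
        cov_unit = np.linalg.pinv(xtwx)
    return beta, cov_unit, mu, it, converged


def fit_binwise(bincells: pd.DataFrame, formula: str,
                weight_col: str | None = "n") -> ModelFit:
    """Fit a quasibinomial proportion model from a formula and return its
    coefficient table.  Thin functional wrapper over
    :class:`QuasibinomialGLM`."""
    model = QuasibinomialGLM(formula=formula, weight_col=weight_col).fit(bincells)
    return model.result()


# ---------------------------------------------------------------------------
# omnibus bin-interaction engine (saturated cell-means parameterization)


class BinwiseGazeModel(BaseEstimator):
    """Omnibus quasibinomial model of proportions by bin x factors.

    Fits ``proportion ~ C(bin) * factor_1 * ... * factor_k`` in its saturated
    cell-means form: one logit per observed (bin, factor combination) cell.
    Because the design is an orthogonal one-hot basis, the weighted MLE of
    each cell logit is the logit of the weighted mean proportion in the cell,
    with covariance ``dispersion / (W_c p_c (1 - p_c))`` where ``W_c`` is the
    cell's total prior weight.  The dispersion is pooled across all cells
    (Pearson chi-square of the unit-level proportions over residual df) —
    exactly the single-omnibus-model route, as opposed to 120 separate
    per-bin fits with per-bin dispersions.

    Cells whose weighted proportion is exactly 0 or 1 get a half-unit
    continuity correction before the logit.

    Parameters
    ----------
    factors : tuple of str
        Grouping columns interacting with bin, e.g. ``("group",)`` or
        ``("group", "modality")``.
    use_weights : bool
        Weight unit proportions by their sample counts (default) or not.
    """

    def __init__(self, factors=("group",), bin_col="bin",
                 proportion_col="proportion", weight_col="n",
                 use_weights: bool = True):
        self.factors = factors
        self.bin_col = bin_col
        self.proportion_col = proportion_col
        self.weight_col = weight_col
        self.use_weights = use_weights

    def fit(self, bincells: pd.DataFrame, y=None) -> "BinwiseGazeModel":
        cols = [self.bin_col, *self.factors]
        df = bincells[cols + [self.proportion_col, self.weight_col]].copy()
        w = (df[self.weight_col].to_numpy(float) if self.use_weights
             else np.ones(len(df)))
        df["_w"] = w
        df["_wy"] = w * df[self.proportion_col].to_numpy(float)

        agg = df.groupby(cols, observed=True).agg(
            weight=("_w", "sum"), wy=("_wy", "sum"), n_units=("_w", "size"),
        ).reset_index()
        p = agg["wy"].to_numpy() / agg["weight"].to_numpy()
        boundary = (p <= 0) | (p >= 1)
        if boundary.any():
            wts = agg["weight"].to_numpy()
            p = np.where(boundary,
                         (agg["wy"].to_numpy() + 0.5) / (wts + 1.0), p)
        agg["p"] = p
        agg["eta"] = logit(p)

        # pooled Pearson dispersion over unit-level cells
        cell_p = df.merge(agg[cols + ["p"]], on=cols, how="left")["p"].to_numpy()
        yv = df[self.proportion_col].to_numpy(float)
        pearson = np.sum(w * (yv - cell_p) ** 2
                         / np.clip(cell_p * (1 - cell_p), 1e-12, None))
        n, k = len(df), len(agg)
        if n <= k:
            raise ValueError("saturated model needs more units than cells")
        self.dispersion_ = float(pearson / (n - k))
        self.df_resid_ = n - k
        self.n_obs_ = n
        agg["var_eta"] = self.dispersion_ / (
            agg["weight"].to_numpy() * agg["p"].to_numpy()
            * (1 - agg["p"].to_numpy()))
        self.cells_ = agg.drop(columns=["wy"])
        self.bins_ = np.sort(agg[self.bin_col].unique())
        return self

    def _require_fitted(self):
        if not hasattr(self, "cells_"):
            raise ValueError("model is not fitted")


def binwise_contrasts(
    model: BinwiseGazeModel,
    factor: str = "group",
    a: str = "pwa",
    b: str = "control",
    interaction_with: tuple | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-bin contrast ``a − b`` on the logit scale from an omnibus fit.

    When other factors besides ``factor`` are present, the contrast is taken
    on marginal means: cell logits are averaged over the other factors'
    levels with equal weights before differencing.  With
    ``interaction_with=(other_factor, m1, m2)`` the result is the difference
    of differences ``(a−b | m1) − (a−b | m2)`` per bin — e.g. whether the
    group effect is larger on the web than in the lab.

    Returns a DataFrame ordered by bin with ``estimate``, ``se``, ``t``,
    ``p`` and ``significant`` (two-sided at ``alpha``) columns.
    """
    model._require_fitted()
    cells = model.cells_
    if factor not in cells.columns:
        raise KeyError(f"factor {factor!r} not in the fitted model")
    for lev in (a, b):
        if lev not in set(cells[factor].unique()):
            raise KeyError(f"level {lev!r} of {factor!r} not estimable; "
                           f"available: {sorted(cells[factor].unique())}")

    other = [f for f in model.factors if f != factor]
    if interaction_with is not None:
        ofac, m1, m2 = interaction_with
        if ofac not in other:
            raise KeyError(f"interaction factor {ofac!r} not in the model")

    rows = []
    for b_idx in model.bins_:
        sub = cells[cells[model.bin_col] == b_idx]

        def marginal(level, restrict=None):
            sel = sub[sub[factor] == level]
            if restrict is not None:
                col, val = restrict
                sel = sel[sel[col] == val]
            if sel.empty:
                return None, None
            return sel["eta"].mean(), sel["var_eta"].sum() / len(sel) ** 2

        if interaction_with is None:
            ea, va = marginal(a)
            eb, vb = marginal(b)
            if ea is None or eb is None:
                continue
            est, var = ea - eb, va + vb
        else:
            ofac, m1, m2 = interaction_with
            parts = [marginal(a, (ofac, m1)), marginal(b, (ofac, m1)),
                     marginal(a, (ofac, m2)), marginal(b, (ofac, m2))]
            if any(x[0] is None for x in parts):
                continue
            est = parts[0][0] - parts[1][0] - (parts[2][0] - parts[3][0])
            var = sum(x[1] for x in parts)
        rows.append((b_idx, est, np.sqrt(var)))

    out = pd.DataFrame(rows, columns=["bin", "estimate", "se"])
    out["t"] = out["estimate"] / out["se"]
    out["df"] = model.df_resid_
    out["p"] = 2.0 * stats.t.sf(np.abs(out["t"]), model.df_resid_)
    out["significant"] = out["p"] < alpha
    name = (f"{a}-{b}" if interaction_with is None
            else f"({a}-{b}|{interaction_with[1]})-({a}-{b}|{interaction_with[2]})")
    out.insert(1, "contrast", name)
    return out.sort_values("bin").reset_index(drop=True)


def significant_windows(contrasts: pd.DataFrame) -> pd.DataFrame:
    """Summarize contiguous runs of significant bins as (onset, offset) rows.

    Runs are split where the sign of the estimate flips, mirroring how
    divergence windows are narrated (e.g. "PWA diverged from controls from
    1300–1400 ms onward").
    """
    sig = contrasts[contrasts["significant"]].sort_values("bin")
    rows = []
    start = prev = None
    sign = 0
    for r in sig.itertuples(index=False):
        s = 1 if r.estimate > 0 else -1
        if start is None or r.bin != prev + 1 or s != sign:
            if start is not None:
                rows.append((start, prev, sign))
            start, sign = r.bin, s
        prev = r.bin
    if start is not None:
        rows.append((start, prev, sign))
    return pd.DataFrame(rows, columns=["onset_bin", "offset_bin", "sign"])


def marginal_contrast(contrasts: pd.DataFrame, weights: np.ndarray) -> float:
    """Bin-frequency-weighted average of per-bin contrasts (the marginal
    effect implied by the omnibus fit)."""
    w = np.asarray(weights, float)
    return float(np.sum(contrasts["estimate"].to_numpy() * w) / np.sum(w))


# ---------------------------------------------------------------------------
# behavioral models (mixed-effects machinery delegated to statsmodels)


def _check_binary(y: pd.Series) -> None:
    levels = pd.unique(y)
    if len(levels) < 2:
        raise ValueError(f"degenerate response: single level {levels!r}")


def fit_accuracy(trials: pd.DataFrame, random_effects: bool = True) -> ModelFit:
    """Binomial (mixed) logistic model of accuracy.

    Intended for the clinical group only when controls are at ceiling;
    accuracy data are never trimmed.  Fixed effects: structure x modality.
    Random intercepts for participant and item are fit variationally; when
    that route fails (or ``random_effects=False``) a plain fixed-effects
    logistic GLM is used, with a logged warning.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = trials.copy()
    _check_binary(df["accurate"])
    df["acc"] = df["accurate"].astype(int)
    fixed = "acc ~ C(structure) * C(modality)"

    if random_effects:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                md = sm.BinomialBayesMixedGLM.from_formula(
                    fixed,
                    {"participant": "0 + C(participant)",
                     "item": "0 + C(trial_id)"},
                    df)
                res = md.fit_vb()
            k = len(md.exog_names)
            est, se = res.fe_mean, res.fe_sd
            if np.all(np.isfinite(est)) and np.all(se > 0):
                df_resid = len(df) - k
                table = _coef_table(md.exog_names, est, se, df_resid,
                                    use_t=False)
                return ModelFit(table=table, method="binomial-mixed-vb",
                                n_obs=len(df),
                                extra={"vc_mean": dict(zip(
                                    res.model.vcp_names, res.vcp_mean))})
        except Exception as exc:  # fall through to fixed-effects fit
            log.warning("mixed accuracy model failed (%s); "
                        "falling back to fixed-effects logistic", exc)

    if random_effects:
        log.warning("accuracy model fit without random effects")
    res = smf.glm(fixed, df, family=sm.families.Binomial()).fit()
    table = _coef_table(res.params.index, res.params.to_numpy(),
                        res.bse.to_numpy(), res.df_resid, use_t=False)
    return ModelFit(table=table, method="binomial-glm", n_obs=len(df),
                    converged=bool(res.converged))


def fit_rt(trials: pd.DataFrame, random_effects: bool = True) -> ModelFit:
    """Linear (mixed) model of square-root RT.

    Fixed effects: group x structure x modality; crossed random intercepts
    for participant and item, encoded as variance components.  Reports
    Nakagawa-style marginal/conditional variance-explained summaries.
    Falls back to OLS (with a warning) when the mixed fit fails.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = trials.copy()
    if "sqrt_rt" not in df.columns:
        raise ValueError("trials must carry a sqrt_rt column (transform_rt)")
    terms = ["C(structure)", "C(modality)"]
    if df["group"].nunique() > 1:
        terms.insert(0, "C(group)")
    fixed = "sqrt_rt ~ " + " * ".join(terms)

    if random_effects:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                md = smf.mixedlm(
                    fixed, df,
                    groups=np.ones(len(df)),
                    re_formula="0",
                    vc_formula={"participant": "0 + C(participant)",
                                "item": "0 + C(trial_id)"})
                res = md.fit(reml=True, method=["powell", "lbfgs"])
            if res.converged and np.all(np.isfinite(res.bse_fe)):
                fe = res.fe_params
                var_f = float(np.var(md.exog @ fe.to_numpy()))
                var_re = float(np.sum(res.vcomp))
                var_e = float(res.scale)
                tot = var_f + var_re + var_e
                k = len(fe)
                df_resid = len(df) - k
                table = _coef_table(fe.index, fe.to_numpy(),
                                    res.bse_fe.to_numpy(), df_resid)
                return ModelFit(
                    table=table, method="gaussian-mixed", n_obs=len(df),
                    extra={"r2_marginal": var_f / tot,
                           "r2_conditional": (var_f + var_re) / tot,
                           "var_components": dict(zip(md.exog_vc.names,
                                                      res.vcomp))})
        except Exception as exc:
            log.warning("mixed RT model failed (%s); falling back to OLS", exc)
        log.warning("RT model fit without random effects")

    res = smf.ols(fixed, df).fit()
    table = _coef_table(res.params.index, res.params.to_numpy(),
                        res.bse.to_numpy(), res.df_resid)
    return ModelFit(table=table, method="gaussian-ols", n_obs=len(df),
                    extra={"r2_marginal": float(res.rsquared),
                           "r2_conditional": float(res.rsquared)})
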