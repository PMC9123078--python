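"""Population-level pooling of per-response tuning metrics.

Three questions are answered across neurons of a cell type:

1. Does a response metric (amplitude A, resultant length r, or mean
   firing rate) depend on the degree of polarization? Ordinary least
   squares of the pooled metric on DoP; if the residuals fail a
   Monte-Carlo Lilliefors normality test the regression is redone on
   log10(DoP), and if that also fails the model with the higher R^2
   wins. Only neurons tested at >= 3 distinct DoPs enter the pool.
2. How many responses are significantly AoP-modulated per cell type and
   DoP (the significance tally)?
3. What is the lowest DoP at which AoP coding is reliable? The metric
   values of all responses must exceed the upper 95% confidence limit
   of the mean of the no-stimulus controls, at that DoP and at every
   higher one on the ladder.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .types import AnalysisConfig

__all__ = [
    "RegressionResult",
    "ThresholdResult",
    "lilliefors_test",
    "fit_dop_regression",
    "significance_tally",
    "nostim_confidence_limit",
    "estimate_threshold",
    "InsufficientDataError",
]


class InsufficientDataError(ValueError):
    pass


@dataclass
class RegressionResult:
    """Selected DoP regression for one (cell type, response metric)."""

    response_var: str
    cell_type: str
    model_form: str  # "linear_dop" or "linear_logdop"
    slope: float
    intercept: float
    r_squared: float
    resid_normal_p: float
    slope_p: float
    n_points: int
    neurons_used: list = field(default_factory=list)
    selection_path: list = field(default_factory=list)
    empty_reason: str | None = None

    @property
    def empty(self) -> bool:
        return self.empty_reason is not None


@dataclass
class ThresholdResult:
    """Lowest ladder DoP with reliable AoP coding for one cell type."""

    cell_type: str
    metric: str  # "r" or "A"
    nostim_mean: float
    nostim_upper95: float
    threshold_dop: float | None
    per_dop_pass: dict = field(default_factory=dict)  # DoP -> (n_above, n_total)


def _ks_normal_stat(x: np.ndarray) -> np.ndarray:
    """KS distance of each row of x from a normal with that row's estimated
    mean and (ddof=1) standard deviation."""
    x = np.atleast_2d(x)
    n = x.shape[1]
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    u = stats.norm.cdf(np.sort(x, axis=1), loc=mu, scale=sd)
    i = np.arange(1, n + 1)
    d_plus = (i / n - u).max(axis=1)
    d_minus = (u - (i - 1) / n).max(axis=1)
    return np.maximum(d_plus, d_minus)


def lilliefors_test(values, n_mc: int = 2000, seed: int | None = None) -> float:
    """Monte-Carlo Lilliefors test of composite normality.

    The KS statistic of the sample against a normal with estimated mean
    and standard deviation is compared with the same statistic on
    ``n_mc`` Gaussian samples of equal size; the p-value is the
    exceedance fraction (add-one corrected).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        raise InsufficientDataError("lilliefors_test: needs n >= 4")
    if np.ptp(x) == 0:
        raise InsufficientDataError("lilliefors_test: zero variance")
    d_obs = float(_ks_normal_stat(x)[0])
    rng = np.random.default_rng(seed)
    sims = rng.standard_normal((n_mc, x.size))
    d_sim = _ks_normal_stat(sims)
    return float((1 + np.sum(d_sim >= d_obs)) / (n_mc + 1))


def _results_frame(results) -> pd.DataFrame:
    if isinstance(results, pd.DataFrame):
        return results
    rows = []
    for tr in results:
        rows.append(
            {
                "neuron_id": tr.neuron_id,
                "cell_type": getattr(tr.cell_type, "value", tr.cell_type),
                "dop": tr.dop,
                "r": tr.r,
                "A": tr.A,
                "mean_rate": tr.mean_rate,
                "p": tr.p,
                "significant": tr.significant,
            }
        )
    return pd.DataFrame(rows)


def fit_dop_regression(
    results,
    response_var: str,
    cell_type: str | None = None,
    cfg: AnalysisConfig | None = None,
) -> RegressionResult:
    """OLS of a pooled response metric on DoP with normality-guided
    selection between the raw-DoP and log10-DoP predictors."""
    cfg = cfg or AnalysisConfig()
    df = _results_frame(results)
    if cell_type is not None:
        df = df[df["cell_type"] == cell_type]
    # eligibility: neurons tested at >= 3 distinct DoPs
    per_neuron = df.groupby("neuron_id")["dop"].nunique()
    eligible = per_neuron[per_neuron >= 3].index
    df = df[df["neuron_id"].isin(eligible)].dropna(subset=[response_var, "dop"])

    def empty(reason: str) -> RegressionResult:
        return RegressionResult(
            response_var=response_var, cell_type=cell_type or "all",
            model_form="none", slope=float("nan"), intercept=float("nan"),
            r_squared=float("nan"), resid_normal_p=float("nan"),
            slope_p=float("nan"), n_points=0, empty_reason=reason,
        )

    if df.empty or df["dop"].nunique() < 2:
        return empty("fewer than 2 distinct DoPs among eligible neurons")
    y = df[response_var].to_numpy(dtype=float)
    d = df["dop"].to_numpy(dtype=float)
    if cfg.log_transform == "response":
        transforms = {"linear_dop": (d, y), "linear_logdop": (d, _safe_log10(y))}
    else:
        transforms = {"linear_dop": (d, y), "linear_logdop": (_safe_log10(d), y)}

    path = []
    fits = {}
    for form in ("linear_dop", "linear_logdop"):
        x, yy = transforms[form]
        model = sm.OLS(yy, sm.add_constant(x)).fit()
        resid = np.asarray(model.resid)
        try:
            p_norm = lilliefors_test(resid, seed=cfg.rng_seed)
        except InsufficientDataError:
            p_norm = float("nan")
        fits[form] = (model, p_norm)
        path.append(f"{form}: R2={model.rsquared:.4f}, lilliefors_p={p_norm:.4f}")
        if np.isnan(p_norm) or p_norm >= cfg.alpha:
            chosen = form
            break
    else:
        # both residual sets non-normal: higher R^2 wins
        chosen = max(fits, key=lambda f: fits[f][0].rsquared)
        path.append(f"both non-normal -> chose {chosen} by R2")

    model, p_norm = fits[chosen]
    return RegressionResult(
        response_var=response_var,
        cell_type=cell_type or "all",
        model_form=chosen,
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        resid_normal_p=p_norm,
        slope_p=float(model.pvalues[1]),
        n_points=int(len(y)),
        neurons_used=sorted(df["neuron_id"].unique().tolist()),
        selection_path=path,
    )


def _safe_log10(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    tiny = np.finfo(float).tiny
    return np.log10(np.clip(v, tiny, None))


def significance_tally(results, cfg: AnalysisConfig | None = None) -> pd.DataFrame:
    """Counts of significant vs tested responses per cell type and DoP.

    Responses whose significance could not be tested (too few spikes,
    degenerate counts) are excluded from n_tested.
    """
    df = _results_frame(results)
    if df.empty:
        return pd.DataFrame(columns=["cell_type", "dop", "n_significant", "n_tested"])
    testable = df[np.isfinite(df["p"].astype(float))]
    out = (
        testable.groupby(["cell_type", "dop"])
        .agg(n_significant=("significant", "sum"), n_tested=("significant", "size"))
        .reset_index()
    )
    out["n_significant"] = out["n_significant"].astype(int)
    return out.sort_values(["cell_type", "dop"], ascending=[True, False]).reset_index(
        drop=True
    )


def nostim_confidence_limit(
    controls, cfg: AnalysisConfig | None = None
) -> tuple[float, float]:
    """Mean of the no-stimulus control values and the upper confidence
    limit of that mean (Student t, two-sided at ``ci_level``)."""
    cfg = cfg or AnalysisConfig()
    x = np.asarray(controls, dtype=float)
    x = x[np.isfinite(x)]
    n = x.size
    if n < 3:
        raise InsufficientDataError("nostim_confidence_limit: needs >= 3 controls")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    tcrit = float(stats.t.ppf(0.5 + cfg.ci_level / 2.0, n - 1))
    return mean, mean + tcrit * sd / np.sqrt(n)


def estimate_threshold(
    results,
    controls,
    cell_type: str | None = None,
    metric: str = "r",
    cfg: AnalysisConfig | None = None,
) -> ThresholdResult:
    """Lowest ladder DoP at which the metric values of *all* responses
    exceed the no-stimulus upper confidence limit.

    Walks the ladder from the highest DoP downward; a failure at any
    level voids every lower candidate, so the returned threshold is the
    lowest DoP of the unbroken passing run from the top. None if the
    highest ladder DoP already fails.
    """
    cfg = cfg or AnalysisConfig()
    if metric not in ("r", "A", "mean_rate"):
        raise ValueError(f"unknown threshold metric {metric!r}")
    mean, upper = nostim_confidence_limit(controls, cfg)
    df = _results_frame(results)
    if cell_type is not None:
        df = df[df["cell_type"] == cell_type]
    df = df.dropna(subset=[metric])
    ladder = sorted(df["dop"].unique(), reverse=True)
    per_dop = {}
    threshold = None
    run_intact = True
    for dop in ladder:
        vals = df.loc[df["dop"] == dop, metric].to_numpy(dtype=float)
        n_above = int(np.sum(vals > upper))
        per_dop[dop] = (n_above, vals.size)
        if run_intact and vals.size and n_above == vals.size:
            threshold = dop
        else:
            run_intact = False
    return ThresholdResult(
        cell_type=cell_type or "all",
        metric=metric,
        nostim_mean=mean,
        nostim_upper95=upper,
        threshold_dop=threshold,
        per_dop_pass=per_dop,
    )
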