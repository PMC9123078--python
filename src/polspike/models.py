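"""Model/Results objects — the package's main user-facing surface.

Two estimation problems are exposed in the familiar build-then-fit
idiom:

* :class:`AoPTuning` — per-neuron tuning analysis. Built from a
  :class:`~polspike.types.Recording`; ``fit()`` analyzes every eligible
  stimulus epoch and returns :class:`AoPTuningResults` with one
  TuningResult per (epoch, DoP), the no-stimulus controls, a tidy
  DataFrame view and a ``summary()`` table.

* :class:`DoPRegression` — population dependence of a response metric
  (A, r or mean rate) on the degree of polarization, with the
  normality-guided choice between raw-DoP and log10-DoP predictors.
  Built from pooled tuning results; ``fit()`` returns
  :class:`DoPRegressionResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .population import (
    RegressionResult,
    ThresholdResult,
    estimate_threshold,
    fit_dop_regression,
)
from .response import (
    ProtocolError,
    TuningResult,
    analyze_response,
    no_stimulus_metrics,
    normalized_extremes,
)
from .types import AnalysisConfig, Recording

__all__ = [
    "AoPTuning",
    "AoPTuningResults",
    "DoPRegression",
    "DoPRegressionResults",
]


class AoPTuning:
    """Tuning analysis of one recording across its stimulus epochs."""

    def __init__(self, recording: Recording, config: AnalysisConfig | None = None):
        self.recording = recording
        self.config = config or AnalysisConfig()

    def fit(self, fit_curve: bool = True) -> "AoPTuningResults":
        results: list[TuningResult] = []
        controls: list[dict] = []
        skipped: list[str] = []
        for epoch in self.recording.epochs:
            try:
                results.append(
                    analyze_response(self.recording, epoch, self.config, fit_curve)
                )
            except ProtocolError as exc:
                skipped.append(str(exc))
                continue
            ctl = no_stimulus_metrics(self.recording, epoch, self.config)
            if ctl is not None:
                ctl.update(
                    neuron_id=self.recording.spike_train.neuron_id,
                    cell_type=self.recording.spike_train.cell_type.value,
                    dop=epoch.dop,
                )
                controls.append(ctl)
        return AoPTuningResults(
            model=self, results=results, controls=controls, skipped=skipped
        )


@dataclass
class AoPTuningResults:
    """Per-response tuning metrics of one neuron, with control values."""

    model: AoPTuning
    results: list[TuningResult]
    controls: list[dict]
    skipped: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for tr in self.results:
            act_max, act_min = normalized_extremes(tr)
            rows.append(
                {
                    "neuron_id": tr.neuron_id,
                    "cell_type": tr.cell_type.value,
                    "dop": tr.dop,
                    "n_spikes": tr.n_spikes,
                    "phi_max_deg": tr.phi_max,
                    "phi_min_deg": tr.phi_min,
                    "r": tr.r,
                    "r_cl": tr.r_cl,
                    "p": tr.p,
                    "significant": tr.significant,
                    "A": tr.A,
                    "rate_phimax_hz": tr.rate_phi_max,
                    "rate_phimin_hz": tr.rate_phi_min,
                    "mean_rate_hz": tr.mean_rate,
                    "ba_median_hz": tr.background.median,
                    "ba_p2_5_hz": tr.background.p2_5,
                    "ba_p97_5_hz": tr.background.p97_5,
                    "act_max_norm": act_max if act_max is not None else np.nan,
                    "act_min_norm": act_min if act_min is not None else np.nan,
                    "flags": ";".join(tr.flags),
                }
            )
        return pd.DataFrame(rows)

    def controls_frame(self) -> pd.DataFrame:
        cols = ["neuron_id", "cell_type", "dop", "r", "A", "mean_rate", "n"]
        return pd.DataFrame(self.controls, columns=cols)

    def summary(self) -> str:
        st = self.model.recording.spike_train
        lines = [
            f"AoP tuning analysis — neuron {st.neuron_id} ({st.cell_type.value})",
            f"  epochs analyzed: {len(self.results)}; "
            f"controls: {len(self.controls)}; skipped: {len(self.skipped)}",
            f"  {'DoP':>6} {'n':>5} {'Phi_max':>8} {'r':>6} {'p':>9} "
            f"{'sig':>4} {'A':>7} {'rate@max':>9} {'rate@min':>9}",
        ]
        for tr in self.results:
            lines.append(
                f"  {tr.dop:>6g} {tr.n_spikes:>5d} {tr.phi_max:>8.1f} "
                f"{tr.r:>6.3f} {tr.p:>9.2e} {str(tr.significant)[0]:>4} "
                f"{tr.A:>7.2f} {tr.rate_phi_max:>9.2f} {tr.rate_phi_min:>9.2f}"
            )
        return "\n".join(lines)

    def plot_tuning(self, index: int = 0, ax=None):
        """Binned rates and the fitted von Mises curve for one response."""
        import matplotlib.pyplot as plt

        from .circstats import rate_at

        tr = self.results[index]
        if ax is None:
            _, ax = plt.subplots()
        ax.bar(tr.binned.bin_centers, tr.binned.rates,
               width=0.9 * np.diff(tr.binned.bin_edges)[0], alpha=0.5,
               label="binned rate")
        if tr.fit.converged:
            grid = np.linspace(0, 180, 361)
            ax.plot(grid, rate_at(tr.fit, grid), "r-", label="von Mises fit")
        if np.isfinite(tr.phi_max):
            ax.axvline(tr.phi_max, color="k", ls="--", label=r"$\Phi_{max}$")
        ax.set_xlabel("AoP (deg)")
        ax.set_ylabel("rate (spikes/s)")
        ax.set_title(f"{tr.neuron_id}, DoP={tr.dop:g}")
        ax.legend(fontsize=8)
        return ax


class DoPRegression:
    """Dependence of a pooled response metric on the degree of polarization."""

    def __init__(
        self,
        results,
        response_var: str = "A",
        cell_type: str | None = None,
        config: AnalysisConfig | None = None,
    ):
        self.results = results
        self.response_var = response_var
        self.cell_type = cell_type
        self.config = config or AnalysisConfig()

    def fit(self) -> "DoPRegressionResults":
        reg = fit_dop_regression(
            self.results, self.response_var, self.cell_type, self.config
        )
        return DoPRegressionResults(model=self, regression=reg)


@dataclass
class DoPRegressionResults:
    model: DoPRegression
    regression: RegressionResult

    @property
    def params(self) -> pd.Series:
        return pd.Series(
            {"intercept": self.regression.intercept, "slope": self.regression.slope}
        )

    @property
    def rsquared(self) -> float:
        return self.regression.r_squared

    @property
    def model_form(self) -> str:
        return self.regression.model_form

    @property
    def slope_p(self) -> float:
        return self.regression.slope_p

    def threshold(self, controls, metric: str | None = None) -> ThresholdResult:
        """Reliable-coding threshold of the same metric against the
        no-stimulus controls' upper confidence limit."""
        return estimate_threshold(
            self.model.results,
            controls,
            cell_type=self.model.cell_type,
            metric=metric or self.model.response_var,
            cfg=self.model.config,
        )

    def summary(self) -> str:
        reg = self.regression
        if reg.empty:
            return f"DoP regression of {reg.response_var}: empty ({reg.empty_reason})"
        pred = "DoP" if reg.model_form == "linear_dop" else "log10(DoP)"
        lines = [
            f"DoP regression — {reg.response_var} ~ {pred} "
            f"[{reg.cell_type}]",
            f"  n points: {reg.n_points}  neurons: {len(reg.neurons_used)}",
            f"  slope:     {reg.slope:>10.4f}  (p = {reg.slope_p:.3g})",
            f"  intercept: {reg.intercept:>10.4f}",
            f"  R^2:       {reg.r_squared:>10.4f}",
            f"  residual normality (Lilliefors p): {reg.resid_normal_p:.3g}",
            "  selection: " + " | ".join(reg.selection_path),
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        from .population import _results_frame

        reg = self.regression
        df = _results_frame(self.model.results)
        if self.model.cell_type is not None:
            df = df[df["cell_type"] == self.model.cell_type]
        if ax is None:
            _, ax = plt.subplots()
        ax.semilogx(df["dop"], df[reg.response_var], "ko", ms=4, alpha=0.6)
        if not reg.empty:
            grid = np.geomspace(max(df["dop"].min(), 1e-3), df["dop"].max(), 100)
            x = grid if reg.model_form == "linear_dop" else np.log10(grid)
            ax.semilogx(grid, reg.intercept + reg.slope * x, "r-")
        ax.set_xlabel("DoP")
        ax.set_ylabel(reg.response_var)
        ax.set_title(f"{reg.cell_type}: {reg.response_var} vs DoP ({reg.model_form})")
        return ax
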