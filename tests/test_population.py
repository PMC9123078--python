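"""Population stage: Lilliefors test, DoP regressions, tally, thresholds."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.diagnostic import lilliefors as sm_lilliefors

from polspike import (
    AnalysisConfig,
    estimate_threshold,
    fit_dop_regression,
    lilliefors_test,
    nostim_confidence_limit,
    significance_tally,
)
from polspike.population import InsufficientDataError

LADDER = (0.99, 0.35, 0.1, 0.05, 0.002)


def results_frame(values_by_dop, metric="r", cell_type="TL2", n_neurons=4):
    """Tidy per-response frame with each neuron tested at every DoP."""
    rows = []
    for j in range(n_neurons):
        for dop, val in values_by_dop.items():
            v = val[j] if np.ndim(val) else val
            rows.append({"neuron_id": f"n{j}", "cell_type": cell_type, "dop": dop,
                         "r": v, "A": v, "mean_rate": v, "p": 0.01,
                         "significant": True})
    return pd.DataFrame(rows)


class TestLilliefors:
    def test_constant_vector_degenerate(self):
        with pytest.raises(InsufficientDataError):
            lilliefors_test([3.0, 3.0, 3.0, 3.0])

    def test_gaussian_calibration(self):
        rng = np.random.default_rng(1)
        rejections = sum(
            lilliefors_test(rng.standard_normal(200), n_mc=400,
                            seed=int(rng.integers(2**31))) < 0.05
            for _ in range(300)
        )
        assert 0.02 <= rejections / 300 <= 0.08

    def test_exponential_power(self):
        rng = np.random.default_rng(2)
        rejections = sum(
            lilliefors_test(rng.exponential(1.0, 200), n_mc=400,
                            seed=int(rng.integers(2**31))) < 0.05
            for _ in range(100)
        )
        assert rejections >= 95

    def test_agrees_with_statsmodels_reference(self):
        """Dual route: the Monte-Carlo p-value tracks statsmodels' lilliefors."""
        rng = np.random.default_rng(3)
        for sample in (rng.standard_normal(150),
                       rng.exponential(1.0, 150),
                       rng.uniform(size=150),
                       rng.standard_t(3, 150)):
            p_ours = lilliefors_test(sample, n_mc=2000, seed=0)
            p_ref = sm_lilliefors(sample, dist="norm")[1]
            assert (p_ours < 0.05) == (p_ref < 0.05) or abs(p_ours - p_ref) < 0.03


class TestDopRegression:
    def test_exact_linear_recovery(self):
        vals = {d: 3.0 + 20.0 * d for d in LADDER}
        df = results_frame({d: [vals[d]] * 4 for d in LADDER})
        reg = fit_dop_regression(df, "r", "TL2")
        assert reg.model_form == "linear_dop"
        assert reg.slope == pytest.approx(20.0, abs=1e-9)
        assert reg.intercept == pytest.approx(3.0, abs=1e-9)
        assert reg.r_squared == pytest.approx(1.0)

    def test_linear_generator_selected(self):
        rng = np.random.default_rng(4)
        chosen = []
        for _ in range(20):
            df = results_frame(
                {d: 3.0 + 20.0 * d + rng.normal(0, 0.5, 40) for d in LADDER},
                n_neurons=40)
            chosen.append(fit_dop_regression(df, "r", "TL2").model_form)
        assert chosen.count("linear_dop") >= 17

    def test_log_generator_selected(self):
        rng = np.random.default_rng(5)
        chosen = []
        for _ in range(20):
            df = results_frame(
                {d: 5.0 + 4.0 * np.log10(d) + rng.normal(0, 0.3, 40)
                 for d in LADDER},
                n_neurons=40)
            chosen.append(fit_dop_regression(df, "r", "TL2").model_form)
        assert chosen.count("linear_logdop") >= 17

    def test_neurons_with_few_dops_excluded(self):
        df = results_frame({d: 1.0 + d for d in LADDER})
        # one extra neuron tested at only two DoPs must not enter the pool
        extra = pd.DataFrame([
            {"neuron_id": "x", "cell_type": "TL2", "dop": 0.99, "r": 99.0,
             "A": 99.0, "mean_rate": 99.0, "p": 0.01, "significant": True},
            {"neuron_id": "x", "cell_type": "TL2", "dop": 0.35, "r": 99.0,
             "A": 99.0, "mean_rate": 99.0, "p": 0.01, "significant": True},
        ])
        reg = fit_dop_regression(pd.concat([df, extra]), "r", "TL2")
        assert "x" not in reg.neurons_used

    def test_empty_pool_reports_reason(self):
        df = results_frame({0.99: 1.0, 0.35: 2.0})  # only 2 DoPs per neuron
        reg = fit_dop_regression(df, "r", "TL2")
        assert reg.empty

    def test_affine_equivariance_of_slope(self):
        rng = np.random.default_rng(6)
        df = results_frame(
            {d: 3.0 + 20.0 * d + rng.normal(0, 0.5, 8) for d in LADDER},
            n_neurons=8)
        df2 = df.copy()
        df2["r"] = 10.0 * df2["r"] + 1.0
        a = fit_dop_regression(df, "r", "TL2", AnalysisConfig(rng_seed=1))
        b = fit_dop_regression(df2, "r", "TL2", AnalysisConfig(rng_seed=1))
        assert b.slope == pytest.approx(10.0 * a.slope, rel=1e-9)
        assert b.model_form == a.model_form


class TestTally:
    def test_all_significant_cohort(self):
        df = results_frame({d: 0.5 for d in LADDER})
        tally = significance_tally(df)
        assert (tally["n_significant"] == tally["n_tested"]).all()

    def test_empty_input(self):
        assert significance_tally(pd.DataFrame()).empty

    def test_untestable_responses_excluded(self):
        df = results_frame({0.99: 0.5})
        df.loc[0, "p"] = np.nan
        tally = significance_tally(df)
        assert tally["n_tested"].iloc[0] == 3


class TestNostimLimit:
    def test_zero_variance_controls(self):
        mean, upper = nostim_confidence_limit([0.2, 0.2, 0.2])
        assert mean == pytest.approx(0.2) and upper == pytest.approx(0.2)

    def test_t_based_closed_form(self):
        mean, upper = nostim_confidence_limit([0.1, 0.2, 0.3])
        assert mean == pytest.approx(0.2)
        assert upper == pytest.approx(0.4484, abs=1e-3)

    def test_too_few_controls(self):
        with pytest.raises(InsufficientDataError):
            nostim_confidence_limit([0.1, 0.2])

    def test_coverage_of_true_mean(self):
        rng = np.random.default_rng(7)
        cover = 0
        n_rep = 1000
        for _ in range(n_rep):
            x = rng.normal(0.1, 0.03, 12)
            mean, upper = nostim_confidence_limit(x)
            lower = 2 * mean - upper  # symmetric t interval
            cover += lower <= 0.1 <= upper
        assert 0.93 <= cover / n_rep <= 0.97


class TestThreshold:
    def test_all_below_limit_gives_none(self):
        df = results_frame({d: 0.01 for d in LADDER})
        th = estimate_threshold(df, controls=[0.1, 0.12, 0.14], cell_type="TL2")
        assert th.threshold_dop is None

    def test_always_above_gives_lowest_dop(self):
        df = results_frame({d: 0.9 for d in LADDER}, n_neurons=1)
        th = estimate_threshold(df, controls=[0.05, 0.06, 0.07], cell_type="TL2")
        assert th.threshold_dop == 0.002

    def test_step_cohort_recovers_planted_level(self):
        vals = {0.99: 0.8, 0.35: 0.7, 0.1: 0.6, 0.05: 0.02, 0.002: 0.01}
        df = results_frame(vals)
        th = estimate_threshold(df, controls=[0.04, 0.05, 0.06], cell_type="TL2")
        assert th.threshold_dop == 0.1
        assert th.per_dop_pass[0.05] == (0, 4)

    def test_single_outlier_at_high_dop_voids_lower_candidates(self):
        vals = {0.99: [0.8, 0.8, 0.8, 0.8], 0.35: [0.8, 0.02, 0.8, 0.8],
                0.1: [0.8] * 4, 0.05: [0.8] * 4, 0.002: [0.8] * 4}
        df = results_frame(vals)
        th = estimate_threshold(df, controls=[0.04, 0.05, 0.06], cell_type="TL2")
        assert th.threshold_dop == 0.99

    def test_monotone_in_confidence_limit(self):
        """Raising the no-stimulus limit can only raise (or void) the threshold."""
        rng = np.random.default_rng(8)
        order = {d: i for i, d in enumerate(sorted(LADDER))}
        for _ in range(50):
            vals = {d: rng.uniform(0, 1, 4) for d in LADDER}
            df = results_frame(vals)
            base = rng.uniform(0.1, 0.6)
            lo = estimate_threshold(df, controls=[base - 0.02, base, base + 0.02],
                                    cell_type="TL2")
            hi = estimate_threshold(df, controls=[base + 0.18, base + 0.2,
                                                  base + 0.22], cell_type="TL2")
            if lo.threshold_dop is None:
                assert hi.threshold_dop is None
            elif hi.threshold_dop is not None:
                assert order[hi.threshold_dop] >= order[lo.threshold_dop]
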