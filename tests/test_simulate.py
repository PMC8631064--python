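import dataclasses

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import expit, logit

from msmiss import (
    DGMConfig,
    MissingnessConfig,
    apply_missingness,
    calibrate_missingness,
    missingness_summary,
    simulate_full_data,
)
from msmiss.errors import CalibrationError, ConfigurationError
from msmiss.simulate import default_missingness, maskable_cells, realized_missingness


class TestSimulateFullData:
    def test_reproducible(self, dgm):
        a = simulate_full_data(dgm, 200, 42)
        b = simulate_full_data(dgm, 200, 42)
        assert a.true.equals(b.true) and a.mask.equals(b.mask)
        c = simulate_full_data(dgm, 200, 43)
        assert not a.true.equals(c.true)

    def test_columns_and_no_missing(self, small_panel):
        assert list(small_panel.true.columns) == [
            "id", "V", "L1_0", "L2_0", "A_0", "L1_1", "L2_1", "A_1",
            "L1_2", "L2_2", "A_2", "Y",
        ]
        assert not small_panel.has_missing()

    def test_invalid_n(self, dgm):
        with pytest.raises(ConfigurationError, match="n"):
            simulate_full_data(dgm, 0, 1)

    def test_randomized_treatment_limit(self):
        """With zero treatment-model slopes, treatment is independent of L."""
        cfg = DGMConfig(treat_l1=0.0, treat_l2=0.0, treat_prev=0.0)
        panel = simulate_full_data(cfg, 50_000, 7)
        df = panel.true
        for k in range(3):
            p1 = df.loc[df[f"L1_{k}"] == 1, f"A_{k}"].mean()
            p0 = df.loc[df[f"L1_{k}"] == 0, f"A_{k}"].mean()
            se = np.sqrt(0.25 * (4 / len(df)))
            assert abs(p1 - p0) < 4 * se

    def test_confounded_treatment_matches_logistic_model(self, big_panel, dgm):
        """P(A_0=1 | L1_0, L2_0) follows the configured logistic model."""
        df = big_panel.true
        for l1 in (0, 1):
            sel = (df["L1_0"] == l1) & (df["L2_0"].abs() < 0.1)
            expected = expit(
                dgm.treat_intercepts[0] + dgm.treat_l1 * l1 + dgm.treat_l2 * df.loc[sel, "L2_0"]
            ).mean()
            observed = df.loc[sel, "A_0"].mean()
            se = np.sqrt(expected * (1 - expected) / sel.sum())
            assert abs(observed - expected) < 4 * se
        assert (
            df.loc[df["L1_0"] == 1, "A_0"].mean() > df.loc[df["L1_0"] == 0, "A_0"].mean()
        )

    def test_treatment_confounder_feedback(self, big_panel):
        """Earlier treatment shifts the later continuous confounder upward."""
        df = big_panel.true
        assert (
            df.loc[df["A_0"] == 1, "L2_1"].mean()
            > df.loc[df["A_0"] == 0, "L2_1"].mean() + 0.1
        )


class TestApplyMissingness:
    def test_mcar_probability_zero_is_identity(self, small_panel):
        mc = MissingnessConfig(mechanism="MCAR", intercept=-40.0)
        out = apply_missingness(small_panel, mc, 3)
        assert not out.has_missing()
        assert out.true.equals(small_panel.true)

    def test_mask_only_contract(self, small_panel):
        """Non-differential overlays never alter true values, only flags."""
        for mech in ("MCAR", "MAR_AL", "MAR_ALY", "MAR_ALV", "CONSTANT"):
            mc = MissingnessConfig(mechanism=mech, intercept=-0.5)
            out = apply_missingness(small_panel, mc, 3)
            assert out.true.equals(small_panel.true), mech

    def test_refuses_preexisting_missingness(self, small_panel):
        mc = MissingnessConfig(mechanism="MCAR", intercept=0.0)
        once = apply_missingness(small_panel, mc, 3)
        with pytest.raises(ConfigurationError, match="already"):
            apply_missingness(once, mc, 4)

    def test_baseline_observed_under_history_mechanisms(self, small_panel):
        for mech in ("MAR_AL", "MAR_ALY", "MAR_ALV", "CONSTANT", "DIFFERENTIAL"):
            mc = MissingnessConfig(mechanism=mech, intercept=0.5)
            out = apply_missingness(small_panel, mc, 3)
            assert not out.mask[["M_L1_0", "M_L2_0"]].to_numpy().any(), mech
            assert out.mask[["M_L1_1", "M_L2_1"]].to_numpy().any(), mech

    def test_mcar_masks_baseline(self, small_panel):
        mc = MissingnessConfig(mechanism="MCAR", intercept=0.0)
        out = apply_missingness(small_panel, mc, 3)
        assert out.mask["M_L1_0"].any() and out.mask["M_L2_0"].any()

    def test_constant_masks_only_exact_repeats(self, dgm):
        panel = simulate_full_data(dgm, 5_000, 21)
        mc = MissingnessConfig(mechanism="CONSTANT", intercept=5.0)
        out = apply_missingness(panel, mc, 21)
        df, mask = out.true, out.mask
        for var in ("L1", "L2"):
            for k in (1, 2):
                changed = df[f"{var}_{k}"].to_numpy() != df[f"{var}_{k - 1}"].to_numpy()
                assert not mask.loc[changed, f"M_{var}_{k}"].any()
        # with a huge intercept, virtually every exact repeat is masked
        repeat = df["L2_1"].to_numpy() == df["L2_0"].to_numpy()
        assert mask.loc[repeat, "M_L2_1"].mean() > 0.98

    def test_constant_requires_sticky_dynamics(self):
        cfg = DGMConfig(carryover=0.0)
        panel = simulate_full_data(cfg, 100, 1)
        mc = MissingnessConfig(mechanism="CONSTANT", intercept=0.0)
        with pytest.raises(ConfigurationError, match="carryover"):
            apply_missingness(panel, mc, 1)

    def test_mar_slope_recovery(self, dgm):
        """Realized missingness log-odds recover the configured slopes."""
        panel = simulate_full_data(dgm, 60_000, 31)
        mc = MissingnessConfig(
            mechanism="MAR_AL", intercept=-1.0,
            slope_prev_treat=0.5, slope_prev_l1=0.7, slope_prev_l2=0.5,
        )
        out = apply_missingness(panel, mc, 31)
        df = out.true
        flag = out.mask["M_L1_1"].to_numpy().astype(float)
        X = sm.add_constant(df[["A_0", "L1_0", "L2_0"]].to_numpy(dtype=float))
        res = sm.GLM(flag, X, family=sm.families.Binomial()).fit()
        target = np.array([-1.0, 0.5, 0.7, 0.5])
        assert np.all(np.abs(res.params - target) < 3 * res.bse)

    def test_differential_severs_contemporaneous_edge(self, dgm):
        """Among records with L1_k masked, treatment no longer depends on true L1_k."""
        panel = simulate_full_data(dgm, 80_000, 41)
        mc = default_missingness("DIFFERENTIAL", 0.40, dgm)
        out = apply_missingness(panel, mc, 41)
        df = out.true
        k = 2
        X = sm.add_constant(
            df[[f"L1_{k}", f"L2_{k}", f"A_{k - 1}"]].to_numpy(dtype=float)
        )
        y = df[f"A_{k}"].to_numpy(dtype=float)
        masked = out.mask[f"M_L1_{k}"].to_numpy()
        res_mask = sm.GLM(y[masked], X[masked], family=sm.families.Binomial()).fit()
        res_obs = sm.GLM(y[~masked], X[~masked], family=sm.families.Binomial()).fit()
        assert abs(res_mask.params[1]) < 3 * res_mask.bse[1]  # severed edge
        assert abs(res_obs.params[1] - dgm.treat_l1) < 3 * res_obs.bse[1]

    def test_differential_preserves_baseline_and_v(self, small_panel):
        mc = MissingnessConfig(
            mechanism="DIFFERENTIAL", intercept=-0.5, slope_prev_treat=0.5
        )
        out = apply_missingness(small_panel, mc, 3)
        for col in ("id", "V", "L1_0", "L2_0"):
            assert np.array_equal(out.true[col].to_numpy(), small_panel.true[col].to_numpy())


class TestCalibration:
    def test_mcar_intercept_is_logit_target(self, dgm):
        mc = MissingnessConfig(mechanism="MCAR")
        out = calibrate_missingness(mc, dgm, 0.40, seed=1)
        assert out.intercept == pytest.approx(float(logit(0.40)))

    @pytest.mark.parametrize("target,lo,hi", [(0.40, 0.38, 0.42), (0.05, 0.03, 0.07)])
    def test_main_and_secondary_targets(self, dgm, target, lo, hi):
        mc = MissingnessConfig(
            mechanism="MAR_AL", slope_prev_treat=0.5, slope_prev_l1=0.7, slope_prev_l2=0.5
        )
        out = calibrate_missingness(mc, dgm, target, seed=2)
        fresh = apply_missingness(simulate_full_data(dgm, 20_000, 77), out, 78)
        assert lo < realized_missingness(fresh, out) < hi

    def test_unreachable_target_reports_range(self, dgm):
        mc = MissingnessConfig(mechanism="CONSTANT")
        with pytest.raises(CalibrationError, match="achievable range"):
            calibrate_missingness(mc, dgm, 0.95, seed=3)

    def test_invalid_target(self, dgm):
        with pytest.raises(ConfigurationError, match="target"):
            calibrate_missingness(MissingnessConfig(mechanism="MCAR"), dgm, 1.2, seed=1)


class TestMissingnessSummary:
    def test_fully_observed_panel(self, small_panel):
        s = missingness_summary(small_panel)
        assert s.overall == 0.0
        assert len(s.patterns) == 1
        assert s.patterns["pattern"].iloc[0] == "complete"
        assert int(s.patterns["count"].iloc[0]) == small_panel.n

    def test_pattern_counts_sum_to_n(self, small_panel, dgm):
        mc = default_missingness("MCAR", 0.40, dgm)
        out = apply_missingness(small_panel, mc, 9)
        s = missingness_summary(out)
        assert int(s.patterns["count"].sum()) == small_panel.n

    @pytest.mark.parametrize("n_times,limit", [(2, 16)])
    def test_pattern_count_bound(self, n_times, limit):
        cfg = DGMConfig(n_times=n_times, treat_intercepts=0.0)
        panel = simulate_full_data(cfg, 2_000, 5)
        mc = MissingnessConfig(mechanism="MCAR", intercept=0.0)
        out = apply_missingness(panel, mc, 5)
        s = missingness_summary(out)
        assert 1 < len(s.patterns) <= limit

    def test_one_time_point_at_most_four_patterns(self):
        """Two confounders at one masked time give at most 4 patterns."""
        cfg = DGMConfig(n_times=2, treat_intercepts=0.0)
        panel = simulate_full_data(cfg, 2_000, 6)
        mc = MissingnessConfig(mechanism="MAR_AL", intercept=0.0)
        out = apply_missingness(panel, mc, 6)  # masks k=1 only
        s = missingness_summary(out)
        assert 1 < len(s.patterns) <= 4
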