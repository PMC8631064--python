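import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msmiss import (
    MissingnessConfig,
    apply_missingness,
    complete_case,
    full_data,
    ipmw_estimate,
    locf_impute,
    mi_estimate,
    mpa_weights,
    rubin_pool,
    simulate_full_data,
)
from msmiss.errors import EmptyAnalysisError, EstimationError, UnsupportedMethodError
from msmiss.methods import ipmw_missing_weights, chained_imputation

from conftest import make_panel


@pytest.fixture(scope="module")
def masked_panel(dgm):
    panel = simulate_full_data(dgm, 2_000, 71)
    mc = MissingnessConfig(mechanism="MCAR", intercept=-1.0)
    return apply_missingness(panel, mc, 71)


class TestCompleteCase:
    def test_fully_observed_is_identity(self, small_panel):
        sub, est = complete_case(small_panel)
        assert sub.true.equals(small_panel.true)
        ref = full_data(small_panel)
        assert np.array_equal(est.params, ref.params)

    def test_counting(self):
        rows = [
            {f"{v}_{k}": 0.0 for k in range(3) for v in ("L1", "L2")}
            | {f"A_{k}": 0 for k in range(3)} | {"Y": 0.5, "L1_0": float(i % 2)}
            for i in range(5)
        ]
        panel = make_panel(rows, mask_cells=[(0, "L1_1"), (3, "L2_2")])
        kept = ~panel.mask_array().any(axis=(1, 2))
        assert kept.sum() == 3

    def test_all_missing_raises(self, small_panel):
        mc = MissingnessConfig(mechanism="MCAR", intercept=12.0)
        panel = apply_missingness(small_panel, mc, 1)
        with pytest.raises(EmptyAnalysisError, match="complete"):
            complete_case(panel)


class TestLOCF:
    def test_forward_fill_trajectory(self):
        rows = [
            {
                "L1_0": 1.0, "L2_0": 2.0, "A_0": 0,
                "L1_1": 0.0, "L2_1": 9.0, "A_1": 1,
                "L1_2": 1.0, "L2_2": 9.0, "A_2": 0,
                "Y": 1.0,
            }
        ]
        rng = np.random.default_rng(2)
        for i in range(40):
            rows.append(
                {
                    "L1_0": float(rng.integers(2)), "L2_0": rng.normal(), "A_0": int(rng.integers(2)),
                    "L1_1": float(rng.integers(2)), "L2_1": rng.normal(), "A_1": int(rng.integers(2)),
                    "L1_2": float(rng.integers(2)), "L2_2": rng.normal(), "A_2": int(rng.integers(2)),
                    "Y": rng.normal(),
                }
            )
        panel = make_panel(rows, mask_cells=[(0, "L2_1"), (0, "L2_2")])
        filled, _ = locf_impute(panel)
        assert filled.true.loc[0, ["L2_0", "L2_1", "L2_2"]].tolist() == [2.0, 2.0, 2.0]

    def test_missing_baseline_dropped(self, masked_panel):
        filled, est = locf_impute(masked_panel)
        baseline_missing = (
            masked_panel.mask["M_L1_0"] | masked_panel.mask["M_L2_0"]
        ).sum()
        assert filled.n == masked_panel.n - baseline_missing
        assert est.n_effective == filled.n

    def test_fully_observed_is_identity(self, small_panel):
        filled, est = locf_impute(small_panel)
        ref = full_data(small_panel)
        assert np.array_equal(est.params, ref.params)


class TestMPA:
    def test_no_missing_matches_standard_weights(self, small_panel):
        from msmiss import compute_stabilized_weights, fit_treatment_models

        res = mpa_weights(small_panel)
        models = fit_treatment_models(small_panel)
        ws = compute_stabilized_weights(small_panel.true, models)
        assert np.allclose(res.weights.final, ws.final, atol=1e-10)
        assert len(res.patterns) == 1

    def test_saturated_pattern_weights_are_cell_frequencies(self):
        """Within a pattern with no usable covariates, the fitted denominator
        equals the pattern's empirical treatment frequency."""
        rows = [
            {"L1_0": float(i % 2), "L2_0": 0.0, "A_0": int(i < 6), "Y": 0.1 * i}
            for i in range(10)
        ]
        # subjects 0..9; mask L1_0 for all, L2 carries no information (constant)
        panel = make_panel(rows, n_times=1, mask_cells=[(i, "L1_0") for i in range(10)])
        res = mpa_weights(panel, min_pattern_size=1)
        assert np.allclose(res.weights.den_prob[:6, 0], 0.6, atol=1e-6)
        assert np.allclose(res.weights.den_prob[6:, 0], 0.4, atol=1e-6)

    def test_sparse_pattern_merged(self, dgm):
        panel = simulate_full_data(dgm, 400, 81)
        mc = MissingnessConfig(mechanism="MCAR", intercept=-3.5)
        masked = apply_missingness(panel, mc, 81)
        res = mpa_weights(masked, min_pattern_size=50)
        assert (res.patterns["person_time_rows"] >= 50).all()

    def test_masked_treatment_unsupported(self, small_panel):
        panel = small_panel.copy()
        panel.true["A_1"] = panel.true["A_1"].astype(float)
        panel.true.loc[0, "A_1"] = np.nan
        with pytest.raises(UnsupportedMethodError, match="exposure or outcome"):
            mpa_weights(panel)


class TestRubinPool:
    def test_identical_imputations(self):
        out = rubin_pool([1.0, 1.0, 1.0], [0.5, 0.5, 0.5])
        assert out["pooled"] == pytest.approx(1.0)
        assert out["B"] == pytest.approx(0.0)
        assert out["T"] == pytest.approx(0.5)

    def test_hand_example(self):
        out = rubin_pool([1.0, 2.0, 3.0], [0.5, 0.5, 0.5])
        assert out["pooled"] == pytest.approx(2.0)
        assert out["W"] == pytest.approx(0.5)
        assert out["B"] == pytest.approx(1.0)
        assert out["T"] == pytest.approx(0.5 + (4.0 / 3.0) * 1.0)

    def test_variance_scaling_linearity(self):
        base = rubin_pool([1.0, 2.0, 3.0], [0.5, 0.4, 0.6])
        scaled = rubin_pool([1.0, 2.0, 3.0], [5.0, 4.0, 6.0])
        assert scaled["W"] == pytest.approx(10 * base["W"])
        assert scaled["T"] - (4.0 / 3.0) * scaled["B"] == pytest.approx(
            10 * (base["T"] - (4.0 / 3.0) * base["B"])
        )

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(
            st.tuples(
                st.floats(-5, 5, allow_nan=False),
                st.floats(0.01, 5, allow_nan=False),
            ),
            min_size=2,
            max_size=12,
        )
    )
    def test_identity_holds_exactly(self, pairs):
        """T = W + (1 + 1/M) B to machine precision on arbitrary inputs."""
        points = [p for p, _ in pairs]
        variances = [v for _, v in pairs]
        out = rubin_pool(points, variances)
        M = len(points)
        assert out["T"] == pytest.approx(out["W"] + (1 + 1 / M) * out["B"], rel=1e-12)
        assert out["pooled"] == pytest.approx(np.mean(points), rel=1e-12)

    def test_single_imputation_rejected(self):
        with pytest.raises(EstimationError, match="2 imputations"):
            rubin_pool([1.0], [0.5])


class TestMI:
    def test_no_missing_degenerate(self, small_panel):
        res = mi_estimate(small_panel, m=3, seed=1)
        assert np.all(res.between == 0.0)
        assert np.allclose(res.total, res.within)
        ref = full_data(small_panel)
        assert np.array_equal(res.pooled.params, ref.params)

    def test_pooled_is_mean_of_per_panel_estimates(self, masked_panel):
        res = mi_estimate(masked_panel, m=3, seed=2)
        points = np.vstack([e.params for e in res.estimates])
        assert np.allclose(res.pooled.params, points.mean(axis=0), atol=1e-12)
        assert np.allclose(
            res.total, res.within + (1 + 1 / 3) * res.between, atol=1e-12
        )

    def test_reproducible(self, masked_panel):
        a = mi_estimate(masked_panel, m=2, seed=3)
        b = mi_estimate(masked_panel, m=2, seed=3)
        assert np.array_equal(a.pooled.params, b.pooled.params)

    def test_imputed_binary_stays_binary(self, masked_panel):
        obs = masked_panel.observed()
        rng = np.random.default_rng(0)
        cols = [f"{v}_{k}" for k in range(3) for v in ("L1", "L2")]
        filled = chained_imputation(obs, cols, rng, n_cycles=3)
        assert not filled[cols].isna().any().any()
        for k in range(3):
            assert filled[f"L1_{k}"].isin([0.0, 1.0]).all()

    def test_column_with_no_observed_values(self, small_panel):
        panel = small_panel.copy()
        panel.mask["M_L2_1"] = True
        obs = panel.observed()
        with pytest.raises(EstimationError, match="no observed values"):
            chained_imputation(obs, ["L2_1"], np.random.default_rng(0), n_cycles=1)

    def test_agrees_with_statsmodels_mice(self, dgm):
        """Cross-check the chained-equation engine against statsmodels MICE."""
        from statsmodels.imputation.mice import MICEData

        panel = simulate_full_data(dgm, 3_000, 91)
        mc = MissingnessConfig(mechanism="MCAR", intercept=-1.2)
        masked = apply_missingness(panel, mc, 91)
        ours = mi_estimate(masked, m=5, seed=4)
        np.random.seed(4)
        frame = masked.observed().drop(columns=["id"])
        imp = MICEData(frame, k_pmm=5)
        from msmiss.methods import _analyze

        ests = []
        for _ in range(5):
            imp.update_all(2)
            completed = imp.data.copy()
            completed.insert(0, "id", masked.true["id"].to_numpy())
            ests.append(_analyze(completed, 3, "MI").params)
        theirs = np.mean(ests, axis=0)
        spread = np.vstack([e.params for e in ours.estimates]).std(axis=0, ddof=1)
        assert np.allclose(ours.pooled.params, theirs, atol=4 * (spread + 0.05))


class TestIPMW:
    def test_hand_weight_product(self):
        num = np.array([[0.85, 0.85]])
        den = np.array([[0.9, 0.8]])
        w = ipmw_missing_weights(num, den)
        assert w[0] == pytest.approx((0.85 / 0.9) * (0.85 / 0.8), abs=1e-12)

    def test_no_missing_matches_full_data(self, small_panel):
        ws, est = ipmw_estimate(small_panel)
        assert np.allclose(ws.final, full_weights_final(small_panel), atol=1e-10)
        ref = full_data(small_panel)
        assert np.allclose(est.params, ref.params, atol=1e-10)

    def test_censoring_is_monotone(self, masked_panel):
        """A subject missing at k contributes no person-time after k."""
        ws, est = ipmw_estimate(masked_panel)
        any_missing = masked_panel.mask_array().any(axis=(1, 2))
        assert est.n_effective == int((~any_missing).sum())
        assert len(ws.final) == est.n_effective

    def test_every_subject_censored_raises(self, small_panel):
        mc = MissingnessConfig(mechanism="MCAR", intercept=12.0)
        panel = apply_missingness(small_panel, mc, 2)
        with pytest.raises(EmptyAnalysisError, match="IPMW"):
            ipmw_estimate(panel)


def full_weights_final(panel):
    from msmiss import compute_stabilized_weights, fit_treatment_models

    models = fit_treatment_models(panel)
    return compute_stabilized_weights(panel.true, models).final


class TestFullyObservedEquivalence:
    def test_all_methods_agree_on_complete_panel(self, small_panel):
        ref = full_data(small_panel).params
        assert np.array_equal(complete_case(small_panel)[1].params, ref)
        assert np.array_equal(locf_impute(small_panel)[1].params, ref)
        assert np.allclose(mpa_weights(small_panel).estimate.params, ref, atol=1e-10)
        assert np.array_equal(mi_estimate(small_panel, m=2, seed=1).pooled.params, ref)
        assert np.allclose(ipmw_estimate(small_panel)[1].params, ref, atol=1e-10)
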