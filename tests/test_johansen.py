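"""Reduced-rank regression and sequential trace test."""

import numpy as np
import pytest

from cointsim import (
    DegenerateInputError,
    JohansenTraceTest,
    critical_value,
    fit_vecm,
    johansen_test,
    sequential_rank,
    trace_test,
)
from cointsim.dgp import DGPSpec, simulate_system
from cointsim.johansen import trace_stats_from_eigenvalues


class TestCriticalValues:
    @pytest.mark.parametrize(
        "n_minus_r, level, expected",
        [
            (2, 0.01, 23.52),
            (1, 0.01, 11.65),
            (2, 0.05, 17.95),
            (1, 0.05, 8.18),
            (2, 0.10, 15.66),
            (1, 0.10, 6.50),
        ],
    )
    def test_table_entries(self, n_minus_r, level, expected):
        assert critical_value(n_minus_r, level) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            critical_value(3, 0.01)
        with pytest.raises(ValueError):
            critical_value(1, 0.025)


class TestSequentialDecision:
    @pytest.mark.parametrize(
        "stats, rank",
        [
            ((97.67, 27.54), 2),  # both hypotheses rejected: stationary pair
            ((13.12, 1.0), 0),  # first null kept: no cointegration
            ((59.96, 3.97), 1),  # one relation: cointegrated
        ],
    )
    def test_published_statistics_reproduce_ranks(self, stats, rank):
        assert sequential_rank(np.array(stats), level=0.01) == rank

    def test_boundary_is_non_rejection(self):
        assert sequential_rank(np.array([23.52, 0.0]), level=0.01) == 0


class TestAgainstIndependentImplementation:
    def test_matches_statsmodels_to_six_significant_digits(self, seed_stream):
        vecm = pytest.importorskip("statsmodels.tsa.vector_ar.vecm")
        kinds = ("I0", "I1", "CI1")
        for i, s in enumerate(seed_stream(20, entropy=2024)):
            y = simulate_system(DGPSpec(kinds[i % 3], T=120, seed=s)).to_array()
            fit = fit_vecm(y, lag_diffs=1)
            res = trace_test(fit)
            sm = vecm.coint_johansen(y, det_order=0, k_ar_diff=1)
            np.testing.assert_allclose(
                fit.eigenvalues, sorted(sm.eig, reverse=True), rtol=1e-6
            )
            np.testing.assert_allclose(res.trace_stats, sm.lr1, rtol=1e-6)
            lead = sm.evec[:, np.argmax(sm.eig)]
            np.testing.assert_allclose(
                fit.beta0_hat(), lead[1] / lead[0], rtol=1e-6
            )

    def test_eigenvalues_are_squared_canonical_correlations(self, ci1_series):
        fit = fit_vecm(ci1_series, lag_diffs=1)
        # independent canonical-correlation computation on the residual sets
        q0, _ = np.linalg.qr(fit.residuals_d)
        q1, _ = np.linalg.qr(fit.residuals_l)
        sv = np.linalg.svd(q0.T @ q1, compute_uv=False)
        np.testing.assert_allclose(fit.eigenvalues, np.sort(sv**2)[::-1], atol=1e-10)


class TestEstimator:
    def test_scale_equivariance_of_beta0(self, ci1_series):
        y = ci1_series.to_array()
        b = fit_vecm(y).beta0_hat()
        y_scaled = y.copy()
        y_scaled[:, 1] *= 4.0
        assert fit_vecm(y_scaled).beta0_hat() == pytest.approx(b / 4.0, rel=1e-10)

    def test_level_shift_invariance(self, ci1_series):
        # the unrestricted intercept absorbs any constant added to the levels
        y = ci1_series.to_array()
        a = trace_test(fit_vecm(y)).trace_stats
        b = trace_test(fit_vecm(y + 17.3)).trace_stats
        np.testing.assert_allclose(a, b, rtol=1e-9)

    def test_consistency_at_large_t(self):
        spec = DGPSpec("CI1", T=5000, params={"b1": 0.4, "b2": 0.6}, seed=31)
        res = johansen_test(simulate_system(spec))
        assert res.rank == 1
        assert res.beta0_hat == pytest.approx(-2 / 3, abs=0.05)

    def test_trace_stats_ordered_and_nonnegative(self, seed_stream):
        for i, s in enumerate(seed_stream(9)):
            kind = ("I0", "I1", "CI1")[i % 3]
            res = johansen_test(simulate_system(DGPSpec(kind, T=100, seed=s)))
            assert res.trace_stats[0] >= res.trace_stats[1] >= 0

    def test_classification_rate_at_large_t(self, seed_stream):
        # with T = 2000 every system type is recognized nearly always
        for entropy, kind in ((301, "I0"), (302, "I1"), (303, "CI1")):
            correct = sum(
                johansen_test(simulate_system(DGPSpec(kind, T=2000, seed=s))).classification
                == kind
                for s in seed_stream(60, entropy=entropy)
            )
            assert correct >= 57, kind

    def test_degenerate_input_raises(self):
        y = np.column_stack([np.ones(80), np.arange(80.0)])
        with pytest.raises(DegenerateInputError):
            fit_vecm(y)

    def test_missing_points_rejected(self, ci1_series):
        s = ci1_series.copy()
        s.observed[5] = False
        with pytest.raises(ValueError, match="drop_missing"):
            fit_vecm(s)

    def test_sklearn_interface(self, ci1_series):
        est = JohansenTraceTest(lag_diffs=1, level=0.01)
        assert est.get_params() == {"lag_diffs": 1, "level": 0.01, "intercept": True}
        est.fit(ci1_series.to_array())
        assert est.rank_ == 1
        assert est.predict() == "CI1"
        assert est.beta0_hat_ == pytest.approx(-1.0, abs=0.2)
        assert 0 <= est.eigenvalues_[1] <= est.eigenvalues_[0] < 1

    def test_stat_reconstruction_from_eigenvalues(self):
        lam = np.array([0.3, 0.1])
        stats = trace_stats_from_eigenvalues(lam, 100)
        expected1 = -100 * np.log(0.9)
        assert stats[1] == pytest.approx(expected1)
        assert stats[0] == pytest.approx(-100 * (np.log(0.7) + np.log(0.9)))
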