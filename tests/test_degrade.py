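"""Degradation operators: scale maps, missingness, ceiling/floor effects."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy.stats import spearmanr

from cointsim import (
    BivariateSeries,
    BoundSpec,
    MissingSpec,
    ScaleSpec,
    apply_bounds,
    drop_missing,
    inject_missing,
    round_to_integers,
    to_interval_scale,
    to_ordinal_scale,
)
from cointsim.degrade import ordinal_spacings

finite_series = arrays(
    np.float64,
    st.integers(20, 80),
    elements=st.floats(-50, 50, allow_nan=False, width=64),
)


class TestIntervalScale:
    def test_equal_width_split(self):
        np.testing.assert_array_equal(
            to_interval_scale(np.array([0.0, 1.0, 2.0, 3.0]), 2), [1, 1, 2, 2]
        )

    def test_integer_spaced_input_is_relabelled(self):
        x = np.array([10.0, 30.0, 20.0, 40.0])
        np.testing.assert_array_equal(to_interval_scale(x, 4), [1, 3, 2, 4])

    def test_rank_correlation_preserved(self):
        # brute-force check on a seeded draw: a 10-point equal-width scale
        # keeps the rank order almost intact (rho = 0.976 on this draw —
        # range-anchored bins are wide in the tails, costing a little rank
        # resolution there)
        x = np.random.default_rng(0).standard_normal(10_000)
        rho = spearmanr(x, to_interval_scale(x, 10)).statistic
        assert rho >= 0.97

    def test_constant_input_warns_and_maps_to_one(self):
        with pytest.warns(UserWarning, match="constant"):
            out = to_interval_scale(np.full(30, 2.5), 5)
        assert set(out) == {1}

    @given(x=finite_series, points=st.integers(2, 10))
    @settings(max_examples=60, deadline=None)
    def test_monotone_and_bounded(self, x, points):
        out = to_interval_scale(x, points)
        order = np.argsort(x, kind="stable")
        assert np.all(np.diff(out[order]) >= 0)  # never inverts order
        assert out.min() >= 1 and out.max() <= points


class TestOrdinalScale:
    def test_equal_spacings_reduce_to_interval(self, monkeypatch):
        import cointsim.degrade as dg

        monkeypatch.setattr(
            dg, "ordinal_spacings", lambda k, scheme, rng=None: np.full(k, 1 / k)
        )
        x = np.random.default_rng(1).standard_normal(500)
        spec = ScaleSpec("ordinal", 7, "random", seed=0)
        np.testing.assert_array_equal(dg.to_ordinal_scale(x, spec), to_interval_scale(x, 7))

    @pytest.mark.parametrize("scheme", [
        "random", "increasing_from_median", "decreasing_from_median",
        "monotone_increasing",
    ])
    def test_monotone_mapping(self, scheme):
        x = np.random.default_rng(2).standard_normal(300)
        out = to_ordinal_scale(x, ScaleSpec("ordinal", 5, scheme, seed=3))
        order = np.argsort(x)
        assert np.all(np.diff(out[order]) >= 0)
        assert 1 <= out.min() and out.max() <= 5

    def test_spacings_normalized_and_shaped(self):
        w = ordinal_spacings(7, "increasing_from_median")
        assert w.sum() == pytest.approx(1.0)
        # symmetric about the median category, widest at the extremes
        np.testing.assert_allclose(w, w[::-1])
        assert w[0] > w[3]
        mono = ordinal_spacings(6, "monotone_increasing")
        assert np.all(np.diff(mono) > 0)

    def test_scale_spec_validation(self):
        with pytest.raises(ValueError, match="points"):
            ScaleSpec("interval", 12)
        with pytest.raises(ValueError, match="ordinal_scheme"):
            ScaleSpec("ordinal", 5, "bogus")
        with pytest.raises(ValueError, match="only valid"):
            ScaleSpec("interval", 5, "random")


class TestRounding:
    def test_rounds_to_whole_numbers(self):
        out = round_to_integers(np.array([0.4, 0.6, -1.2, 2.5]))
        np.testing.assert_array_equal(out, [0.0, 1.0, -1.0, 2.0])


class TestBounds:
    def test_forty_percent_ceiling_summarizes_top_four_values_to_seven(self):
        x = np.repeat(np.arange(1, 11), 10)
        out = apply_bounds(x, BoundSpec("above", 0.4))
        np.testing.assert_array_equal(out, np.minimum(x, 7))

    def test_fifty_percent_ceiling(self):
        x = np.repeat(np.arange(1, 11), 10)
        out = apply_bounds(x, BoundSpec("above", 0.5))
        np.testing.assert_array_equal(out, np.minimum(x, 6))

    def test_floor_merges_bottom_categories(self):
        x = np.repeat(np.arange(1, 11), 10)
        out = apply_bounds(x, BoundSpec("below", 0.3))
        np.testing.assert_array_equal(out, np.maximum(x, 3))

    def test_both_sides_split_fraction_between_tails(self):
        # 30% on both sides: ~15% per tail, two categories each
        x = np.repeat(np.arange(1, 11), 10)
        out = apply_bounds(x, BoundSpec("both", 0.3))
        np.testing.assert_array_equal(out, np.clip(x, 2, 9))

    def test_tiny_fraction_is_identity(self):
        x = np.repeat(np.arange(1, 11), 10)
        out = apply_bounds(x, BoundSpec("above", 0.1))
        np.testing.assert_array_equal(out, x)  # a single-point merge is a no-op

    def test_monotone_property(self):
        rng = np.random.default_rng(4)
        x = rng.integers(1, 11, size=200)
        out = apply_bounds(x, BoundSpec("both", 0.5))
        order = np.argsort(x)
        assert np.all(np.diff(out[order]) >= 0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="1..10"):
            apply_bounds(np.array([0, 5, 11]), BoundSpec("above", 0.3))


class TestMissingness:
    def make(self, T=100):
        rng = np.random.default_rng(0)
        return BivariateSeries(rng.standard_normal(T), rng.standard_normal(T))

    def test_regular_marks_every_kth_occasion(self):
        out = inject_missing(self.make(), MissingSpec("regular", every_k=10))
        assert (~out.observed).sum() == 10
        np.testing.assert_array_equal(np.where(~out.observed)[0], np.arange(9, 100, 10))

    def test_random_marks_exact_count(self):
        out = inject_missing(self.make(), MissingSpec("random", pct=0.30, seed=1))
        assert (~out.observed).sum() == 30

    def test_same_seed_same_mask(self):
        s = self.make()
        a = inject_missing(s, MissingSpec("random", pct=0.2, seed=9))
        b = inject_missing(s, MissingSpec("random", pct=0.2, seed=9))
        np.testing.assert_array_equal(a.observed, b.observed)

    def test_observed_values_bit_identical(self):
        s = self.make()
        out = inject_missing(s, MissingSpec("random", pct=0.25, seed=2))
        np.testing.assert_array_equal(out.y1[out.observed], s.y1[out.observed])

    def test_too_few_remaining_rejected(self):
        with pytest.raises(ValueError, match="refusing"):
            inject_missing(self.make(T=25), MissingSpec("random", pct=0.4, seed=0))

    def test_drop_missing_concatenates(self):
        s = self.make()
        out = drop_missing(inject_missing(s, MissingSpec("random", pct=0.30, seed=3)))
        assert len(out) == 70
        assert out.observed.all()

    def test_drop_missing_identity_when_complete(self):
        s = self.make()
        np.testing.assert_array_equal(drop_missing(s).y1, s.y1)

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            MissingSpec("regular", pct=0.1)
        with pytest.raises(ValueError):
            MissingSpec("random", pct=0.7)
        with pytest.raises(ValueError):
            MissingSpec("regular", every_k=1)
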