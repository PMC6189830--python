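"""Apoptosis readout model: pmfs, thresholds, enrichment analytics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dropscreen.assay import (
    AssayParams,
    NoPositivesError,
    aggregate_count_pmf,
    aggregate_positive_prob,
    enrichment_curve,
    expected_apoptotic_per_aggregate,
    fold_enrichment,
    fold_improvement_vs_single,
    midsize_threshold,
    post_sort_positive_fraction,
)


def brute_force_binomial_tail(n, p, t):
    """Independent oracle: direct summation of C(n,k) p^k (1-p)^(n-k)."""
    return sum(
        math.comb(n, k) * p**k * (1 - p) ** (n - k) for k in range(t, n + 1)
    )


class TestThreshold:
    @pytest.mark.parametrize("n, t", [(1, 1), (10, 5), (12, 6), (13, 7)])
    def test_midsize_is_ceil_half(self, n, t):
        assert midsize_threshold(n) == t

    def test_invalid_size_rejected(self):
        with pytest.raises(ValueError):
            midsize_threshold(0)


class TestCountPmf:
    def test_binomial_pmf_matches_brute_force(self):
        res = aggregate_count_pmf(10, 0.1, "binomial")
        oracle = [
            brute_force_binomial_tail(10, 0.1, k) - brute_force_binomial_tail(10, 0.1, k + 1)
            for k in range(10)
        ] + [brute_force_binomial_tail(10, 0.1, 10)]
        np.testing.assert_allclose(res.pmf, oracle, atol=1e-12)
        assert res.pmf.sum() == pytest.approx(1.0, abs=1e-9)
        assert res.truncation_mass == 0.0

    def test_binomial_background_mean_is_one_for_ten_cells(self):
        res = aggregate_count_pmf(10, 0.1, "binomial")
        assert (res.k * res.pmf).sum() == pytest.approx(1.0, abs=1e-9)

    def test_zero_rate_is_point_mass(self):
        for model in ("binomial", "poisson"):
            res = aggregate_count_pmf(8, 0.0, model)
            assert res.pmf[0] == pytest.approx(1.0)
            assert res.pmf[1:].sum() == pytest.approx(0.0, abs=1e-12)

    def test_poisson_reports_truncation_mass(self):
        res = aggregate_count_pmf(10, 0.5, "poisson")
        assert res.pmf.sum() + res.truncation_mass == pytest.approx(1.0, abs=1e-9)
        assert res.truncation_mass > 0

    def test_poisson_converges_to_binomial_at_small_p(self):
        """Total variation < 0.01 at N=1000, p=0.001 (law of rare events)."""
        binom = aggregate_count_pmf(1000, 0.001, "binomial")
        poiss = aggregate_count_pmf(1000, 0.001, "poisson")
        tv = 0.5 * (np.abs(binom.pmf - poiss.pmf).sum() + poiss.truncation_mass)
        assert tv < 0.01

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            aggregate_count_pmf(10, 1.5)
        with pytest.raises(ValueError):
            aggregate_count_pmf(0, 0.1)


class TestPositiveProb:
    def test_matches_brute_force_tail(self):
        assert aggregate_positive_prob(10, 0.1, 5) == pytest.approx(
            brute_force_binomial_tail(10, 0.1, 5), rel=1e-12
        )
        # frozen value of the oracle: P(K >= 5 | N=10, p=0.1) = 1.63e-3
        assert aggregate_positive_prob(10, 0.1, 5) == pytest.approx(1.63e-3, rel=5e-3)

    def test_single_cell_reduction(self):
        assert aggregate_positive_prob(1, 0.37, 1) == pytest.approx(0.37)

    def test_saturated_rate(self):
        assert aggregate_positive_prob(10, 1.0, 5) == pytest.approx(1.0)

    def test_threshold_out_of_range(self):
        with pytest.raises(ValueError):
            aggregate_positive_prob(10, 0.1, 11)
        with pytest.raises(ValueError):
            aggregate_positive_prob(10, 0.1, 0)

    @settings(derandomize=True, max_examples=60)
    @given(
        st.integers(min_value=2, max_value=30),
        st.floats(min_value=0.0, max_value=0.99),
        st.floats(min_value=0.001, max_value=0.01),
    )
    def test_monotone_in_p_and_threshold(self, n, p, dp):
        t = midsize_threshold(n)
        assert aggregate_positive_prob(n, min(p + dp, 1.0), t) >= aggregate_positive_prob(
            n, p, t
        )
        if t < n:
            assert aggregate_positive_prob(n, p, t + 1) <= aggregate_positive_prob(
                n, p, t
            )


class TestEnrichment:
    def test_post_sort_fraction_frozen_value(self):
        # f=0.001, S_hit=1, S_null=0.1 -> 0.001 / 0.1009
        assert post_sort_positive_fraction(0.001, 1.0, 0.1) == pytest.approx(
            9.91e-3, rel=1e-3
        )

    def test_degenerate_cases(self):
        assert post_sort_positive_fraction(0.0, 1.0, 0.1) == 0.0
        assert post_sort_positive_fraction(0.5, 0.8, 0.0) == 1.0
        with pytest.raises(NoPositivesError):
            post_sort_positive_fraction(0.5, 0.0, 0.0)

    def test_fold_enrichment_frozen_value(self):
        assert fold_enrichment(0.001, 1.0, 0.1) == pytest.approx(9.91, rel=1e-3)

    def test_uninformative_readout_gives_unit_enrichment(self):
        assert fold_enrichment(0.2, 0.4, 0.4) == pytest.approx(1.0)

    def test_zero_input_fraction_rejected(self):
        with pytest.raises(ValueError):
            fold_enrichment(0.0, 1.0, 0.1)

    def test_enrichment_grows_as_background_drops(self):
        vals = [fold_enrichment(0.001, 0.9, s) for s in (0.2, 0.1, 0.05, 0.01)]
        assert vals == sorted(vals)

    @settings(derandomize=True, max_examples=60)
    @given(
        st.floats(min_value=0.0, max_value=1.0),
        st.floats(min_value=0.0, max_value=1.0),
        st.floats(min_value=0.0, max_value=1.0),
    )
    def test_post_sort_fraction_is_a_fraction(self, f, s_hit, s_null):
        try:
            frac = post_sort_positive_fraction(f, s_hit, s_null)
        except NoPositivesError:
            return
        assert 0.0 <= frac <= 1.0
        if s_hit == s_null and s_hit > 0:
            assert frac == pytest.approx(f)


class TestFoldImprovement:
    def test_unity_at_single_cells(self):
        assert fold_improvement_vs_single(1, 0.1, 0.9, 0.001) == 1.0

    @pytest.mark.parametrize("count_model", ["binomial", "poisson"])
    def test_larger_aggregates_enrich_more(self, count_model):
        """Gain grows with aggregate size along parity-comparable steps.

        The integer mid-size threshold T = ceil(N/2) makes the curve
        zigzag between even and odd N, so the size benefit is asserted
        as strict growth within each parity class (every N -> N+2 step)
        over N = 1..50.
        """
        vals = [
            fold_improvement_vs_single(n, 0.1, 0.9, 0.001, count_model)
            for n in range(1, 51)
        ]
        for i in range(len(vals) - 2):
            assert vals[i + 2] > vals[i]
        assert vals[-1] > vals[0] and vals[-2] > vals[1]

    def test_monte_carlo_cross_check(self):
        """Analytic fold improvement vs a large two-arm simulation oracle."""
        n_draws, n_cells, p_bg, p_hit, f = 10_000_000, 10, 0.1, 0.9, 0.001
        t = midsize_threshold(n_cells)
        rng = np.random.default_rng(20240917)
        s_hit_mc = (rng.binomial(n_cells, p_hit, n_draws) >= t).mean()
        s_null_mc = (rng.binomial(n_cells, p_bg, n_draws) >= t).mean()
        single_hit = (rng.binomial(1, p_hit, n_draws) >= 1).mean()
        single_null = (rng.binomial(1, p_bg, n_draws) >= 1).mean()
        mc = fold_enrichment(f, s_hit_mc, s_null_mc) / fold_enrichment(
            f, single_hit, single_null
        )
        analytic = fold_improvement_vs_single(n_cells, p_bg, p_hit, f)
        # dominant MC error comes from the rare null-arm tail rate
        s_null = aggregate_positive_prob(n_cells, p_bg, t)
        rel_se = math.sqrt(
            (1 - s_null) / (s_null * n_draws)
            + (1 - p_bg) / (p_bg * n_draws)
            + (1 - p_hit) / (p_hit * n_draws)
        )
        assert abs(mc - analytic) / analytic < 3 * rel_se


class TestExpectedCountAndCurve:
    @pytest.mark.parametrize(
        "n, p, expected", [(10, 0.1, 1.0), (7, 0.0, 0.0), (12, 0.1, 1.2)]
    )
    def test_expected_apoptotic(self, n, p, expected):
        assert expected_apoptotic_per_aggregate(n, p) == pytest.approx(expected)

    def test_curve_table_is_consistent(self):
        table = enrichment_curve(range(1, 13), 0.1, 0.9, 0.001, "binomial")
        assert list(table["n_cells"]) == list(range(1, 13))
        assert table.loc[0, "fold_improvement"] == pytest.approx(1.0)
        row12 = table[table["n_cells"] == 12].iloc[0]
        assert row12["threshold"] == 6
        assert row12["fold_improvement"] == pytest.approx(
            fold_improvement_vs_single(12, 0.1, 0.9, 0.001)
        )


class TestAssayParams:
    def test_midsize_threshold_value(self):
        params = AssayParams(
            hit_fraction=0.001, p_background=0.1, p_hit=0.9, aggregate_size=12
        )
        assert params.threshold_value == 6

    def test_explicit_threshold(self):
        params = AssayParams(
            hit_fraction=0.001,
            p_background=0.1,
            p_hit=0.9,
            aggregate_size=12,
            threshold=3,
        )
        assert params.threshold_value == 3

    def test_invariants_enforced(self):
        with pytest.raises(Exception):
            AssayParams(
                hit_fraction=0.001, p_background=0.5, p_hit=0.2, aggregate_size=12
            )
        with pytest.raises(Exception):
            AssayParams(
                hit_fraction=0.001,
                p_background=0.1,
                p_hit=0.9,
                aggregate_size=12,
                threshold=13,
            )
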