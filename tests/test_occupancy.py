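"""Poisson occupancy: dropout inversion, censored MLE, proficiency."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import special

from qpcrval import (
    GT10,
    expected_empty_count,
    expected_empty_fraction,
    lambda_from_dropout,
    lambda_mle,
    proficiency_check,
    theoretical_empty_table,
    zero_truncated_mean,
)
from qpcrval.datasets import load_occupancy_counts
from qpcrval.occupancy import format_lambda


class TestTheory:
    def test_single_copy_empty_fraction(self):
        assert expected_empty_fraction(1.0) == pytest.approx(0.3679, abs=5e-5)

    def test_zero_input_all_empty(self):
        assert expected_empty_fraction(0.0) == 1.0

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            expected_empty_fraction(-0.1)

    def test_expected_empties_of_100_wells_at_one_copy(self):
        assert expected_empty_count(1.0, 100) == 37

    def test_occupancy_table_one_through_ten(self):
        table = theoretical_empty_table(range(1, 11))
        assert table["percent_empty"].tolist() == [
            36.79, 13.53, 4.98, 1.83, 0.67, 0.25, 0.09, 0.03, 0.01, 0.00,
        ]

    def test_empty_input_empty_table(self):
        assert len(theoretical_empty_table([])) == 0


class TestLambdaFromDropout:
    def test_near_single_copy_level(self):
        est = lambda_from_dropout(26, 60)
        assert est.lambda_dropout == pytest.approx(0.84, abs=5e-3)
        assert est.empty_fraction == pytest.approx(26 / 60)

    def test_no_empties_is_saturated_sentinel(self):
        est = lambda_from_dropout(0, 18)
        assert est.lambda_dropout is GT10
        assert est.saturated
        assert format_lambda(est.lambda_dropout) == ">10"
        lo, hi = est.ci95
        assert lo > 0 and math.isinf(hi)

    def test_all_empty_gives_zero(self):
        assert lambda_from_dropout(12, 12).lambda_dropout == 0.0

    def test_ci_brackets_point_estimate(self):
        est = lambda_from_dropout(18, 60)
        lo, hi = est.ci95
        assert lo < est.lambda_dropout < hi

    def test_counts_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            lambda_from_dropout(61, 60)

    @given(st.floats(min_value=0.01, max_value=10.0))
    def test_inverts_expected_empty_fraction(self, lam):
        assert -math.log(expected_empty_fraction(lam)) == pytest.approx(lam, abs=1e-12)

    def test_reproduces_published_dropout_column(self):
        """Every numeric dropout-copies cell of the bundled occupancy table
        is -ln(empty fraction) at the printed precision; zero-empty rows
        carry the ">10" sentinel."""
        table = load_occupancy_counts().dropna(subset=["n_wells"])
        assert len(table) >= 30
        for row in table.itertuples(index=False):
            est = lambda_from_dropout(int(row.n_empty), int(row.n_wells))
            assert format_lambda(est.lambda_dropout) == row.printed_poisson_copies, (
                row.target,
                row.standard,
            )


class TestLambdaMle:
    def test_all_empty_is_zero_in_both_modes(self):
        assert lambda_mle([0, 0, 0, 0], mode="rounded_poisson") == 0.0
        assert lambda_mle([0, 0, 0, 0], mode="censored_positive") == 0.0

    def test_rounded_poisson_is_sample_mean(self):
        assert lambda_mle([1, 0, 2, 1], mode="rounded_poisson") == pytest.approx(1.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            lambda_mle([])

    def test_censored_matches_grid_search_oracle(self):
        # 60 wells, 18 empty, positives zero-truncated Poisson(1.2)
        rng = np.random.default_rng(42)
        positives = []
        while len(positives) < 42:
            k = rng.poisson(1.2)
            if k >= 1:
                positives.append(float(k))
        obs = [0.0] * 18 + positives

        # independent oracle: brute-force the censored log-likelihood
        grid = np.arange(1e-4, 10, 1e-4)
        counts = np.array(positives)
        ll = (
            -18 * grid
            - counts.size * grid
            + np.log(grid) * counts.sum()
            - special.gammaln(counts + 1).sum()
        )
        oracle = grid[np.argmax(ll)]

        lam_hat = lambda_mle(obs, mode="censored_positive")
        assert lam_hat == pytest.approx(oracle, abs=2e-4)
        # and the estimate sits inside the dropout CI of the generating input
        ci = lambda_from_dropout(18, 60).ci95
        assert ci[0] < 1.2 < ci[1]

    def test_estimators_agree_at_large_n(self):
        rng = np.random.default_rng(5)
        counts = rng.poisson(1.0, size=5000).astype(float)
        mle = lambda_mle(counts, mode="censored_positive")
        drop = lambda_from_dropout(int((counts == 0).sum()), 5000).lambda_dropout
        assert abs(mle - drop) / drop < 0.05

    def test_consistency_over_seeds(self):
        # median relative error stays below 15% at n=60 wells
        for lam in (0.5, 2.0):
            errs = []
            for seed in range(200):
                counts = np.random.default_rng(seed).poisson(lam, size=60).astype(float)
                errs.append(abs(lambda_mle(counts) - lam) / lam)
            assert np.median(errs) < 0.15


class TestZeroTruncatedMean:
    def test_fractional_single_copy_level(self):
        # mean copies among occupied wells at 0.875 mean input
        assert zero_truncated_mean(0.875) == pytest.approx(1.50, abs=5e-3)

    def test_limits(self):
        assert zero_truncated_mean(50.0) == pytest.approx(50.0, rel=1e-9)
        assert zero_truncated_mean(1e-9) == pytest.approx(1.0, abs=1e-6)

    def test_domain(self):
        with pytest.raises(ValueError):
            zero_truncated_mean(0.0)


class TestProficiencyCheck:
    def test_observed_equal_expectation_passes(self):
        lam, n = 1.0, 60
        expected_pos = round(n * (1 - math.exp(-lam)))
        ok, p = proficiency_check(expected_pos, n, lam)
        assert ok and p > 0.5

    def test_saturated_positives_fail_at_single_copy(self):
        # all 60 wells positive is inconsistent with Poisson(1) occupancy
        ok, p = proficiency_check(60, 60, 1.0)
        assert not ok and p < 1e-10

    def test_consistent_with_own_dropout_estimate(self):
        # a level re-tested against the input its own dropout implies passes
        est = lambda_from_dropout(5, 36)
        ok, _ = proficiency_check(31, 36, est.lambda_dropout)
        assert ok

    def test_domain(self):
        with pytest.raises(ValueError):
            proficiency_check(5, 36, -1.0)
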