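import math

import numpy as np
import pytest

from _oracles import poisson_grid_bounds_oracle
from sorfconstraint.constraint_metrics import (
    OEUFResult,
    compute_oeuf,
    decile_cutoff,
    frame_respect_flag,
    poisson_bounds,
    regional_utr_constraint,
)

ORACLE_LAMBDAS = (1.0, 2.0, 5.0, 10.0, 20.0, 50.0)


class TestPoissonBounds:
    def test_matches_independent_grid_oracle(self):
        """Agreement within one grid step over k in 0..50, lambda' in the lattice."""
        for lam in ORACLE_LAMBDAS:
            for k in range(51):
                lo, up = poisson_bounds(k, lam)
                lo_o, up_o = poisson_grid_bounds_oracle(k, lam)
                assert abs(lo - lo_o) <= 0.001 + 1e-12, (k, lam)
                assert abs(up - up_o) <= 0.001 + 1e-12, (k, lam)

    def test_closed_form_for_zero_observed(self):
        # for k = 0 the normalised cumulative is ~ (1 - e^(-lam*x)) / (1 - e^(-2 lam)),
        # so the upper bound solves that expression = 0.95
        lam = 30.0
        _, upper = poisson_bounds(0, lam)
        x_closed = -math.log(1 - 0.95 * (1 - math.exp(-2 * lam))) / lam
        assert abs(upper - x_closed) <= 0.002  # within two grid steps of the continuum

    def test_interval_brackets_point_ratio(self):
        lo, up = poisson_bounds(10, 10.0)
        assert lo < 1.0 < up

    def test_upper_shrinks_with_expected_at_zero_observed(self):
        _, up1 = poisson_bounds(0, 10.0)
        _, up2 = poisson_bounds(0, 20.0)
        assert up2 < up1

    @pytest.mark.parametrize("k", [0, 3, 10, 25])
    def test_monotone_in_expected(self, k):
        uppers = [poisson_bounds(k, lam)[1] for lam in ORACLE_LAMBDAS]
        assert all(b <= a + 1e-12 for a, b in zip(uppers, uppers[1:]))

    @pytest.mark.parametrize("lam", [5.0, 20.0])
    def test_monotone_in_observed(self, lam):
        uppers = [poisson_bounds(k, lam)[1] for k in range(0, 30, 3)]
        assert all(b >= a - 1e-12 for a, b in zip(uppers, uppers[1:]))

    def test_coverage_of_the_90_percent_interval(self):
        """k ~ Poisson(20): the interval should cover the truth ~90% of the time."""
        rng = np.random.default_rng(7)
        lam = 20.0
        n = 2000
        cache: dict[int, tuple[float, float]] = {}
        hits = 0
        for k in rng.poisson(lam, n):
            k = int(k)
            if k not in cache:
                cache[k] = poisson_bounds(k, lam)
            lo, up = cache[k]
            hits += lo * lam <= lam <= up * lam
        assert 0.87 <= hits / n <= 0.93

    def test_extreme_overobservation_pins_to_grid_top(self):
        # ratio so far beyond the grid that the pmf underflows everywhere
        assert poisson_bounds(56, 3e-6) == (2.0, 2.0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            poisson_bounds(3, 0.0)
        with pytest.raises(ValueError):
            poisson_bounds(-1, 5.0)

    def test_bounds_capped_at_grid_max(self):
        # hugely over-observed element: the grid cannot express ratios above 2
        lo, up = poisson_bounds(100, 10.0)
        assert up >= 2.0 - 0.001  # pinned to the top of the grid
        assert up <= 2.0


class TestComputeOeuf:
    def test_powered_flag_threshold(self):
        assert compute_oeuf("e", 5, 9.9, "SNVOEUF").powered is False
        assert compute_oeuf("e", 5, 10.0, "SNVOEUF").powered is True

    def test_point_ratio(self):
        res = compute_oeuf("e", 20, 20.0, "SNVOEUF")
        assert res.point_ratio == pytest.approx(1.0)
        assert res.lower < 1.0 < res.upper

    def test_zero_expected_not_computable(self):
        res = compute_oeuf("e", 0, 0.0, "LOEUF")
        assert res.computable is False and res.powered is False


class TestDecileCutoff:
    def test_hundred_values(self):
        values = [float(v) for v in range(1, 101)]
        cutoff, deciles = decile_cutoff(values)
        assert cutoff == 10.0
        assert deciles[:10] == [1] * 10
        assert deciles[-1] == 10

    def test_degenerate_all_equal(self):
        cutoff, deciles = decile_cutoff([3.5] * 20)
        assert cutoff == 3.5
        assert deciles.count(1) == 2

    def test_25_values_lowest_bin_holds_ceiling(self):
        # rank r falls in decile 1 + (r*10)//n: bin 1 holds ceil(25/10) = 3
        values = [float(v) for v in range(25, 0, -1)]
        cutoff, deciles = decile_cutoff(values)
        assert deciles.count(1) == 3
        assert cutoff == 3.0  # max of the three smallest values {1,2,3}

    def test_fraction_at_or_below_cutoff(self):
        rng = np.random.default_rng(5)
        values = rng.normal(size=1000).tolist()  # tie-free
        cutoff, _ = decile_cutoff(values)
        frac = sum(v <= cutoff for v in values) / len(values)
        assert frac == pytest.approx(0.1, abs=0.001)

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            decile_cutoff([1.0] * 9)


def oeuf(element="e", upper=1.0, powered=True):
    return OEUFResult(
        element_id=element, oeuf_class="x", observed=10, expected=12.0,
        lower=0.5, upper=upper, point_ratio=0.8, powered=powered,
    )


class TestFrameRespect:
    def test_direction(self):
        assert frame_respect_flag(oeuf(upper=0.6), oeuf(upper=0.933)) is True

    def test_equal_values_false(self):
        assert frame_respect_flag(oeuf(upper=1.0), oeuf(upper=1.0)) is False

    def test_unpowered_rejected(self):
        with pytest.raises(ValueError):
            frame_respect_flag(oeuf(powered=False), oeuf())

    def test_element_mismatch(self):
        with pytest.raises(ValueError):
            frame_respect_flag(oeuf(element="a"), oeuf(element="b"))


class TestRegionalUtrConstraint:
    def test_separated_by_two_deciles(self):
        assert regional_utr_constraint("g", [1, 4], [20.0, 20.0]) is True

    def test_single_gap_insufficient(self):
        assert regional_utr_constraint("g", [1, 3], [20.0, 20.0]) is False

    def test_pairwise_over_three_utrs(self):
        assert regional_utr_constraint("g", [2, 2, 7], [20.0, 20.0, 20.0]) is True

    def test_underpowered_utrs_dropped(self):
        assert regional_utr_constraint("g", [1, 4], [20.0, 5.0]) is False

    def test_short_utrs_dropped(self):
        assert (
            regional_utr_constraint(
                "g", [1, 4], [20.0, 20.0], utr_lengths=[900, 500], min_len=800
            )
            is False
        )

    def test_lengths_required_when_min_len_set(self):
        with pytest.raises(ValueError):
            regional_utr_constraint("g", [1, 4], [20.0, 20.0], min_len=800)
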