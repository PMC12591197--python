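"""Mixture-proportion estimators: hand-checkable examples, independent
grid-search and enumeration oracles, the zero-error closed form, and the
donor-relabelling symmetry."""

import itertools
import math

import numpy as np
import pytest
from scipy.stats import binom

from chimera_deconv import (AlleleCounts, ConfigurationError, EstimationError,
                            bootstrap_ci, classify_counts,
                            estimate_binomial_mle, estimate_read_fraction,
                            estimate_site_share)
from chimera_deconv.origin import BOTH, C_ONLY, O_ONLY, OriginCall


def ac(n_o, n_c, pos=None, _counter=itertools.count(1)):
    return AlleleCounts("chr1", pos if pos is not None else next(_counter),
                        "OCC", n_o, n_c)


def call(category, n_o=0, n_c=0, pos=None, _counter=itertools.count(1)):
    p = pos if pos is not None else next(_counter)
    n = n_o + n_c
    return OriginCall("chr1", p, category, n_o, n_c, n_o / n if n else None)


def grid_oracle(counts, eps, n_grid=10**5):
    """Independent maximizer: dense grid over p, per-site binomial logpmf."""
    n_c = np.array([c.n_C for c in counts])
    n = np.array([c.n for c in counts])
    p = np.linspace(0.0, 1.0, n_grid + 1)
    q = p * (1 - eps) + (1 - p) * eps
    ll = binom.logpmf(n_c[:, None], n[:, None], q[None, :]).sum(axis=0)
    return p[np.argmax(ll)], ll.max()


class TestSiteShare:
    def test_counting_example(self):
        calls = [call(C_ONLY), call(C_ONLY), call(C_ONLY), call(O_ONLY)]
        est = estimate_site_share(calls)
        assert est.p_C == 0.75 and est.n_sites_used == 4

    def test_both_site_contributes_one_minus_f_O(self):
        est = estimate_site_share([call(BOTH, 5, 5)])
        assert est.p_C == 0.5

    def test_twenty_mixed_calls_match_hand_enumeration(self):
        rng = np.random.default_rng(42)
        calls = []
        for i in range(20):
            kind = rng.integers(4)
            if kind == 0:
                calls.append(call(O_ONLY, 20, 0, pos=i))
            elif kind == 1:
                calls.append(call(C_ONLY, 0, 20, pos=i))
            elif kind == 2:
                n_o = int(rng.integers(3, 18))
                calls.append(call(BOTH, n_o, 20 - n_o, pos=i))
            else:
                calls.append(call("UNINFORMATIVE", 1, 1, pos=i))
        # independent enumeration over the list
        num = den = 0.0
        for c in calls:
            if c.category == C_ONLY:
                num += 1; den += 1
            elif c.category == O_ONLY:
                den += 1
            elif c.category == BOTH:
                num += 1 - c.n_O / (c.n_O + c.n_C); den += 1
        est = estimate_site_share(calls)
        assert est.p_C == pytest.approx(num / den, abs=1e-12)
        assert est.n_sites_used == den

    def test_zero_informative_is_estimation_error(self):
        with pytest.raises(EstimationError):
            estimate_site_share([call("UNINFORMATIVE", 1, 1)])


class TestReadFraction:
    @pytest.mark.parametrize("pairs,expected", [
        ([(0, 30), (0, 12)], 1.0),            # all reads donor C
        ([(10, 10)], 0.5),
        ([(9, 1), (8, 2), (10, 0)], 0.1),
    ])
    def test_pooled_fraction(self, pairs, expected):
        counts = [ac(o, c, pos=i) for i, (o, c) in enumerate(pairs)]
        assert estimate_read_fraction(counts).p_C == pytest.approx(expected)

    def test_zero_reads_is_estimation_error(self):
        with pytest.raises(EstimationError):
            estimate_read_fraction([ac(0, 0)])


class TestBinomialMle:
    def test_zero_eps_is_pooled_fraction_exactly(self):
        counts = [ac(1, 9), ac(2, 8), ac(0, 10)]
        assert estimate_binomial_mle(counts, 0.0).p_C == 27 / 30

    def test_matches_grid_oracle_with_error_rate(self):
        counts = [ac(1, 9), ac(2, 8), ac(0, 10)]
        est = estimate_binomial_mle(counts, 0.05)
        p_star, _ = grid_oracle(counts, 0.05)
        assert est.p_C == pytest.approx(p_star, abs=2e-5)

    def test_symmetric_counts_give_half(self):
        for eps in (0.0, 0.01, 0.2):
            counts = [ac(7, 7), ac(30, 30)]
            assert estimate_binomial_mle(counts, eps).p_C == \
                pytest.approx(0.5, abs=1e-8)

    def test_eps_consistency_with_read_fraction(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            counts = [ac(int(o), int(c), pos=i) for i, (o, c) in
                      enumerate(rng.integers(0, 80, size=(15, 2)))]
            if sum(c.n for c in counts) == 0:
                continue
            assert abs(estimate_binomial_mle(counts, 0.0).p_C
                       - estimate_read_fraction(counts).p_C) <= 1e-9

    def test_loglik_at_estimate_beats_every_grid_point(self):
        counts = [ac(3, 40), ac(1, 22), ac(9, 9)]
        est = estimate_binomial_mle(counts, 0.01)
        _, ll_best_grid = grid_oracle(counts, 0.01, n_grid=2000)
        assert est.loglik >= ll_best_grid - 1e-9

    def test_boundary_estimates_stay_in_unit_interval(self):
        assert estimate_binomial_mle([ac(0, 50)], 0.005).p_C == pytest.approx(1.0, abs=1e-6)
        assert estimate_binomial_mle([ac(50, 0)], 0.005).p_C == pytest.approx(0.0, abs=1e-6)

    def test_bad_epsilon_rejected(self):
        with pytest.raises(ConfigurationError):
            estimate_binomial_mle([ac(1, 1)], 0.5)

    def test_all_zero_depths_is_estimation_error(self):
        with pytest.raises(EstimationError):
            estimate_binomial_mle([ac(0, 0), ac(0, 0)], 0.01)


class TestLabelSymmetry:
    def test_every_estimator_maps_p_to_one_minus_p(self):
        rng = np.random.default_rng(8)
        counts = [ac(int(o), int(c), pos=i) for i, (o, c) in
                  enumerate(rng.integers(0, 60, size=(40, 2)))]
        swapped = [AlleleCounts(c.chrom, c.pos, c.sample_id, c.n_C, c.n_O)
                   for c in counts]
        assert estimate_read_fraction(swapped).p_C == pytest.approx(
            1 - estimate_read_fraction(counts).p_C, abs=1e-12)
        assert estimate_binomial_mle(swapped, 0.01).p_C == pytest.approx(
            1 - estimate_binomial_mle(counts, 0.01).p_C, abs=1e-6)
        assert estimate_site_share(classify_counts(swapped)).p_C == \
            pytest.approx(1 - estimate_site_share(classify_counts(counts)).p_C,
                          abs=1e-12)


class TestBootstrap:
    def test_identical_sites_give_degenerate_interval(self):
        counts = [ac(0, 50, pos=i) for i in range(10)]
        assert bootstrap_ci(counts, "read_fraction", B=200, seed=1) == (1.0, 1.0)

    def test_same_seed_reproduces_interval(self):
        rng = np.random.default_rng(5)
        counts = [ac(int(o), int(c), pos=i) for i, (o, c) in
                  enumerate(rng.integers(0, 50, size=(30, 2)))]
        a = bootstrap_ci(counts, "binomial_mle", B=300, seed=9)
        b = bootstrap_ci(counts, "binomial_mle", B=300, seed=9)
        assert a == b
        c = bootstrap_ci(counts, "binomial_mle", B=300, seed=10)
        assert a != c

    def test_exhaustive_three_sites_matches_enumeration(self):
        counts = [ac(9, 1, pos=0), ac(5, 5, pos=1), ac(0, 10, pos=2)]
        got = bootstrap_ci(counts, "read_fraction", exhaustive=True)
        # independent enumeration of all 27 ordered resamples
        ests = []
        for combo in itertools.product(range(3), repeat=3):
            n_c = sum(counts[i].n_C for i in combo)
            n = sum(counts[i].n for i in combo)
            ests.append(n_c / n)
        lo, hi = np.quantile(ests, [0.025, 0.975])
        assert got == pytest.approx((lo, hi), abs=1e-12)

    def test_interval_brackets_point_estimate(self):
        rng = np.random.default_rng(2)
        counts = [ac(int(o), int(c), pos=i) for i, (o, c) in
                  enumerate(rng.integers(0, 50, size=(50, 2)))]
        lo, hi = bootstrap_ci(counts, "read_fraction", B=500, seed=0)
        p = estimate_read_fraction(counts).p_C
        assert lo <= p <= hi

    @pytest.mark.parametrize("kwargs,err", [
        (dict(B=0), ConfigurationError),
        (dict(estimator="nope"), ConfigurationError),
        (dict(level=1.5), ConfigurationError),
    ])
    def test_bad_configuration_rejected(self, kwargs, err):
        counts = [ac(1, 1, pos=0), ac(2, 2, pos=1)]
        merged = dict(estimator="read_fraction", B=10, seed=0)
        merged.update(kwargs)
        with pytest.raises(err):
            bootstrap_ci(counts, **merged)

    def test_single_site_rejected(self):
        with pytest.raises(EstimationError):
            bootstrap_ci([ac(1, 1)], "read_fraction")
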