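"""Tests for rank-abundance model fitting and the ZSM likelihood.

The Ewens oracle is an independent implementation of the Ewens sampling
formula written directly from its textbook product form (no shared code
with the Etienne evaluation it checks).
"""

import math

import numpy as np
import pytest
from scipy import stats

from decaywood.sad_assembly import (
    ALL_MODELS,
    ModelFit,
    RankAbundance,
    akaike_weights,
    compare_models,
    expected_abundance,
    fit_rad_model,
    fit_zsm,
    fit_zsm_ranks,
    zsm_expected_sad,
    zsm_loglik,
)
from decaywood.synthetic_data import (
    NeutralParams,
    NicheParams,
    simulate_neutral_sample,
    simulate_niche_sample,
)


def ewens_log_prob(abundances, theta):
    """Independent Ewens sampling formula oracle.

    P(config) = J! / (theta)_J * prod_j theta^Phi_j / (j^Phi_j Phi_j!)
    computed with exact fractions of floats, straight from the product
    form over abundance classes.
    """
    a = sorted(abundances, reverse=True)
    J = sum(a)
    log_p = math.lgamma(J + 1)
    for i in range(J):            # rising factorial (theta)_J
        log_p -= math.log(theta + i)
    for j in set(a):              # theta^Phi_j / (j^Phi_j * Phi_j!)
        phi = a.count(j)
        log_p += phi * math.log(theta)
        log_p -= phi * math.log(j)
        log_p -= math.lgamma(phi + 1)
    return log_p


class TestRankAbundance:
    def test_sorted_and_validated(self):
        ra = RankAbundance(np.array([2, 7, 1]))
        assert list(ra.abundances) == [7, 2, 1]
        assert ra.S == 3 and ra.J == 10

    def test_zero_rejected_but_from_counts_drops(self):
        with pytest.raises(ValueError):
            RankAbundance(np.array([3, 0]))
        ra = RankAbundance.from_counts([3, 0, 5])
        assert list(ra.abundances) == [5, 3]


class TestExpectedAbundance:
    def test_brokenstick_hand_values(self):
        lam = expected_abundance("brokenstick", {}, 3, 18)
        assert np.allclose(lam, [11, 5, 2])

    def test_preemption_hand_values(self):
        lam = expected_abundance("preemption", {"alpha": 0.5}, 2, 3)
        assert np.allclose(lam, [2, 1])

    def test_zipf_hand_values(self):
        lam = expected_abundance("zipf", {"p1": 0.5, "gamma": -1.0}, 2, 4)
        assert np.allclose(lam, [2, 1])

    def test_mandelbrot_beta_zero_equals_zipf(self):
        z = expected_abundance("zipf", {"p1": 0.4, "gamma": -1.3}, 10, 100)
        m = expected_abundance(
            "mandelbrot", {"c": 0.4, "gamma": -1.3, "beta": 0.0}, 10, 100)
        assert np.allclose(z, m)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            expected_abundance("preemption", {"alpha": 0.0}, 3, 10)
        with pytest.raises(ValueError):
            expected_abundance("unknown", {}, 3, 10)


class TestNicheFits:
    def test_brokenstick_loglik_is_poisson_at_mean(self):
        ra = RankAbundance(np.array([11, 5, 2]))
        fit = fit_rad_model(ra, "brokenstick")
        lam = expected_abundance("brokenstick", {}, 3, 18)
        expected = stats.poisson.logpmf([11, 5, 2], lam).sum()
        assert fit.log_likelihood == pytest.approx(expected)
        assert fit.npar == 0

    def test_geometric_alpha_recovery_vs_grid(self):
        ra = RankAbundance(np.array([16, 8, 4, 2, 1]))
        fit = fit_rad_model(ra, "preemption")
        # grid-search oracle over alpha
        grid = np.linspace(0.01, 0.99, 981)
        best = None
        for alpha in grid:
            lam = expected_abundance("preemption", {"alpha": alpha},
                                     ra.S, ra.J)
            ll = stats.poisson.logpmf(ra.abundances, lam).sum()
            if best is None or ll > best[1]:
                best = (alpha, ll)
        assert abs(fit.params["alpha"] - 0.5) < 0.05
        assert abs(fit.params["alpha"] - best[0]) < 0.005
        assert fit.log_likelihood >= best[1] - 1e-6

    def test_mandelbrot_nests_zipf(self):
        for seed in range(3):
            ra = simulate_niche_sample(
                NicheParams("zipf", {"p1": 0.3, "gamma": -1.1}, 30, 500),
                seed)
            z = fit_rad_model(ra, "zipf")
            m = fit_rad_model(ra, "mandelbrot")
            assert m.log_likelihood >= z.log_likelihood - 1e-6

    def test_zipf_fit_beats_fixed_params(self):
        ra = simulate_niche_sample(
            NicheParams("zipf", {"p1": 0.3, "gamma": -1.1}, 30, 500), 1)
        fit = fit_rad_model(ra, "zipf")
        lam = expected_abundance("zipf", {"p1": 0.2, "gamma": -0.8},
                                 ra.S, ra.J)
        fixed_ll = stats.poisson.logpmf(ra.abundances, lam).sum()
        assert fit.log_likelihood >= fixed_ll - 1e-9

    def test_aic_identity(self):
        fit = ModelFit("zipf", {}, -123.25, 2)
        assert fit.aic == -2.0 * -123.25 + 2 * 2


class TestZsmLoglik:
    def test_single_individual_probability_one(self):
        ra = RankAbundance(np.array([1]))
        for theta, m in [(0.5, 1.0), (3.0, 0.4), (50.0, 0.9)]:
            assert zsm_loglik(ra, theta, m) == pytest.approx(0.0, abs=1e-10)

    def test_ewens_pair_closed_form(self):
        # J=2 same species at m=1: P = 1/(1+theta)
        ra = RankAbundance(np.array([2]))
        assert math.exp(zsm_loglik(ra, 1.0, 1.0)) == pytest.approx(0.5)
        ra2 = RankAbundance(np.array([1, 1]))
        assert math.exp(zsm_loglik(ra2, 1.0, 1.0)) == pytest.approx(0.5)

    def test_matches_independent_ewens_oracle(self, partition_fn):
        for theta in (0.5, 1.0, 5.0):
            for J in (3, 6, 8):
                for part in partition_fn(J):
                    ra = RankAbundance(np.array(part))
                    assert zsm_loglik(ra, theta, 1.0) == pytest.approx(
                        ewens_log_prob(part, theta), abs=1e-6)

    def test_total_probability_sums_to_one(self, partition_fn):
        for theta, m in [(2.0, 0.3), (5.0, 0.7)]:
            total = sum(math.exp(zsm_loglik(RankAbundance(np.array(p)),
                                            theta, m))
                        for p in partition_fn(6))
            assert total == pytest.approx(1.0, abs=1e-8)

    def test_invalid_params_rejected(self):
        ra = RankAbundance(np.array([3, 1]))
        with pytest.raises(ValueError):
            zsm_loglik(ra, -1.0, 0.5)
        with pytest.raises(ValueError):
            zsm_loglik(ra, 1.0, 0.0)


class TestFitZsm:
    def test_optimum_beats_reference_point(self):
        for seed in (0, 1):
            ra = simulate_neutral_sample(NeutralParams(10, 0.3, 200), seed)
            fit = fit_zsm(ra)
            assert fit.log_likelihood >= zsm_loglik(ra, 1.0, 0.5) - 1e-9

    def test_all_singletons_flagged_boundary(self):
        ra = RankAbundance(np.ones(8, dtype=int))
        fit = fit_zsm(ra)
        assert not fit.converged
        assert fit.params["theta"] > 1e3

    def test_npar_and_aic(self):
        ra = simulate_neutral_sample(NeutralParams(10, 0.3, 150), 2)
        fit = fit_zsm(ra)
        assert fit.npar == 2
        assert fit.aic == pytest.approx(-2 * fit.log_likelihood + 4)


class TestZsmExpectedSad:
    def test_total_individuals_conserved(self):
        from decaywood.sad_assembly import _HEAD_MAX
        n, phi = zsm_expected_sad(30.0, 0.2, 1080)
        # integrate n * phi over the grid (trapezoid on the tail)
        k = int((n <= _HEAD_MAX + 0.5).sum())
        total = (n[:k] * phi[:k]).sum()
        total += np.trapezoid((n * phi)[k - 1:], n[k - 1:])
        assert total == pytest.approx(1080, rel=0.02)

    def test_m1_matches_ewens_richness(self):
        from decaywood.sad_assembly import _HEAD_MAX
        theta, J = 5.0, 300
        n, phi = zsm_expected_sad(theta, 1.0, J)
        k = int((n <= _HEAD_MAX + 0.5).sum())
        e_s = phi[:k].sum() + np.trapezoid(phi[k - 1:], n[k - 1:])
        closed = (theta / (theta + np.arange(J))).sum()
        assert e_s == pytest.approx(closed, rel=0.02)

    def test_rank_fit_reasonable_on_neutral_data(self):
        ra = simulate_neutral_sample(NeutralParams(30, 0.2, 1080), 3)
        fit = fit_zsm_ranks(ra)
        assert fit.npar == 2
        assert np.isfinite(fit.log_likelihood)
        # the rank fit should beat a wildly wrong parameter pair
        from decaywood.sad_assembly import zsm_expected_ranks, _poisson_loglik
        bad = _poisson_loglik(ra.abundances.astype(float),
                              zsm_expected_ranks(1.0, 0.99, ra.J, ra.S))
        assert fit.log_likelihood >= bad


class TestAkaikeWeights:
    def test_equal_aics_split_evenly(self):
        assert np.allclose(akaike_weights([10.0, 10.0]), [0.5, 0.5])

    def test_hand_value_two_apart(self):
        w = akaike_weights([100.0, 102.0])
        assert w[0] == pytest.approx(0.7311, abs=1e-4)
        assert w[1] == pytest.approx(0.2689, abs=1e-4)

    def test_shift_invariance(self):
        a = np.array([12.0, 15.5, 13.1])
        assert np.allclose(akaike_weights(a), akaike_weights(a + 77.7))

    def test_nonfinite_gets_zero(self):
        w = akaike_weights([10.0, math.inf])
        assert w[1] == 0.0 and w[0] == 1.0

    def test_all_nonfinite_errors(self):
        with pytest.raises(ValueError):
            akaike_weights([math.inf, math.nan])


class TestCompareModels:
    def test_weights_sum_to_one(self):
        ra = simulate_neutral_sample(NeutralParams(20, 0.3, 400), 5)
        comp = compare_models(ra)
        assert sum(comp.akaike_weight.values()) == pytest.approx(1.0,
                                                                 abs=1e-9)
        assert comp.best_model == max(comp.akaike_weight,
                                      key=comp.akaike_weight.get)
        assert set(comp.fits) == set(ALL_MODELS)

    def test_verdict_families(self):
        ra = simulate_niche_sample(
            NicheParams("preemption", {"alpha": 0.5}, 50, 1080), 0)
        comp = compare_models(ra)
        assert comp.verdict in ("niche", "both")

    def test_mixed_scoring_mode_runs(self):
        ra = simulate_neutral_sample(NeutralParams(20, 0.3, 300), 8)
        comp = compare_models(ra, scoring="mixed")
        assert set(comp.fits) == set(ALL_MODELS)
        assert sum(comp.akaike_weight.values()) == pytest.approx(1.0)

    def test_unknown_scoring_rejected(self):
        ra = RankAbundance(np.array([5, 3, 1]))
        with pytest.raises(ValueError):
            compare_models(ra, scoring="bogus")
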