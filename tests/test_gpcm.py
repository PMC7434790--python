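"""GPCM probabilities, information, estimation, scoring, and alpha."""

import math

import numpy as np
import pytest

import scaleshort as ss
from scaleshort.bank import ValidationError
from scaleshort.gpcm import marginal_loglik


class TestCategoryProbs:
    def test_zero_discrimination_uniform(self):
        item = ss.ItemParameters(0.0, (-1.0, 0.0, 1.0, 2.0))
        assert np.allclose(ss.category_probs(item, 0.7), 0.2)

    def test_three_category_hand_values(self):
        # a=1, b=(0,1), theta=0: unnormalised weights 1, 1, e^-1
        item = ss.ItemParameters(1.0, (0.0, 1.0))
        z = 2.0 + math.exp(-1.0)
        expected = np.array([1.0, 1.0, math.exp(-1.0)]) / z
        assert np.allclose(ss.category_probs(item, 0.0), expected)

    def test_probabilities_sum_to_one(self, rng):
        for _ in range(200):
            m = rng.integers(1, 6)
            item = ss.ItemParameters(rng.uniform(0, 3),
                                     tuple(rng.normal(0, 2, m)))
            th = rng.normal(0, 2, size=7)
            p = ss.category_probs(item, th)
            assert np.allclose(p.sum(axis=-1), 1.0, atol=1e-12)

    def test_adjacent_equality_at_each_step(self, ref_params):
        q1 = ref_params["Q1"]
        for j, bj in enumerate(q1.b):
            p = ss.category_probs(q1, bj)
            assert p[j] == pytest.approx(p[j + 1], rel=1e-12)


class TestInformation:
    def test_zero_discrimination(self):
        item = ss.ItemParameters(0.0, (0.0, 1.0))
        assert np.allclose(ss.item_information(item, np.linspace(-3, 3, 7)),
                           0.0)

    def test_matches_score_derivative(self, ref_params):
        # I(theta) = a * dE[C|theta]/dtheta
        h = 1e-5
        for par in ref_params.values():
            for th in (-2.0, 0.0, 1.5):
                deriv = (ss.expected_score(par, th + h)
                         - ss.expected_score(par, th - h)) / (2 * h)
                assert abs(ss.item_information(par, th)
                           - par.a * deriv) < 1e-6

    def test_integral_identity_single_item(self):
        from scipy.integrate import quad

        item = ss.ItemParameters(1.3, (-1.5, 0.2, 2.0))
        val, _ = quad(lambda t: float(ss.item_information(item, t)),
                      -np.inf, np.inf, limit=400)
        assert val == pytest.approx(item.a * item.m, abs=1e-3)

    def test_test_information_additivity(self, ref_params):
        th = np.linspace(-3, 3, 13)
        total = ss.test_information(list(ref_params.values()), theta=th)
        manual = sum(ss.item_information(p, th)
                     for p in ref_params.values())
        assert np.allclose(total, manual)

    def test_single_item_test_equals_item(self, ref_params):
        q1 = ref_params["Q1"]
        assert ss.test_information([q1], bounds="full") == pytest.approx(
            ss.total_item_information(q1, "full"))

    def test_invalid_range(self, ref_params):
        with pytest.raises(ValueError):
            ss.total_item_information(ref_params["Q1"], (2.0, -2.0))


class TestStandardError:
    def test_inverse_sqrt_relationship(self, ref_params):
        pts, se, avg = ss.standard_error_curve(list(ref_params.values()))
        info = ss.test_information(list(ref_params.values()), theta=pts)
        assert np.allclose(se, 1.0 / np.sqrt(info))
        assert avg == pytest.approx(float(np.mean(se)))

    def test_removing_item_never_decreases_se(self, ref_params):
        full = list(ref_params.values())
        reduced = [v for k, v in ref_params.items() if k != "Q10"]
        _, se_full, _ = ss.standard_error_curve(full)
        _, se_red, _ = ss.standard_error_curve(reduced)
        assert np.all(se_red >= se_full - 1e-12)

    def test_point_value(self):
        # a test whose information is 4 at theta=0 has SE 0.5 there
        item = ss.ItemParameters(2.0, (0.0,))
        info0 = float(ss.item_information(item, 0.0))
        grid = ss.LatentGrid.even(3, -1, 1)
        pts, se, _ = ss.standard_error_curve([item], grid)
        assert se[1] == pytest.approx(1.0 / np.sqrt(info0))


class TestFit:
    def test_loglik_matches_bruteforce_oracle(self, rng):
        # independent direct evaluation on a 5-person, 2-item toy
        X = rng.integers(0, 3, size=(5, 2))
        grid = ss.LatentGrid.normal(21)
        params = [ss.ItemParameters(1.2, (-0.5, 0.8)),
                  ss.ItemParameters(0.7, (0.1, 1.1))]
        brute = 0.0
        for x in X:
            person = 0.0
            for q, w in zip(grid.points, grid.weights):
                lik = w
                for j, par in enumerate(params):
                    lik *= float(ss.category_probs(par, q)[x[j]])
                person += lik
            brute += math.log(person)
        assert marginal_loglik(params, X, grid) == pytest.approx(
            brute, abs=1e-8)

    def test_em_monotone_loglik(self, small_fixture):
        fit = ss.fit_gpcm(small_fixture.matrix, se=False)
        diffs = np.diff(fit.loglik_history)
        assert np.all(diffs > -1e-6)
        assert fit.converged

    def test_more_iterations_never_lower_loglik(self, small_fixture):
        short = ss.fit_gpcm(small_fixture.matrix, se=False, max_iter=5)
        longer = ss.fit_gpcm(small_fixture.matrix, se=False, max_iter=10)
        assert longer.loglik >= short.loglik - 1e-8

    def test_final_loglik_matches_final_params(self, small_fixture):
        fit = ss.fit_gpcm(small_fixture.matrix, se=False)
        recomputed = marginal_loglik(fit.param_list(), small_fixture.matrix,
                                     fit.grid)
        assert fit.loglik == pytest.approx(recomputed, abs=1e-8)

    def test_single_category_item_errors(self):
        X = np.zeros((20, 2), dtype=int)
        X[:, 0] = np.arange(20) % 3
        with pytest.raises(ValidationError, match="item2"):
            ss.fit_gpcm(X)

    def test_standard_errors_finite(self, small_fixture):
        fit = ss.fit_gpcm(small_fixture.matrix, se=True)
        for iid, (se_a, se_b) in fit.se_params.items():
            assert np.isfinite(se_a) and se_a > 0
            assert all(np.isfinite(s) and s > 0 for s in se_b)


class TestEap:
    def test_extreme_patterns_order(self, ref_params):
        fit = ss.GpcmFit.from_params(ref_params)
        X = np.array([[0] * 12, [2] * 12, [4] * 12])
        scores, psd = ss.eap_scores(fit, X)
        assert scores[0] < scores[1] < scores[2]
        assert scores[0] == min(scores)
        assert np.all(psd > 0)

    def test_shrinkage_vs_grid_ml(self, fixture404, fit404):
        eap, _ = ss.eap_scores(fit404, fixture404.matrix)
        # grid-ML oracle: argmax of the likelihood without the prior
        grid = fit404.grid
        X = fixture404.matrix.codes
        ll = np.zeros((X.shape[0], len(grid.points)))
        for j, iid in enumerate(fit404.item_ids):
            logp = np.log(ss.category_probs(fit404.params[iid],
                                            grid.points))
            ll += logp[:, X[:, j]].T
        ml = grid.points[np.argmax(ll, axis=1)]
        assert np.mean(np.abs(eap)) <= np.mean(np.abs(ml))

    def test_recovers_true_trait(self, fixture404, fit404):
        eap, _ = ss.eap_scores(fit404, fixture404.matrix)
        assert np.corrcoef(eap, fixture404.thetas)[0, 1] > 0.9

    def test_unfitted_item_errors(self, fit404, fixture404):
        with pytest.raises(KeyError):
            ss.eap_scores(fit404, fixture404.matrix, item_ids=["Q99"])


class TestCronbachAlpha:
    def test_identical_columns(self, rng):
        col = rng.integers(1, 6, size=200).astype(float)
        assert ss.cronbach_alpha(np.column_stack([col, col])) == (
            pytest.approx(1.0))

    def test_population_covariance_oracle(self, rng):
        # 3 items, unit variances, pairwise covariance 0.5: alpha = 0.75
        cov = np.array([[1.0, 0.5, 0.5], [0.5, 1.0, 0.5], [0.5, 0.5, 1.0]])
        data = rng.multivariate_normal(np.zeros(3), cov, size=10_000)
        assert ss.cronbach_alpha(data) == pytest.approx(0.75, abs=0.02)

    def test_reference_band(self, fixture404):
        # the reference calibration implies alpha near 0.834 at n=404
        assert ss.cronbach_alpha(fixture404.matrix) == pytest.approx(
            0.834, abs=0.05)

    def test_degenerate_inputs(self):
        with pytest.raises(ValidationError):
            ss.cronbach_alpha(np.ones((10, 3)))
        with pytest.raises(ValidationError):
            ss.cronbach_alpha(np.random.default_rng(0).normal(size=(10, 1)))


class TestLatentGrid:
    def test_normal_weights_normalised(self):
        g = ss.LatentGrid.normal(61)
        assert g.weights.sum() == pytest.approx(1.0)
        assert np.all(np.diff(g.points) > 0)

    def test_gauss_hermite_moments(self):
        g = ss.LatentGrid.gauss_hermite(31)
        assert (g.weights * g.points).sum() == pytest.approx(0.0, abs=1e-10)
        assert (g.weights * g.points ** 2).sum() == pytest.approx(
            1.0, abs=1e-8)

    def test_validation(self):
        with pytest.raises(ValueError):
            ss.LatentGrid(points=[0.0, 0.0], weights=[0.5, 0.5])
        with pytest.raises(ValueError):
            ss.LatentGrid(points=[0.0, 1.0], weights=[0.5, -0.5])
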