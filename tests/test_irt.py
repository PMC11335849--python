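"""2PL estimation, EAP scoring, curves: closed forms and independent oracles."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import expit
from scipy.stats import norm

import acoforms as af
from acoforms.irt import CurveSet, ThetaGrid, _row_logsumexp, curve_set


def dense_grid(n=2001, lo=-8.0, hi=8.0):
    nodes = np.linspace(lo, hi, n)
    w = norm.pdf(nodes)
    return ThetaGrid(nodes, w / w.sum())


class TestThetaGrid:
    def test_default_grid_contract(self, grid):
        assert grid.n_nodes == 61
        assert grid.nodes[0] == -6 and grid.nodes[-1] == 6
        assert abs(grid.weights.sum() - 1) < 1e-12

    def test_invalid_grids_rejected(self):
        with pytest.raises(ValueError):
            ThetaGrid(np.array([0.0, 0.0, 1.0]), np.full(3, 1 / 3))
        with pytest.raises(ValueError):
            ThetaGrid(np.array([0.0, 1.0]), np.array([0.9, 0.2]))


class TestCurves:
    def test_tcc_logistic_midpoint(self, grid):
        form = af.CalibratedForm(["i1"], [2.7], [0.0], -1.0, True, 10)
        g = ThetaGrid(np.array([-1.0, 0.0, 1.0]), np.array([0.25, 0.5, 0.25]))
        assert af.tcc(form, g)[1] == pytest.approx(0.5, abs=1e-12)

    def test_tcc_hand_computed_two_items(self):
        form = af.CalibratedForm(["i1", "i2"], [1.0, 2.0], [-1.0, 1.0], -1.0, True, 10)
        g = ThetaGrid(np.array([-1.0, 0.0, 1.0]), np.array([0.25, 0.5, 0.25]))
        # expit(1*(0+1)) + expit(2*(0-1)) = 0.7311 + 0.1192
        assert af.tcc(form, g)[1] == pytest.approx(0.8503, abs=1e-4)

    def test_tcc_monotone_and_saturating(self, fitted_form, grid):
        curve = af.tcc(fitted_form, grid)
        assert np.all(np.diff(curve) >= 0)
        wide = ThetaGrid(np.linspace(-40, 40, 5), np.full(5, 0.2))
        assert af.tcc(fitted_form, wide)[-1] == pytest.approx(fitted_form.n_items, abs=1e-6)

    def test_tif_maximum_at_difficulty(self):
        form = af.CalibratedForm(["i1"], [1.7], [0.3], -1.0, True, 10)
        g = ThetaGrid(np.array([-1.0, 0.3, 1.0]), np.array([0.25, 0.5, 0.25]))
        assert af.tif(form, g)[1] == pytest.approx(1.7**2 / 4, abs=1e-12)

    def test_tif_sum_of_item_maxima(self):
        form = af.CalibratedForm(["i1", "i2"], [1.0, 2.0], [0.0, 0.0], -1.0, True, 10)
        g = ThetaGrid(np.array([-1.0, 0.0, 1.0]), np.array([0.25, 0.5, 0.25]))
        assert af.tif(form, g)[1] == pytest.approx(1.25, abs=1e-12)

    def test_tif_matches_finite_difference_of_item_curves(self, grid):
        """a_i * dP_i/dtheta = a_i^2 P(1-P): the TIF integrand."""
        a, b = np.array([0.8, 1.5]), np.array([-0.4, 0.9])
        form = af.CalibratedForm(["i1", "i2"], a, b, -1.0, True, 10)
        eps = 1e-6
        theta = grid.nodes
        fd = (expit(a[:, None] * (theta + eps - b[:, None]))
              - expit(a[:, None] * (theta - eps - b[:, None]))) / (2 * eps)
        assert np.allclose(af.tif(form, grid), (a[:, None] * fd).sum(axis=0), atol=1e-4)

    def test_tif_nonnegative(self, fitted_form, grid):
        assert np.all(af.tif(fitted_form, grid) >= 0)


class TestCurveSqsum:
    def _curves(self, arrays, n_nodes):
        g = ThetaGrid(np.linspace(-3, 3, n_nodes), np.full(n_nodes, 1 / n_nodes))
        return CurveSet(g, arrays, "tif")

    def test_identical_curves_zero(self):
        c = np.linspace(0, 2, 81)
        assert af.curve_sqsum(self._curves([c, c, c], 81)) == 0.0

    def test_constant_offset(self):
        c = np.linspace(0, 2, 81)
        assert af.curve_sqsum(self._curves([c, c + 1], 81)) == pytest.approx(81.0)

    def test_three_forms_pairwise_enumeration(self):
        c = np.linspace(0, 1, 10)
        # pairs: (c,c+1)=10, (c,c+2)=40, (c+1,c+2)=10
        val = af.curve_sqsum(self._curves([c, c + 1, c + 2], 10))
        assert val == pytest.approx(60.0)

    def test_mismatched_grids_rejected(self):
        g1 = ThetaGrid(np.linspace(-3, 3, 5), np.full(5, 0.2))
        with pytest.raises(ValueError):
            CurveSet(g1, [np.zeros(4)], "tcc")


class TestFit2PL:
    def test_parameter_recovery(self):
        bank = af.generate_item_bank(
            12, 1, a_dist={"dist": "fixed", "value": 1.2},
            b_dist={"dist": "fixed", "value": -0.5}, seed=0,
        )
        data = af.simulate_responses(bank, 2000, seed=21)
        form = af.fit_2pl(data, item_ids=data.item_ids)
        assert form.converged
        assert np.sqrt(np.mean((form.a_hat - 1.2) ** 2)) < 0.15
        assert np.sqrt(np.mean((form.b_hat + 0.5) ** 2)) < 0.10

    def test_all_correct_item_error_names_item(self):
        X = np.array([[1, 0, 1], [1, 1, 0], [1, 0, 0], [1, 1, 1]])
        with pytest.raises(ValueError, match="itemA"):
            af.fit_2pl(X, item_ids=["itemA", "itemB", "itemC"])

    def test_loglik_matches_direct_optimizer(self, grid):
        """Independent oracle: direct numerical maximization of the same
        marginal likelihood must agree with EM within 1e-3."""
        bank = af.generate_item_bank(2, 2, seed=13)
        data = af.simulate_responses(bank, 200, seed=14)
        form = af.fit_2pl(data, grid, item_ids=data.item_ids)

        X = data.responses.astype(float)
        w = grid.weights
        nodes = grid.nodes

        def negll(p):
            a, b = p[:4], p[4:]
            z = a[:, None] * (nodes[None, :] - b[:, None])
            logp = -np.logaddexp(0, -z)
            log1mp = -np.logaddexp(0, z)
            ll = X @ logp + (1 - X) @ log1mp + np.log(w)[None, :]
            return -float(_row_logsumexp(ll).sum())

        res = minimize(
            negll, np.concatenate([np.ones(4), np.zeros(4)]),
            method="L-BFGS-B",
            bounds=[(0.05, 8)] * 4 + [(-8, 8)] * 4,
        )
        assert form.loglik == pytest.approx(-res.fun, abs=1e-3)

    def test_loglik_path_nondecreasing(self, small_data):
        est = af.TwoParameterLogistic().fit(
            small_data.subset(small_data.item_ids[:6])
        )
        assert np.all(np.diff(est.loglik_path_) >= -1e-8)

    def test_column_permutation_invariance(self, small_data, grid):
        items = small_data.item_ids[:6]
        f1 = af.fit_2pl(small_data.subset(items), grid, item_ids=items)
        perm = items[::-1]
        f2 = af.fit_2pl(small_data.subset(perm), grid, item_ids=perm)
        assert np.allclose(f1.a_hat, f2.a_hat[::-1], atol=5e-3)
        assert np.allclose(f1.b_hat, f2.b_hat[::-1], atol=5e-3)

    def test_bias_shrinks_with_sample_size(self):
        bank = af.generate_item_bank(2, 4, seed=8)
        truth_a = bank.params_frame().a_true.to_numpy()
        truth_b = bank.params_frame().b_true.to_numpy()
        err = {}
        for n in (500, 2000):
            rmses = []
            for rep in range(3):
                data = af.simulate_responses(bank, n, seed=100 * n + rep)
                form = af.fit_2pl(data, item_ids=data.item_ids)
                rmses.append(np.sqrt(np.mean(
                    (form.a_hat - truth_a) ** 2 + (form.b_hat - truth_b) ** 2
                )))
            err[n] = np.mean(rmses)
        assert err[2000] < err[500]

    def test_too_few_items_rejected(self):
        with pytest.raises(ValueError):
            af.fit_2pl(np.array([[0], [1]]))


class TestEAP:
    def test_single_item_symmetry(self, grid):
        form = af.CalibratedForm(["i1"], [1.0], [0.0], -1.0, True, 10)
        scores, sds = af.eap_scores(form, np.array([[1], [0]]), grid)
        assert scores[0] == pytest.approx(-scores[1], abs=1e-10)
        assert scores[0] > 0
        assert np.all(sds > 0)

    def test_all_zero_on_hard_items_scores_below_zero(self, grid):
        form = af.CalibratedForm(["i1", "i2"], [1.0, 1.2], [1.0, 1.5], -1.0, True, 10)
        scores, _ = af.eap_scores(form, np.array([[0, 0]]), grid)
        assert scores[0] < 0

    def test_matches_dense_grid_oracle(self):
        """Brute-force posterior mean on the same 2001-node grid, written
        independently of the package's path."""
        g = dense_grid()
        form = af.CalibratedForm(["i1", "i2"], [1.3, 0.7], [-0.2, 0.6], -1.0, True, 10)
        X = np.array([[1, 0], [0, 0], [1, 1], [0, 1]])
        scores, sds = af.eap_scores(form, X, g)
        prior = norm.pdf(g.nodes)
        for r, x in enumerate(X):
            like = np.ones_like(g.nodes)
            for j, (a, b) in enumerate(zip(form.a_hat, form.b_hat)):
                p = expit(a * (g.nodes - b))
                like *= p if x[j] == 1 else (1 - p)
            post = like * prior
            post /= post.sum()
            mean = post @ g.nodes
            sd = np.sqrt(post @ g.nodes**2 - mean**2)
            assert scores[r] == pytest.approx(mean, abs=1e-6)
            assert sds[r] == pytest.approx(sd, abs=1e-6)

    def test_eap_is_shrunken_toward_prior_mean(self, grid):
        """|EAP| below the maximum-likelihood estimate for a mixed pattern."""
        form = af.CalibratedForm(["i1", "i2", "i3"], [1.0, 1.0, 1.0],
                                 [-1.0, 0.0, 1.0], -1.0, True, 10)
        X = np.array([[1, 1, 0]])
        scores, _ = af.eap_scores(form, X, grid)

        def negll(theta):
            p = expit(theta - form.b_hat)
            return -(np.log(p[0]) + np.log(p[1]) + np.log(1 - p[2]))

        ml = minimize(lambda t: negll(t[0]), [0.0]).x[0]
        assert abs(scores[0]) <= abs(ml) + 1e-9

    def test_column_mismatch_rejected(self, grid):
        form = af.CalibratedForm(["i1", "i2"], [1, 1], [0, 0], -1.0, True, 10)
        with pytest.raises(ValueError):
            af.eap_scores(form, np.zeros((3, 3), dtype=int), grid)


class TestEAPReliability:
    def test_definitional_arithmetic(self):
        scores = np.array([-0.5, 0.5])  # ddof=1 variance = 0.5
        sds = np.full(2, np.sqrt(0.5))
        assert af.eap_reliability(scores, sds) == pytest.approx(0.5)

    def test_zero_error_limit_is_one(self):
        scores = np.array([-1.0, 0.0, 1.0])
        for sd in (1e-3, 1e-6):
            rel = af.eap_reliability(scores, np.full(3, sd))
            assert rel > 1 - 2 * sd**2
        assert af.eap_reliability(scores, np.zeros(3)) <= 1.0

    def test_zero_variance_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            assert af.eap_reliability(np.zeros(5), np.ones(5)) == 0.0

    def test_longer_test_is_more_reliable(self, grid):
        bank = af.generate_item_bank(
            12, 3, a_dist={"dist": "fixed", "value": 1.3}, seed=2
        )
        data = af.simulate_responses(bank, 1000, seed=33)
        long_form = af.fit_2pl(data, grid, item_ids=data.item_ids)
        rel_long = af.eap_reliability(*af.eap_scores(long_form, data, grid))
        short_items = data.item_ids[:12]
        sub = data.subset(short_items)
        short_form = af.fit_2pl(sub, grid, item_ids=short_items)
        rel_short = af.eap_reliability(*af.eap_scores(short_form, sub, grid))
        assert rel_long > rel_short
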