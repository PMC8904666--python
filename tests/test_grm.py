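"""Graded response model primitives against closed forms and brute force."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from burnlink.errors import InvalidParameterError, NoInformationError
from burnlink.irt import (
    ItemParams,
    LatentDensity,
    QuadratureGrid,
    eap_theta,
    grm_category_probs,
    loglikelihood,
    summed_score_eap,
    summed_score_likelihoods,
    tcc,
    test_information as fisher_information,
)


@st.composite
def item_params(draw, max_cats=6):
    m = draw(st.integers(2, max_cats))
    a = draw(st.floats(0.2, 3.0))
    b1 = draw(st.floats(-3, 1))
    gaps = [draw(st.floats(0.1, 1.5)) for _ in range(m - 2)]
    b = b1 + np.concatenate([[0.0], np.cumsum(gaps)])
    return ItemParams("x", a, tuple(b))


class TestCategoryProbs:
    def test_single_threshold_symmetry(self):
        p = ItemParams("x", 1.0, (0.0,))
        assert grm_category_probs(p, 0.0) == pytest.approx([0.5, 0.5])

    def test_two_threshold_closed_form(self):
        # boundary logistics at a=2, b=(-1, 1), theta=0: expit(2) = 0.8808
        p = ItemParams("x", 2.0, (-1.0, 1.0))
        probs = grm_category_probs(p, 0.0)
        assert probs == pytest.approx([0.1192, 0.7616, 0.1192], abs=5e-5)

    def test_saturation_at_extreme_theta(self):
        p = ItemParams("x", 1.5, (-1.0, 0.0, 1.0))
        probs = grm_category_probs(p, 40.0)
        assert probs[-1] == pytest.approx(1.0)
        assert grm_category_probs(p, -40.0)[0] == pytest.approx(1.0)

    def test_unordered_thresholds_rejected(self):
        with pytest.raises(InvalidParameterError):
            ItemParams("x", 1.0, (1.0, -1.0))
        with pytest.raises(InvalidParameterError):
            ItemParams("x", -0.5, (0.0,))

    @given(item_params(), st.floats(-5, 5))
    def test_normalization_and_nonnegativity(self, p, theta):
        probs = grm_category_probs(p, theta)
        assert np.all(probs >= 0)
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)


class TestSummedScores:
    def test_single_item_base_case(self):
        p = ItemParams("x", 1.3, (-0.5, 0.4, 1.1))
        raw, probs = summed_score_likelihoods([p], 0.7, lowest_codes=1)
        assert list(raw) == [1, 2, 3, 4]
        assert probs == pytest.approx(grm_category_probs(p, 0.7))

    def test_matches_exhaustive_enumeration(self, toy_params):
        """Lord-Wingersky equals the brute-force sum over all 27 patterns."""
        plist = list(toy_params.values())
        theta = 0.3
        raw, probs = summed_score_likelihoods(plist, theta)
        tables = [grm_category_probs(p, theta) for p in plist]
        brute = np.zeros(len(raw))
        for pattern in itertools.product(range(3), repeat=3):
            brute[sum(pattern)] += np.prod([t[k] for t, k in zip(tables, pattern)])
        assert np.max(np.abs(probs - brute)) < 1e-12

    def test_conservation_at_every_node(self, toy_params):
        grid = QuadratureGrid.default()
        _, probs = summed_score_likelihoods(list(toy_params.values()), grid.nodes)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-12)


class TestSummedScoreEAP:
    def test_symmetric_scale_centers_at_zero(self):
        plist = [ItemParams("a", 1.4, (-1.0,)), ItemParams("b", 1.4, (1.0,))]
        table = summed_score_eap(plist, LatentDensity(), QuadratureGrid.default())
        assert table["theta"].iloc[1] == pytest.approx(0.0, abs=1e-9)

    def test_monotone_in_raw_score(self, study_fixture):
        grid = QuadratureGrid.default()
        for name, sc in study_fixture.scales.items():
            plist = [study_fixture.params[i] for i in sc.item_ids]
            table = summed_score_eap(plist, LatentDensity(), grid, sc.lowest_code)
            assert (np.diff(table["theta"]) > 0).all(), name

    def test_matches_monte_carlo_average(self, toy_scale, toy_params):
        """E[theta | raw] against direct simulation of a million respondents."""
        from burnlink.synthetic import simulate_responses

        rng = np.random.default_rng(11)
        theta = rng.standard_normal(1_000_000)
        mat = simulate_responses(theta, toy_scale, toy_params, seed=12)
        raws = mat.sum(axis=1).to_numpy()
        table = summed_score_eap(
            list(toy_params.values()), LatentDensity(), QuadratureGrid.default()
        )
        for s in range(7):
            mc = theta[raws == s].mean()
            assert table["theta"].iloc[s] == pytest.approx(mc, abs=0.02)


class TestTCC:
    def test_limits_and_symmetry(self, toy_params):
        plist = list(toy_params.values())
        assert tcc(plist, -40.0) == pytest.approx(0.0, abs=1e-8)
        assert tcc(plist, 40.0) == pytest.approx(6.0, abs=1e-8)
        single = [ItemParams("x", 1.0, (0.0,))]
        assert tcc(single, 0.0) == pytest.approx(0.5)

    def test_equals_summed_score_mean(self, toy_params):
        plist = list(toy_params.values())
        for theta in (-1.2, 0.0, 0.8):
            raw, probs = summed_score_likelihoods(plist, theta)
            assert tcc(plist, theta) == pytest.approx(raw @ probs, abs=1e-10)


class TestInformation:
    def test_uninformative_and_additive(self, toy_params):
        flat = [ItemParams("x", 1e-6, (0.0,))]
        assert fisher_information(flat, np.linspace(-3, 3, 7)).max() < 1e-9
        plist = list(toy_params.values())
        theta = np.array([-0.7, 0.4])
        doubled = plist + [ItemParams(p.item + "_c", p.a, p.b) for p in plist]
        assert fisher_information(doubled, theta) == pytest.approx(
            2 * fisher_information(plist, theta)
        )

    def test_matches_finite_difference_expected_hessian(self, toy_params):
        """I(theta) = -E[d2 log P / dtheta2], by central differences."""
        plist = list(toy_params.values())
        theta0, h = 0.45, 1e-4
        total = 0.0
        for p in plist:
            lp = np.log([grm_category_probs(p, t) for t in (theta0 - h, theta0, theta0 + h)])
            d2 = (lp[0] - 2 * lp[1] + lp[2]) / h**2
            total -= float(grm_category_probs(p, theta0) @ d2)
        info = float(fisher_information(plist, theta0))
        assert abs(info - total) / total < 1e-4


class TestPatternEAPAndLoglik:
    def test_symmetric_pattern_scores_zero(self):
        plist = [ItemParams("a", 1.4, (-1.0,)), ItemParams("b", 1.4, (1.0,))]
        theta, se = eap_theta([1, 0], plist, LatentDensity(), QuadratureGrid.default())
        assert theta == pytest.approx(0.0, abs=1e-6)
        assert se > 0

    def test_matches_dense_quadrature(self, toy_params):
        plist = list(toy_params.values())
        coarse = QuadratureGrid.default()
        dense = QuadratureGrid.dense()
        for pattern in ([0, 1, 2], [2, 2, 2], [1, -1, 0]):
            t1, _ = eap_theta(pattern, plist, LatentDensity(), coarse)
            t2, _ = eap_theta(pattern, plist, LatentDensity(), dense)
            assert t1 == pytest.approx(t2, abs=1e-4)

    def test_uninformative_items_return_prior(self):
        plist = [ItemParams("x", 1e-6, (0.0,))]
        density = LatentDensity(0.3, 0.9)
        theta, se = eap_theta([1], plist, density, QuadratureGrid.default())
        assert theta == pytest.approx(0.3, abs=1e-3)
        assert se == pytest.approx(0.9, abs=0.02)

    def test_all_missing_pattern_rejected(self, toy_params):
        with pytest.raises(NoInformationError):
            eap_theta([-1, -1, -1], list(toy_params.values()),
                      LatentDensity(), QuadratureGrid.default())

    def test_loglik_matches_direct_summation(self, toy_matrix, toy_scale, toy_params):
        grid = QuadratureGrid.default()
        density = LatentDensity()
        X = toy_scale.to_indices(toy_matrix.iloc[:25])
        plist = list(toy_params.values())
        ll = loglikelihood(X, plist, density, grid)
        w = density.weights(grid)
        brute = 0.0
        for row in X:
            like = np.ones(len(grid.nodes))
            for j, k in enumerate(row):
                if k >= 0:
                    like *= np.array(
                        [grm_category_probs(plist[j], t)[k] for t in grid.nodes]
                    )
            brute += np.log(like @ w)
        assert ll == pytest.approx(brute, abs=1e-8)

    def test_loglik_additivity_and_uninformative_item(self, toy_matrix, toy_scale, toy_params):
        grid = QuadratureGrid.default()
        density = LatentDensity()
        X = toy_scale.to_indices(toy_matrix.iloc[:40])
        plist = list(toy_params.values())
        ll = loglikelihood(X, plist, density, grid)
        assert loglikelihood(np.vstack([X, X]), plist, density, grid) == pytest.approx(
            2 * ll, rel=1e-12
        )
        flat = [ItemParams("x", 1e-6, (0.0,))]
        assert loglikelihood(np.array([[1]]), flat, density, grid) == pytest.approx(
            np.log(0.5), abs=1e-6
        )
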