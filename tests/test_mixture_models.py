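import numpy as np
import pytest
from scipy import integrate, optimize

from jsbseg import (
    CollapseError,
    DomainError,
    EMConfig,
    GaussianParams,
    GrayHistogram,
    JohnsonSBParams,
    MixtureModel,
    e_step,
    fit_em,
    fit_gmm,
    init_model,
    jsb_cdf,
    jsb_pdf,
    log_likelihood,
    logit_transform,
    m_step,
    mixture_pdf,
)
from jsbseg.mixture_models import FitResult
from jsbseg.phantom import make_mixture_histogram

from conftest import jsb_with_median


def random_model(rng, K=2, xi=-0.5, lam=256.0):
    w = rng.dirichlet(np.ones(K))
    comps = tuple(
        JohnsonSBParams(rng.uniform(-2, 2), rng.uniform(0.8, 4.0), xi, lam)
        for _ in range(K)
    )
    return MixtureModel("johnson_sb", w, comps)


class TestGrayHistogram:
    def test_rejects_negative_and_empty(self):
        with pytest.raises(ValueError):
            GrayHistogram(np.arange(3), np.array([1, -1, 0]))
        with pytest.raises(ValueError):
            GrayHistogram(np.arange(3), np.zeros(3))

    def test_restrict_keeps_total_within_range(self):
        h = GrayHistogram(np.arange(10), np.array([5, 0, 1, 2, 0, 0, 3, 0, 0, 4]))
        sub = h.restrict(2, 6)
        assert sub.total == 6
        assert sub.populated_range == (2, 6)


class TestMixturePdf:
    def test_single_component_equals_component_pdf(self):
        comp = JohnsonSBParams(1.0, 2.0, -0.5, 256.0)
        model = MixtureModel("johnson_sb", [1.0], (comp,))
        x = np.linspace(5, 250, 50)
        np.testing.assert_allclose(mixture_pdf(x, model), jsb_pdf(x, comp), rtol=1e-12)

    def test_identical_components_collapse_by_convexity(self):
        comp = JohnsonSBParams(0.5, 1.5, -0.5, 256.0)
        model = MixtureModel("johnson_sb", [0.3, 0.7], (comp, comp))
        x = np.linspace(1, 254, 40)
        np.testing.assert_allclose(mixture_pdf(x, model), jsb_pdf(x, comp), rtol=1e-12)

    def test_integrates_to_one(self):
        model = random_model(np.random.default_rng(0), K=3)
        total, _ = integrate.quad(
            lambda x: mixture_pdf(x, model), -0.5, 255.5, limit=300
        )
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_weights_must_sum_to_one(self):
        comp = JohnsonSBParams(0.0, 1.0, 0.0, 255.0)
        with pytest.raises(ValueError):
            MixtureModel("johnson_sb", [0.6, 0.6], (comp, comp))

    def test_shared_support_enforced(self):
        a = JohnsonSBParams(0.0, 1.0, 0.0, 255.0)
        b = JohnsonSBParams(0.0, 1.0, 0.0, 200.0)
        with pytest.raises(ValueError):
            MixtureModel("johnson_sb", [0.5, 0.5], (a, b))


class TestLogLikelihood:
    def test_single_level_single_component(self):
        comp = JohnsonSBParams(1.0, 2.0, -0.5, 256.0)
        model = MixtureModel("johnson_sb", [1.0], (comp,))
        levels = np.array([100])
        h = GrayHistogram(levels, np.array([1]))
        assert log_likelihood(h, model) == pytest.approx(np.log(jsb_pdf(100.0, comp)))

    def test_linear_in_counts(self):
        model = random_model(np.random.default_rng(1))
        h1 = GrayHistogram(np.arange(50, 60), np.arange(1, 11))
        h2 = GrayHistogram(np.arange(50, 60), 2 * np.arange(1, 11))
        assert log_likelihood(h2, model) == pytest.approx(2 * log_likelihood(h1, model))

    def test_matches_per_pixel_computation(self):
        # 4-pixel image, brute-force sum of per-pixel log densities
        model = random_model(np.random.default_rng(2))
        pixels = np.array([12, 12, 40, 200])
        brute = sum(np.log(mixture_pdf(float(p), model)) for p in pixels)
        levels, counts = np.unique(pixels, return_counts=True)
        assert log_likelihood(GrayHistogram(levels, counts), model) == pytest.approx(brute)

    def test_populated_level_outside_support_raises(self):
        comp = JohnsonSBParams(0.0, 1.0, 10.0, 50.0)
        model = MixtureModel("johnson_sb", [1.0], (comp,))
        h = GrayHistogram(np.array([5]), np.array([3]))
        with pytest.raises(DomainError):
            log_likelihood(h, model)


class TestEStep:
    def test_single_component_all_ones(self):
        model = MixtureModel(
            "johnson_sb", [1.0], (JohnsonSBParams(0.0, 1.0, -0.5, 256.0),)
        )
        h = GrayHistogram(np.arange(100, 110), np.ones(10, dtype=int))
        np.testing.assert_allclose(e_step(h, model), 1.0)

    def test_identical_components_split_evenly(self):
        comp = JohnsonSBParams(0.0, 1.0, -0.5, 256.0)
        model = MixtureModel("johnson_sb", [0.5, 0.5], (comp, comp))
        h = GrayHistogram(np.arange(100, 110), np.ones(10, dtype=int))
        np.testing.assert_allclose(e_step(h, model), 0.5)

    def test_populated_rows_sum_to_one(self):
        rng = np.random.default_rng(3)
        model = random_model(rng, K=4)
        counts = rng.integers(0, 5, size=200)
        counts[0] = 1  # ensure non-degenerate
        h = GrayHistogram(np.arange(20, 220), counts)
        resp = e_step(h, model)
        pop = h.counts > 0
        np.testing.assert_allclose(resp[pop].sum(axis=1), 1.0, atol=1e-12)
        assert np.all(resp[~pop] == 0)
        assert resp.min() >= 0 and resp.max() <= 1


class TestMStep:
    def test_unit_transform_statistics_give_canonical_shape(self):
        # responsibilities concentrating f-mean 0 and f-variance 1 must give
        # delta = 1, gamma = 0
        support = (-0.5, 255.5)
        ref = JohnsonSBParams(0.0, 1.0, -0.5, 256.0)
        f_targets = np.array([-1.0, 0.0, 1.0])
        levels = np.rint(
            -0.5 + 256.0 / (1 + np.exp(-f_targets))
        ).astype(int)
        f = logit_transform(levels.astype(float), ref)
        # two-point symmetric weighting with matched mean/var via count choice
        h = GrayHistogram(levels, np.array([1, 0, 1]))
        h = GrayHistogram(h.levels[h.counts > 0], h.counts[h.counts > 0])
        resp = np.ones((2, 1))
        model = m_step(h, resp, support=support)
        fs = logit_transform(h.levels.astype(float), ref)
        mu, var = fs.mean(), fs.var()
        assert model.components[0].delta == pytest.approx(1 / np.sqrt(var))
        assert model.components[0].gamma == pytest.approx(-mu / np.sqrt(var))

    def test_weighted_closed_form(self):
        rng = np.random.default_rng(4)
        levels = np.arange(30, 80)
        counts = rng.integers(1, 50, size=levels.size)
        h = GrayHistogram(levels, counts)
        resp = rng.dirichlet(np.ones(3), size=levels.size)
        support = (-0.5, 255.5)
        model = m_step(h, resp, support=support)
        ref = JohnsonSBParams(0.0, 1.0, -0.5, 256.0)
        f = logit_transform(levels.astype(float), ref)
        for k in range(3):
            w = counts * resp[:, k]
            mu = np.average(f, weights=w)
            var = np.average((f - mu) ** 2, weights=w)
            assert model.components[k].delta == pytest.approx(1 / np.sqrt(var))
            assert model.components[k].gamma == pytest.approx(-mu / np.sqrt(var))
        assert model.weights.sum() == pytest.approx(1.0, abs=1e-12)

    def test_closed_form_matches_numerical_maximizer(self):
        # the closed-form (gamma, delta) update must agree with direct
        # numerical maximization of the weighted component log-likelihood
        rng = np.random.default_rng(5)
        support = (-0.5, 255.5)
        ref = JohnsonSBParams(0.0, 1.0, -0.5, 256.0)
        for _ in range(20):
            n_levels = rng.integers(5, 30)
            levels = np.sort(rng.choice(np.arange(1, 255), size=n_levels, replace=False))
            counts = rng.integers(1, 30, size=n_levels)
            h = GrayHistogram(levels, counts)
            resp = rng.dirichlet(np.ones(2), size=n_levels)
            model = m_step(h, resp, support=support)
            f = logit_transform(levels.astype(float), ref)
            for k in range(2):
                w = counts * resp[:, k]

                def neg_ll(params, w=w):
                    gamma, delta = params
                    if delta <= 0:
                        return np.inf
                    return -np.sum(w * (np.log(delta) - 0.5 * (gamma + delta * f) ** 2))

                res = optimize.minimize(
                    neg_ll, x0=[0.0, 1.0], method="Nelder-Mead",
                    options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000},
                )
                assert model.components[k].gamma == pytest.approx(res.x[0], abs=1e-4)
                assert model.components[k].delta == pytest.approx(res.x[1], abs=1e-4)

    def test_collapse_raises_naming_component(self):
        h = GrayHistogram(np.array([100, 101, 150]), np.array([5, 5, 7]))
        resp = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        with pytest.raises(CollapseError) as err:
            m_step(h, resp, support=(-0.5, 255.5))
        assert err.value.component == 1


class TestInitModel:
    def test_even_spacing_and_equal_weights(self):
        h = GrayHistogram(np.arange(256), np.ones(256, dtype=int))
        model = init_model(h, EMConfig(K=2, init_delta=2.0))
        np.testing.assert_allclose(model.weights, 0.5)
        # medians at the 1/3 and 2/3 points of the populated range [0, 255]
        np.testing.assert_allclose(model.medians(), [85.0, 170.0], atol=1e-9)

    def test_component_medians_sit_at_centers(self):
        h = GrayHistogram(np.arange(50, 151), np.ones(101, dtype=int))
        model = init_model(h, EMConfig(K=5))
        for comp, med in zip(model.components, model.medians()):
            assert jsb_cdf(med, comp) == pytest.approx(0.5, abs=1e-12)

    def test_too_few_levels_rejected(self):
        h = GrayHistogram(np.array([5, 9, 200]), np.array([1, 2, 3]))
        with pytest.raises(ValueError):
            init_model(h, EMConfig(K=4))


class TestFitEM:
    def test_single_component_parameter_recovery(self):
        truth = JohnsonSBParams(1.0, 2.0, -0.5, 256.0)
        hist = make_mixture_histogram(
            MixtureModel("johnson_sb", [1.0], (truth,)), 50000, seed=3
        )
        fit = fit_em(hist, EMConfig(K=1), support=(-0.5, 255.5))
        c = fit.model.components[0]
        assert c.gamma == pytest.approx(truth.gamma, rel=0.05)
        assert c.delta == pytest.approx(truth.delta, rel=0.05)

    def test_three_component_recovery(self):
        comps = (
            jsb_with_median(80, 5.0),
            jsb_with_median(140, 6.0),
            jsb_with_median(200, 5.0),
        )
        truth = MixtureModel("johnson_sb", [0.3, 0.45, 0.25], comps)
        hist = make_mixture_histogram(truth, 100000, seed=5)
        fit = fit_em(hist, EMConfig(K=3), support=(-0.5, 255.5))
        order = np.argsort(fit.model.medians())
        np.testing.assert_allclose(
            fit.model.weights[order], truth.weights, atol=0.02
        )
        np.testing.assert_allclose(
            fit.model.medians()[order], truth.medians(), atol=2.0
        )
        for i, k in enumerate(order):
            assert fit.model.components[k].delta == pytest.approx(
                comps[i].delta, rel=0.10
            )

    def test_loglik_trace_monotone_and_weights_conserved(self):
        comps = (jsb_with_median(90, 4.0), jsb_with_median(180, 4.0))
        hist = make_mixture_histogram(
            MixtureModel("johnson_sb", [0.4, 0.6], comps), 20000, seed=9
        )
        fit = fit_em(hist, EMConfig(K=4))
        diffs = np.diff(fit.loglik_trace)
        assert np.all(diffs >= -1e-8 * np.abs(fit.loglik_trace[:-1]))
        assert fit.loglik_trace[-1] >= fit.loglik_trace[0]
        assert fit.model.weights.sum() == pytest.approx(1.0, abs=1e-10)
        assert fit.converged

    def test_deterministic(self):
        comps = (jsb_with_median(90, 4.0), jsb_with_median(180, 4.0))
        hist = make_mixture_histogram(
            MixtureModel("johnson_sb", [0.4, 0.6], comps), 10000, seed=2
        )
        a = fit_em(hist, EMConfig(K=3))
        b = fit_em(hist, EMConfig(K=3))
        np.testing.assert_array_equal(a.loglik_trace, b.loglik_trace)
        np.testing.assert_array_equal(a.model.weights, b.model.weights)

    def test_serialization_round_trip(self, tmp_path):
        comps = (jsb_with_median(90, 4.0), jsb_with_median(180, 4.0))
        hist = make_mixture_histogram(
            MixtureModel("johnson_sb", [0.4, 0.6], comps), 5000, seed=2
        )
        fit = fit_em(hist, EMConfig(K=2))
        path = tmp_path / "fit.json"
        fit.to_json(path)
        loaded = FitResult.from_json(path)
        np.testing.assert_allclose(loaded.model.weights, fit.model.weights)
        assert loaded.model.components == fit.model.components
        assert loaded.converged == fit.converged


class TestFitGMM:
    def test_single_gaussian_recovery(self):
        truth = MixtureModel("gaussian", [1.0], (GaussianParams(120.0, 144.0),))
        hist = make_mixture_histogram(truth, 50000, seed=7)
        fit = fit_gmm(hist, EMConfig(K=1))
        c = fit.model.components[0]
        assert c.mean == pytest.approx(120.0, abs=0.5)
        assert c.var == pytest.approx(144.0, rel=0.05)

    def test_symmetric_two_component_recovery(self):
        truth = MixtureModel(
            "gaussian", [0.5, 0.5], (GaussianParams(100.0, 100.0), GaussianParams(160.0, 100.0))
        )
        hist = make_mixture_histogram(truth, 100000, seed=8)
        fit = fit_gmm(hist, EMConfig(K=2))
        means = np.sort([c.mean for c in fit.model.components])
        data_mean = np.average(hist.levels, weights=hist.counts)
        np.testing.assert_allclose(means, [100.0, 160.0], atol=1.0)
        assert (means[0] + means[1]) / 2 == pytest.approx(data_mean, abs=1.0)

    def test_monotone_loglik(self):
        truth = MixtureModel(
            "gaussian", [0.3, 0.7], (GaussianParams(80.0, 64.0), GaussianParams(170.0, 225.0))
        )
        hist = make_mixture_histogram(truth, 30000, seed=4)
        fit = fit_gmm(hist, EMConfig(K=3))
        diffs = np.diff(fit.loglik_trace)
        assert np.all(diffs >= -1e-8 * np.abs(fit.loglik_trace[:-1]))
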