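"""Tests for model composition, normalisation and the named model zoo."""

import numpy as np
import pytest

from cepel.kde1d import ValidationError
from cepel.models import (CepelModel, ModelStateError, SupportBox,
                          build_named_model, evaluate, integrate_probability,
                          normalize, raw_integral)


@pytest.fixture(scope="module")
def gauss2d():
    return np.random.default_rng(3).standard_normal((400, 2))


class TestSupportBox:
    def test_from_data_pads(self):
        box = SupportBox.from_data(np.array([[0.0, 0.0], [1.0, 2.0]]))
        assert np.allclose(box.bounds[:, 0], [-0.05, -0.1])
        assert np.allclose(box.bounds[:, 1], [1.05, 2.1])
        assert box.volume == pytest.approx(1.1 * 2.2)

    def test_invalid_bounds(self):
        with pytest.raises(ValidationError):
            SupportBox(np.array([[1.0, 1.0]]))
        with pytest.raises(ValidationError):
            SupportBox(np.array([[0.0, np.inf]]))


class TestEvaluate:
    def test_mean_of_identical_components_is_identity(self, gauss2d):
        single = build_named_model("radial", gauss2d, center=[0.0, 0.0])
        tripled = CepelModel(components=single.components * 3, combiner="mean",
                             dimensionality=2, support=single.support)
        pts = np.random.default_rng(0).standard_normal((50, 2))
        assert np.allclose(evaluate(tripled, pts), evaluate(single, pts),
                           rtol=1e-12)

    def test_product_single_component_is_back_projection(self, gauss2d):
        model = build_named_model("single_axis", gauss2d)
        comp = model.components[0]
        pts = np.random.default_rng(1).standard_normal((50, 2))
        assert np.allclose(evaluate(model, pts),
                           comp.value(comp.projection(pts), 2), rtol=1e-12)

    def test_product_of_marginals_matches_analytic_gaussian(self):
        r = np.random.default_rng(8)
        train = r.standard_normal((600, 2))
        test = r.standard_normal((300, 2))
        model = build_named_model("naive_bayes", train)
        got = np.mean(np.log(evaluate(model, test)))
        expected = np.mean(-0.5 * np.sum(test ** 2, axis=1) - np.log(2 * np.pi))
        assert got == pytest.approx(expected, rel=0.02)

    def test_nonnegative_all_combiners(self, gauss2d):
        base = build_named_model("naive_bayes", gauss2d)
        pts = np.random.default_rng(2).uniform(-4, 4, (200, 2))
        for combiner in ("product", "mean", "max"):
            m = CepelModel(components=base.components, combiner=combiner,
                           dimensionality=2, support=base.support)
            assert np.all(evaluate(m, pts) >= 0)

    def test_mean_combiner_bounds(self, gauss2d):
        base = build_named_model("naive_bayes", gauss2d)
        m = CepelModel(components=base.components, combiner="mean",
                       dimensionality=2, support=base.support)
        pts = np.random.default_rng(2).uniform(-3, 3, (100, 2))
        per = np.stack([c.value(c.projection(pts), 2) for c in base.components])
        k = len(base.components)
        vals = evaluate(m, pts)
        assert np.all(per.min(axis=0) - 1e-12 <= k * vals)
        assert np.all(k * vals <= k * per.max(axis=0) + 1e-12)

    def test_dimension_mismatch(self, gauss2d):
        model = build_named_model("naive_bayes", gauss2d)
        with pytest.raises(ValidationError):
            evaluate(model, np.zeros((5, 3)))


class TestNormalize:
    def test_single_axis_1d_already_normalized(self):
        data = np.random.default_rng(4).standard_normal((500, 1))
        box = SupportBox(np.array([[-8.0, 8.0]]))
        model = build_named_model("naive_bayes", data, support=box,
                                  normalized=True)
        assert 0.99 < model.normalization_constant < 1.01

    def test_radial_2d_against_monte_carlo(self, gauss2d):
        box = SupportBox.from_data(gauss2d)
        model = build_named_model("radial", gauss2d, support=box,
                                  normalized=True)
        r = np.random.default_rng(99)
        mc = r.uniform(box.bounds[:, 0], box.bounds[:, 1], size=(1_000_000, 2))
        vals = evaluate(model, mc)
        integral = box.volume * vals.mean()
        # the MC oracle carries its own sampling error; allow 3 standard errors
        se = box.volume * vals.std() / np.sqrt(vals.size)
        assert integral == pytest.approx(1.0, abs=1e-3 + 3 * se)

    def test_compact_support_constant_stable_under_doubling(self):
        data = np.random.default_rng(5).uniform(0.4, 0.6, (300, 2))
        box1 = SupportBox(np.array([[0.0, 1.0], [0.0, 1.0]]))
        m1 = build_named_model("naive_bayes", data, support=box1, normalized=True)
        m2 = normalize(m1, box1.expand(2.0))
        assert m2.normalization_constant == pytest.approx(
            m1.normalization_constant, rel=1e-3)

    def test_idempotent(self, gauss2d):
        box = SupportBox.from_data(gauss2d)
        m1 = build_named_model("naive_bayes", gauss2d, support=box,
                               normalized=True)
        m2 = normalize(m1, box)
        assert m2.normalization_constant == pytest.approx(
            m1.normalization_constant, rel=1e-3)

    def test_degenerate_integral_raises(self, gauss2d):
        model = build_named_model("naive_bayes", gauss2d)
        far = SupportBox(np.array([[500.0, 501.0], [500.0, 501.0]]))
        with pytest.raises(ModelStateError):
            normalize(model, far)


class TestIntegrateProbability:
    def test_full_support_and_monotonicity(self, gauss2d):
        box = SupportBox.from_data(gauss2d)
        model = build_named_model("naive_bayes", gauss2d, support=box,
                                  normalized=True)
        assert integrate_probability(model, box) == pytest.approx(1.0, abs=1e-3)
        half = SupportBox(np.column_stack([box.bounds[:, 0],
                                           box.bounds.mean(axis=1)]))
        p_half = integrate_probability(model, half)
        assert 0.0 <= p_half <= integrate_probability(model, box) + 1e-3

    def test_far_box_is_empty(self, gauss2d):
        box = SupportBox.from_data(gauss2d)
        model = build_named_model("naive_bayes", gauss2d, support=box,
                                  normalized=True)
        far = SupportBox(np.array([[50.0, 51.0], [50.0, 51.0]]))
        assert integrate_probability(model, far) < 1e-9

    def test_half_space_of_symmetric_model(self):
        r = np.random.default_rng(6)
        data = r.standard_normal((2000, 1))
        data = np.vstack([data, -data])  # exactly symmetric sample
        box = SupportBox(np.array([[-8.0, 8.0]]))
        model = build_named_model("naive_bayes", data, support=box,
                                  normalized=True)
        left = SupportBox(np.array([[-8.0, 0.0]]))
        assert integrate_probability(model, left) == pytest.approx(0.5, abs=0.01)

    def test_requires_normalization(self, gauss2d):
        model = build_named_model("naive_bayes", gauss2d)
        with pytest.raises(ModelStateError):
            integrate_probability(model, model.support)


class TestNamedModels:
    def test_naive_bayes_1d_equals_single_axis(self):
        data = np.random.default_rng(7).standard_normal((200, 1))
        nb = build_named_model("naive_bayes", data)
        sa = build_named_model("single_axis", data, direction=[1.0])
        pts = np.linspace(-3, 3, 50)[:, None]
        assert np.allclose(evaluate(nb, pts), evaluate(sa, pts), rtol=1e-10)

    def test_radial_density_peaks_at_cluster(self):
        r = np.random.default_rng(9)
        sigma = 0.5
        data = r.normal(0.0, sigma, (400, 2))
        model = build_named_model("radial", data)
        at_center = evaluate(model, np.zeros((1, 2)))[0]
        ring = np.array([[5 * sigma, 0.0], [0.0, 5 * sigma],
                         [-5 * sigma, 0.0], [3.5 * sigma, 3.5 * sigma]])
        assert np.all(at_center > evaluate(model, ring))

    def test_unknown_name(self, gauss2d):
        with pytest.raises(ValidationError):
            build_named_model("mystery", gauss2d)

    def test_naive_bayes_independent_matches_per_axis_product(self):
        """On independent coordinates the model's LOO score is close to the
        sum of the per-axis 1d LOO scores."""
        from cepel.kde1d import Sample1D, fit_kde1d
        r = np.random.default_rng(10)
        data = r.standard_normal((400, 2))
        box = SupportBox(np.array([[-8.0, 8.0], [-8.0, 8.0]]))
        model = build_named_model("naive_bayes", data, support=box,
                                  normalized=True)
        from cepel.selection import score_model_loo
        joint = 2.0 * score_model_loo(model, data)  # undo the /d normalisation
        per_axis = sum(fit_kde1d(Sample1D(data[:, i])).loo_log_likelihood
                       for i in range(2))
        assert joint == pytest.approx(per_axis, rel=0.03)
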