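"""Unit and property tests for the adaptive 1-d kernel density estimator."""

import numpy as np
import pytest
from scipy.stats import norm

from cepel.kde1d import (DegenerateSampleError, DiscretePMF, KDEConfig,
                         Sample1D, ValidationError, bandwidth_grid,
                         find_modes, fit_discrete, fit_kde1d,
                         loo_log_likelihood)


def naive_loo(values, h):
    """O(N^2) double-loop oracle for the LOO log-likelihood."""
    n = len(values)
    total = 0.0
    for i in range(n):
        dens = 0.0
        for j in range(n):
            if j != i:
                dens += norm.pdf(values[i], loc=values[j], scale=h)
        total += np.log(dens / (n - 1))
    return total / n


class TestLOOLikelihood:
    def test_two_point_closed_form(self):
        # both LOO terms equal the kernel value at distance 1
        got = loo_log_likelihood(Sample1D(np.array([0.0, 1.0])), 1.0)
        assert got == pytest.approx(np.log(norm.pdf(1.0)), abs=1e-12)

    @pytest.mark.parametrize("h", [0.3, 1.0, 2.5])
    def test_identical_points(self, h):
        got = loo_log_likelihood(Sample1D(np.zeros(3)), h)
        assert got == pytest.approx(np.log(norm.pdf(0.0, scale=h)), abs=1e-12)

    def test_matches_double_loop_oracle(self, rng):
        x = rng.uniform(0.0, 1.0, 50)
        for h in (0.05, 0.2, 1.0):
            assert loo_log_likelihood(Sample1D(x), h) == pytest.approx(
                naive_loo(x, h), abs=1e-12)

    def test_rejects_bad_bandwidth(self):
        with pytest.raises(ValidationError):
            loo_log_likelihood(Sample1D(np.array([0.0, 1.0])), 0.0)
        with pytest.raises(ValidationError):
            loo_log_likelihood(Sample1D(np.array([0.0, 1.0])), -1.0)


class TestFit:
    @pytest.mark.parametrize("data", [
        np.random.default_rng(0).standard_normal(200),
        np.random.default_rng(1).lognormal(size=150),
        np.random.default_rng(2).uniform(0, 1, 120),
    ], ids=["normal", "lognormal", "uniform"])
    def test_normalization(self, data):
        dens = fit_kde1d(Sample1D(data))
        hmax = dens.local_bandwidths.max()
        lo = data.min() - 10 * hmax
        hi = data.max() + 10 * hmax
        grid = np.linspace(lo, hi, 20001)
        assert np.trapezoid(dens(grid), grid) == pytest.approx(1.0, abs=1e-6)
        assert dens.integrate(lo, hi) == pytest.approx(1.0, abs=1e-6)

    def test_bandwidth_near_brute_force_optimum(self, rng):
        x = rng.standard_normal(200)
        sample = Sample1D(x)
        dens = fit_kde1d(sample)
        fine = np.geomspace(bandwidth_grid(sample)[0], bandwidth_grid(sample)[-1],
                            10 * KDEConfig().bandwidth_grid_size)
        scores = [loo_log_likelihood(sample, h) for h in fine]
        h_star = fine[int(np.argmax(scores))]
        ratio = dens.global_bandwidth / h_star
        assert 1 / 1.05 < ratio < 1.05

    def test_evaluator_nonnegative_and_vectorised(self, rng):
        dens = fit_kde1d(Sample1D(rng.standard_normal(80)))
        x = np.linspace(-5, 5, 101)
        assert np.all(dens(x) >= 0)
        assert dens(0.0) == pytest.approx(dens(np.array([0.0]))[0])

    def test_degenerate_sample_raises(self):
        with pytest.raises(DegenerateSampleError):
            fit_kde1d(Sample1D(np.full(10, 3.0)))
        with pytest.raises(DegenerateSampleError):
            fit_kde1d(Sample1D(np.array([1.0])))

    def test_nonfinite_rejected(self):
        with pytest.raises(ValidationError):
            Sample1D(np.array([0.0, np.nan]))
        with pytest.raises(ValidationError):
            Sample1D(np.array([0.0, np.inf]))

    def test_loo_argmax_mostly_unique(self):
        """On unimodal Gaussian samples the bandwidth-grid argmax is unique in
        at least 95% of replicates."""
        unique = 0
        reps = 100
        for seed in range(reps):
            x = np.random.default_rng(seed).standard_normal(80)
            sample = Sample1D(x)
            grid = bandwidth_grid(sample)
            scores = np.array([loo_log_likelihood(sample, h) for h in grid])
            unique += int((scores == scores.max()).sum() == 1)
        assert unique >= 0.95 * reps


class TestModes:
    def test_unimodal_normal(self, rng):
        dens = fit_kde1d(Sample1D(rng.standard_normal(300)))
        modes = find_modes(dens)
        assert len(modes) == 1
        assert abs(modes[0]) < 0.3

    def test_three_cluster_axis_projection(self, three_cluster_2d):
        pts, _ = three_cluster_2d
        for axis in range(2):
            dens = fit_kde1d(Sample1D(pts[:, axis]))
            assert len(find_modes(dens)) == 3

    def test_grid_refinement_stability(self, rng):
        from dataclasses import replace
        x = np.concatenate([rng.standard_normal(150) - 4,
                            rng.standard_normal(150) + 4])
        dens = fit_kde1d(Sample1D(x))
        coarse = np.array(find_modes(dens))
        spacing = (dens.support[1] - dens.support[0]) / dens.config.eval_grid_size
        dens4 = replace(dens, config=replace(dens.config,
                                             eval_grid_size=4 * dens.config.eval_grid_size))
        fine = np.array(find_modes(dens4))
        assert len(fine) == len(coarse)
        assert np.all(np.abs(fine - coarse) < spacing)

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_mode_count_on_separated_clusters(self, k):
        """k well-separated Gaussian clusters give k modes in >= 95% of
        seeded replicates."""
        hits = 0
        reps = 100
        for seed in range(reps):
            r = np.random.default_rng(1000 + seed)
            parts = [r.normal(8.0 * c, 1.0, 60) for c in range(k)]
            dens = fit_kde1d(Sample1D(np.concatenate(parts)))
            hits += int(len(find_modes(dens)) == k)
        assert hits >= 0.95 * reps

    def test_affine_rescale_shifts_modes(self, rng):
        x = np.concatenate([rng.standard_normal(120) - 3,
                            rng.standard_normal(120) + 3])
        s = 7.5
        m1 = np.array(find_modes(fit_kde1d(Sample1D(x))))
        d2 = fit_kde1d(Sample1D(s * x))
        m2 = np.array(find_modes(d2))
        cell = (d2.support[1] - d2.support[0]) / d2.config.eval_grid_size
        assert len(m1) == len(m2)
        assert np.all(np.abs(m2 - s * m1) < cell)


class TestDiscrete:
    def test_relative_frequencies(self):
        pmf = fit_discrete(["a", "a", "b", "b"])
        assert pmf.as_dict() == {"a": 0.5, "b": 0.5}
        assert fit_discrete(["a"]).as_dict() == {"a": 1.0}

    def test_sampling_accuracy(self, rng):
        draws = rng.choice(["a", "b"], size=1000, p=[0.7, 0.3])
        pmf = fit_discrete(draws.tolist())
        assert pmf.prob("a") == pytest.approx(0.7, abs=0.05)
        assert pmf.prob("b") == pytest.approx(0.3, abs=0.05)
        assert isinstance(pmf, DiscretePMF)

    def test_empty_raises(self):
        with pytest.raises(ValidationError):
            fit_discrete([])
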