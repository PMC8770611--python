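import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from traitenv.evaluation import (
    UndefinedMetricError,
    aggregate_fits,
    auprc,
    auprc_prevalence_ratio,
    auroc,
    metric_report,
    morans_i,
    plot_residuals,
    spatial_weights,
)


class TestAuroc:
    def test_perfect_and_reversed(self):
        y = np.array([0, 0, 1, 1])
        assert auroc(y, np.array([0.1, 0.2, 0.8, 0.9])) == 1.0
        assert auroc(y, np.array([0.9, 0.8, 0.2, 0.1])) == 0.0

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 10_000)
        assert auroc(y, rng.random(10_000)) == pytest.approx(0.5, abs=0.02)

    def test_single_class_undefined(self):
        with pytest.raises(UndefinedMetricError):
            auroc(np.ones(5), np.random.default_rng(0).random(5))

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=30, deadline=None)
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, 50)
        if y.min() == y.max():
            return
        s = rng.normal(size=50)
        base = auroc(y, s)
        assert auroc(y, np.exp(s)) == pytest.approx(base, abs=1e-12)
        assert auroc(y, 3.0 * s - 7.0) == pytest.approx(base, abs=1e-12)


class TestAuprc:
    def test_perfect_classifier(self):
        y = np.array([0, 0, 0, 1])
        assert auprc(y, np.array([0.1, 0.2, 0.3, 0.9])) == 1.0

    def test_all_tied_scores_equal_prevalence(self):
        # enumeration over small label vectors: a single threshold yields
        # recall jumping 0 -> 1 at precision = prevalence
        for y in ([0, 1], [0, 0, 1], [1, 1, 0, 1], [0, 1, 0, 1, 1]):
            y = np.array(y)
            assert auprc(y, np.full(y.size, 0.5)) == pytest.approx(y.mean(), abs=1e-12)

    def test_random_scores_approach_prevalence(self):
        rng = np.random.default_rng(1)
        y = (rng.random(10_000) < 0.15).astype(int)
        assert auprc(y, rng.random(10_000)) == pytest.approx(y.mean(), abs=0.02)

    def test_no_positives_undefined(self):
        with pytest.raises(UndefinedMetricError):
            auprc(np.zeros(10), np.random.default_rng(0).random(10))


class TestAuprcPrevalenceRatio:
    def test_random_scores_near_one(self):
        rng = np.random.default_rng(2)
        y = (rng.random(10_000) < 0.2).astype(int)
        assert auprc_prevalence_ratio(y, rng.random(10_000)) == pytest.approx(1.0, abs=0.1)

    def test_perfect_classifier_at_quarter_prevalence(self):
        y = np.array([1, 0, 0, 0] * 5)
        scores = np.where(y == 1, 1.0, 0.0)
        assert auprc_prevalence_ratio(y, scores) == pytest.approx(4.0)


class TestMetricReport:
    def test_report_shape_and_ranges(self):
        rng = np.random.default_rng(3)
        Y = (rng.random((60, 5)) < 0.3).astype(float)
        P = np.clip(0.3 + 0.4 * (Y - 0.3) + rng.normal(0, 0.1, Y.shape), 0.01, 0.99)
        rep = metric_report(Y, P, species_ids=[f"s{j}" for j in range(5)])
        assert 0.0 <= rep.pooled_auroc <= 1.0
        assert (rep.per_species["auroc"].between(0, 1)).all()
        assert (rep.per_species["auprc_prevalence"] >= 0).all()
        assert rep.ratio_min <= rep.ratio_mean <= rep.ratio_max


class TestMoransI:
    def test_null_mean_matches_expectation(self):
        """i.i.d. residuals: average I over simulations is about -1/(N-1)."""
        rng = np.random.default_rng(4)
        N = 150
        coords = rng.uniform(0, 1000, (N, 2))
        values = [
            morans_i(rng.normal(size=N), coords, n_permutations=9, seed=0).I
            for _ in range(300)
        ]
        assert np.mean(values) == pytest.approx(-1.0 / (N - 1), abs=0.01)

    def test_smooth_gradient_is_detected(self):
        rng = np.random.default_rng(5)
        N = 100
        coords = rng.uniform(0, 100, (N, 2))
        gradient = coords[:, 0] / 100.0 + 0.05 * rng.normal(size=N)
        res = morans_i(gradient, coords, seed=1)
        assert res.I > res.expected_I
        assert res.p_value < 0.05

    def test_two_plots_error(self):
        with pytest.raises(ValueError):
            morans_i(np.array([1.0, 2.0]), np.array([[0, 0], [1, 1]]))

    def test_constant_residuals_undefined(self):
        with pytest.raises(ValueError):
            morans_i(np.ones(5), np.random.default_rng(0).uniform(0, 1, (5, 2)))

    def test_weights_row_standardized_zero_diagonal(self):
        coords = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 2.0], [3.0, 3.0]])
        for kind in ("inverse_distance", "knn"):
            W = spatial_weights(coords, kind=kind, k=2)
            assert np.allclose(W.sum(axis=1), 1.0)
            assert np.all(np.diag(W) == 0.0)

    def test_permutation_p_uniform_under_null(self):
        """KS test over simulated null datasets at alpha = 0.01."""
        from scipy import stats

        rng = np.random.default_rng(6)
        N = 40
        pvals = []
        for k in range(400):
            coords = rng.uniform(0, 100, (N, 2))
            res = morans_i(rng.normal(size=N), coords, n_permutations=199, seed=k)
            pvals.append(res.p_value)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestPlotResiduals:
    def test_mean_pearson_residual_shape_and_sign(self):
        Y = np.array([[1.0, 0.0], [0.0, 0.0]])
        P = np.full((2, 2), 0.5)
        r = plot_residuals(Y, P)
        assert r.shape == (2,)
        assert r[0] == pytest.approx(0.0)
        assert r[1] == pytest.approx(-1.0)


class TestAggregateFits:
    def test_identical_fits_collapse(self, tiny_data, intercept_structure):
        from traitenv.glmm import fit_map

        fit = fit_map(tiny_data, structure=intercept_structure)
        table = aggregate_fits([fit] * 10)
        assert len(table) == 16
        assert np.allclose(table["mean"], fit.fixed.pack())
        assert np.allclose(table["min"], table["max"])
        # every individual fit's coefficient lies in the reported range
        assert (table["min"] <= fit.fixed.pack()).all()
        assert (fit.fixed.pack() <= table["max"]).all()

    def test_range_formatting(self, tiny_data, intercept_structure):
        from traitenv.glmm import fit_map

        fit = fit_map(tiny_data, structure=intercept_structure)
        table = aggregate_fits([fit])
        assert all("/" in s for s in table["range"])
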