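import numpy as np
import pytest
from scipy import special, stats

from traitenv.glmm import (
    FixedEffects,
    ModelData,
    ModelStructure,
    PriorSpec,
    RandomEffects,
    bernoulli_loglik,
    conditional_r2,
    eta_matrix,
    fit_map,
    laplace_marginal_loglik,
    latent_r2,
    linear_predictor,
    log_posterior,
    predict_probability,
    summarize_fixed_effects,
    trait_response_profile,
    wald_p,
)
from traitenv.quadrature import fit_map_gh, marginal_loglik_gh


def reference_fixed() -> FixedEffects:
    """Fitted point estimates of the reference analysis, used as inputs."""
    beta12 = np.zeros((4, 3))
    beta12[3, 0] = -0.32  # MH x elevation
    return FixedEffects(alpha=-2.23, beta1=np.array([0.27, -0.15, 0.34]), beta12=beta12)


class TestLinearPredictor:
    def test_intercept_only_at_mean_conditions(self):
        fx = reference_fixed()
        eta = linear_predictor(fx, None, np.zeros(3), np.array([0.5, -0.2, 0.1, 0.7]))
        assert eta == pytest.approx(-2.23)
        assert special.expit(eta) == pytest.approx(0.0971, abs=5e-4)

    def test_no_interactions_means_trait_invariance(self):
        fx = FixedEffects(alpha=0.3, beta1=np.array([1.0, -0.5, 0.2]))
        X_i = np.array([0.4, 0.1, -0.3])
        etas = {
            linear_predictor(fx, None, X_i, np.array(z))
            for z in ([0, 0, 0, 0], [1, 2, 3, 4], [-1, 0.5, 0, 2])
        }
        assert len(etas) == 1

    def test_tall_species_at_high_elevation(self):
        # unit elevation, maximum-height trait at +1: main effect plus the
        # negative height x elevation association
        eta = linear_predictor(
            reference_fixed(), None, np.array([1.0, 0, 0]), np.array([0, 0, 0, 1.0])
        )
        assert eta == pytest.approx(-2.23 + 0.27 - 0.32, abs=1e-12)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            linear_predictor(reference_fixed(), None, np.zeros(2), np.zeros(4))


class TestLogPosterior:
    def test_matches_term_by_term_oracle(self):
        """Independently coded sum of log pmf / log pdf terms, 2 species x 3 plots."""
        rng = np.random.default_rng(7)
        n, m, d = 3, 2, 4
        data = ModelData(
            X=rng.normal(0, 0.5, (n, 3)),
            Z=rng.normal(0, 0.5, (m, 4)),
            Y=rng.integers(0, 2, (n, m)).astype(float),
        )
        fx = FixedEffects(
            alpha=-0.4, beta1=rng.normal(0, 0.3, 3), beta12=rng.normal(0, 0.2, (4, 3))
        )
        A = rng.normal(0, 0.3, (d, d))
        Sigma = A @ A.T + np.eye(d)
        random = RandomEffects(
            species=rng.normal(0, 0.5, (m, d)),
            site=rng.normal(0, 0.5, n),
            Sigma=Sigma,
            sigma_site=1.3,
        )
        priors = PriorSpec()

        expected = 0.0
        for i in range(n):
            for j in range(m):
                eta = fx.alpha + random.species[j, 0] + random.site[i]
                for e in range(3):
                    eta += (fx.beta1[e] + random.species[j, 1 + e]) * data.X[i, e]
                    for t in range(4):
                        eta += fx.beta12[t, e] * data.X[i, e] * data.Z[j, t]
                expected += stats.bernoulli.logpmf(data.Y[i, j], special.expit(eta))
        for j in range(m):
            expected += stats.multivariate_normal.logpdf(
                random.species[j], np.zeros(d), Sigma
            )
        expected += stats.norm.logpdf(random.site, 0.0, 1.3).sum()
        expected += stats.norm.logpdf(fx.pack(), 0.0, 1.0).sum()
        expected += stats.invwishart.logpdf(Sigma, 8, 2 * np.eye(4))
        expected += stats.invgamma.logpdf(1.3**2, 0.5, scale=100.0)

        assert log_posterior(fx, random, data, priors) == pytest.approx(
            float(expected), abs=1e-10
        )

    def test_prior_penalty_with_zero_observations(self):
        data = ModelData(
            X=np.zeros((3, 3)), Z=np.zeros((2, 4)), Y=np.zeros((3, 2)),
            mask=np.zeros((3, 2)),
        )
        random = RandomEffects.zeros(2, 3, ModelStructure())
        base = log_posterior(FixedEffects(), random, data)
        moved = FixedEffects(alpha=1.0)
        assert base - log_posterior(moved, random, data) == pytest.approx(0.5, abs=1e-12)

    def test_even_odds_likelihood(self):
        assert bernoulli_loglik(
            np.array([[1.0]]), np.array([[0.0]]), np.array([[1.0]])
        ) == pytest.approx(np.log(0.5))

    def test_nonfinite_term_is_reported(self):
        data = ModelData(X=np.zeros((2, 3)), Z=np.zeros((2, 4)), Y=np.zeros((2, 2)))
        random = RandomEffects.zeros(2, 2, ModelStructure())
        bad = FixedEffects(alpha=np.inf)
        with pytest.raises(ValueError, match="likelihood"):
            log_posterior(bad, random, data)


class TestLaplaceVsQuadrature:
    def test_marginal_loglik_close_on_tiny_instance(
        self, tiny_data, intercept_structure
    ):
        fx = FixedEffects(
            alpha=-0.5, beta1=np.array([0.3, -0.2, 0.1]), beta12=0.1 * np.ones((4, 3))
        )
        for var in (0.25, 1.0):
            lap = laplace_marginal_loglik(
                tiny_data, fx, Sigma=var * np.eye(1), structure=intercept_structure
            )
            gh = marginal_loglik_gh(
                tiny_data, fx, var * np.eye(1), intercept_structure, n_nodes=40
            )
            assert abs(lap - gh) / abs(gh) < 0.01

    def test_map_matches_quadrature_map(self, tiny_data, intercept_structure):
        fit = fit_map(tiny_data, structure=intercept_structure)
        fx_gh, _, res = fit_map_gh(tiny_data, structure=intercept_structure, n_nodes=30)
        assert res.success
        assert np.max(np.abs(fit.fixed.pack() - fx_gh.pack())) < 1e-3


class TestFitMap:
    def test_prior_dominance_with_zero_observations(self):
        """No data: fixed MAP at the prior mode 0, Sigma at the inverse-Wishart
        mode scale/(df + dim + 1), site variance at the inverse-gamma mode."""
        n, m = 6, 3
        data = ModelData(
            X=np.linspace(-0.5, 0.5, n * 3).reshape(n, 3),
            Z=np.linspace(-0.5, 0.5, m * 4).reshape(m, 4),
            Y=np.zeros((n, m)),
            mask=np.zeros((n, m)),
        )
        fit = fit_map(data)
        assert np.allclose(fit.fixed.pack(), 0.0, atol=1e-4)
        assert np.allclose(fit.random_modes.Sigma, (2.0 / 13.0) * np.eye(4), atol=1e-3)
        assert fit.random_modes.sigma_site**2 == pytest.approx(100.0 / 1.5, rel=1e-2)

    def test_separable_data_bounded_by_prior(self):
        rng = np.random.default_rng(3)
        n, m = 24, 3
        X = np.zeros((n, 3))
        X[:, 0] = np.linspace(-0.9, 0.9, n)
        Z = rng.normal(0, 0.5, (m, 4))
        Z -= Z.mean(axis=0)
        Y = np.tile((X[:, 0] > 0).astype(float)[:, None], (1, m))
        fit = fit_map(ModelData(X=X, Z=Z, Y=Y))
        assert np.all(np.isfinite(fit.fixed.pack()))
        assert np.max(np.abs(fit.fixed.pack())) < 20.0

    def test_nonconvergence_is_flagged_not_raised(self, tiny_data):
        fit = fit_map(tiny_data, control={"maxiter": 1})
        assert fit.converged is False
        assert np.all(np.isfinite([fit.grad_norm]))

    def test_species_permutation_leaves_fixed_effects_unchanged(self):
        rng = np.random.default_rng(11)
        n, m = 20, 4
        X = rng.normal(0, 0.5, (n, 3))
        X -= X.mean(axis=0)
        Z = rng.normal(0, 0.5, (m, 4))
        Z -= Z.mean(axis=0)
        Y = rng.integers(0, 2, (n, m)).astype(float)
        perm = np.array([2, 0, 3, 1])
        structure = ModelStructure(species_effects=("intercept",), site_effect=False)

        # exact invariance of the objective itself
        fx = FixedEffects(alpha=-0.3, beta1=np.array([0.2, 0.1, -0.1]),
                          beta12=0.05 * np.ones((4, 3)))
        base = laplace_marginal_loglik(
            ModelData(X=X, Z=Z, Y=Y), fx, 0.8 * np.eye(1), structure=structure
        )
        permuted = laplace_marginal_loglik(
            ModelData(X=X, Z=Z[perm], Y=Y[:, perm]), fx, 0.8 * np.eye(1),
            structure=structure,
        )
        assert permuted == pytest.approx(base, abs=1e-8)

        # and of the fitted fixed effects, to optimizer tolerance
        fit_a = fit_map(ModelData(X=X, Z=Z, Y=Y), structure=structure)
        fit_b = fit_map(ModelData(X=X, Z=Z[perm], Y=Y[:, perm]), structure=structure)
        assert np.allclose(fit_a.fixed.pack(), fit_b.fixed.pack(), atol=1e-4)
        assert np.allclose(fit_b.random_modes.species[:, 0],
                           fit_a.random_modes.species[perm, 0], atol=1e-3)


class TestSummaries:
    def test_wald_p_examples(self):
        assert wald_p(0.34, 0.16) == pytest.approx(0.0336, abs=5e-4)
        assert wald_p(0.34, 0.16) < 0.05
        assert wald_p(1.96, 1.0) == pytest.approx(0.05, abs=1e-3)
        assert wald_p(0.0, 0.7) == pytest.approx(1.0)

    def test_summary_table_layout(self, tiny_data, intercept_structure):
        fit = fit_map(tiny_data, structure=intercept_structure)
        table = summarize_fixed_effects(fit)
        assert list(table.columns) == ["coefficient", "se", "p"]
        assert len(table) == 16
        assert table.index[0] == "Intercept"
        assert (table["se"] > 0).all()
        assert ((table["p"] >= 0) & (table["p"] <= 1)).all()

    def test_latent_r2_examples(self):
        assert latent_r2(1.0, 2.0) == pytest.approx(3.0 / (3.0 + np.pi**2 / 3.0), abs=1e-4)
        assert latent_r2(0.0, 0.0) == 0.0
        assert latent_r2(1.0, 2.5) > latent_r2(1.0, 2.0)

    def test_conditional_r2_in_unit_interval(self, tiny_data, intercept_structure):
        fit = fit_map(tiny_data, structure=intercept_structure)
        assert 0.0 <= conditional_r2(fit) <= 1.0


class TestPredictions:
    def test_inverse_logit_values(self, tiny_data, intercept_structure):
        fit = fit_map(tiny_data, structure=intercept_structure)
        p = predict_probability(fit, np.zeros(3), np.zeros(4))
        assert p == pytest.approx(special.expit(fit.fixed.alpha))
        assert 0.0 < p < 1.0

    def test_monotone_in_eta(self):
        fx = FixedEffects(alpha=0.0, beta1=np.array([1.0, 0.0, 0.0]))
        etas = [
            linear_predictor(fx, None, np.array([x, 0, 0]), np.zeros(4))
            for x in (-1.0, 0.0, 1.0)
        ]
        probs = special.expit(etas)
        assert np.all(np.diff(probs) > 0)
        assert special.expit(0.0) == 0.5


class TestTraitResponseProfile:
    def _fit(self, tiny_data, intercept_structure):
        return fit_map(tiny_data, structure=intercept_structure)

    def test_zero_coefficient_gives_flat_line(self, tiny_data, intercept_structure):
        fit = self._fit(tiny_data, intercept_structure)
        fit.fixed.beta12[:] = 0.0
        prof = trait_response_profile(fit, "max_height", "elevation")
        assert np.allclose(prof.line, 0.0)
        assert prof.zero_crossing is None

    def test_zero_crossing_at_reference_estimates(self, tiny_data, intercept_structure):
        fit = self._fit(tiny_data, intercept_structure)
        fit.fixed.alpha = -2.23
        fit.fixed.beta1 = np.array([0.27, -0.15, 0.34])
        fit.fixed.beta12 = np.zeros((4, 3))
        fit.fixed.beta12[3, 0] = -0.32
        prof = trait_response_profile(fit, "max_height", "elevation")
        assert prof.zero_crossing == pytest.approx(0.27 / 0.32, abs=1e-6)
        # line is centered: zero at standardized trait 0
        mid = np.argmin(np.abs(prof.grid))
        assert abs(prof.line[mid]) < 0.05

    def test_unknown_names_error(self, tiny_data, intercept_structure):
        fit = self._fit(tiny_data, intercept_structure)
        with pytest.raises(ValueError, match="trait"):
            trait_response_profile(fit, "leafiness", "elevation")
        with pytest.raises(ValueError, match="environment"):
            trait_response_profile(fit, "sla", "rainfall")
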