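"""Hierarchical trait-environment occurrence model.

The model is a Bernoulli-logit GLMM for species j at plot (site) i:

    logit(p_ij) = alpha + a_j + (beta1 + b_j) . X_i + sum_{t,e} beta12[t,e] X_i[e] Z_j[t] + c_i

where X_i are the standardized environmental variables (elevation, slope,
aspect), Z_j the standardized traits (SLA, seed mass, wood density, maximum
height), alpha the overall prevalence on the logit scale, beta1 the average
environmental responses, and beta12 the 12 trait-environment associations.
Traits enter only through the interactions: they modulate responses to the
environment rather than shifting prevalence directly.  Random terms are a
species-level deviation vector (a_j, b_j) with covariance Sigma and a site
intercept c_i with SD sigma_site.

Fitting is approximate Bayesian maximum posterior estimation: weak priors
(normal(0,1) on every fixed effect, inverse-Wishart on Sigma, inverse-gamma
on the site variance) regularize the fit, random effects are integrated out
by a Laplace approximation, and the resulting marginal posterior is
maximized over the fixed effects and variance components.  Random-effect
modes come from the inner penalized-likelihood Newton problem.  Standard
errors are the inverse curvature of the approximated log posterior at the
mode (Schur complement of the joint Hessian over fixed and random effects,
holding variance components at their estimates), and p-values are two-sided
Wald z tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize, special, stats

from traitenv.preprocessing import (
    DISPLAY,
    ENVIRONMENTS,
    INTERACTION_INDEX,
    TRAITS,
    DesignMatrices,
)

_LOG2PI = float(np.log(2.0 * np.pi))

SPECIES_EFFECT_NAMES = ("intercept",) + ENVIRONMENTS


# ---------------------------------------------------------------------------
# containers


@dataclass
class ModelStructure:
    """Which random terms are active.

    The full model uses a 4-dimensional species effect (intercept plus a
    slope for each environmental variable) and a site intercept.  Reduced
    structures (e.g. species intercept only, no site term) are used for
    small validation instances.
    """

    species_effects: tuple[str, ...] = SPECIES_EFFECT_NAMES
    site_effect: bool = True

    def __post_init__(self) -> None:
        bad = [s for s in self.species_effects if s not in SPECIES_EFFECT_NAMES]
        if bad:
            raise ValueError(f"unknown species effects {bad}; choose from {SPECIES_EFFECT_NAMES}")

    @property
    def n_species_dims(self) -> int:
        return len(self.species_effects)

    def species_design(self, X: np.ndarray) -> np.ndarray:
        """n x d design for the species random-effect vector."""
        cols = []
        for name in self.species_effects:
            if name == "intercept":
                cols.append(np.ones(X.shape[0]))
            else:
                cols.append(X[:, ENVIRONMENTS.index(name)])
        if not cols:
            return np.zeros((X.shape[0], 0))
        return np.column_stack(cols)


@dataclass
class PriorSpec:
    """Weak priors of the maximum-posterior fit.

    * species random-effect covariance: inverse-Wishart with ``wishart_df``
      degrees of freedom and a diagonal scale matrix with
      ``wishart_scale_diag`` on the diagonal (mode = scale/(df + d + 1));
    * site intercept variance: inverse-gamma(shape, scale);
    * every fixed effect: independent normal(0, ``fixed_sd``).
    """

    wishart_df: float = 8.0
    wishart_scale_diag: float = 2.0
    site_shape: float = 0.5
    site_scale: float = 100.0
    fixed_sd: float = 1.0

    def wishart_scale(self, d: int) -> np.ndarray:
        return self.wishart_scale_diag * np.eye(d)

    def to_dict(self) -> dict:
        return {
            "wishart_df": self.wishart_df,
            "wishart_scale_diag": self.wishart_scale_diag,
            "site_shape": self.site_shape,
            "site_scale": self.site_scale,
            "fixed_sd": self.fixed_sd,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PriorSpec":
        return cls(**d)


@dataclass
class FixedEffects:
    """alpha (logit prevalence), beta1 (3 environments), beta12 (4 traits x 3 envs)."""

    alpha: float = 0.0
    beta1: np.ndarray = field(default_factory=lambda: np.zeros(3))
    beta12: np.ndarray = field(default_factory=lambda: np.zeros((4, 3)))

    def __post_init__(self) -> None:
        self.beta1 = np.asarray(self.beta1, dtype=float)
        self.beta12 = np.asarray(self.beta12, dtype=float)
        if self.beta1.shape != (len(ENVIRONMENTS),):
            raise ValueError(f"beta1 must have shape ({len(ENVIRONMENTS)},)")
        if self.beta12.shape != (len(TRAITS), len(ENVIRONMENTS)):
            raise ValueError(f"beta12 must have shape ({len(TRAITS)}, {len(ENVIRONMENTS)})")

    def pack(self) -> np.ndarray:
        """16-vector in reporting order: intercept, 3 mains, 12 interactions."""
        return np.concatenate([[self.alpha], self.beta1, self.beta12.ravel()])

    @classmethod
    def unpack(cls, vec: np.ndarray) -> "FixedEffects":
        vec = np.asarray(vec, dtype=float)
        ne, nt = len(ENVIRONMENTS), len(TRAITS)
        if vec.shape != (1 + ne + nt * ne,):
            raise ValueError(f"expected {1 + ne + nt * ne} packed fixed effects")
        return cls(
            alpha=float(vec[0]),
            beta1=vec[1 : 1 + ne].copy(),
            beta12=vec[1 + ne :].reshape(nt, ne).copy(),
        )

    @staticmethod
    def names() -> list[str]:
        return (
            ["Intercept"]
            + [DISPLAY[e] for e in ENVIRONMENTS]
            + [f"{DISPLAY[t]}: {DISPLAY[e]}" for t, e in INTERACTION_INDEX]
        )


@dataclass
class RandomEffects:
    """Species deviations (m x d), site intercepts (n), and their (co)variances."""

    species: np.ndarray
    site: np.ndarray
    Sigma: np.ndarray
    sigma_site: float | None = None

    def __post_init__(self) -> None:
        self.species = np.asarray(self.species, dtype=float)
        self.site = np.asarray(self.site, dtype=float)
        self.Sigma = np.asarray(self.Sigma, dtype=float)
        d = self.Sigma.shape[0]
        if self.Sigma.shape != (d, d) or not np.allclose(self.Sigma, self.Sigma.T):
            raise ValueError("Sigma must be square symmetric")
        if self.species.ndim != 2 or self.species.shape[1] != d:
            raise ValueError("species effects must be m x d matching Sigma")
        if self.sigma_site is not None and not self.sigma_site > 0:
            raise ValueError("sigma_site must be positive")

    @classmethod
    def zeros(
        cls, m: int, n: int, structure: ModelStructure, sigma_site: float | None = 1.0
    ) -> "RandomEffects":
        d = structure.n_species_dims
        return cls(
            species=np.zeros((m, d)),
            site=np.zeros(n),
            Sigma=np.eye(d),
            sigma_site=sigma_site if structure.site_effect else None,
        )


@dataclass
class ModelData:
    """Standardized design plus the binary occurrence matrix.

    ``Y`` is n_plots x m_species in {0,1}; entries with ``mask`` 0 do not
    contribute to the likelihood (missing observations, or an all-zero mask
    for prior-only fits).
    """

    X: np.ndarray
    Z: np.ndarray
    Y: np.ndarray
    mask: np.ndarray | None = None
    plot_ids: Sequence | None = None
    species_ids: Sequence | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.Z = np.asarray(self.Z, dtype=float)
        Y = np.asarray(self.Y, dtype=float)
        if self.mask is None:
            self.mask = np.where(np.isnan(Y), 0.0, 1.0)
        else:
            self.mask = np.asarray(self.mask, dtype=float)
        self.Y = np.where(np.isnan(Y), 0.0, Y)
        n, m = self.Y.shape
        if self.X.shape != (n, len(ENVIRONMENTS)):
            raise ValueError(f"X must be {n} x {len(ENVIRONMENTS)} to match Y")
        if self.Z.shape != (m, len(TRAITS)):
            raise ValueError(f"Z must be {m} x {len(TRAITS)} to match Y")
        if self.mask.shape != (n, m):
            raise ValueError("mask must match Y")
        observed = self.Y[self.mask > 0]
        if observed.size and not np.isin(observed, (0.0, 1.0)).all():
            raise ValueError("occurrence entries must be binary")

    @property
    def n(self) -> int:
        return self.Y.shape[0]

    @property
    def m(self) -> int:
        return self.Y.shape[1]

    @classmethod
    def from_design(cls, design: DesignMatrices, occurrence: pd.DataFrame) -> "ModelData":
        """Join a wide occurrence table (index plot_id, columns species) to a design."""
        occ = occurrence.loc[design.X.index, design.Z.index]
        return cls(
            X=design.X.to_numpy(),
            Z=design.Z.to_numpy(),
            Y=occ.to_numpy(dtype=float),
            plot_ids=list(design.X.index),
            species_ids=list(design.Z.index),
        )

    def flagged_species(self) -> list:
        """Species with zero observed presences or zero observed absences."""
        ids = self.species_ids if self.species_ids is not None else list(range(self.m))
        flagged = []
        for j in range(self.m):
            obs = self.mask[:, j] > 0
            y = self.Y[obs, j]
            if y.size == 0 or y.min() == y.max():
                flagged.append(ids[j])
        return flagged


@dataclass
class ModelFit:
    """Result of the maximum-posterior fit (fixed-effect table semantics)."""

    fixed: FixedEffects
    se: np.ndarray
    p_values: np.ndarray
    random_modes: RandomEffects
    random_sd: dict[str, float]
    log_posterior_value: float
    converged: bool
    grad_norm: float
    n_outer_evals: int
    structure: ModelStructure
    priors: PriorSpec
    data: ModelData
    message: str = ""
    se_defined: bool = True

    @property
    def n_sites(self) -> int:
        return self.data.n

    @property
    def m_species(self) -> int:
        return self.data.m

    @property
    def fixed_names(self) -> list[str]:
        return FixedEffects.names()

    def to_dict(self) -> dict:
        return {
            "fixed": {
                name: {"coefficient": float(c), "se": float(s), "p": float(p)}
                for name, c, s, p in zip(
                    self.fixed_names, self.fixed.pack(), self.se, self.p_values
                )
            },
            "random_sd": {k: float(v) for k, v in self.random_sd.items()},
            "Sigma": self.random_modes.Sigma.tolist(),
            "sigma_site": (
                None if self.random_modes.sigma_site is None
                else float(self.random_modes.sigma_site)
            ),
            "species_modes": self.random_modes.species.tolist(),
            "site_modes": self.random_modes.site.tolist(),
            "species_ids": list(self.data.species_ids or range(self.m_species)),
            "plot_ids": list(self.data.plot_ids or range(self.n_sites)),
            "species_effects": list(self.structure.species_effects),
            "site_effect": self.structure.site_effect,
            "log_posterior": float(self.log_posterior_value),
            "converged": bool(self.converged),
            "grad_norm": float(self.grad_norm),
            "n_outer_evals": int(self.n_outer_evals),
            "message": self.message,
            "se_defined": bool(self.se_defined),
            "priors": self.priors.to_dict(),
            "flagged_species": self.data.flagged_species(),
            "n_sites": self.n_sites,
            "m_species": self.m_species,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


# ---------------------------------------------------------------------------
# linear predictor and joint log posterior


def eta_matrix(
    fixed: FixedEffects,
    random: RandomEffects | None,
    X: np.ndarray,
    Z: np.ndarray,
    structure: ModelStructure | None = None,
) -> np.ndarray:
    """Full n x m matrix of linear predictors."""
    structure = structure or ModelStructure()
    eta = fixed.alpha + (X @ fixed.beta1)[:, None] + X @ fixed.beta12.T @ Z.T
    if random is not None:
        Xs = structure.species_design(X)
        if random.species.size:
            eta = eta + Xs @ random.species.T
        if structure.site_effect and random.site.size:
            eta = eta + random.site[:, None]
    return eta


def linear_predictor(
    fixed: FixedEffects,
    random: RandomEffects | None,
    X_i: np.ndarray,
    Z_j: np.ndarray,
    *,
    species_index: int = 0,
    site_index: int = 0,
    structure: ModelStructure | None = None,
) -> float:
    """Logit-scale predictor for one (site, species) pair.

    With ``random=None`` (or zero random effects) this is the population-level
    predictor alpha + beta1.X + sum beta12[t,e] X[e] Z[t].
    """
    X_i = np.asarray(X_i, dtype=float)
    Z_j = np.asarray(Z_j, dtype=float)
    if X_i.shape != (len(ENVIRONMENTS),) or Z_j.shape != (len(TRAITS),):
        raise ValueError("X_i must have 3 entries and Z_j 4 entries")
    structure = structure or ModelStructure()
    eta = fixed.alpha + fixed.beta1 @ X_i + Z_j @ fixed.beta12 @ X_i
    if random is not None:
        Xs_i = structure.species_design(X_i[None, :])[0]
        if random.species.size:
            eta += Xs_i @ random.species[species_index]
        if structure.site_effect and random.site.size:
            eta += random.site[site_index]
    return float(eta)


def bernoulli_loglik(Y: np.ndarray, eta: np.ndarray, mask: np.ndarray) -> float:
    """Sum of Bernoulli-logit log pmf over observed cells."""
    return float(np.sum(mask * (Y * eta - np.logaddexp(0.0, eta))))


def log_posterior(
    fixed: FixedEffects,
    random: RandomEffects,
    data: ModelData,
    priors: PriorSpec | None = None,
    structure: ModelStructure | None = None,
) -> float:
    """Joint log posterior density of all parameters and random effects.

    Sum of the Bernoulli-logit log likelihood, the log densities of the
    random effects given their covariances, and the log prior densities
    (normal on fixed effects, inverse-Wishart on Sigma, inverse-gamma on the
    site variance).  All distribution normalizing constants are included, so
    the value matches a term-by-term sum of standard log pdfs.
    """
    priors = priors or PriorSpec()
    structure = structure or ModelStructure()
    terms: dict[str, float] = {}

    eta = eta_matrix(fixed, random, data.X, data.Z, structure)
    terms["likelihood"] = bernoulli_loglik(data.Y, eta, data.mask)

    d = structure.n_species_dims
    if d:
        sign, logdet = np.linalg.slogdet(random.Sigma)
        if sign <= 0:
            raise ValueError("Sigma must be positive definite")
        Sinv = np.linalg.inv(random.Sigma)
        quad = float(np.einsum("jk,kl,jl->", random.species, Sinv, random.species))
        terms["species_effects"] = -0.5 * (quad + data.m * (logdet + d * _LOG2PI))
        terms["Sigma_prior"] = float(
            stats.invwishart.logpdf(random.Sigma, priors.wishart_df, priors.wishart_scale(d))
        )
    if structure.site_effect:
        if random.sigma_site is None:
            raise ValueError("structure has a site effect but sigma_site is None")
        s2 = random.sigma_site**2
        terms["site_effects"] = -0.5 * (
            float(np.sum(random.site**2)) / s2 + data.n * (np.log(s2) + _LOG2PI)
        )
        terms["site_var_prior"] = float(
            stats.invgamma.logpdf(s2, priors.site_shape, scale=priors.site_scale)
        )
    terms["fixed_prior"] = float(
        np.sum(stats.norm.logpdf(fixed.pack(), loc=0.0, scale=priors.fixed_sd))
    )

    for name, value in terms.items():
        if not np.isfinite(value):
            raise ValueError(f"log posterior term {name!r} is not finite ({value})")
    return float(sum(terms.values()))


# ---------------------------------------------------------------------------
# Laplace machinery


def _chol_unpack(theta: np.ndarray, d: int) -> np.ndarray:
    """Lower-triangular Cholesky factor from packed log-Cholesky parameters."""
    L = np.zeros((d, d))
    idx = np.tril_indices(d)
    L[idx] = theta
    L[np.diag_indices(d)] = np.exp(np.diag(L))
    return L


def _chol_pack(Sigma: np.ndarray) -> np.ndarray:
    L = np.linalg.cholesky(Sigma)
    M = L.copy()
    M[np.diag_indices(Sigma.shape[0])] = np.log(np.diag(L))
    return M[np.tril_indices(Sigma.shape[0])]


class _LaplaceProblem:
    """Inner Newton solver and Laplace objective for one dataset."""

    def __init__(self, data: ModelData, priors: PriorSpec, structure: ModelStructure):
        self.data = data
        self.priors = priors
        self.structure = structure
        self.Xs = structure.species_design(data.X)  # n x d
        self.d = structure.n_species_dims
        self.n = data.n
        self.m = data.m
        self.dim_u = self.m * self.d + (self.n if structure.site_effect else 0)
        self._warm: np.ndarray | None = None

    # -- joint penalized log posterior over u given (beta, Sigma, sigma2) --

    def _eta(self, beta: np.ndarray, V: np.ndarray, c: np.ndarray) -> np.ndarray:
        fx = FixedEffects.unpack(beta)
        eta = fx.alpha + (self.data.X @ fx.beta1)[:, None] + (
            self.data.X @ fx.beta12.T @ self.data.Z.T
        )
        if self.d:
            eta = eta + self.Xs @ V.T
        if self.structure.site_effect:
            eta = eta + c[:, None]
        return eta

    def _g(self, beta, V, c, Sigma_inv, logdet_Sigma, sigma2) -> float:
        eta = self._eta(beta, V, c)
        g = bernoulli_loglik(self.data.Y, eta, self.data.mask)
        if self.d:
            g += -0.5 * (
                float(np.einsum("jk,kl,jl->", V, Sigma_inv, V))
                + self.m * (logdet_Sigma + self.d * _LOG2PI)
            )
        if self.structure.site_effect:
            g += -0.5 * (float(c @ c) / sigma2 + self.n * (np.log(sigma2) + _LOG2PI))
        return g

    def inner_mode(
        self,
        beta: np.ndarray,
        Sigma_inv: np.ndarray,
        logdet_Sigma: float,
        sigma2: float | None,
        *,
        gtol: float = 1e-9,
        maxiter: int = 200,
    ) -> tuple[np.ndarray, np.ndarray, float, float]:
        """Newton maximization over random effects.

        Returns (V, c, g_at_mode, logdet_H) with H the negative Hessian of
        the penalized log posterior over u at the mode.
        """
        n, m, d = self.n, self.m, self.d
        md = m * d
        site = self.structure.site_effect
        if self.dim_u == 0:
            g = self._g(beta, np.zeros((m, 0)), np.zeros(n), Sigma_inv, logdet_Sigma, sigma2)
            return np.zeros((m, 0)), np.zeros(n), g, 0.0
        if (
            self._warm is not None
            and self._warm.size == self.dim_u
            and np.all(np.isfinite(self._warm))
        ):
            u = self._warm.copy()
        else:
            u = np.zeros(self.dim_u)
        V = u[:md].reshape(m, d)
        c = u[md:] if site else np.zeros(n)

        g = self._g(beta, V, c, Sigma_inv, logdet_Sigma, sigma2)
        chol = None
        for _ in range(maxiter):
            eta = self._eta(beta, V, c)
            p = special.expit(eta)
            r = self.data.mask * (self.data.Y - p)
            w = self.data.mask * p * (1.0 - p)

            grad = np.empty(self.dim_u)
            if d:
                grad[:md] = (r.T @ self.Xs - V @ Sigma_inv).ravel()
            if site:
                grad[md:] = r.sum(axis=1) - c / sigma2

            H = np.zeros((self.dim_u, self.dim_u))
            if d:
                A = np.einsum("ij,ik,il->jkl", w, self.Xs, self.Xs)
                A += Sigma_inv[None, :, :]
                for j in range(m):
                    H[j * d : (j + 1) * d, j * d : (j + 1) * d] = A[j]
            if site:
                if d:
                    B = np.einsum("ij,ik->jki", w, self.Xs).reshape(md, n)
                    H[:md, md:] = B
                    H[md:, :md] = B.T
                H[md:, md:] = np.diag(w.sum(axis=1) + 1.0 / sigma2)

            if not (np.all(np.isfinite(grad)) and np.all(np.isfinite(H))):
                self._warm = None
                raise linalg.LinAlgError("non-finite terms in the inner Newton problem")
            try:
                chol = linalg.cho_factor(H, lower=True)
            except linalg.LinAlgError:
                # extreme variance iterates can make H numerically indefinite
                chol = linalg.cho_factor(
                    H + 1e-8 * np.max(np.diag(H)) * np.eye(H.shape[0]), lower=True
                )
            if np.max(np.abs(grad)) < gtol:
                break
            step = linalg.cho_solve(chol, grad)
            t = 1.0
            for _ in range(40):
                V_new = V + t * step[:md].reshape(m, d)
                c_new = c + t * step[md:] if site else c
                g_new = self._g(beta, V_new, c_new, Sigma_inv, logdet_Sigma, sigma2)
                if g_new >= g - 1e-12:
                    break
                t *= 0.5
            V, c, g = V_new, c_new, g_new
        self._warm = np.concatenate([V.ravel(), c]) if site else V.ravel()
        logdet_H = 2.0 * float(np.sum(np.log(np.diag(chol[0]))))
        return V, c, g, logdet_H

    # -- Laplace-approximated marginal log posterior --

    def unpack_params(self, params: np.ndarray):
        nb = 1 + len(ENVIRONMENTS) + len(TRAITS) * len(ENVIRONMENTS)
        beta = params[:nb]
        ntheta = self.d * (self.d + 1) // 2
        L = _chol_unpack(params[nb : nb + ntheta], self.d) if self.d else np.zeros((0, 0))
        sigma2 = None
        if self.structure.site_effect:
            sigma2 = float(np.exp(2.0 * params[nb + ntheta]))
        return beta, L, sigma2

    def n_params(self) -> int:
        nb = 1 + len(ENVIRONMENTS) + len(TRAITS) * len(ENVIRONMENTS)
        return nb + self.d * (self.d + 1) // 2 + (1 if self.structure.site_effect else 0)

    def marginal_loglik(self, beta, Sigma, sigma2, **kw) -> float:
        """Laplace-approximated log of the likelihood with random effects
        integrated out (no parameter priors)."""
        if self.d:
            Sigma_inv = np.linalg.inv(Sigma)
            sign, logdet_Sigma = np.linalg.slogdet(Sigma)
        else:
            Sigma_inv, logdet_Sigma = np.zeros((0, 0)), 0.0
        _, _, g, logdet_H = self.inner_mode(beta, Sigma_inv, logdet_Sigma, sigma2, **kw)
        return g + 0.5 * self.dim_u * _LOG2PI - 0.5 * logdet_H

    def log_prior(self, beta, Sigma, sigma2) -> float:
        lp = float(np.sum(stats.norm.logpdf(beta, 0.0, self.priors.fixed_sd)))
        if self.d:
            lp += float(
                stats.invwishart.logpdf(
                    Sigma, self.priors.wishart_df, self.priors.wishart_scale(self.d)
                )
            )
        if sigma2 is not None:
            lp += float(
                stats.invgamma.logpdf(sigma2, self.priors.site_shape, scale=self.priors.site_scale)
            )
        return lp

    def objective(self, params: np.ndarray) -> float:
        """Negative Laplace-approximated marginal log posterior."""
        beta, L, sigma2 = self.unpack_params(params)
        try:
            if self.d:
                Sigma = L @ L.T
                Linv = linalg.solve_triangular(L, np.eye(self.d), lower=True)
                Sigma_inv = Linv.T @ Linv
                logdet_Sigma = 2.0 * float(np.sum(np.log(np.diag(L))))
            else:
                Sigma = np.zeros((0, 0))
                Sigma_inv, logdet_Sigma = np.zeros((0, 0)), 0.0
            _, _, g, logdet_H = self.inner_mode(beta, Sigma_inv, logdet_Sigma, sigma2)
            value = g + 0.5 * self.dim_u * _LOG2PI - 0.5 * logdet_H
            value += self.log_prior(beta, Sigma, sigma2)
        except (linalg.LinAlgError, np.linalg.LinAlgError, ValueError):
            return 1e12
        if not np.isfinite(value):
            return 1e12
        return -value


def laplace_marginal_loglik(
    data: ModelData,
    fixed: FixedEffects,
    Sigma: np.ndarray | None = None,
    sigma_site: float | None = None,
    structure: ModelStructure | None = None,
    priors: PriorSpec | None = None,
) -> float:
    """Laplace-approximated marginal log likelihood (random effects integrated)."""
    structure = structure or ModelStructure()
    prob = _LaplaceProblem(data, priors or PriorSpec(), structure)
    d = structure.n_species_dims
    Sigma = np.eye(d) if (Sigma is None and d) else np.asarray(Sigma) if d else np.zeros((0, 0))
    sigma2 = sigma_site**2 if (sigma_site is not None and structure.site_effect) else None
    if structure.site_effect and sigma2 is None:
        raise ValueError("structure has a site effect; sigma_site is required")
    return prob.marginal_loglik(fixed.pack(), Sigma, sigma2)


# ---------------------------------------------------------------------------
# fitting


DEFAULT_CONTROL = {
    "maxiter": 500,
    "gtol": 1e-5,
    "ftol": 1e-12,
    "fd_eps": 5e-7,
    "inner_gtol": 1e-9,
    "grad_norm_ok": 1e-2,
}


def fit_map(
    data: ModelData,
    priors: PriorSpec | None = None,
    structure: ModelStructure | None = None,
    control: dict | None = None,
) -> ModelFit:
    """Maximum-posterior fit with Laplace-integrated random effects.

    The outer quasi-Newton optimization runs over the 16 fixed effects, the
    log-Cholesky parameters of the species covariance, and the log site SD;
    the random-effect modes solve the inner penalized-likelihood problem.
    Deterministic given the data and starting values (fixed effects start at
    0, covariances at identity).  Non-convergence is reported through the
    ``converged`` flag and diagnostics, not an exception.
    """
    priors = priors or PriorSpec()
    structure = structure or ModelStructure()
    ctl = {**DEFAULT_CONTROL, **(control or {})}
    prob = _LaplaceProblem(data, priors, structure)

    x0 = np.zeros(prob.n_params())
    d = structure.n_species_dims

    res = optimize.minimize(
        prob.objective,
        x0,
        method="L-BFGS-B",
        options={
            "maxiter": ctl["maxiter"],
            "ftol": ctl["ftol"],
            "gtol": ctl["gtol"],
            "eps": ctl["fd_eps"],
        },
    )
    grad_norm = float(np.max(np.abs(res.jac))) if res.jac is not None else np.inf
    converged = bool(res.success) or grad_norm < ctl["grad_norm_ok"]

    beta, L, sigma2 = prob.unpack_params(res.x)
    Sigma = L @ L.T if d else np.zeros((0, 0))
    if d:
        Sigma_inv = np.linalg.inv(Sigma)
        _, logdet_Sigma = np.linalg.slogdet(Sigma)
    else:
        Sigma_inv, logdet_Sigma = np.zeros((0, 0)), 0.0
    V, c, _, _ = prob.inner_mode(beta, Sigma_inv, logdet_Sigma, sigma2, gtol=ctl["inner_gtol"])

    fixed = FixedEffects.unpack(beta)
    sigma_site = float(np.sqrt(sigma2)) if sigma2 is not None else None
    random = RandomEffects(species=V, site=c, Sigma=Sigma, sigma_site=sigma_site)

    se, se_defined = _fixed_effect_se(prob, beta, V, c, Sigma_inv, sigma2)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(se > 0, beta / se, 0.0)
    p_values = 2.0 * stats.norm.sf(np.abs(z))

    random_sd: dict[str, float] = {}
    if structure.site_effect:
        random_sd["Site (Intercept)"] = sigma_site
    for k, name in enumerate(structure.species_effects):
        label = "Intercept" if name == "intercept" else DISPLAY[name]
        random_sd[f"Species ({label})"] = float(np.sqrt(Sigma[k, k]))

    return ModelFit(
        fixed=fixed,
        se=se,
        p_values=p_values,
        random_modes=random,
        random_sd=random_sd,
        log_posterior_value=-float(res.fun),
        converged=converged,
        grad_norm=grad_norm,
        n_outer_evals=int(res.nfev),
        structure=structure,
        priors=priors,
        data=data,
        message=str(res.message),
        se_defined=se_defined,
    )


def _fixed_effect_se(
    prob: _LaplaceProblem,
    beta: np.ndarray,
    V: np.ndarray,
    c: np.ndarray,
    Sigma_inv: np.ndarray,
    sigma2: float | None,
) -> tuple[np.ndarray, bool]:
    """SEs from the curvature of the approximated log posterior at the mode.

    The covariance of the fixed effects is the inverse Schur complement of
    the joint negative Hessian over (fixed effects, random effects), with the
    variance components held at their estimates.
    """
    data, Xs = prob.data, prob.Xs
    n, m, d = prob.n, prob.m, prob.d
    site = prob.structure.site_effect
    nb = beta.size
    eta = prob._eta(beta, V, c)
    p = special.expit(eta)
    w = data.mask * p * (1.0 - p)

    F = np.empty((n, m, nb))
    F[:, :, 0] = 1.0
    for e in range(len(ENVIRONMENTS)):
        F[:, :, 1 + e] = data.X[:, e][:, None]
    k = 1 + len(ENVIRONMENTS)
    for t in range(len(TRAITS)):
        for e in range(len(ENVIRONMENTS)):
            F[:, :, k] = data.X[:, e][:, None] * data.Z[None, :, t]
            k += 1

    H_bb = np.einsum("ijk,ij,ijl->kl", F, w, F) + np.eye(nb) / prob.priors.fixed_sd**2
    blocks = []
    if d:
        H_bV = np.einsum("ijk,ij,il->kjl", F, w, Xs).reshape(nb, m * d)
        blocks.append(H_bV)
    if site:
        H_bc = np.einsum("ijk,ij->ki", F, w)
        blocks.append(H_bc)
    if blocks:
        H_bu = np.hstack(blocks)
        md = m * d
        H_uu = np.zeros((prob.dim_u, prob.dim_u))
        if d:
            A = np.einsum("ij,ik,il->jkl", w, Xs, Xs) + Sigma_inv[None, :, :]
            for j in range(m):
                H_uu[j * d : (j + 1) * d, j * d : (j + 1) * d] = A[j]
        if site:
            if d:
                B = np.einsum("ij,ik->jki", w, Xs).reshape(md, n)
                H_uu[:md, md:] = B
                H_uu[md:, :md] = B.T
            H_uu[md:, md:] = np.diag(w.sum(axis=1) + 1.0 / sigma2)
        try:
            chol = linalg.cho_factor(H_uu, lower=True)
            H_bb = H_bb - H_bu @ linalg.cho_solve(chol, H_bu.T)
        except linalg.LinAlgError:
            return np.full(nb, np.nan), False
    try:
        cov = np.linalg.inv(H_bb)
        se = np.sqrt(np.diag(cov))
        if not np.all(np.isfinite(se)):
            return np.full(nb, np.nan), False
        return se, True
    except np.linalg.LinAlgError:
        return np.full(nb, np.nan), False


# ---------------------------------------------------------------------------
# summaries and predictions


def summarize_fixed_effects(fit: ModelFit) -> pd.DataFrame:
    """Fixed-effect table: coefficient, SE, two-sided Wald p, reporting order."""
    return pd.DataFrame(
        {
            "coefficient": fit.fixed.pack(),
            "se": fit.se,
            "p": fit.p_values,
        },
        index=pd.Index(fit.fixed_names, name="fixed_effect"),
    )


def wald_p(coefficient: float, se: float) -> float:
    """Two-sided Wald z-test p-value."""
    if se <= 0:
        raise ValueError("SE must be positive")
    return float(2.0 * stats.norm.sf(abs(coefficient) / se))


def latent_r2(var_fixed: float, var_random: float) -> float:
    """Latent-scale conditional R-squared for a logit model.

    (sigma2_fixed + sigma2_random) / (sigma2_fixed + sigma2_random + pi^2/3),
    with pi^2/3 the variance of the standard-logistic observation level.
    """
    total = var_fixed + var_random
    return float(total / (total + np.pi**2 / 3.0))


def conditional_r2(fit: ModelFit) -> float:
    """Conditional R-squared of a fit on the latent (logit) scale.

    The fixed-effect variance is the variance of the fixed-effect linear
    predictor over all plot x species cells; the random-effect variance sums
    the site variance and the mean over plots of Xs_i' Sigma Xs_i (the
    species random intercept-and-slope contribution).
    """
    eta_fix = eta_matrix(fit.fixed, None, fit.data.X, fit.data.Z, fit.structure)
    var_fixed = float(eta_fix.var())
    var_random = 0.0
    if fit.structure.n_species_dims:
        Xs = fit.structure.species_design(fit.data.X)
        var_random += float(np.mean(np.einsum("ik,kl,il->i", Xs, fit.random_modes.Sigma, Xs)))
    if fit.structure.site_effect and fit.random_modes.sigma_site is not None:
        var_random += fit.random_modes.sigma_site**2
    return latent_r2(var_fixed, var_random)


def predict_probability(
    fit: ModelFit,
    X_i: np.ndarray,
    Z_j: np.ndarray,
    *,
    include_random: bool = False,
    species_index: int = 0,
    site_index: int = 0,
) -> float:
    """Occurrence probability for one (site, species) pair."""
    random = fit.random_modes if include_random else None
    eta = linear_predictor(
        fit.fixed, random, X_i, Z_j,
        species_index=species_index, site_index=site_index, structure=fit.structure,
    )
    return float(special.expit(eta))


def predict_matrix(fit: ModelFit, *, include_random: bool = True) -> np.ndarray:
    """n x m matrix of fitted occurrence probabilities for the training data."""
    random = fit.random_modes if include_random else None
    eta = eta_matrix(fit.fixed, random, fit.data.X, fit.data.Z, fit.structure)
    return special.expit(eta)


@dataclass
class TraitResponseProfile:
    """One panel of the trait-response figure: how a trait shifts the
    response to one environmental variable."""

    trait: str
    environment: str
    grid: np.ndarray
    line: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    species_trait_values: np.ndarray
    species_responses: np.ndarray
    coefficient: float
    se: float
    zero_crossing: float | None


def trait_response_profile(
    fit: ModelFit,
    trait: str,
    environment: str,
    grid: np.ndarray | None = None,
) -> TraitResponseProfile:
    """Centered trait-modulated environmental response with a 95% band.

    The line at standardized trait value z is beta12[trait, env] * z (zero at
    z = 0, i.e. at the mean trait); the band is +/- 1.96 SE * |z|.  Species
    points are their estimated responses to the environment (beta1 + b_j plus
    the trait-interaction contribution), centered at the response of a
    hypothetical mean-trait species, and positioned at their standardized
    trait values.
    """
    if trait not in TRAITS:
        raise ValueError(f"unknown trait {trait!r}; choose from {TRAITS}")
    if environment not in ENVIRONMENTS:
        raise ValueError(f"unknown environment {environment!r}; choose from {ENVIRONMENTS}")
    t = TRAITS.index(trait)
    e = ENVIRONMENTS.index(environment)
    coef = float(fit.fixed.beta12[t, e])
    se_idx = 1 + len(ENVIRONMENTS) + t * len(ENVIRONMENTS) + e
    se = float(fit.se[se_idx])

    Zt = fit.data.Z[:, t]
    if grid is None:
        pad = 0.1 * (Zt.max() - Zt.min() + 1e-9)
        grid = np.linspace(Zt.min() - pad, Zt.max() + pad, 101)
    grid = np.asarray(grid, dtype=float)
    line = coef * grid
    half = 1.96 * se * np.abs(grid)

    # species response to this environment: beta1[e] + b_j[e] + interactions
    resp = np.full(fit.data.m, float(fit.fixed.beta1[e]))
    resp += fit.data.Z @ fit.fixed.beta12[:, e]
    if environment in fit.structure.species_effects:
        k = fit.structure.species_effects.index(environment)
        resp = resp + fit.random_modes.species[:, k]
    # center: subtract the mean-trait (all standardized traits at 0) response
    resp_centered = resp - float(fit.fixed.beta1[e])

    crossing = -float(fit.fixed.beta1[e]) / coef if coef != 0.0 else None
    return TraitResponseProfile(
        trait=trait,
        environment=environment,
        grid=grid,
        line=line,
        lower=line - half,
        upper=line + half,
        species_trait_values=Zt.copy(),
        species_responses=resp_centered,
        coefficient=coef,
        se=se,
        zero_crossing=crossing,
    )
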