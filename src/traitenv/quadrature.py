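"""Adaptive Gauss-Hermite integration of the random effects.

An independent, brute-force route to the marginal likelihood of the
trait-environment model, used to validate the Laplace approximation on
instances small enough to integrate numerically (no site effect, so species
factorize; a handful of plots).  Everything here is computed from first
principles - per-species linear predictors, Bernoulli log pmf, Gaussian
random-effect density - without touching the Laplace machinery.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import optimize, special, stats

from traitenv.glmm import FixedEffects, ModelData, ModelStructure, PriorSpec
from traitenv.preprocessing import ENVIRONMENTS, TRAITS


def _species_fixed_eta(fixed: FixedEffects, X: np.ndarray, Z_j: np.ndarray) -> np.ndarray:
    """Fixed-effect predictor for one species at every plot (length n)."""
    out = np.empty(X.shape[0])
    for i in range(X.shape[0]):
        eta = fixed.alpha
        for e in range(len(ENVIRONMENTS)):
            eta += fixed.beta1[e] * X[i, e]
            for t in range(len(TRAITS)):
                eta += fixed.beta12[t, e] * X[i, e] * Z_j[t]
        out[i] = eta
    return out


def _species_loglik(v: np.ndarray, eta0: np.ndarray, Xs: np.ndarray, y: np.ndarray,
                    mask: np.ndarray) -> float:
    """Bernoulli log likelihood of one species given its random effects v."""
    eta = eta0 + Xs @ v
    return float(np.sum(mask * (y * eta - np.logaddexp(0.0, eta))))


def marginal_loglik_gh(
    data: ModelData,
    fixed: FixedEffects,
    Sigma: np.ndarray,
    structure: ModelStructure | None = None,
    n_nodes: int = 20,
) -> float:
    """Marginal log likelihood with species random effects integrated by
    adaptive Gauss-Hermite quadrature.

    Requires a structure without a site effect, so the marginal likelihood
    factorizes over species:  log L = sum_j log Int N(v; 0, Sigma)
    prod_i Bernoulli(y_ij | eta_ij(v)) dv.  The grid is centered and scaled
    at each species' posterior mode (adaptive rule), which keeps a modest
    node count accurate.
    """
    structure = structure or ModelStructure(site_effect=False)
    if structure.site_effect:
        raise ValueError("quadrature route requires a structure without a site effect")
    d = structure.n_species_dims
    Sigma = np.asarray(Sigma, dtype=float)
    if Sigma.shape != (d, d):
        raise ValueError(f"Sigma must be {d} x {d}")
    Sigma_inv = np.linalg.inv(Sigma)
    _, logdet_Sigma = np.linalg.slogdet(Sigma)
    Xs = structure.species_design(data.X)

    nodes_1d, weights_1d = np.polynomial.hermite.hermgauss(n_nodes)
    log_w_1d = np.log(weights_1d)
    grids = list(itertools.product(range(n_nodes), repeat=d))
    Znodes = np.array([[nodes_1d[k] for k in combo] for combo in grids])
    log_w = np.array([sum(log_w_1d[k] for k in combo) for combo in grids])

    total = 0.0
    for j in range(data.m):
        eta0 = _species_fixed_eta(fixed, data.X, data.Z[j])
        y, mask = data.Y[:, j], data.mask[:, j]

        def neg_joint(v):
            return -(
                _species_loglik(v, eta0, Xs, y, mask)
                - 0.5 * (v @ Sigma_inv @ v + logdet_Sigma + d * np.log(2 * np.pi))
            )

        res = optimize.minimize(neg_joint, np.zeros(d), method="BFGS")
        mode = res.x
        # numerical Hessian of neg_joint at the mode
        H = _numerical_hessian(neg_joint, mode)
        C = np.linalg.inv(H)
        Lc = np.linalg.cholesky((C + C.T) / 2.0)
        # Int f(v) dv = 2^{d/2} |Lc| sum_k w_k exp(|z_k|^2) f(mode + sqrt2 Lc z_k)
        pts = mode[None, :] + np.sqrt(2.0) * Znodes @ Lc.T
        log_vals = np.array([-neg_joint(v) for v in pts])
        log_terms = log_w + np.sum(Znodes**2, axis=1) + log_vals
        total += (
            0.5 * d * np.log(2.0)
            + float(np.sum(np.log(np.diag(Lc))))
            + special.logsumexp(log_terms)
        )
    return total


def _numerical_hessian(f, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    d = x.size
    H = np.empty((d, d))
    for a in range(d):
        for b in range(a, d):
            ea = np.eye(d)[a] * h
            eb = np.eye(d)[b] * h
            H[a, b] = H[b, a] = (
                f(x + ea + eb) - f(x + ea - eb) - f(x - ea + eb) + f(x - ea - eb)
            ) / (4.0 * h * h)
    return H


def log_posterior_gh(
    params: np.ndarray,
    data: ModelData,
    priors: PriorSpec,
    structure: ModelStructure,
    n_nodes: int = 20,
) -> float:
    """Quadrature-based marginal log posterior over (fixed effects, log-chol Sigma)."""
    nb = 1 + len(ENVIRONMENTS) + len(TRAITS) * len(ENVIRONMENTS)
    beta = params[:nb]
    d = structure.n_species_dims
    L = np.zeros((d, d))
    L[np.tril_indices(d)] = params[nb:]
    L[np.diag_indices(d)] = np.exp(np.diag(L))
    Sigma = L @ L.T
    fixed = FixedEffects.unpack(beta)
    value = marginal_loglik_gh(data, fixed, Sigma, structure, n_nodes=n_nodes)
    value += float(np.sum(stats.norm.logpdf(beta, 0.0, priors.fixed_sd)))
    value += float(stats.invwishart.logpdf(Sigma, priors.wishart_df, priors.wishart_scale(d)))
    return value


def fit_map_gh(
    data: ModelData,
    priors: PriorSpec | None = None,
    structure: ModelStructure | None = None,
    n_nodes: int = 12,
    maxiter: int = 400,
):
    """Maximize the quadrature-integrated marginal posterior (oracle fit).

    Returns ``(FixedEffects, Sigma, optimize_result)``.  Only practical on
    tiny instances; serves as the reference for the Laplace-based fit.
    """
    priors = priors or PriorSpec()
    structure = structure or ModelStructure(site_effect=False)
    d = structure.n_species_dims
    nb = 1 + len(ENVIRONMENTS) + len(TRAITS) * len(ENVIRONMENTS)
    x0 = np.zeros(nb + d * (d + 1) // 2)

    def neg(params):
        return -log_posterior_gh(params, data, priors, structure, n_nodes=n_nodes)

    res = optimize.minimize(neg, x0, method="L-BFGS-B", options={"maxiter": maxiter})
    beta = res.x[:nb]
    L = np.zeros((d, d))
    L[np.tril_indices(d)] = res.x[nb:]
    L[np.diag_indices(d)] = np.exp(np.diag(L))
    return FixedEffects.unpack(beta), L @ L.T, res
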