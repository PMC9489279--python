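"""Gibbs/Metropolis sampler for the phylogenetic mixed model.

The liability model is ``l = X beta + sum_t Z_t u_t + e`` with
``u_t ~ N(0, sigma2_t K_t)`` (``K_phylo = A``, identity otherwise) and
``e ~ N(0, sigma2_e I)``.  The Gaussian response observes ``y = l``; the
binomial response observes ``k_i ~ Binomial(n_i, logistic(l_i))`` with the
liability latent.

Updates per sweep:

* binomial only: per-site random-walk Metropolis on the liabilities, with
  per-site step sizes adapted during burn-in towards 0.44 acceptance;
* joint multivariate-normal Gibbs draw of ``(beta, eta)`` given variances
  and working parameters, through the mixed-model equations (using the
  pre-computed ``A^-1``);
* parameter expansion: each random term is written ``u_t = alpha_t eta_t``
  with ``eta_t ~ N(0, sigma2_eta_t K_t)`` and a normal working parameter
  ``alpha_t ~ N(alpha_mu, alpha_V)``; ``alpha`` has a conjugate normal
  update and ``sigma2_eta_t`` a conjugate inverse-gamma (inverse-Wishart,
  dimension 1) update.  The reported variance component is
  ``sigma2_t = alpha_t^2 sigma2_eta_t``, whose implied prior is the scaled
  F distribution of the parameter-expanded prior family;
* conjugate inverse-gamma update of the residual variance (optionally held
  fixed, which is useful for binomial responses where the liability-scale
  residual is only weakly identified).

The per-draw conditional deviance ``D = -2 log p(y | liabilities/params)``
is stored for DIC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cholesky, cho_solve, solve_triangular
from scipy.special import gammaln

from .design import DesignBundle

logger = logging.getLogger(__name__)

__all__ = [
    "PriorSpec",
    "ChainSettings",
    "PosteriorSamples",
    "sample_posterior",
    "compute_dic",
]


@dataclass(frozen=True)
class PriorSpec:
    """Hyperparameters: diffuse normal fixed effects, parameter-expanded
    variance components, inverse-Wishart residual."""

    fixed_variance: float = 1e8
    px_V: float = 1.0
    px_nu: float = 1.0
    alpha_mu: float = 0.0
    alpha_V: float = 1000.0
    residual_V: float = 1.0
    residual_nu: float = 0.002

    def __post_init__(self):
        for name in ("fixed_variance", "px_V", "px_nu", "alpha_V", "residual_V", "residual_nu"):
            if getattr(self, name) <= 0:
                raise ValueError(f"prior hyperparameter {name} must be positive")


@dataclass(frozen=True)
class ChainSettings:
    """Single-chain MCMC settings; stored draws = (n_iterations - burn_in) / thin."""

    n_iterations: int = 50_000
    burn_in: int = 10_000
    thin: int = 20
    seed: int = 0

    def __post_init__(self):
        if self.burn_in >= self.n_iterations:
            raise ValueError("burn_in must be smaller than n_iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_stored(self) -> int:
        return (self.n_iterations - self.burn_in) // self.thin


@dataclass
class PosteriorSamples:
    """Stored MCMC draws plus the running quantities DIC needs."""

    fixed_names: list
    fixed_effects: np.ndarray  # (S, p)
    variance_components: dict  # term name -> (S,)
    residual_variance: np.ndarray  # (S,)
    deviance: np.ndarray  # (S,)
    latent_liabilities: np.ndarray | None  # (S, n), binomial only
    mean_fitted: np.ndarray  # (n,) running mean of X beta + Z u over stored draws
    meta: dict = field(default_factory=dict)

    @property
    def n_stored(self) -> int:
        return self.fixed_effects.shape[0]


def _binomial_loglik(ell: np.ndarray, y: np.ndarray, trials: np.ndarray) -> np.ndarray:
    """Per-observation log Binomial(y | trials, logistic(ell)), incl. constant."""
    const = gammaln(trials + 1) - gammaln(y + 1) - gammaln(trials - y + 1)
    return const - y * np.logaddexp(0.0, -ell) - (trials - y) * np.logaddexp(0.0, ell)


def binomial_deviance(ell: np.ndarray, y: np.ndarray, trials: np.ndarray) -> float:
    return float(-2.0 * _binomial_loglik(ell, y, trials).sum())


def gaussian_deviance(y: np.ndarray, mu: np.ndarray, sigma2_e: float) -> float:
    n = len(y)
    resid = y - mu
    return float(n * np.log(2.0 * np.pi * sigma2_e) + resid @ resid / sigma2_e)


def _sample_inverse_gamma(rng, shape: float, scale: float) -> float:
    return scale / rng.gamma(shape)


def sample_posterior(
    design: DesignBundle,
    priors: PriorSpec | None = None,
    chain: ChainSettings | None = None,
    fix_residual_variance: float | None = None,
) -> PosteriorSamples:
    """Run the Gibbs/Metropolis sampler; see the module docstring for the model."""
    priors = priors or PriorSpec()
    chain = chain or ChainSettings()
    rng = np.random.default_rng(chain.seed)

    X, y, trials = design.X, design.y, design.trials
    n, p = X.shape
    terms = design.terms
    T = len(terms)
    q = [t.n_levels for t in terms]
    Q = int(sum(q))
    binomial = design.spec.response == "binomial"

    W = np.hstack([X] + [t.Z for t in terms]) if T else X.copy()
    Gram = W.T @ W
    # block index ranges into theta = (beta, eta_1, ..., eta_T)
    edges = np.cumsum([p] + q)
    blocks = [(int(edges[i]), int(edges[i + 1])) for i in range(T)]
    dim = p + Q

    # --- initial state ---------------------------------------------------
    if binomial:
        ell = np.log((y + 0.5) / (trials - y + 0.5))
        r = ell.copy()
    else:
        r = y.copy()
    # ridge least squares start for beta
    beta = np.linalg.solve(X.T @ X + 1e-8 * np.eye(p), X.T @ r)
    eta = [np.zeros(k) for k in q]
    alpha = np.ones(T)
    sigma2_eta = np.ones(T)
    sigma2_e = fix_residual_variance if fix_residual_variance is not None else 1.0
    mu = X @ beta
    step = np.full(n, 1.0)  # MH proposal sd per site
    accept_count = np.zeros(n)
    accept_total = 0

    S = chain.n_stored
    store_beta = np.empty((S, p))
    store_var = {t.name: np.empty(S) for t in terms}
    store_res = np.empty(S)
    store_dev = np.empty(S)
    store_ell = np.empty((S, n)) if binomial else None
    fitted_sum = np.zeros(n)

    scale = np.ones(dim)
    stored = 0
    adapt_rate = 0.05

    for it in range(chain.n_iterations):
        # 1. latent liabilities (binomial)
        if binomial:
            prop = ell + step * rng.standard_normal(n)
            log_accept = (
                _binomial_loglik(prop, y, trials)
                - _binomial_loglik(ell, y, trials)
                - ((prop - mu) ** 2 - (ell - mu) ** 2) / (2.0 * sigma2_e)
            )
            accept = np.log(rng.random(n)) < log_accept
            ell = np.where(accept, prop, ell)
            if it < chain.burn_in:
                step *= np.exp(adapt_rate * (accept.astype(float) - 0.44))
            else:
                accept_count += accept
                accept_total += 1
            r = ell

        # 2. joint (beta, eta) given variances and alpha
        for i in range(T):
            scale[blocks[i][0] : blocks[i][1]] = alpha[i]
        C = Gram * np.outer(scale, scale) / sigma2_e
        idx = np.arange(p)
        C[idx, idx] += 1.0 / priors.fixed_variance
        for i, t in enumerate(terms):
            b0, b1 = blocks[i]
            C[b0:b1, b0:b1] += t.K_inv / sigma2_eta[i]
        rhs = scale * (W.T @ r) / sigma2_e
        try:
            L = cholesky(C, lower=True)
        except np.linalg.LinAlgError as exc:
            raise RuntimeError(f"non-positive-definite precision at iteration {it}") from exc
        m = cho_solve((L, True), rhs)
        theta = m + solve_triangular(L, rng.standard_normal(dim), lower=True, trans="T")
        beta = theta[:p]
        eta = [theta[b0:b1] for (b0, b1) in blocks]

        # 3. working parameters alpha (jointly)
        if T:
            M = np.column_stack([terms[i].Z @ eta[i] for i in range(T)])
            resid0 = r - X @ beta
            P_alpha = M.T @ M / sigma2_e + np.eye(T) / priors.alpha_V
            rhs_a = M.T @ resid0 / sigma2_e + priors.alpha_mu / priors.alpha_V
            La = cholesky(P_alpha, lower=True)
            ma = cho_solve((La, True), rhs_a)
            alpha = ma + solve_triangular(La, rng.standard_normal(T), lower=True, trans="T")
            mu = X @ beta + M @ alpha
        else:
            mu = X @ beta

        # 4. variance of the expanded effects (inverse-Wishart, dim 1)
        for i, t in enumerate(terms):
            quad = eta[i] @ t.K_inv @ eta[i]
            shape = (priors.px_nu + t.n_levels) / 2.0
            scale_ig = (priors.px_nu * priors.px_V + quad) / 2.0
            sigma2_eta[i] = _sample_inverse_gamma(rng, shape, scale_ig)

        # 5. residual variance
        if fix_residual_variance is None:
            resid = r - mu
            shape = (priors.residual_nu + n) / 2.0
            scale_ig = (priors.residual_nu * priors.residual_V + resid @ resid) / 2.0
            sigma2_e = _sample_inverse_gamma(rng, shape, scale_ig)

        # 6. store
        if it >= chain.burn_in and (it - chain.burn_in) % chain.thin == 0 and stored < S:
            if binomial:
                dev = binomial_deviance(ell, y, trials)
                store_ell[stored] = ell
            else:
                dev = gaussian_deviance(y, mu, sigma2_e)
            draw_ok = (
                np.all(np.isfinite(beta))
                and np.isfinite(dev)
                and np.isfinite(sigma2_e)
                and all(np.isfinite(a) for a in alpha)
            )
            if not draw_ok:
                raise RuntimeError(f"non-finite draw at iteration {it}; aborting")
            store_beta[stored] = beta
            for i, t in enumerate(terms):
                store_var[t.name][stored] = alpha[i] ** 2 * sigma2_eta[i]
            store_res[stored] = sigma2_e
            store_dev[stored] = dev
            fitted_sum += mu
            stored += 1

    meta = {
        "settings": {
            "n_iterations": chain.n_iterations,
            "burn_in": chain.burn_in,
            "thin": chain.thin,
            "seed": chain.seed,
        },
        "fix_residual_variance": fix_residual_variance,
        "response": design.spec.response,
    }
    if binomial and accept_total:
        meta["mh_acceptance_rate"] = float(accept_count.mean() / accept_total)

    return PosteriorSamples(
        fixed_names=list(design.fixed_names),
        fixed_effects=store_beta[:stored],
        variance_components={k: v[:stored] for k, v in store_var.items()},
        residual_variance=store_res[:stored],
        deviance=store_dev[:stored],
        latent_liabilities=store_ell[:stored] if binomial else None,
        mean_fitted=fitted_sum / max(stored, 1),
        meta=meta,
    )


def compute_dic(samples: PosteriorSamples, design: DesignBundle) -> float:
    """DIC = mean deviance + pD, with pD = mean(D) - D(theta_bar).

    ``theta_bar`` is the posterior mean of the liabilities (binomial) or of
    the fitted values and residual variance (Gaussian); the deviance is the
    conditional one stored per draw.
    """
    if samples.n_stored < 2:
        raise ValueError("DIC requires at least 2 stored draws")
    d_bar = float(samples.deviance.mean())
    if design.spec.response == "binomial":
        ell_bar = samples.latent_liabilities.mean(axis=0)
        d_hat = binomial_deviance(ell_bar, design.y, design.trials)
    else:
        mu_bar = samples.mean_fitted
        sigma2_bar = float(samples.residual_variance.mean())
        d_hat = gaussian_deviance(design.y, mu_bar, sigma2_bar)
    p_d = d_bar - d_hat
    return d_bar + p_d
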