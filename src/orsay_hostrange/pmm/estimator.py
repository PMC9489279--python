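"""Scikit-learn-style estimator wrapping the phylogenetic mixed model.

``PhylogeneticMixedModel`` follows the estimator conventions (constructor
stores hyperparameters, ``fit`` learns, fitted attributes carry a trailing
underscore, ``get_params``/``set_params`` work) so fits can be configured,
cloned and inspected uniformly.  It consumes a strain-level observation
table plus a relatedness structure rather than a feature matrix, so it is
not a drop-in transformer for sklearn pipelines; it is the fitting surface
the rest of the package builds on.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ..trees import RelatednessStructure
from .design import ModelSpec, build_design
from .diagnostics import heidelberger_welch
from .sampler import ChainSettings, PosteriorSamples, PriorSpec, compute_dic, sample_posterior
from .summary import FitSummary, summarize_fit

__all__ = ["PhylogeneticMixedModel"]


class PhylogeneticMixedModel(BaseEstimator):
    """Bayesian phylogenetic mixed model with a binomial or Gaussian response.

    Parameters
    ----------
    response : "binomial" or "gaussian"
        Binomial responses are per-strain counts (``n_infected`` of
        ``n_replicates``) on a logit liability scale; Gaussian responses
        read ``response_col`` directly.
    fixed : tuple of str
        Numeric covariate columns (intercept always included).
    random : tuple of str
        Subset of {"phylo", "species", "strain"}.
    priors : PriorSpec, optional
    n_iterations, burn_in, thin, seed : chain settings.
    fix_residual_variance : float, optional
        Hold the liability-scale residual variance fixed instead of
        sampling it (recommended for binomial fits, where it is only
        weakly identified).
    interval : "hpd" or "equal-tailed" credible intervals.
    """

    def __init__(
        self,
        response: str = "binomial",
        fixed: tuple = (),
        random: tuple = (),
        response_col: str = "score",
        priors: PriorSpec | None = None,
        n_iterations: int = 50_000,
        burn_in: int = 10_000,
        thin: int = 20,
        seed: int = 0,
        fix_residual_variance: float | None = None,
        interval: str = "hpd",
    ):
        self.response = response
        self.fixed = fixed
        self.random = random
        self.response_col = response_col
        self.priors = priors
        self.n_iterations = n_iterations
        self.burn_in = burn_in
        self.thin = thin
        self.seed = seed
        self.fix_residual_variance = fix_residual_variance
        self.interval = interval

    # ------------------------------------------------------------------
    def fit(self, data: pd.DataFrame, rel: RelatednessStructure | None = None):
        """Sample the posterior on ``data`` (strain-level observations)."""
        spec = ModelSpec(
            response=self.response,
            fixed=tuple(self.fixed),
            random=tuple(self.random),
            response_col=self.response_col,
        )
        chain = ChainSettings(
            n_iterations=self.n_iterations,
            burn_in=self.burn_in,
            thin=self.thin,
            seed=self.seed,
        )
        self.design_ = build_design(data, spec, rel)
        self.samples_ = sample_posterior(
            self.design_,
            priors=self.priors,
            chain=chain,
            fix_residual_variance=self.fix_residual_variance,
        )
        self.dic_ = compute_dic(self.samples_, self.design_)
        self.summary_ = summarize_fit(self.samples_, interval=self.interval)
        self.summary_.dic = self.dic_
        self._run_diagnostics()
        return self

    def _run_diagnostics(self):
        verdicts = {}
        for j, name in enumerate(self.samples_.fixed_names):
            verdicts[name] = heidelberger_welch(self.samples_.fixed_effects[:, j])
        verdicts["deviance"] = heidelberger_welch(self.samples_.deviance)
        self.stationarity_ = verdicts
        self.converged_ = all(v.passed for v in verdicts.values())
        self.summary_.converged = self.converged_
        self.summary_.diagnostics = {
            name: {"passed": v.passed, "pvalue": v.pvalue, "retained": v.retained_fraction}
            for name, v in verdicts.items()
        }

    # ------------------------------------------------------------------
    def predict(self, data: pd.DataFrame | None = None) -> np.ndarray:
        """Posterior-mean fitted values: probabilities (binomial) or scores.

        With no argument, returns fitted values for the training
        observations (including random effects, via the stored posterior
        mean of the linear predictor).  With new data, only fixed effects
        are used.
        """
        self._check_fitted()
        if data is None:
            eta = self.samples_.mean_fitted
            if self.response == "binomial":
                # average the per-draw probabilities, not the liabilities
                from scipy.special import expit

                return expit(self.samples_.latent_liabilities).mean(axis=0)
            return eta
        X = np.column_stack(
            [np.ones(len(data))] + [data[c].to_numpy(dtype=float) for c in self.fixed]
        )
        eta = X @ self.samples_.fixed_effects.mean(axis=0)
        if self.response == "binomial":
            from scipy.special import expit

            return expit(eta)
        return eta

    def posterior_draws(self) -> pd.DataFrame:
        """Tidy frame: one row per stored draw, one column per parameter."""
        self._check_fitted()
        frame = pd.DataFrame(
            self.samples_.fixed_effects, columns=list(self.samples_.fixed_names)
        )
        for name, draws in self.samples_.variance_components.items():
            frame[f"var_{name}"] = draws
        frame["var_residual"] = self.samples_.residual_variance
        frame["deviance"] = self.samples_.deviance
        return frame

    def _check_fitted(self):
        if not hasattr(self, "samples_"):
            raise RuntimeError("model is not fitted; call fit() first")
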