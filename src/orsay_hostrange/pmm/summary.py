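"""Posterior summaries: means, 95% HPD intervals, pMCMC."""

from __future__ import annotations

from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd

from .sampler import PosteriorSamples

__all__ = ["FitSummary", "summarize_fit", "pmcmc"]

MIN_DRAWS = 100


def pmcmc(draws: np.ndarray) -> float:
    """Two-sided MCMC tail probability that the effect crosses zero.

    ``2 * max(1, min(#draws > 0, #draws < 0)) / S``, capped at 1 -- the
    convention never returns exactly zero however one-sided the posterior.
    """
    draws = np.asarray(draws)
    s = len(draws)
    n_pos = int((draws > 0).sum())
    n_neg = int((draws < 0).sum())
    return min(1.0, 2.0 * max(1, min(n_pos, n_neg)) / s)


def _hpd(draws: np.ndarray, level: float) -> tuple[float, float]:
    lo, hi = az.hdi(np.asarray(draws, dtype=float), hdi_prob=level)
    return float(lo), float(hi)


def _equal_tailed(draws: np.ndarray, level: float) -> tuple[float, float]:
    a = (1 - level) / 2
    lo, hi = np.quantile(draws, [a, 1 - a])
    return float(lo), float(hi)


@dataclass
class FitSummary:
    """Per-term posterior summaries of one fitted model."""

    fixed: pd.DataFrame  # mean, ci_low, ci_high, pmcmc (index: term)
    variances: pd.DataFrame  # mean, ci_low, ci_high (index: term incl. residual)
    dic: float | None = None
    converged: bool | None = None
    diagnostics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "fixed": self.fixed.to_dict(orient="index"),
            "variances": self.variances.to_dict(orient="index"),
            "dic": self.dic,
            "converged": self.converged,
            "diagnostics": self.diagnostics,
        }


def summarize_fit(
    samples: PosteriorSamples,
    level: float = 0.95,
    interval: str = "hpd",
) -> FitSummary:
    """Posterior mean, ``level`` credible interval and pMCMC per fixed term,
    plus interval summaries of every variance component.

    Intervals are highest-posterior-density by default (the convention for
    these models, robust to the skew of variance posteriors); pass
    ``interval="equal-tailed"`` for quantile intervals.
    """
    if samples.n_stored < MIN_DRAWS:
        raise ValueError(
            f"need at least {MIN_DRAWS} stored draws to summarize, "
            f"got {samples.n_stored}"
        )
    ci = _hpd if interval == "hpd" else _equal_tailed

    fixed_rows = {}
    for j, name in enumerate(samples.fixed_names):
        draws = samples.fixed_effects[:, j]
        lo, hi = ci(draws, level)
        fixed_rows[name] = {
            "mean": float(draws.mean()),
            "ci_low": lo,
            "ci_high": hi,
            "pmcmc": pmcmc(draws),
        }

    var_rows = {}
    for name, draws in samples.variance_components.items():
        lo, hi = ci(draws, level)
        var_rows[name] = {"mean": float(np.mean(draws)), "ci_low": lo, "ci_high": hi}
    res = samples.residual_variance
    lo, hi = ci(res, level)
    var_rows["residual"] = {"mean": float(res.mean()), "ci_low": lo, "ci_high": hi}

    return FitSummary(
        fixed=pd.DataFrame.from_dict(fixed_rows, orient="index"),
        variances=pd.DataFrame.from_dict(var_rows, orient="index"),
    )
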