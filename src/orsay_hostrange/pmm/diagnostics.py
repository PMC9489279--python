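"""Heidelberger & Welch stationarity diagnostic for a single MCMC chain.

The test applies a Cramér–von Mises statistic to the Brownian-bridge
transform of the cumulative sums of the chain, using a spectral-density-at-
zero estimate of the long-run variance (from an AIC-selected AR fit on the
second half of the chain).  If the full chain fails, successive 10%
prefixes are discarded (up to 50%) and the test repeated; the verdict
reports the fraction retained.  The statistic is scale-free, so the verdict
is invariant to affine transformations of the chain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gamma as gamma_fn
from scipy.special import kv
from statsmodels.regression.linear_model import yule_walker

__all__ = ["StationarityResult", "heidelberger_welch", "cramer_von_mises_cdf"]

MIN_DRAWS = 100


@dataclass
class StationarityResult:
    passed: bool
    start_fraction: float  # fraction of the chain discarded from the front
    retained_fraction: float
    pvalue: float
    statistic: float
    message: str = ""


def cramer_von_mises_cdf(q: float, eps: float = 1e-5) -> float:
    """Asymptotic CDF of the Cramér–von Mises statistic (series with Bessel K)."""
    if q <= 0:
        return 0.0
    total = 0.0
    for k in range(4):
        z = gamma_fn(k + 0.5) * np.sqrt(4 * k + 1) / (
            gamma_fn(k + 1) * np.pi ** 1.5 * np.sqrt(q)
        )
        u = (4 * k + 1) ** 2 / (16.0 * q)
        if u <= -np.log(eps):
            total += z * np.exp(-u) * kv(0.25, u)
    return float(min(max(total, 0.0), 1.0))


def _spectral_density_zero(x: np.ndarray, max_order: int | None = None) -> float:
    """Spectral density at frequency zero via an AIC-selected AR fit."""
    n = len(x)
    if np.allclose(x, x[0]):
        return 0.0
    # A chain that is (numerically) a deterministic linear trend has no
    # stochastic long-run variance; treat it as degenerate.
    t = np.arange(n, dtype=float)
    coef = np.polyfit(t, x, 1)
    resid = x - np.polyval(coef, t)
    if np.std(resid) <= 1e-10 * max(np.std(x), 1e-300):
        return 0.0
    if max_order is None:
        max_order = int(min(n - 2, 10 * np.log10(n)))
    best = None
    xc = x - x.mean()
    for order in range(max_order + 1):
        if order == 0:
            sigma2 = float(np.var(xc))
            rho_sum = 0.0
        else:
            try:
                rho, sigma = yule_walker(xc, order=order, method="mle")
            except np.linalg.LinAlgError:
                continue
            sigma2 = float(sigma**2)
            rho_sum = float(np.sum(rho))
        if sigma2 <= 0 or abs(1 - rho_sum) < 1e-10:
            continue
        aic = n * np.log(sigma2) + 2.0 * order
        if best is None or aic < best[0]:
            best = (aic, sigma2 / (1.0 - rho_sum) ** 2)
    if best is None:
        return 0.0
    return best[1]


def heidelberger_welch(draws, alpha: float = 0.05) -> StationarityResult:
    """Iterative stationarity test on one chain of draws.

    Returns pass/fail, the fraction of the chain retained, and the
    Cramér–von Mises p-value of the retained portion.  A (near-)constant
    chain fails outright: its long-run variance is zero and stationarity of
    a degenerate chain carries no evidence of mixing.
    """
    x = np.asarray(draws, dtype=float).ravel()
    n = len(x)
    if n < MIN_DRAWS:
        raise ValueError(f"need at least {MIN_DRAWS} draws, got {n}")
    s0 = _spectral_density_zero(x[n // 2 :])
    if s0 <= 0:
        return StationarityResult(
            passed=False,
            start_fraction=0.0,
            retained_fraction=1.0,
            pvalue=0.0,
            statistic=np.inf,
            message=(
                "degenerate chain (constant or deterministic trend): "
                "zero spectral density at frequency 0"
            ),
        )
    for start_fraction in (0.0, 0.1, 0.2, 0.3, 0.4, 0.5):
        seg = x[int(start_fraction * n) :]
        m = len(seg)
        csum = np.cumsum(seg)
        mean = seg.mean()
        k = np.arange(1, m + 1)
        bridge = (csum - k * mean) / np.sqrt(m * s0)
        statistic = float(np.sum(bridge**2) / m)
        pvalue = 1.0 - cramer_von_mises_cdf(statistic)
        if pvalue > alpha:
            return StationarityResult(
                passed=True,
                start_fraction=start_fraction,
                retained_fraction=1.0 - start_fraction,
                pvalue=pvalue,
                statistic=statistic,
            )
    return StationarityResult(
        passed=False,
        start_fraction=0.5,
        retained_fraction=0.5,
        pvalue=pvalue,
        statistic=statistic,
        message="stationarity rejected even after discarding half the chain",
    )
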