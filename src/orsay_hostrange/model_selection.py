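"""DIC-based model comparison and per-draw variance decomposition.

Models within a suite are compared on the deviance information criterion.
With ``Delta_m = DIC_m - min_j DIC_j``, the evidence weight of model *m* is

    w_m = exp(-Delta_m / 2) / sum_j exp(-Delta_j / 2)

and the weight of a model *component* (a fixed or random term) is the sum
of w_m over the models whose formula contains that term -- interpretable as
the posterior probability that the component belongs in the "true" model,
assuming the true model is in the suite.  Weights are computed in log space
for numerical safety at large Delta.

``r_squared`` decomposes a fitted model's variance per posterior draw:
each fixed term contributes the population variance of its linear
contribution over the observed design rows, each random term its variance
component draw, the residual its variance draw; shares are normalised to
sum to one within each draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

__all__ = [
    "ModelEntry",
    "ModelSet",
    "dic_weights",
    "component_weight",
    "any_of_components_weight",
    "variance_shares",
    "r_squared",
]


@dataclass(frozen=True)
class ModelEntry:
    """One candidate model: a formula (term sets) and its DIC (or ΔDIC)."""

    model_id: str
    fixed: frozenset
    random: frozenset
    dic: float

    @property
    def terms(self) -> frozenset:
        return self.fixed | self.random


@dataclass
class ModelSet:
    entries: list[ModelEntry]
    is_delta: bool = False  # dic fields hold pre-computed ΔDIC

    def __post_init__(self):
        if not self.entries:
            raise ValueError("empty model set")
        ids = [e.model_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate model ids in {ids}")
        formulas = [(e.fixed, e.random) for e in self.entries]
        if len(set(formulas)) != len(formulas):
            raise ValueError("model formulas must be distinct")
        if not all(np.isfinite(e.dic) for e in self.entries):
            raise ValueError("non-finite DIC value in model set")

    @classmethod
    def from_records(cls, records, is_delta: bool = False) -> "ModelSet":
        """records: iterable of (model_id, fixed terms, random terms, dic)."""
        entries = [
            ModelEntry(str(mid), frozenset(fx), frozenset(rd), float(d))
            for mid, fx, rd, d in records
        ]
        return cls(entries=entries, is_delta=is_delta)

    @property
    def known_terms(self) -> set:
        return set().union(*(e.terms for e in self.entries))


def dic_weights(models: ModelSet) -> pd.DataFrame:
    """Per-model ΔDIC and normalized evidence weights.

    Returns a DataFrame indexed by model_id with columns ``delta`` and
    ``weight``; weights sum to 1 within 1e-12 and only differences in DIC
    matter.
    """
    dics = np.array([e.dic for e in models.entries])
    delta = dics if models.is_delta else dics - dics.min()
    delta = delta - delta.min()  # guard pre-computed deltas not anchored at 0
    loglik = -delta / 2.0
    weights = np.exp(loglik - logsumexp(loglik))
    return pd.DataFrame(
        {"delta": delta, "weight": weights},
        index=pd.Index([e.model_id for e in models.entries], name="model_id"),
    )


def _check_components(models: ModelSet, components) -> None:
    unknown = set(components) - models.known_terms
    if unknown:
        raise ValueError(
            f"unknown model component(s) {sorted(unknown)}; known terms: "
            f"{sorted(models.known_terms)}"
        )


def component_weight(models: ModelSet, weights: pd.DataFrame, component: str) -> float:
    """Summed weight of the models whose formula contains ``component``."""
    _check_components(models, [component])
    total = 0.0
    for entry in models.entries:
        if component in entry.terms:
            total += float(weights.loc[entry.model_id, "weight"])
    return total


def any_of_components_weight(models: ModelSet, weights: pd.DataFrame, components) -> float:
    """Summed weight of models containing at least one of ``components``."""
    components = set(components)
    if not components:
        raise ValueError("components set is empty")
    _check_components(models, components)
    total = 0.0
    for entry in models.entries:
        if entry.terms & components:
            total += float(weights.loc[entry.model_id, "weight"])
    return total


def variance_shares(samples, design) -> pd.DataFrame:
    """Per-draw variance share of every model component (rows = draws).

    A non-intercept fixed term *j* contributes ``Var_n(x_j * beta_js)``
    (population variance over the observed design rows); each random term
    its variance-component draw; the residual its variance draw.  Shares
    are normalised within each draw, so every row sums to exactly one.
    Draws whose total variance is zero are dropped with a warning.
    """
    X = design.X
    names = design.fixed_names
    beta = samples.fixed_effects  # (S, p)
    contributions: dict[str, np.ndarray] = {}
    for j, name in enumerate(names):
        if name == "intercept":
            continue
        col = X[:, j]
        contributions[name] = np.var(col) * beta[:, j] ** 2
    for name, draws in samples.variance_components.items():
        contributions[name] = np.asarray(draws, dtype=float)
    contributions["residual"] = np.asarray(samples.residual_variance, dtype=float)

    comp_names = list(contributions)
    mat = np.vstack([contributions[name] for name in comp_names])  # (C, S)
    totals = mat.sum(axis=0)
    keep = totals > 0
    n_skipped = int((~keep).sum())
    if n_skipped:
        import logging

        logging.getLogger(__name__).warning(
            "variance_shares: skipped %d draws with zero total variance", n_skipped
        )
    if not keep.any():
        raise ValueError("all draws have zero total variance")
    shares = mat[:, keep] / totals[keep]
    return pd.DataFrame(shares.T, columns=comp_names)


def r_squared(samples, design, level: float = 0.95) -> pd.DataFrame:
    """Posterior mean and central ``level`` interval of each component's R².

    R² of a component is its per-draw variance share (see
    :func:`variance_shares`).
    """
    shares = variance_shares(samples, design)
    lo = (1 - level) / 2
    rows = []
    for name in shares.columns:
        qs = np.quantile(shares[name], [lo, 1 - lo])
        rows.append(
            {
                "component": name,
                "r2_mean": float(shares[name].mean()),
                "ci_low": float(qs[0]),
                "ci_high": float(qs[1]),
            }
        )
    return pd.DataFrame(rows).set_index("component")
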