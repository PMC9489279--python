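"""Design construction for phylogenetic mixed models.

Observations are strain-level units.  The liability model is

    l = X beta + sum_t Z_t u_t + e

with ``u_phylo ~ N(0, sigma2_p A)`` over species (A the tip-pair MRCA-depth
matrix), ``u_species ~ N(0, sigma2_s I)``, ``u_strain ~ N(0, sigma2_st I)``
and ``e ~ N(0, sigma2_e I)``.  For the binomial response the liability is
latent and ``k_i ~ Binomial(n_i, logistic(l_i))``; for the Gaussian response
the score is the liability itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..trees import RelatednessStructure

logger = logging.getLogger(__name__)

__all__ = ["ModelSpec", "RandomTerm", "DesignBundle", "build_design"]

RANDOM_TERM_NAMES = ("phylo", "species", "strain")


@dataclass(frozen=True)
class ModelSpec:
    """Formula of one candidate model.

    ``fixed`` lists numeric covariate columns (the intercept is always
    included and never listed); ``random`` is a subset of
    ``{"phylo", "species", "strain"}``.  For the binomial response the data
    must carry ``n_infected`` and ``n_replicates`` columns; for the Gaussian
    response, ``response_col`` (default ``"score"``).
    """

    response: str  # "binomial" | "gaussian"
    fixed: tuple = ()
    random: tuple = ()
    response_col: str = "score"

    def __post_init__(self):
        if self.response not in ("binomial", "gaussian"):
            raise ValueError(f"response must be binomial or gaussian, got {self.response!r}")
        unknown = set(self.random) - set(RANDOM_TERM_NAMES)
        if unknown:
            raise ValueError(
                f"unknown random terms {sorted(unknown)}; allowed: {RANDOM_TERM_NAMES}"
            )

    @property
    def link(self) -> str:
        return "logit" if self.response == "binomial" else "identity"


@dataclass
class RandomTerm:
    """One random-effect term: incidence matrix plus covariance structure.

    ``K_inv`` is the precision structure of the effects (A^-1 for the
    phylogenetic term, identity otherwise), up to the variance component.
    """

    name: str
    levels: list
    Z: np.ndarray
    K_inv: np.ndarray

    @property
    def n_levels(self) -> int:
        return len(self.levels)


@dataclass
class DesignBundle:
    spec: ModelSpec
    X: np.ndarray
    fixed_names: list
    y: np.ndarray
    trials: np.ndarray | None  # binomial totals, None for gaussian
    terms: list  # list[RandomTerm]
    n: int
    data: pd.DataFrame = field(repr=False, default=None)

    def linear_predictor(self, beta: np.ndarray, effects: dict | None = None) -> np.ndarray:
        """X beta plus any supplied random-term effect vectors (by name)."""
        eta = self.X @ np.asarray(beta, dtype=float)
        if effects:
            for term in self.terms:
                if term.name in effects:
                    eta = eta + term.Z @ np.asarray(effects[term.name], dtype=float)
        return eta


def _incidence(values: pd.Series, levels: list) -> np.ndarray:
    index = {lv: i for i, lv in enumerate(levels)}
    Z = np.zeros((len(values), len(levels)))
    for row, value in enumerate(values):
        Z[row, index[value]] = 1.0
    return Z


def build_design(
    data: pd.DataFrame,
    spec: ModelSpec,
    rel: RelatednessStructure | None = None,
) -> DesignBundle:
    """Assemble response, fixed design matrix and random-term incidences.

    Every observation's species must be a tip of ``rel`` when a phylogenetic
    term is requested (observations on unplaced species are expected to have
    been dropped upstream -- see :func:`drop_unplaced_species`).
    """
    data = data.reset_index(drop=True)
    n = len(data)
    if n == 0:
        raise ValueError("empty observation table")

    cols = [np.ones(n)]
    names = ["intercept"]
    for cov in spec.fixed:
        if cov not in data.columns:
            raise ValueError(f"fixed covariate {cov!r} not in data columns {list(data.columns)}")
        col = data[cov].to_numpy(dtype=float)
        if not np.all(np.isfinite(col)):
            raise ValueError(f"fixed covariate {cov!r} contains non-finite values")
        if np.var(col) == 0:
            logger.warning("fixed covariate %r has zero variance", cov)
        cols.append(col)
        names.append(cov)
    X = np.column_stack(cols)

    if spec.response == "binomial":
        for c in ("n_infected", "n_replicates"):
            if c not in data.columns:
                raise ValueError(f"binomial response requires column {c!r}")
        y = data["n_infected"].to_numpy(dtype=float)
        trials = data["n_replicates"].to_numpy(dtype=float)
        if np.any(trials < 1):
            raise ValueError("binomial trials must be >= 1")
        if np.any((y < 0) | (y > trials)):
            raise ValueError("n_infected must lie in [0, n_replicates]")
    else:
        if spec.response_col not in data.columns:
            raise ValueError(f"gaussian response requires column {spec.response_col!r}")
        y = data[spec.response_col].to_numpy(dtype=float)
        if not np.all(np.isfinite(y)):
            raise ValueError("gaussian response contains non-finite values")
        trials = None

    terms = []
    for name in spec.random:
        if name == "phylo":
            if rel is None:
                raise ValueError("phylo random term requires a RelatednessStructure")
            missing = sorted(set(data["species"]) - set(rel.taxon_order))
            if missing:
                raise ValueError(
                    f"species not on the tree: {missing}; prune the observations "
                    "first (drop_unplaced_species)"
                )
            levels = list(rel.taxon_order)
            Z = _incidence(data["species"], levels)
            K_inv = rel.A_inv
        elif name == "species":
            levels = list(dict.fromkeys(data["species"]))
            Z = _incidence(data["species"], levels)
            K_inv = np.eye(len(levels))
        else:  # strain
            levels = list(dict.fromkeys(data["strain"]))
            Z = _incidence(data["strain"], levels)
            K_inv = np.eye(len(levels))
        terms.append(RandomTerm(name=name, levels=levels, Z=Z, K_inv=K_inv))

    return DesignBundle(
        spec=spec, X=X, fixed_names=names, y=y, trials=trials, terms=terms, n=n, data=data
    )


def drop_unplaced_species(data: pd.DataFrame, rel: RelatednessStructure) -> pd.DataFrame:
    """Drop observations whose species is not a tip of the phylogeny.

    A species without a position on the tree has no defined focal distance
    or covariance with other species, so it cannot enter a phylogenetic
    model; exclusions are logged so the loss of information is visible.
    """
    placed = data["species"].isin(rel.taxon_order)
    if (~placed).any():
        dropped = sorted(set(data.loc[~placed, "species"]))
        logger.warning(
            "dropping %d observations from %d species without phylogenetic "
            "placement: %s",
            int((~placed).sum()),
            len(dropped),
            dropped,
        )
    return data[placed].reset_index(drop=True)
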