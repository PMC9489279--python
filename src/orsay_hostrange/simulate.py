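"""Synthetic data with the statistical structure the analysis assumes.

Generates every input the pipeline consumes: an ultrametric species tree
(pure-birth, rescaled to height 1), strain-level susceptibility counts from
a logit liability model with a distance-from-focal-host fixed effect and
phylogenetic + species random effects, a blocked qPCR Ct table with the
control/benchmark roles of the assay design, and serial-passage
trajectories whose per-passage persistence depends on viral amplification
(Ct) in the primary exposure population.

Default parameters mirror the assay design being emulated: 44 species with
one to three strains each (84 strains in the real panel), three replicate
populations per strain, eight experimental blocks, benchmark/control Ct
moments (benchmark 4: 38.4 +/- 2.6, benchmark 5: 22.0 +/- 0.6, positive
controls 15.7 +/- 2.0 and 12.7 +/- 2.2), and non-detections at Ct 40.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .assays import CtTable, PassageTrajectory
from .trees import UltrametricTree, distance_from_focal, parse_newick, relatedness_matrix

__all__ = [
    "SimulationConfig",
    "simulate_yule_tree",
    "simulate_susceptibility",
    "simulate_ct_assay",
    "simulate_passage_trajectories",
]


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generators, with assay-design defaults."""

    seed: int = 0
    n_species: int = 44
    birth_rate: float = 1.0
    strains_per_species: tuple = (1, 3)  # inclusive range; int also accepted
    replicates_per_strain: int = 3
    n_blocks: int = 8
    # liability model truth (height-1 tree scale)
    true_beta0: float = 0.5
    true_beta1: float = -2.0
    sigma2_phylo: float = 1.0
    sigma2_species: float = 0.5
    sigma2_residual: float = 1.0
    # per-role Ct moments (mean, sd)
    ct_params: dict = field(
        default_factory=lambda: {
            "infected": (20.0, 4.0),
            "uninfected": (38.4, 2.6),  # carry-over regime of benchmark 4
            "control2_N2": (15.7, 2.0),
            "control3_JU1580": (12.7, 2.2),
            "benchmark4": (38.4, 2.6),
            "benchmark5": (22.0, 0.6),
        }
    )
    undetected_ct: float = 40.0
    # passage persistence: p = logistic(a - ct_slope * (ct0 - 20)),
    # a = logit(1 - baseline_loss_prob)
    baseline_loss_prob: float = 0.3
    ct_slope: float = 0.25

    def __post_init__(self):
        for name in ("sigma2_phylo", "sigma2_species", "sigma2_residual"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.baseline_loss_prob <= 1:
            raise ValueError("baseline_loss_prob must be a probability")

    def strain_range(self) -> tuple[int, int]:
        s = self.strains_per_species
        if isinstance(s, int):
            return (s, s)
        lo, hi = s
        return int(lo), int(hi)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["ct_params"] = {k: list(v) for k, v in self.ct_params.items()}
        return d


# ----------------------------------------------------------------------
def simulate_yule_tree(n_species: int, birth_rate: float = 1.0, seed: int = 0) -> UltrametricTree:
    """Pure-birth ultrametric tree on ``n_species`` tips, rescaled to height 1.

    Deterministic given the seed; tips are labelled ``s1..sN`` in Newick
    appearance order.
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    rng = np.random.default_rng(seed)
    # Each active lineage is a (children, birth_time) pair; the root splits
    # at time 0 into two lineages.
    next_id = [0]

    def new_node(birth):
        next_id[0] += 1
        return {"id": next_id[0], "birth": birth, "children": []}

    t = 0.0
    root = {"id": 0, "birth": 0.0, "children": [new_node(0.0), new_node(0.0)]}
    active = list(root["children"])
    while len(active) < n_species:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        parent = active.pop(rng.integers(len(active)))
        parent["split"] = t
        kids = [new_node(t), new_node(t)]
        parent["children"] = kids
        active.extend(kids)
    t += rng.exponential(1.0 / (birth_rate * len(active)))
    height = t

    label_counter = [0]

    def newick_node(node) -> str:
        if not node["children"]:
            label_counter[0] += 1
            length = (height - node["birth"]) / height
            return f"s{label_counter[0]}:{length:.12f}"
        parts = ",".join(newick_node(c) for c in node["children"])
        length = (node["split"] - node["birth"]) / height
        return f"({parts}):{length:.12f}"

    parts = ",".join(newick_node(c) for c in root["children"])
    return parse_newick(f"({parts});")


# ----------------------------------------------------------------------
def simulate_susceptibility(
    tree: UltrametricTree,
    config: SimulationConfig,
    focal: str | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Strain-level susceptibility counts under the liability model.

    Per strain: liability ``l = beta0 + beta1 * d + u_phylo[sp] +
    u_species[sp] + e`` and ``k ~ Binomial(n_replicates, logistic(l))``,
    where ``d`` is the species' cophenetic distance from the focal host,
    ``u_phylo ~ N(0, sigma2_phylo A)`` and ``u_species`` i.i.d.  Returns
    the observation table and a truth record (parameters plus the drawn
    effects and liabilities).
    """
    rng = np.random.default_rng(config.seed + 1)
    focal = focal or tree.taxa[0]
    rel = relatedness_matrix(tree)
    dvec = distance_from_focal(tree, focal)
    species = list(tree.taxa)
    n_sp = len(species)

    if config.sigma2_phylo > 0:
        chol = np.linalg.cholesky(
            config.sigma2_phylo * rel.A + 1e-12 * rel.height * np.eye(n_sp)
        )
        u_phylo = chol @ rng.standard_normal(n_sp)
    else:
        u_phylo = np.zeros(n_sp)
    u_species = np.sqrt(config.sigma2_species) * rng.standard_normal(n_sp)

    lo, hi = config.strain_range()
    rows = []
    liabilities = {}
    for i, sp in enumerate(species):
        n_strains = int(rng.integers(lo, hi + 1))
        for s in range(n_strains):
            strain = f"{sp}_st{s + 1}"
            e = np.sqrt(config.sigma2_residual) * rng.standard_normal()
            liab = (
                config.true_beta0
                + config.true_beta1 * dvec.distances[sp]
                + u_phylo[i]
                + u_species[i]
                + e
            )
            k = int(rng.binomial(config.replicates_per_strain, expit(liab)))
            liabilities[strain] = float(liab)
            rows.append(
                {
                    "species": sp,
                    "strain": strain,
                    "focal_distance": dvec.distances[sp],
                    "n_infected": k,
                    "n_replicates": config.replicates_per_strain,
                }
            )
    obs = pd.DataFrame(rows)
    truth = {
        "config": config.to_dict(),
        "focal": focal,
        "beta0": config.true_beta0,
        "beta1": config.true_beta1,
        "sigma2_phylo": config.sigma2_phylo,
        "sigma2_species": config.sigma2_species,
        "sigma2_residual": config.sigma2_residual,
        "u_phylo": {sp: float(u) for sp, u in zip(species, u_phylo)},
        "u_species": {sp: float(u) for sp, u in zip(species, u_species)},
        "liability": liabilities,
    }
    return obs, truth


def _draw_truncated_ct(rng, mean: float, sd: float, size: int) -> np.ndarray:
    """Normal draws clipped into (0, 40) by resampling the lower tail and
    treating the upper tail as given (callers decide about >= 40)."""
    draws = rng.normal(mean, sd, size=size)
    for _ in range(100):
        bad = draws <= 0
        if not bad.any():
            break
        draws[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    return draws


def simulate_ct_assay(observations: pd.DataFrame, config: SimulationConfig) -> CtTable:
    """Blocked qPCR Ct table for the given strain-level infection counts.

    The first ``n_infected`` replicates of each strain draw Ct from the
    infected regime; the rest from the uninfected (carry-over) regime, with
    draws at or beyond 40 cycles recorded as undetected.  Controls and
    benchmarks are emitted in triplicate per block: a water-exposed negative
    control (undetected), two positive controls and the two threshold
    benchmarks at their configured moments.
    """
    rng = np.random.default_rng(config.seed + 2)
    required = {"species", "strain", "n_infected", "n_replicates"}
    missing = required - set(observations.columns)
    if missing:
        raise ValueError(f"observations missing columns {sorted(missing)}")
    for role, (mean, sd) in config.ct_params.items():
        if sd < 0 or mean <= 0:
            raise ValueError(f"invalid Ct moments for {role}: ({mean}, {sd})")

    rows = []
    blocks_used = set()
    for idx, rec in observations.reset_index(drop=True).iterrows():
        block = (idx % config.n_blocks) + 1
        blocks_used.add(block)
        n_rep = int(rec["n_replicates"])
        n_inf = int(rec["n_infected"])
        mean_i, sd_i = config.ct_params["infected"]
        mean_u, sd_u = config.ct_params["uninfected"]
        for rep in range(1, n_rep + 1):
            infected = rep <= n_inf
            mean, sd = (mean_i, sd_i) if infected else (mean_u, sd_u)
            ct = float(_draw_truncated_ct(rng, mean, sd, 1)[0])
            rows.append(
                {
                    "strain": rec["strain"],
                    "species": rec["species"],
                    "block": block,
                    "replicate": rep,
                    "role": "experimental",
                    "ct": np.nan if ct >= config.undetected_ct else ct,
                }
            )
    role_specs = [
        ("control1_neg", None),
        ("control2_N2", config.ct_params["control2_N2"]),
        ("control3_JU1580", config.ct_params["control3_JU1580"]),
        ("benchmark4", config.ct_params["benchmark4"]),
        ("benchmark5", config.ct_params["benchmark5"]),
    ]
    for block in sorted(blocks_used):
        for role, moments in role_specs:
            for rep in range(1, 4):
                if moments is None:
                    ct = np.nan  # water control: no template
                else:
                    mean, sd = moments
                    val = float(_draw_truncated_ct(rng, mean, sd, 1)[0])
                    ct = np.nan if val >= config.undetected_ct else val
                rows.append(
                    {
                        "strain": role,
                        "species": "C. elegans",
                        "block": block,
                        "replicate": rep,
                        "role": role,
                        "ct": ct,
                    }
                )
    return CtTable(records=pd.DataFrame(rows), undetected_ct=config.undetected_ct)


# ----------------------------------------------------------------------
def simulate_passage_trajectories(
    lines: pd.DataFrame,
    config: SimulationConfig,
    tau: float,
) -> list[PassageTrajectory]:
    """Serial-passage detection trajectories for exposed replicate lines.

    ``lines`` needs columns line_id, strain, passage0_ct (NaN = undetected).
    Detection at passage 0 requires ``Ct < tau``; thereafter the virus
    persists each passage with probability
    ``logistic(logit(1 - baseline_loss_prob) - ct_slope * (ct0 - 20))`` --
    lines with less amplification at exposure (higher Ct) lose the virus
    sooner.  Trajectories stop at the first loss; six passages maximum.
    """
    rng = np.random.default_rng(config.seed + 3)
    a = logit(1.0 - config.baseline_loss_prob)
    trajectories = []
    for rec in lines.to_dict(orient="records"):
        ct0 = rec.get("passage0_ct")
        ct0 = None if ct0 is None or (isinstance(ct0, float) and np.isnan(ct0)) else float(ct0)
        detected0 = ct0 is not None and ct0 < tau
        detections = [detected0]
        if detected0:
            p_persist = float(expit(a - config.ct_slope * (ct0 - 20.0)))
            for _ in range(5):
                if rng.random() < p_persist:
                    detections.append(True)
                else:
                    detections.append(False)
                    break
        trajectories.append(
            PassageTrajectory(
                line_id=str(rec["line_id"]),
                strain=str(rec["strain"]),
                species=str(rec.get("species")) if rec.get("species") is not None else None,
                detections=detections,
                passage0_ct=ct0,
            )
        )
    return trajectories


def write_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
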