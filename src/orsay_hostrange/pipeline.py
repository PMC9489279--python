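"""End-to-end orchestration of the host-range analysis.

One call reproduces the full analysis from a config: susceptibility calls
from a Ct table against a benchmark-derived threshold, transmission scores
from passage trajectories, two suites of phylogenetic mixed models (a
binomial-logit suite for susceptibility, a Gaussian suite for transmission
scores), DIC weight tables, component weights, and an R² variance
decomposition of each suite's best model.  Inputs are either paths to
existing files or a simulation config, in which case every input is
generated first.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assays, model_selection, simulate, trees
from .pmm import PhylogeneticMixedModel, drop_unplaced_species

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "SUSCEPTIBILITY_SUITE",
    "TRANSMISSION_SUITE",
    "run_pipeline",
]

# Default model suites.  Terms: fixed "focal_distance" (distance from the
# native host) and "passage0_ct" (viral amplification at exposure); random
# "phylo" (pairwise relatedness, covariance A), "species", "strain".
SUSCEPTIBILITY_SUITE = [
    ("S1", ("focal_distance",), ("phylo", "species")),
    ("S2", ("focal_distance",), ("species",)),
    ("S3", (), ("phylo", "species")),
    ("S4", (), ("species",)),
]

TRANSMISSION_SUITE = [
    ("T1", ("passage0_ct", "focal_distance"), ("phylo", "species", "strain")),
    ("T2", ("passage0_ct", "focal_distance"), ("species", "strain")),
    ("T3", ("passage0_ct",), ("phylo", "species", "strain")),
    ("T4", ("passage0_ct",), ("species", "strain")),
    ("T5", ("focal_distance",), ("phylo", "species", "strain")),
    ("T6", ("focal_distance",), ("species", "strain")),
    ("T7", (), ("species", "strain")),
    ("T8", (), ("phylo", "species", "strain")),
]


@dataclass
class PipelineConfig:
    out_dir: str = "pipeline_out"
    seed: int = 0
    # either file paths ...
    tree_path: str | None = None
    ct_table_path: str | None = None
    trajectories_path: str | None = None
    # ... or a simulation config
    simulation: simulate.SimulationConfig | None = None
    focal_taxon: str | None = None  # default: first tip
    benchmark_choice: int = 4
    undetected_ct: float = 40.0
    n_iterations: int = 20_000
    burn_in: int = 4_000
    thin: int = 16
    fix_residual_variance_binomial: float | None = 1.0
    susceptibility_suite: list = field(default_factory=lambda: list(SUSCEPTIBILITY_SUITE))
    transmission_suite: list = field(default_factory=lambda: list(TRANSMISSION_SUITE))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        config = cls(**raw)
        if sim is not None:
            if "ct_params" in sim:
                sim["ct_params"] = {k: tuple(v) for k, v in sim["ct_params"].items()}
            if "strains_per_species" in sim and isinstance(sim["strains_per_species"], list):
                sim["strains_per_species"] = tuple(sim["strains_per_species"])
            config.simulation = simulate.SimulationConfig(**sim)
        return config


def _log(stage: str, message: str, log_lines: list):
    line = f"{time.strftime('%Y-%m-%dT%H:%M:%S')}\t{stage}\t{message}"
    log_lines.append(line)
    print(line, file=sys.stderr)


def _fit_suite(suite, response, data, rel, config: PipelineConfig, log_lines, out_dir):
    """Fit every model of a suite, write per-model JSONs, return a ModelSet."""
    records = []
    fits = {}
    for i, (model_id, fixed, random) in enumerate(suite):
        model = PhylogeneticMixedModel(
            response=response,
            fixed=tuple(fixed),
            random=tuple(random),
            n_iterations=config.n_iterations,
            burn_in=config.burn_in,
            thin=config.thin,
            seed=config.seed + 100 + i,
            fix_residual_variance=(
                config.fix_residual_variance_binomial if response == "binomial" else None
            ),
        )
        model.fit(data, rel=rel)
        fits[model_id] = model
        records.append((model_id, fixed, random, model.dic_))
        _log("fit", f"{model_id}: fixed={fixed} random={random} DIC={model.dic_:.3f}", log_lines)
        payload = model.summary_.to_dict()
        payload["model_id"] = model_id
        payload["fixed_terms"] = list(fixed)
        payload["random_terms"] = list(random)
        with open(out_dir / f"fit_{model_id}.json", "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
    return model_selection.ModelSet.from_records(records), fits


def _weight_report(models, out_dir, prefix, log_lines):
    weights = model_selection.dic_weights(models)
    table = weights.copy()
    table.insert(0, "dic", [e.dic for e in models.entries])
    table = table.round(3)
    table.to_csv(out_dir / f"{prefix}_dic_weights.tsv", sep="\t")
    components = sorted(models.known_terms)
    comp_report = {
        c: round(model_selection.component_weight(models, weights, c), 3) for c in components
    }
    phylo_terms = {"focal_distance", "phylo"} & models.known_terms
    if phylo_terms:
        comp_report["any_phylogenetic"] = round(
            model_selection.any_of_components_weight(models, weights, phylo_terms), 3
        )
    with open(out_dir / f"{prefix}_component_weights.json", "w") as fh:
        json.dump(comp_report, fh, indent=1, sort_keys=True)
    _log("weights", f"{prefix}: {comp_report}", log_lines)
    return weights


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns a dict of result objects and paths."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_lines: list = []
    stage = "setup"
    try:
        # ------------------------------------------------ inputs
        if config.simulation is not None:
            stage = "simulate"
            sim = config.simulation
            tree = simulate.simulate_yule_tree(sim.n_species, sim.birth_rate, seed=sim.seed)
            (out_dir / "tree.nwk").write_text(tree.newick() + "\n")
            obs, truth = simulate.simulate_susceptibility(tree, sim)
            ct_table = simulate.simulate_ct_assay(obs, sim)
            assays.write_ct_table(ct_table, out_dir / "ct_table.tsv")
            obs.to_csv(out_dir / "observations.tsv", sep="\t", index=False)
            simulate.write_truth(truth, out_dir / "truth.json")
            focal = config.focal_taxon or truth["focal"]
            _log(stage, f"simulated {sim.n_species} species, {len(obs)} strains", log_lines)
        else:
            stage = "load"
            if not (config.tree_path and config.ct_table_path):
                raise ValueError("either simulation config or tree+ct table paths required")
            tree = trees.parse_newick(Path(config.tree_path).read_text())
            ct_table = assays.load_ct_table(config.ct_table_path, config.undetected_ct)
            focal = config.focal_taxon or tree.taxa[0]
            _log(stage, f"loaded tree ({tree.n_taxa} tips) and Ct table", log_lines)

        stage = "tree"
        rel = trees.relatedness_matrix(tree)
        rel.to_tsv(out_dir / "relatedness_A.tsv")
        dvec = trees.distance_from_focal(tree, focal)

        # ------------------------------------------------ susceptibility calls
        stage = "threshold"
        sigma_w = assays.within_strain_sd(ct_table)
        threshold = assays.derive_threshold(ct_table, sigma_w, benchmark=config.benchmark_choice)
        bench_summary = assays.summarize_benchmarks(ct_table)
        with open(out_dir / "threshold.json", "w") as fh:
            json.dump(
                {
                    "within_strain_sd": sigma_w,
                    "benchmark": config.benchmark_choice,
                    "benchmark_max_virus_ct": threshold.benchmark_max_virus_ct,
                    "threshold": threshold.threshold,
                    "benchmark_summary": bench_summary.round(4).to_dict(orient="index"),
                },
                fh,
                indent=1,
                sort_keys=True,
            )
        _log(stage, f"sigma_w={sigma_w:.3f} tau={threshold.threshold:.3f}", log_lines)

        stage = "calls"
        calls = assays.call_susceptibility(ct_table, threshold)
        calls_frame = assays.calls_to_frame(calls)
        calls_frame.to_csv(out_dir / "susceptibility_calls.tsv", sep="\t", index=False)
        species_map = (
            ct_table.experimental[["strain", "species"]].drop_duplicates().set_index("strain")["species"]
        )
        _log(stage, f"{int(calls_frame.susceptible.sum())}/{len(calls_frame)} strains susceptible",
             log_lines)

        # ------------------------------------------------ susceptibility models
        stage = "susceptibility-models"
        sus_data = calls_frame.copy()
        sus_data["focal_distance"] = sus_data["species"].map(dvec.distances)
        unplaced = sus_data["focal_distance"].isna()
        if unplaced.any():
            _log(stage, f"dropping {int(unplaced.sum())} strains of unplaced species", log_lines)
            sus_data = sus_data[~unplaced].reset_index(drop=True)
        sus_data = drop_unplaced_species(sus_data, rel)
        sus_models, sus_fits = _fit_suite(
            config.susceptibility_suite, "binomial", sus_data, rel, config, log_lines, out_dir
        )
        sus_weights = _weight_report(sus_models, out_dir, "susceptibility", log_lines)

        # ------------------------------------------------ transmission assay
        stage = "transmission"
        if config.simulation is not None:
            # lines: susceptible strains' replicates, passage-0 Ct from the assay
            exp = ct_table.experimental
            susceptible = set(calls_frame.loc[calls_frame.susceptible, "strain"])
            lines = exp[exp.strain.isin(susceptible)].copy()
            lines["line_id"] = lines["strain"] + "_L" + lines["replicate"].astype(str)
            lines = lines.rename(columns={"ct": "passage0_ct"})[
                ["line_id", "strain", "species", "passage0_ct"]
            ]
            trajectories = simulate.simulate_passage_trajectories(
                lines, config.simulation, tau=threshold.threshold
            )
            assays.write_trajectories(trajectories, out_dir / "trajectories.tsv")
        elif config.trajectories_path:
            trajectories = assays.load_trajectories(config.trajectories_path)
        else:
            trajectories = []

        results = {
            "threshold": threshold,
            "calls": calls_frame,
            "susceptibility_models": sus_models,
            "susceptibility_weights": sus_weights,
            "out_dir": out_dir,
        }

        if trajectories:
            stage = "scores"
            scores = [assays.score_transmission(t) for t in trajectories]
            score_frame = pd.DataFrame(
                [
                    {
                        "line_id": s.line_id,
                        "strain": s.strain,
                        "species": t.species or species_map.get(s.strain, ""),
                        "score": s.score,
                        "passage0_ct": (
                            t.passage0_ct if t.passage0_ct is not None else config.undetected_ct
                        ),
                    }
                    for s, t in zip(scores, trajectories)
                ]
            )
            score_frame.to_csv(out_dir / "transmission_scores.tsv", sep="\t", index=False)
            _log(stage, f"scored {len(score_frame)} lines", log_lines)

            stage = "transmission-models"
            trans_data = score_frame.copy()
            trans_data["focal_distance"] = trans_data["species"].map(dvec.distances)
            trans_data = trans_data.dropna(subset=["focal_distance"]).reset_index(drop=True)
            trans_models, trans_fits = _fit_suite(
                config.transmission_suite, "gaussian", trans_data, rel, config, log_lines, out_dir
            )
            trans_weights = _weight_report(trans_models, out_dir, "transmission", log_lines)
            results["transmission_models"] = trans_models
            results["transmission_weights"] = trans_weights

            stage = "r-squared"
            for prefix, models, fits, design_data in (
                ("susceptibility", sus_models, sus_fits, None),
                ("transmission", trans_models, trans_fits, None),
            ):
                best_id = min(models.entries, key=lambda e: e.dic).model_id
                best = fits[best_id]
                r2 = model_selection.r_squared(best.samples_, best.design_)
                r2.round(4).to_csv(out_dir / f"{prefix}_best_model_r2.tsv", sep="\t")
                _log(stage, f"{prefix} best model {best_id}", log_lines)
        else:
            stage = "r-squared"
            best_id = min(sus_models.entries, key=lambda e: e.dic).model_id
            best = sus_fits[best_id]
            r2 = model_selection.r_squared(best.samples_, best.design_)
            r2.round(4).to_csv(out_dir / "susceptibility_best_model_r2.tsv", sep="\t")

        _log("done", "pipeline complete", log_lines)
        return results
    except Exception as exc:
        _log(stage, f"FAILED: {exc}", log_lines)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    finally:
        (out_dir / "run.log").write_text("\n".join(log_lines) + "\n")
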