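"""End-to-end orchestration: generate → distances → rarity → nulls → phylo → conservation.

A run either synthesizes a pool from a :class:`PoolConfig` or loads a
bundle of input files, then executes every stage in order and writes a
report bundle of CSV tables plus a JSON manifest recording the config
hash, seed and library versions.  Runs are deterministic under a fixed
seed: a master seed spawns one fixed substream per stage, so stages can
be rerun in isolation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io
from .conservation import (
    conservation_target,
    group_comparison,
    range_covariate_mean,
    regroup_status,
    status_composition,
    target_achievement,
)
from .phylo import d_statistic, ed_by_class, evolutionary_distinctiveness
from .rarity import (
    classify,
    functional_distinctiveness,
    geographical_restrictedness,
    local_distinctiveness,
    threshold_sensitivity,
)
from .spatial_null import hotspot_summary, rare_richness_map, ses_rare_richness
from .synthetic import (
    PoolConfig,
    generate_conservation_layers,
    generate_occurrence,
    generate_phylogeny,
    generate_traits,
)
from .traits_space import broken_stick_axes, gower_distance, pcoa

# fixed per-stage substream tags under the master seed
_STREAMS = {"null": 101, "phylo": 102, "layers": 103}


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``pool`` (synthesize) or ``inputs`` (paths to
    traits/occurrence/tree files) must be provided.
    """

    out_dir: str
    pool: PoolConfig | None = None
    inputs: dict | None = None  # keys: traits, traits_meta, occurrence, cells, tree
    lower: float = 0.25
    upper: float = 0.75
    n_rand: int = 1000
    n_perm: int = 1000
    seed: int = 0
    thresholds: tuple = ((0.30, 0.70), (0.20, 0.80))

    def __post_init__(self) -> None:
        if (self.pool is None) == (self.inputs is None):
            raise ValueError("provide exactly one of pool config or input paths")


def _config_hash(cfg: RunConfig) -> str:
    def default(o):
        if hasattr(o, "__dict__"):
            return o.__dict__
        return str(o)

    d = asdict(cfg)
    d.pop("out_dir", None)  # hash the scientific config, not the output location
    blob = json.dumps(d, sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _load_inputs(inputs: dict):
    for key in ("traits", "traits_meta", "occurrence", "cells", "tree"):
        if key not in inputs:
            raise ValueError(f"missing input path for {key!r}")
        if not Path(inputs[key]).exists():
            raise FileNotFoundError(f"input file not found: {inputs[key]}")
    traits = io.read_traits(inputs["traits"], inputs["traits_meta"])
    occ = io.read_occurrence(inputs["occurrence"], inputs["cells"])
    tree = io.read_tree(inputs["tree"])
    return traits, occ, tree, None, None


def validate_inputs(traits, occ, tree, species_layers=None) -> list[str]:
    """Cross-stage invariant checks; returns a list of violations (empty = OK)."""
    problems: list[str] = []
    try:
        traits.validate()
    except ValueError as e:
        problems.append(f"traits: {e}")
    try:
        occ.validate()
    except ValueError as e:
        problems.append(f"occurrence: {e}")
    trait_sp = set(traits.species)
    occ_sp = set(occ.species)
    for sp in sorted(occ_sp - trait_sp)[:10]:
        problems.append(f"species {sp!r} in occurrence but not in traits")
    for sp in sorted(trait_sp - occ_sp)[:10]:
        problems.append(f"species {sp!r} in traits but not in occurrence")
    tips = {lf.taxon.label for lf in tree.leaf_node_iter() if lf.taxon}
    for sp in sorted(occ_sp - tips)[:10]:
        problems.append(f"species {sp!r} missing from the tree")
    if species_layers is not None:
        lay_sp = set(species_layers.index)
        for sp in sorted(occ_sp - lay_sp)[:10]:
            problems.append(f"species {sp!r} missing from conservation layers")
    return problems


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and write the report bundle.

    Returns a dict of in-memory results keyed by stage; the same tables
    are written as CSV under ``config.out_dir`` together with
    ``manifest.json``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        if config.pool is not None:
            stage = "synthetic"
            traits = generate_traits(config.pool)
            occ = generate_occurrence(config.pool)
            tree = generate_phylogeny(
                config.pool.n_species, seed=config.pool.seed, labels=config.pool.species_ids
            )
            species_layers, cell_layers = generate_conservation_layers(
                config.pool,
                occ,
                seed=int(np.random.default_rng([config.seed, _STREAMS["layers"]]).integers(2**31)),
            )
            io.write_traits(traits, out / "traits.csv", out / "traits_meta.yaml")
            io.write_occurrence(occ, out / "occurrence.csv", out / "cells.csv")
            io.write_tree(tree, out / "tree.nwk")
        else:
            stage = "load"
            traits, occ, tree, species_layers, cell_layers = _load_inputs(config.inputs)

        stage = "validate"
        problems = validate_inputs(traits, occ, tree, species_layers)
        if problems:
            raise ValueError("invalid inputs: " + "; ".join(problems))

        stage = "distances"
        dist = gower_distance(traits)
        io.write_distance(dist, out / "distances.csv")
        ordination = pcoa(dist)
        n_axes = broken_stick_axes(ordination.eigenvalues)
        ord_df = ordination.coordinates.copy()
        ord_df.to_csv(out / "ordination.csv", index_label="species_id")

        stage = "rarity"
        D = functional_distinctiveness(dist)
        R = geographical_restrictedness(occ)
        profile = classify(D, R, lower=config.lower, upper=config.upper)
        profile.to_csv(out / "rarity.csv", index_label="species_id")
        sens = threshold_sensitivity(D, R, thresholds=config.thresholds, occ=occ)
        local = local_distinctiveness(occ, dist)

        stage = "null"
        rich = rare_richness_map(occ, profile)
        ses = ses_rare_richness(
            occ, profile, n_rand=config.n_rand, seed=int(np.random.default_rng([config.seed, _STREAMS["null"]]).integers(2**31))
        )
        pd.concat([rich, ses[["null_mean", "null_sd", "ses"]]], axis=1).to_csv(
            out / "ses.csv", index_label="cell_id"
        )
        hotspots = hotspot_summary(rich, island=occ.island)

        stage = "phylo"
        rare_trait = (profile["rarity_class"] == "rare").astype(int)
        if 0 < rare_trait.sum() < len(rare_trait):
            d_res = d_statistic(
                tree,
                rare_trait,
                n_perm=config.n_perm,
                seed=np.random.default_rng([config.seed, _STREAMS["phylo"]]),
            )
        else:  # no rare species in a tiny pool: signal undefined
            d_res = None
        ed = evolutionary_distinctiveness(tree)
        ed.to_csv(out / "ed.csv", index_label="species_id", header=True)
        ed_summary, ed_comp = ed_by_class(ed, profile)

        stage = "conservation"
        results: dict = {}
        if species_layers is not None:
            target = conservation_target(species_layers["range_km2"])
            achievement = target_achievement(species_layers["protected_fraction"], target)
            status = regroup_status(species_layers["status"])
            composition = status_composition(profile, status)
            cons = pd.DataFrame(
                {
                    "range_km2": species_layers["range_km2"],
                    "protected_fraction": species_layers["protected_fraction"],
                    "target": target,
                    "achievement": achievement,
                    "status": status,
                }
            )
            for cov in cell_layers.columns:
                cons[f"mean_{cov}"] = range_covariate_mean(occ, cell_layers[cov])
            cons.to_csv(out / "conservation.csv", index_label="species_id")
            comparisons = {}
            for metric in ("achievement", "mean_human_footprint", "mean_hdi"):
                try:
                    comparisons[metric] = group_comparison(cons[metric], profile["rarity_class"])
                except ValueError:  # too few usable classes in a tiny pool
                    comparisons[metric] = None
            results["conservation"] = {
                "table": cons,
                "composition": composition,
                "comparisons": comparisons,
            }

        stage = "manifest"
        manifest = {
            "config_hash": _config_hash(config),
            "seed": config.seed,
            "ecorare_version": __version__,
            "versions": {
                m.__name__: m.__version__
                for m in (np, pd)
            },
            "n_species": len(traits.species),
            "n_cells": occ.k_tot,
            "n_axes_broken_stick": int(n_axes),
            "class_counts": {
                str(k): int(v) for k, v in profile["rarity_class"].value_counts().items()
            },
            "hotspots": {k: (None if v is None else float(v)) for k, v in hotspots.items()},
            "D_statistic": None if d_res is None else float(d_res.D),
            "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    except Exception as e:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {e}") from e

    results.update(
        {
            "traits": traits,
            "occurrence": occ,
            "tree": tree,
            "distances": dist,
            "ordination": ordination,
            "profile": profile,
            "threshold_sensitivity": sens,
            "local_distinctiveness": local,
            "richness_map": rich,
            "ses": ses,
            "hotspots": hotspots,
            "d_statistic": d_res,
            "ed": ed,
            "ed_by_class": (ed_summary, ed_comp),
            "manifest": manifest,
        }
    )
    return results
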