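"""Plain-text readers and writers for the pipeline's tables.

Traits travel as a CSV plus a YAML sidecar declaring trait kinds,
weights and the columns of each fuzzy super-trait.  Occurrences travel
as a sparse triplet CSV (cell_id, species_id) with a cells CSV carrying
grid coordinates and the island flag; an optional MatrixMarket export is
available.  Trees are Newick via dendropy.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import dendropy
import yaml
from scipy.io import mmwrite
from scipy.sparse import csr_matrix
from skbio import DistanceMatrix

from .rarity import OccurrenceMatrix
from .synthetic import PoolConfig
from .traits_space import TraitSpec, TraitTable


def write_traits(table: TraitTable, csv_path, meta_path) -> None:
    table.data.to_csv(csv_path, index_label="species_id")
    meta = {
        "traits": [
            {
                "name": s.name,
                "kind": s.kind,
                "weight": float(s.weight),
                "columns": table.columns_of(s.name),
                **({"n_levels": s.n_levels} if s.n_levels else {}),
                **({"n_components": s.n_components} if s.n_components else {}),
            }
            for s in table.specs
        ]
    }
    Path(meta_path).write_text(yaml.safe_dump(meta, sort_keys=False))


def read_traits(csv_path, meta_path) -> TraitTable:
    data = pd.read_csv(csv_path, index_col="species_id")
    meta = yaml.safe_load(Path(meta_path).read_text())
    specs, trait_columns = [], {}
    for m in meta["traits"]:
        specs.append(
            TraitSpec(
                m["name"],
                m["kind"],
                n_levels=m.get("n_levels"),
                n_components=m.get("n_components"),
                weight=m.get("weight", 1.0),
            )
        )
        trait_columns[m["name"]] = list(m["columns"])
    return TraitTable(data, specs, trait_columns)


def write_occurrence(occ: OccurrenceMatrix, triplets_path, cells_path) -> None:
    A = occ.data.to_numpy()
    rows, cols = np.nonzero(A)
    trip = pd.DataFrame(
        {"cell_id": occ.cells[rows], "species_id": occ.species[cols]}
    )
    trip.to_csv(triplets_path, index=False)
    cells = pd.DataFrame(index=occ.cells)
    if occ.grid_shape is not None:
        r, c = np.divmod(np.arange(len(occ.cells)), occ.grid_shape[1])
        cells["row"], cells["col"] = r, c
        cells.attrs["grid_shape"] = occ.grid_shape
    cells["island"] = (
        occ.island.astype(int) if occ.island is not None else 0
    )
    if occ.grid_shape is not None:
        cells["grid_rows"] = occ.grid_shape[0]
        cells["grid_cols"] = occ.grid_shape[1]
    cells.to_csv(cells_path, index_label="cell_id")


def read_occurrence(triplets_path, cells_path) -> OccurrenceMatrix:
    trip = pd.read_csv(triplets_path)
    cells = pd.read_csv(cells_path, index_col="cell_id")
    species = sorted(trip["species_id"].unique())
    data = pd.DataFrame(0, index=cells.index, columns=pd.Index(species, name="species_id"), dtype=np.int8)
    for cell, sp in zip(trip["cell_id"], trip["species_id"]):
        data.at[cell, sp] = 1
    grid_shape = None
    if {"grid_rows", "grid_cols"} <= set(cells.columns):
        grid_shape = (int(cells["grid_rows"].iloc[0]), int(cells["grid_cols"].iloc[0]))
    island = cells["island"].astype(bool) if "island" in cells else None
    return OccurrenceMatrix(data, grid_shape=grid_shape, island=island)


def write_occurrence_mtx(occ: OccurrenceMatrix, path) -> None:
    mmwrite(str(path), csr_matrix(occ.data.to_numpy()))


def write_tree(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=False)


def read_tree(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick", preserve_underscores=True)


def write_distance(dist: DistanceMatrix, path) -> None:
    pd.DataFrame(dist.data, index=list(dist.ids), columns=list(dist.ids)).to_csv(
        path, index_label="species_id"
    )


def read_distance(path) -> DistanceMatrix:
    df = pd.read_csv(path, index_col="species_id")
    return DistanceMatrix(df.to_numpy(), ids=list(df.index))


def write_pool_config(config: PoolConfig, path) -> None:
    d = {
        "n_species": config.n_species,
        "grid_shape": list(config.grid_shape),
        "range_size_log_mean": config.range_size_log_mean,
        "range_size_log_sd": config.range_size_log_sd,
        "island_fraction": config.island_fraction,
        "prevalence_rare": config.prevalence_rare,
        "seed": config.seed,
        "trait_spec": [
            {
                "name": s.name,
                "kind": s.kind,
                **({"n_levels": s.n_levels} if s.n_levels else {}),
                **({"n_components": s.n_components} if s.n_components else {}),
                "weight": s.weight,
            }
            for s in config.trait_spec
        ],
    }
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def read_pool_config(path) -> PoolConfig:
    d = yaml.safe_load(Path(path).read_text())
    specs = [
        TraitSpec(
            m["name"],
            m["kind"],
            n_levels=m.get("n_levels"),
            n_components=m.get("n_components"),
            weight=m.get("weight", 1.0),
        )
        for m in d.pop("trait_spec", [])
    ] or None
    kwargs = {k: v for k, v in d.items()}
    if "grid_shape" in kwargs:
        kwargs["grid_shape"] = tuple(kwargs["grid_shape"])
    if specs is not None:
        kwargs["trait_spec"] = specs
    return PoolConfig(**kwargs)
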