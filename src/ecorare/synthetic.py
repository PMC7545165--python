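"""Synthetic species pools with the statistical structure the analysis assumes.

The generators emulate a global macroecological dataset at desk scale:

* mixed-kind Eltonian traits (a fuzzy diet composition, log body mass,
  activity cycle, foraging height),
* heavily right-skewed range sizes — log-normal occupied-cell counts on
  an abstract equal-area grid, with spatially coherent ranges grown by
  breadth-first accretion around a seed cell,
* rooted ultrametric pure-birth phylogenies,
* binary traits placed on trees at a fixed prevalence, either at random,
  by thresholding a Brownian trait (phylogenetically clumped), or
  confined to one flank of the tree (strongly clumped),
* conservation layers: range size at 2500 km² per cell (a 50 × 50 km
  grid), protected fractions, status labels enriched for threat among
  restricted species, and spatially autocorrelated covariate grids
  (human footprint / HDI / conflict analogues).

Every generator is deterministic under a fixed seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import dendropy
from dendropy.simulate import treesim
from scipy import ndimage
from scipy.special import expit

from ._tree import TreeArrays, threshold_at_prevalence
from .rarity import OccurrenceMatrix
from .traits_space import TraitSpec, TraitTable

__all__ = [
    "PoolConfig",
    "eltonian_trait_spec",
    "generate_traits",
    "generate_occurrence",
    "generate_phylogeny",
    "generate_binary_trait",
    "generate_conservation_layers",
    "lag1_autocorrelation",
    "CELL_AREA_KM2",
]

CELL_AREA_KM2 = 2500.0  # 50 km x 50 km equal-area cells


def eltonian_trait_spec() -> list[TraitSpec]:
    """Default trait set mirroring the four Eltonian super-traits."""
    return [
        TraitSpec("diet", "fuzzy", n_components=10),
        TraitSpec("body_mass", "continuous"),
        TraitSpec("activity", "categorical", n_levels=3),
        TraitSpec("foraging_height", "categorical", n_levels=5),
    ]


@dataclass
class PoolConfig:
    """Parameters of one synthetic species pool.

    ``range_size_log_mean`` / ``range_size_log_sd`` parameterise the
    log-normal occupied-cell counts (defaults give a median range of
    ~8 of 400 cells — 2% occupancy, strongly right-skewed, so
    restrictedness sits near 1 for most species as in a global grid).
    ``prevalence_rare`` is the target share of "1" tips for binary-trait
    simulation on trees.
    """

    n_species: int = 200
    grid_shape: tuple[int, int] = (20, 20)
    trait_spec: list[TraitSpec] = field(default_factory=eltonian_trait_spec)
    range_size_log_mean: float = 2.08  # log(8) cells
    range_size_log_sd: float = 1.2
    island_fraction: float = 0.15
    prevalence_rare: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 3:
            raise ValueError("n_species must be >= 3")
        if self.n_cells < 2:
            raise ValueError("need >= 2 grid cells")
        for name in ("island_fraction", "prevalence_rare"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.range_size_log_sd < 0:
            raise ValueError("range_size_log_sd must be >= 0")
        if not self.trait_spec:
            raise ValueError("trait_spec must declare at least one trait")

    @property
    def n_cells(self) -> int:
        return self.grid_shape[0] * self.grid_shape[1]

    @property
    def species_ids(self) -> list[str]:
        return [f"sp{i:04d}" for i in range(self.n_species)]

    @property
    def cell_ids(self) -> list[str]:
        return [f"c{i:04d}" for i in range(self.n_cells)]


def generate_traits(config: PoolConfig) -> TraitTable:
    """Draw a species × trait table matching ``config.trait_spec``.

    Continuous traits are standard-normal (log-mass analogue),
    categorical levels are uniform, and fuzzy compositions are sparse
    Dirichlet draws (concentration 0.3), mimicking specialised diets.
    """
    rng = np.random.default_rng([config.seed, 11])
    cols: dict[str, np.ndarray] = {}
    trait_columns: dict[str, list[str]] = {}
    for spec in config.trait_spec:
        if spec.kind == "continuous":
            cols[spec.name] = rng.normal(0.0, 1.0, config.n_species)
            trait_columns[spec.name] = [spec.name]
        elif spec.kind == "categorical":
            levels = np.array([f"{spec.name}_{k}" for k in range(spec.n_levels)])
            cols[spec.name] = levels[rng.integers(0, spec.n_levels, config.n_species)]
            trait_columns[spec.name] = [spec.name]
        else:  # fuzzy
            comp = rng.dirichlet(np.full(spec.n_components, 0.3), config.n_species)
            names = [f"{spec.name}.{k + 1}" for k in range(spec.n_components)]
            for k, cname in enumerate(names):
                cols[cname] = comp[:, k]
            trait_columns[spec.name] = names
    data = pd.DataFrame(cols, index=pd.Index(config.species_ids, name="species_id"))
    table = TraitTable(data, list(config.trait_spec), trait_columns)
    table.validate()
    return table


def _grow_patch(rng: np.random.Generator, shape: tuple[int, int], size: int) -> np.ndarray:
    """Flat indices of a contiguous patch grown by random frontier accretion."""
    rows, cols = shape
    n = rows * cols
    size = min(size, n)
    occupied = np.zeros(n, dtype=bool)
    in_frontier = np.zeros(n, dtype=bool)
    start = int(rng.integers(n))
    occupied[start] = True
    frontier: list[int] = []

    def push_neighbors(idx: int) -> None:
        r, c = divmod(idx, cols)
        for rr, cc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
            if 0 <= rr < rows and 0 <= cc < cols:
                j = rr * cols + cc
                if not occupied[j] and not in_frontier[j]:
                    in_frontier[j] = True
                    frontier.append(j)

    push_neighbors(start)
    while occupied.sum() < size and frontier:
        pick = int(rng.integers(len(frontier)))
        frontier[pick], frontier[-1] = frontier[-1], frontier[pick]
        nxt = frontier.pop()
        in_frontier[nxt] = False
        occupied[nxt] = True
        push_neighbors(nxt)
    return np.flatnonzero(occupied)


def generate_occurrence(config: PoolConfig) -> OccurrenceMatrix:
    """Binary cell × species matrix with log-normal, spatially coherent ranges.

    Occupied-cell counts are drawn log-normally and clipped to
    [1, n_cells]; each species' range is a contiguous patch around a
    random seed cell.  A contiguous block of cells is flagged insular.
    """
    rng = np.random.default_rng([config.seed, 22])
    n_occ = np.exp(
        rng.normal(config.range_size_log_mean, config.range_size_log_sd, config.n_species)
    )
    n_occ = np.clip(np.rint(n_occ).astype(int), 1, config.n_cells)
    A = np.zeros((config.n_cells, config.n_species), dtype=np.int8)
    for s in range(config.n_species):
        A[_grow_patch(rng, config.grid_shape, n_occ[s]), s] = 1
    data = pd.DataFrame(
        A,
        index=pd.Index(config.cell_ids, name="cell_id"),
        columns=pd.Index(config.species_ids, name="species_id"),
    )
    island = pd.Series(False, index=data.index, name="island")
    k_island = int(round(config.island_fraction * config.n_cells))
    if k_island > 0:
        island.iloc[_grow_patch(rng, config.grid_shape, k_island)] = True
    occ = OccurrenceMatrix(data, grid_shape=config.grid_shape, island=island)
    occ.validate()
    return occ


def generate_phylogeny(n_tips: int, seed: int = 0, labels: list[str] | None = None) -> dendropy.Tree:
    """Rooted ultrametric pure-birth tree with labelled tips.

    The birth process stops at the n-th speciation, which would leave
    zero-length pendant edges; all tip edges are therefore extended by
    the waiting time to the next birth event, keeping the tree
    ultrametric with strictly positive branch lengths.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    pyrng = random.Random(seed)
    tree = treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_tips, rng=pyrng
    )
    extra = pyrng.expovariate(n_tips * 1.0)
    leaves = list(tree.leaf_node_iter())
    if labels is None:
        labels = [f"sp{i:04d}" for i in range(len(leaves))]
    if len(labels) != len(leaves):
        raise ValueError("labels length does not match n_tips")
    for leaf, label in zip(leaves, labels):
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
        if leaf.taxon is None:
            leaf.taxon = tree.taxon_namespace.new_taxon(label)
        leaf.taxon.label = label
    tree.seed_node.edge.length = None
    return tree


def generate_binary_trait(
    tree: dendropy.Tree,
    mode: str = "random",
    prevalence: float = 0.25,
    seed: int | np.random.Generator | None = None,
) -> pd.Series:
    """Binary tip labels at exactly round(prevalence × n_tips) ones.

    ``random`` ignores topology; ``brownian_threshold`` simulates a
    Brownian trait (sigma² = 1; the scale cancels after thresholding)
    and labels the tips above the prevalence quantile;
    ``clade_clumped`` labels one flank of the tree — a run of tips
    consecutive in traversal order, i.e. a stack of nested clades.
    """
    if not 0 < prevalence < 1:
        raise ValueError("prevalence must lie in (0, 1)")
    ta = TreeArrays.from_dendropy(tree)
    if ta.n_tips < 4:
        raise ValueError("need >= 4 tips")
    k = int(round(prevalence * ta.n_tips))
    if k == 0 or k == ta.n_tips:
        raise ValueError("prevalence yields a monomorphic trait")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ones = np.zeros(ta.n_tips, dtype=np.int8)
    if mode == "random":
        ones[rng.choice(ta.n_tips, size=k, replace=False)] = 1
    elif mode == "brownian_threshold":
        vals = ta.brownian_tips(rng, 1)[:, 0]
        ones = threshold_at_prevalence(vals[:, None], k)[:, 0]
    elif mode == "clade_clumped":
        # tips are in preorder: a prefix or suffix is a union of nested clades
        ones[:k] = 1 if rng.integers(2) == 0 else 0
        if not ones.any():
            ones[-k:] = 1
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return pd.Series(ones, index=ta.tip_labels, name="rare")


def _smooth_grid(rng: np.random.Generator, shape: tuple[int, int], sigma: float = 2.0) -> np.ndarray:
    """Standardised spatially autocorrelated noise field."""
    z = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="reflect")
    return (z - z.mean()) / z.std()


def generate_conservation_layers(
    config: PoolConfig,
    occurrence: OccurrenceMatrix,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-species conservation attributes and per-cell covariate grids.

    Returns ``(species, cells)``: species carry range size (occupied
    cells × 2500 km²), a protected fraction in [0, 1], and a raw IUCN
    status code drawn with threat probability increasing in
    restrictedness rank (restricted species are more often CR/EN/VU, as
    in real assessments); cells carry smoothed spatial noise fields —
    a human-footprint analogue, an HDI analogue in [0.3, 0.95] and a
    non-negative conflict-years analogue.
    """
    occurrence.validate()
    rng = np.random.default_rng([config.seed if seed is None else seed, 33])
    k = occurrence.occupancy
    range_km2 = k.astype(float) * CELL_AREA_KM2
    protected = pd.Series(
        rng.beta(1.5, 6.0, len(k)), index=k.index, name="protected_fraction"
    )
    restrict_rank = (1.0 - k / occurrence.k_tot).rank(pct=True)
    p_threat = 0.05 + 0.55 * restrict_rank**3
    u = rng.random(len(k))
    status = np.where(
        u < p_threat,
        rng.choice(["CR", "EN", "VU"], len(k)),
        np.where(
            rng.random(len(k)) < 0.10,
            rng.choice(["DD", "NE"], len(k)),
            np.where(rng.random(len(k)) < 0.8, "LC", "NT"),
        ),
    )
    species = pd.DataFrame(
        {
            "range_km2": range_km2,
            "protected_fraction": protected,
            "status": status,
        },
        index=k.index,
    )
    shape = occurrence.grid_shape or (1, occurrence.k_tot)
    hf = 25.0 * expit(_smooth_grid(rng, shape)).ravel() * 2.0
    hdi = (0.3 + 0.65 * expit(1.5 * _smooth_grid(rng, shape))).ravel()
    conflicts = np.rint(np.exp(1.0 + 0.8 * _smooth_grid(rng, shape))).ravel()
    cells = pd.DataFrame(
        {"human_footprint": hf, "hdi": hdi, "conflicts": conflicts},
        index=occurrence.cells,
    )
    return species, cells


def lag1_autocorrelation(grid: np.ndarray) -> float:
    """Mean lag-1 Pearson correlation over horizontal and vertical shifts."""
    grid = np.asarray(grid, dtype=float)
    h = np.corrcoef(grid[:, :-1].ravel(), grid[:, 1:].ravel())[0, 1]
    v = np.corrcoef(grid[:-1, :].ravel(), grid[1:, :].ravel())[0, 1]
    return float((h + v) / 2.0)
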