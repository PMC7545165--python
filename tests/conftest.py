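import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

import ecorare as ec
from ecorare.traits_space import TraitSpec, TraitTable

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def pool_cfg():
    return ec.PoolConfig(n_species=40, grid_shape=(8, 8), seed=3)


@pytest.fixture(scope="session")
def small_pool(pool_cfg):
    traits = ec.generate_traits(pool_cfg)
    occ = ec.generate_occurrence(pool_cfg)
    return traits, occ


@pytest.fixture(scope="session")
def tree64():
    return ec.generate_phylogeny(64, seed=101)


def random_mixed_table(seed: int, n_species: int, with_missing: bool = False) -> TraitTable:
    """Small mixed-kind trait table for oracle comparisons."""
    rng = np.random.default_rng(seed)
    ids = [f"s{i}" for i in range(n_species)]
    cont = rng.normal(size=n_species)
    cat = rng.choice(["A", "B", "C"], n_species).astype(object)
    fuzzy = rng.dirichlet(np.ones(3), n_species)
    if with_missing:
        # fuzzy stays complete so every pair shares at least one trait
        cont[rng.random(n_species) < 0.15] = np.nan
        cat[rng.random(n_species) < 0.15] = None
    data = pd.DataFrame(
        {
            "size": cont,
            "habit": cat,
            "diet.1": fuzzy[:, 0],
            "diet.2": fuzzy[:, 1],
            "diet.3": fuzzy[:, 2],
        },
        index=pd.Index(ids, name="species_id"),
    )
    specs = [
        TraitSpec("size", "continuous", weight=1.0),
        TraitSpec("habit", "categorical", n_levels=3, weight=2.0),
        TraitSpec("diet", "fuzzy", n_components=3, weight=1.5),
    ]
    cols = {"size": ["size"], "habit": ["habit"], "diet": ["diet.1", "diet.2", "diet.3"]}
    return TraitTable(data, specs, cols)


def gower_oracle(table: TraitTable) -> np.ndarray:
    """Brute-force per-pair Gower loop, independent of the vectorised path."""
    n = len(table.species)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            num = den = 0.0
            for spec in table.specs:
                cols = table.columns_of(spec.name)
                xi = table.data.iloc[i][cols]
                xj = table.data.iloc[j][cols]
                if spec.kind == "fuzzy":
                    if xi.isna().any() or xj.isna().any():
                        continue
                    d = 0.5 * float(np.abs(xi.to_numpy(float) - xj.to_numpy(float)).sum())
                elif spec.kind == "continuous":
                    if pd.isna(xi.iloc[0]) or pd.isna(xj.iloc[0]):
                        continue
                    col = table.data[cols[0]]
                    rng_ = col.max() - col.min()
                    d = abs(float(xi.iloc[0]) - float(xj.iloc[0])) / rng_ if rng_ > 0 else 0.0
                else:
                    if xi.iloc[0] is None or pd.isna(xi.iloc[0]) or xj.iloc[0] is None or pd.isna(xj.iloc[0]):
                        continue
                    d = float(xi.iloc[0] != xj.iloc[0])
                num += spec.weight * d
                den += spec.weight
            out[i, j] = num / den
    return out
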