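"""Spatial null model for rarity richness maps.

Per-cell counts of ecologically rare species are compared against a
marginal-preserving randomization of the occurrence matrix: the
curveball algorithm repeatedly picks two cells and re-deals the species
that occur in exactly one of them, exactly preserving every cell's
richness and every species' occupancy.  Rarity class labels are never
re-randomized.  The per-cell standardized effect size is

    SES = (observed - mean(null)) / sd(null),

positive where a cell hosts more ecologically rare species than its
richness alone predicts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .rarity import OccurrenceMatrix, RARITY_CLASSES

__all__ = [
    "rare_richness_map",
    "curveball_randomize",
    "ses_rare_richness",
    "standardized_effect_size",
    "hotspot_summary",
]


def rare_richness_map(occ: OccurrenceMatrix, profile: pd.DataFrame) -> pd.DataFrame:
    """Per-cell counts of total, rare, common, average and other species."""
    occ.validate()
    missing = [s for s in occ.species if s not in profile.index]
    if missing:
        raise ValueError(f"species missing from profile: {missing[:5]}")
    cls = profile["rarity_class"].reindex(occ.species)
    A = occ.data.to_numpy()
    out = {"richness": A.sum(axis=1)}
    for c in RARITY_CLASSES:
        out[c] = A @ (cls == c).to_numpy().astype(int)
    return pd.DataFrame(out, index=occ.cells)


def _curveball_steps(A: np.ndarray, n_steps: int, rng: np.random.Generator) -> None:
    """In-place curveball trades on a binary array (rows = cells)."""
    n_rows = A.shape[0]
    for _ in range(n_steps):
        i = int(rng.integers(n_rows))
        j = int(rng.integers(n_rows - 1))
        if j >= i:
            j += 1
        diff = np.flatnonzero(A[i] != A[j])
        if diff.size == 0:
            continue
        k = int(A[i, diff].sum())
        if k == 0 or k == diff.size:
            continue
        sel = rng.permutation(diff)
        A[i, sel[:k]] = 1
        A[i, sel[k:]] = 0
        A[j, sel[:k]] = 0
        A[j, sel[k:]] = 1


def curveball_randomize(
    occ: OccurrenceMatrix,
    n_steps: int | None = None,
    seed: int | np.random.Generator | None = None,
) -> OccurrenceMatrix:
    """Randomize occurrences while exactly preserving both marginals.

    ``n_steps`` defaults to 5 × the number of cells (trade attempts),
    enough for the chain to mix on matrices of this shape.
    """
    occ.validate()
    if n_steps is None:
        n_steps = 5 * len(occ.cells)
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    A = occ.data.to_numpy().copy()
    _curveball_steps(A, n_steps, rng)
    data = pd.DataFrame(A, index=occ.cells, columns=occ.species)
    return OccurrenceMatrix(data, grid_shape=occ.grid_shape, island=occ.island)


def standardized_effect_size(observed: np.ndarray, nulls: np.ndarray) -> np.ndarray:
    """SES of per-cell observations against null draws (rows = draws).

    Cells whose null distribution is degenerate (sd = 0) get NaN.
    """
    mean = nulls.mean(axis=0)
    sd = nulls.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ses = (observed - mean) / sd
    return np.where(sd > 0, ses, np.nan)


def ses_rare_richness(
    occ: OccurrenceMatrix,
    profile: pd.DataFrame,
    n_rand: int = 1000,
    n_steps: int | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-cell SES of rare richness against curveball randomizations.

    Each of the ``n_rand`` null matrices is an independent chain started
    from the observed matrix (``n_steps`` trades, default 5 × cells).
    Returns a frame with observed counts, null mean/sd and SES (NaN
    where the null sd is 0); ``.attrs`` records n_rand and n_steps.
    """
    if n_rand < 2:
        raise ValueError("n_rand must be >= 2")
    occ.validate()
    if n_steps is None:
        n_steps = 5 * len(occ.cells)
    rng = np.random.default_rng(seed)
    cls = profile["rarity_class"].reindex(occ.species)
    rare = (cls == "rare").to_numpy().astype(np.int64)
    A_obs = occ.data.to_numpy()
    observed = A_obs @ rare
    nulls = np.empty((n_rand, len(occ.cells)), dtype=np.int64)
    for r in range(n_rand):
        A = A_obs.copy()
        _curveball_steps(A, n_steps, rng)
        nulls[r] = A @ rare
    ses = standardized_effect_size(observed, nulls)
    out = pd.DataFrame(
        {
            "observed": observed,
            "null_mean": nulls.mean(axis=0),
            "null_sd": nulls.std(axis=0, ddof=1),
            "ses": ses,
        },
        index=occ.cells,
    )
    out.attrs["n_rand"] = n_rand
    out.attrs["n_steps"] = n_steps
    return out


def hotspot_summary(
    richness_map: pd.DataFrame,
    island: pd.Series | None = None,
    second_map: pd.DataFrame | None = None,
) -> dict:
    """Descriptive hotspot statistics from a rare-richness map.

    Reports the percentage of cells hosting at least one rare species,
    the maximum per-cell count, the percentage of rare-hosting cells
    that are insular (None without an island flag), and — when a second
    pool's map is supplied — the percentage of cells hosting rare
    species of both pools.
    """
    rare = richness_map["rare"]
    n_cells = len(rare)
    has_rare = rare > 0
    out = {
        "n_cells": n_cells,
        "pct_cells_with_rare": 100.0 * has_rare.mean(),
        "max_rare_per_cell": int(rare.max()),
        "pct_rare_cells_insular": None,
        "pct_cells_rare_both_pools": None,
    }
    if island is not None:
        island = island.reindex(richness_map.index)
        out["pct_rare_cells_insular"] = (
            100.0 * island[has_rare].mean() if has_rare.any() else 0.0
        )
    if second_map is not None:
        both = has_rare & (second_map["rare"].reindex(richness_map.index) > 0)
        out["pct_cells_rare_both_pools"] = 100.0 * both.mean()
    return out
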