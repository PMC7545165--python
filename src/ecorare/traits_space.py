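"""Global functional space built from mixed-kind traits.

Species are positioned in an Eltonian niche space from traits of three
kinds — continuous (e.g. log body mass), categorical (e.g. activity
cycle) and fuzzy (compositional "super" traits such as diet fractions).
Pairwise dissimilarity uses a Gower combination of per-trait
contributions, each bounded in [0, 1]:

* continuous  — range-normalised absolute difference,
* categorical — 0/1 mismatch,
* fuzzy       — half the Manhattan distance between composition vectors.

Contributions are combined as a weighted mean over traits, skipping
traits missing for either member of a pair.  A principal coordinates
analysis (PCoA) of the resulting distance matrix yields orthogonal
functional axes; the broken-stick rule decides how many are worth
keeping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist
from skbio import DistanceMatrix
from skbio.stats.ordination import pcoa as _skbio_pcoa

TRAIT_KINDS = ("continuous", "categorical", "fuzzy")

__all__ = [
    "TraitSpec",
    "TraitTable",
    "Ordination",
    "gower_distance",
    "pcoa",
    "broken_stick_axes",
    "axis_distinctiveness_correlation",
    "trait_deletion_sensitivity",
]


@dataclass(frozen=True)
class TraitSpec:
    """Declaration of one trait: its kind, weight and generator shape.

    ``n_levels`` applies to categorical traits, ``n_components`` to
    fuzzy ones.  ``weight`` is the trait's relative weight in the Gower
    combination (a fuzzy super-trait counts as *one* trait regardless of
    its number of components).
    """

    name: str
    kind: str
    n_levels: int | None = None
    n_components: int | None = None
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in TRAIT_KINDS:
            raise ValueError(f"unknown trait kind {self.kind!r} for {self.name!r}")
        if self.kind == "categorical" and (self.n_levels is None or self.n_levels < 2):
            raise ValueError(f"categorical trait {self.name!r} needs >= 2 levels")
        if self.kind == "fuzzy" and (self.n_components is None or self.n_components < 2):
            raise ValueError(f"fuzzy trait {self.name!r} needs >= 2 components")
        if not np.isfinite(self.weight) or self.weight < 0:
            raise ValueError(f"trait {self.name!r} weight must be non-negative")


@dataclass
class TraitTable:
    """Species × trait values plus per-trait metadata.

    ``data`` is indexed by species id; a fuzzy trait spans several
    columns, listed in ``trait_columns[name]``.
    """

    data: pd.DataFrame
    specs: list[TraitSpec]
    trait_columns: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for spec in self.specs:
            self.trait_columns.setdefault(spec.name, [spec.name])

    @property
    def species(self) -> pd.Index:
        return self.data.index

    def columns_of(self, name: str) -> list[str]:
        return self.trait_columns[name]

    def validate(self) -> None:
        if self.data.index.duplicated().any():
            raise ValueError("duplicated species ids in trait table")
        for spec in self.specs:
            cols = self.columns_of(spec.name)
            missing = [c for c in cols if c not in self.data.columns]
            if missing:
                raise ValueError(f"trait {spec.name!r} misses columns {missing}")
            block = self.data[cols]
            if spec.kind == "fuzzy":
                vals = block.to_numpy(float)
                ok = np.isnan(vals).all(axis=1)  # fully-missing rows allowed
                sums = np.nansum(vals, axis=1)
                bad = ~ok & ((vals < -1e-9).any(axis=1) | (np.abs(sums - 1.0) > 1e-9))
                if bad.any():
                    raise ValueError(
                        f"fuzzy trait {spec.name!r} is not simplex-valued for species "
                        f"{list(self.data.index[bad][:5])}"
                    )
            if block.isna().all().all():
                raise ValueError(f"trait {spec.name!r} is missing for every species")

    def drop_trait(self, name: str) -> "TraitTable":
        """Remove one trait; a fuzzy super-trait loses all its components."""
        if name not in self.trait_columns:
            raise KeyError(name)
        specs = [s for s in self.specs if s.name != name]
        if not specs:
            raise ValueError("cannot drop the only trait")
        cols = {n: c for n, c in self.trait_columns.items() if n != name}
        keep = [c for n in cols for c in cols[n]]
        return TraitTable(self.data[keep].copy(), specs, cols)


def _pair_valid(valid: np.ndarray) -> np.ndarray:
    return np.logical_and.outer(valid, valid)


def gower_distance(table: TraitTable) -> DistanceMatrix:
    """Mixed-kind Gower dissimilarity between all species pairs.

    Returns a symmetric :class:`skbio.DistanceMatrix` with entries in
    [0, 1].  A continuous trait that is constant over the pool
    contributes 0 (its range would otherwise divide by zero).  Traits
    missing for either species of a pair are skipped; a pair sharing no
    observed trait is an error.
    """
    table.validate()
    n = len(table.species)
    if n < 2:
        raise ValueError("need at least 2 species")
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    for spec in table.specs:
        cols = table.columns_of(spec.name)
        if spec.kind == "fuzzy":
            x = table.data[cols].to_numpy(float)
            valid = ~np.isnan(x).any(axis=1)
            d = 0.5 * cdist(np.nan_to_num(x), np.nan_to_num(x), metric="cityblock")
        elif spec.kind == "continuous":
            x = table.data[cols[0]].to_numpy(float)
            valid = ~np.isnan(x)
            rng = np.nanmax(x) - np.nanmin(x) if valid.any() else 0.0
            if rng > 0:
                d = np.abs(np.subtract.outer(np.nan_to_num(x), np.nan_to_num(x))) / rng
            else:
                d = np.zeros((n, n))
        else:  # categorical
            x = table.data[cols[0]]
            valid = x.notna().to_numpy()
            codes = pd.factorize(x)[0]
            d = (codes[:, None] != codes[None, :]).astype(float)
        pv = _pair_valid(valid)
        num += spec.weight * np.where(pv, d, 0.0)
        den += spec.weight * pv
    if (den == 0).any():
        i, j = np.argwhere((den == 0) & ~np.eye(n, dtype=bool))[0]
        raise ValueError(
            f"species {table.species[i]!r} and {table.species[j]!r} share no observed trait"
        )
    d = num / den
    d = np.clip((d + d.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, ids=[str(s) for s in table.species])


@dataclass
class Ordination:
    """PCoA embedding of a distance matrix.

    ``coordinates`` holds one column per positive eigenvalue (axes
    named PC1, PC2, ...); ``proportion_explained`` is computed over the
    positive eigenvalues only.  Negative eigenvalues (a non-Euclidean
    input) are reported separately and carry no coordinates.
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray
    negative_eigenvalues: np.ndarray

    @property
    def n_axes(self) -> int:
        return self.coordinates.shape[1]


def pcoa(dist: DistanceMatrix) -> Ordination:
    """Principal coordinates analysis of a species distance matrix.

    Eigen-decomposition of the double-centred squared-distance matrix
    (delegated to scikit-bio); axes with non-positive eigenvalues are
    dropped without Cailliez/Lingoes correction.  For a Euclidean input
    the inter-point distances on the retained axes reproduce the input.
    """
    if np.isnan(dist.data).any():
        raise ValueError("distance matrix contains NaN")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = _skbio_pcoa(dist, method="eigh", warn_neg_eigval=False)
    eig = np.asarray(res.eigvals, dtype=float)
    order = np.argsort(eig)[::-1]
    eig = eig[order]
    coords = np.asarray(res.samples, dtype=float)[:, order]
    tol = max(1.0, np.abs(eig).max()) * 1e-12
    pos = eig > tol
    pos_eig = eig[pos]
    cols = [f"PC{k + 1}" for k in range(pos.sum())]
    coordinates = pd.DataFrame(coords[:, pos], index=list(dist.ids), columns=cols)
    total = pos_eig.sum()
    prop = pos_eig / total if total > 0 else np.zeros_like(pos_eig)
    return Ordination(coordinates, pos_eig, prop, eig[eig < -tol])


def broken_stick_axes(eigenvalues) -> int:
    """Number of leading axes whose share of variance meets the broken-stick expectation.

    For ``p`` positive eigenvalues the broken-stick share of axis ``k``
    is ``(1/p) * sum_{i=k}^{p} 1/i``; the leading run of axes whose
    relative eigenvalue is at least this expectation is retained.
    """
    eig = np.asarray(eigenvalues, dtype=float)
    eig = eig[eig > 0]
    if eig.size == 0:
        raise ValueError("need at least one positive eigenvalue")
    eig = np.sort(eig)[::-1]
    p = eig.size
    rel = eig / eig.sum()
    inv = 1.0 / np.arange(1, p + 1)
    bstick = np.cumsum(inv[::-1])[::-1] / p
    keep = 0
    for k in range(p):
        if rel[k] >= bstick[k] - 1e-12:
            keep += 1
        else:
            break
    return keep


def axis_distinctiveness_correlation(ordination: Ordination, distinctiveness: pd.Series) -> pd.Series:
    """Pearson correlation of each retained axis with functional distinctiveness.

    A reporting aid for choosing which axes to plot; not an inference step.
    """
    d = distinctiveness.reindex(ordination.coordinates.index)
    out = {}
    for col in ordination.coordinates.columns:
        out[col] = stats.pearsonr(ordination.coordinates[col], d)[0]
    return pd.Series(out, name="pearson_r")


def trait_deletion_sensitivity(table: TraitTable) -> pd.DataFrame:
    """Jackknife traits one at a time and correlate distinctiveness.

    Each trait (a fuzzy super-trait with all its components at once) is
    deleted, functional distinctiveness is recomputed on the reduced
    table, and the Pearson correlation with the full-table values is
    reported.  High correlations mean no single trait dominates the
    functional space.
    """
    from .rarity import functional_distinctiveness

    if len(table.specs) < 2:
        raise ValueError("need at least 2 traits to delete one")
    d_full = functional_distinctiveness(gower_distance(table))
    rows = []
    for spec in table.specs:
        reduced = table.drop_trait(spec.name)
        d_red = functional_distinctiveness(gower_distance(reduced))
        r = stats.pearsonr(d_full, d_red.reindex(d_full.index))[0]
        rows.append(
            {
                "trait": spec.name,
                "n_columns_removed": len(table.columns_of(spec.name)),
                "pearson_r": r,
            }
        )
    return pd.DataFrame(rows).set_index("trait")
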