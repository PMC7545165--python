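"""The two axes of ecological rarity and the joint classification.

Functional distinctiveness of species *i* is its average Gower distance
to every other species in the pool,

    D_i = sum_{j != i} d_ij / (N - 1),

0 when all species share the same traits and 1 when species *i* is
maximally different from everyone else.  Geographical restrictedness is
one minus the occupied fraction of the grid,

    R_i = 1 - K_i / K_tot,

close to 1 for a single-cell endemic and 0 for a ubiquitous species.

Species are *ecologically rare* when both values sit strictly above the
upper pool quantile (default 75%), *ecologically common* when both sit
strictly below the lower quantile (default 25%), *average* when D is
below the upper and R above the lower quantile, and *other* for the
residual corners of the bivariate space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix

__all__ = [
    "OccurrenceMatrix",
    "RARITY_CLASSES",
    "functional_distinctiveness",
    "geographical_restrictedness",
    "classify",
    "threshold_sensitivity",
    "local_distinctiveness",
]

RARITY_CLASSES = ("rare", "common", "average", "other")


@dataclass
class OccurrenceMatrix:
    """Binary cell × species matrix on an abstract equal-area grid.

    ``data`` is indexed by cell id with one 0/1 column per species.
    ``grid_shape`` (rows, cols) and the per-cell ``island`` flag are
    optional metadata used by range growth and hotspot summaries.
    """

    data: pd.DataFrame
    grid_shape: tuple[int, int] | None = None
    island: pd.Series | None = None

    @property
    def cells(self) -> pd.Index:
        return self.data.index

    @property
    def species(self) -> pd.Index:
        return self.data.columns

    @property
    def k_tot(self) -> int:
        return len(self.data.index)

    @property
    def occupancy(self) -> pd.Series:
        """K_i: number of occupied cells per species."""
        return self.data.sum(axis=0)

    def validate(self) -> None:
        vals = self.data.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("occurrence entries must be 0/1")
        empty = self.occupancy == 0
        if empty.any():
            raise ValueError(
                f"species with zero occupancy: {list(self.data.columns[empty][:5])}"
            )
        if self.island is not None and not self.island.index.equals(self.data.index):
            raise ValueError("island flag index does not match cells")


def functional_distinctiveness(dist: DistanceMatrix) -> pd.Series:
    """Per-species mean distance to all other pool members (D_i)."""
    n = dist.shape[0]
    if n < 2:
        raise ValueError("need at least 2 species")
    d = dist.data.sum(axis=0) / (n - 1)
    return pd.Series(d, index=list(dist.ids), name="D")


def geographical_restrictedness(occ: OccurrenceMatrix) -> pd.Series:
    """Per-species R_i = 1 - K_i / K_tot."""
    occ.validate()
    if occ.k_tot < 1:
        raise ValueError("occurrence matrix has no cells")
    r = 1.0 - occ.occupancy / occ.k_tot
    r.name = "R"
    return r


def classify(
    D: pd.Series,
    R: pd.Series,
    lower: float = 0.25,
    upper: float = 0.75,
) -> pd.DataFrame:
    """Assign rare / common / average / other from joint pool quantiles.

    Quantiles use linear interpolation between order statistics, and the
    rare/common conditions are strict (a species exactly at a quantile is
    neither).  Returns a frame with columns ``D``, ``R``,
    ``rarity_class``; the thresholds used are stored in ``.attrs``.
    """
    if not 0 < lower < upper < 1:
        raise ValueError("need 0 < lower < upper < 1")
    if set(D.index) != set(R.index):
        raise ValueError("D and R species sets differ")
    R = R.reindex(D.index)
    qd_lo, qd_up = np.quantile(D, [lower, upper])
    qr_lo, qr_up = np.quantile(R, [lower, upper])
    rare = (D > qd_up) & (R > qr_up)
    common = (D < qd_lo) & (R < qr_lo)
    average = (D < qd_up) & (R > qr_lo) & ~rare & ~common
    labels = np.where(rare, "rare", np.where(common, "common", np.where(average, "average", "other")))
    out = pd.DataFrame(
        {
            "D": D,
            "R": R,
            "rarity_class": pd.Categorical(labels, categories=list(RARITY_CLASSES)),
        }
    )
    out.attrs["lower"] = lower
    out.attrs["upper"] = upper
    out.attrs["quantiles"] = {"D": (qd_lo, qd_up), "R": (qr_lo, qr_up)}
    return out


@dataclass
class ThresholdSensitivity:
    """Re-classification under alternative quantile pairs.

    ``profiles`` maps (lower, upper) — including the baseline — to the
    corresponding classification; ``rare_richness_corr`` holds the
    Pearson correlation of per-cell rare richness between the baseline
    and each alternative (requires an occurrence matrix).
    """

    baseline: tuple[float, float]
    profiles: dict[tuple[float, float], pd.DataFrame]
    rare_richness_corr: pd.Series | None = None

    def rare_set(self, pair: tuple[float, float]) -> set:
        prof = self.profiles[pair]
        return set(prof.index[prof["rarity_class"] == "rare"])


def threshold_sensitivity(
    D: pd.Series,
    R: pd.Series,
    thresholds: list[tuple[float, float]] = ((0.30, 0.70), (0.20, 0.80)),
    baseline: tuple[float, float] = (0.25, 0.75),
    occ: OccurrenceMatrix | None = None,
) -> ThresholdSensitivity:
    """Robustness of the rare class to the choice of quantile thresholds.

    Rare sets are nested by construction: a stricter upper quantile can
    only shrink the set.  When ``occ`` is given, per-cell rare richness
    of every alternative is correlated with the baseline map.
    """
    pairs = [tuple(baseline)] + [tuple(t) for t in thresholds]
    profiles = {pair: classify(D, R, *pair) for pair in pairs}
    corr = None
    if occ is not None:
        A = occ.data.to_numpy(float)
        species = list(occ.species)
        base_rare = profiles[tuple(baseline)]["rarity_class"] == "rare"
        base_counts = A @ base_rare.reindex(species).to_numpy(float)
        vals = {}
        for pair in pairs[1:]:
            rare = profiles[pair]["rarity_class"] == "rare"
            counts = A @ rare.reindex(species).to_numpy(float)
            if base_counts.std() == 0 or counts.std() == 0:
                vals[f"{pair[0]:.2f}-{pair[1]:.2f}"] = np.nan
            else:
                vals[f"{pair[0]:.2f}-{pair[1]:.2f}"] = stats.pearsonr(base_counts, counts)[0]
        corr = pd.Series(vals, name="pearson_r")
    return ThresholdSensitivity(tuple(baseline), profiles, corr)


@dataclass
class LocalDistinctiveness:
    """Within-cell distinctiveness versus the global pool value."""

    local: pd.DataFrame  # cells × species, NaN where absent or undefined
    mean_local: pd.Series  # per species, over cells where defined
    pearson_r: float
    n_skipped_cells: int


def local_distinctiveness(occ: OccurrenceMatrix, dist: DistanceMatrix) -> LocalDistinctiveness:
    """D_i recomputed inside each cell's assemblage.

    Cells hosting fewer than two species leave local distinctiveness
    undefined and are skipped (with a warning).  The headline number is
    the Pearson correlation between each species' mean local value and
    its global distinctiveness.
    """
    occ.validate()
    species = [str(s) for s in occ.species]
    M = dist.filter(species).data
    A = occ.data.to_numpy(float)
    n_c = A.sum(axis=1)
    sums = A @ M  # distance of each species to the cell's assemblage (self = 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        local = sums / (n_c - 1)[:, None]
    defined = (A > 0) & (n_c >= 2)[:, None]
    local = np.where(defined, local, np.nan)
    n_skipped = int((n_c < 2).sum())
    if n_skipped:
        warnings.warn(f"{n_skipped} cells with < 2 species skipped", stacklevel=2)
    local_df = pd.DataFrame(local, index=occ.cells, columns=occ.species)
    mean_local = local_df.mean(axis=0)
    mean_local.name = "mean_local_D"
    global_d = functional_distinctiveness(dist).reindex(species).to_numpy()
    mask = mean_local.notna().to_numpy()
    if mask.sum() >= 3 and np.std(mean_local[mask]) > 0 and np.std(global_d[mask]) > 0:
        r = float(stats.pearsonr(mean_local[mask], global_d[mask])[0])
    else:
        r = float("nan")
    return LocalDistinctiveness(local_df, mean_local, r, n_skipped)
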