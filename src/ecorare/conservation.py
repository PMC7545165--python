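"""Threat exposure, status regrouping and the protected-area gap analysis.

Conservation targets follow the gap-analysis convention that restricted
species need proportionally more of their range protected: the target
is an affine function of log range size, pinned at 100% for the
smallest-ranged species of the pool and 10% for the largest.  Target
achievement is the protected fraction divided by the target, capped at
1.  IUCN categories are regrouped to threatened (TH = CR+EN+VU), least
concern (LC = LC+NT) and not evaluated (NE = DD + not assessed), and
indices are compared across groups with a Kruskal–Wallis rank test plus
Bonferroni-adjusted pairwise comparisons summarised as compact letters.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .rarity import OccurrenceMatrix

__all__ = [
    "conservation_target",
    "target_achievement",
    "range_covariate_mean",
    "regroup_status",
    "group_comparison",
    "GroupComparison",
    "status_composition",
    "STATUS_GROUPS",
]

STATUS_GROUPS = {
    "CR": "TH",
    "EN": "TH",
    "VU": "TH",
    "LC": "LC",
    "NT": "LC",
    "DD": "NE",
    "NE": "NE",
}


def conservation_target(range_sizes: pd.Series) -> pd.Series:
    """Per-species protection target from range size (km²).

    Linear in log range size between the pool's endpoints: the
    smallest-ranged species gets a target of 1.0 (100% of its range),
    the largest 0.10.  The mapping is invariant to the log base.
    """
    a = pd.Series(range_sizes, dtype=float)
    if (a <= 0).any():
        raise ValueError("range sizes must be positive")
    log_a = np.log(a)
    lo, hi = log_a.min(), log_a.max()
    if hi - lo <= 0:
        raise ValueError("need >= 2 distinct range sizes to anchor the target line")
    t = 1.0 + (0.10 - 1.0) * (log_a - lo) / (hi - lo)
    t.name = "target"
    return t


def target_achievement(protected_fraction, target):
    """min(1, protected / target): how far each species' target is met."""
    p = pd.Series(protected_fraction, dtype=float)
    t = pd.Series(target, dtype=float).reindex(p.index)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("protected fractions must lie in [0, 1]")
    if (t <= 0).any() or (t > 1).any():
        raise ValueError("targets must lie in (0, 1]")
    a = np.minimum(1.0, p / t)
    a.name = "achievement"
    return a


def range_covariate_mean(occ: OccurrenceMatrix, grid: pd.Series) -> pd.Series:
    """Mean covariate value over each species' occupied cells.

    ``grid`` maps cell id to a covariate (NaN allowed); cells with
    missing values are ignored, and species whose entire range is
    missing get NaN (their ids are listed in ``.attrs['all_missing']``).
    """
    occ.validate()
    g = grid.reindex(occ.cells).to_numpy(float)
    A = occ.data.to_numpy(float)
    ok = ~np.isnan(g)
    counts = A[ok].sum(axis=0)
    sums = A[ok].T @ g[ok]
    with np.errstate(divide="ignore", invalid="ignore"):
        mean = sums / counts
    out = pd.Series(np.where(counts > 0, mean, np.nan), index=occ.species, name=grid.name)
    out.attrs["all_missing"] = list(occ.species[counts == 0])
    return out


def regroup_status(raw_status: pd.Series) -> pd.Series:
    """Map raw IUCN codes to the three-way TH / LC / NE grouping."""
    raw = pd.Series(raw_status, dtype=object)
    unknown = raw[~raw.isin(STATUS_GROUPS)]
    if len(unknown):
        raise ValueError(
            f"unknown status codes for species {list(unknown.index[:5])}: "
            f"{sorted(set(unknown))}"
        )
    out = raw.map(STATUS_GROUPS)
    out.name = "status"
    return out


@dataclass
class GroupComparison:
    """Kruskal–Wallis test plus Bonferroni pairwise rank comparisons."""

    statistic: float
    pvalue: float
    pairwise: pd.DataFrame | None  # columns: a, b, u, p, p_adj
    letters: dict | None  # compact letter display; groups sharing a letter do not differ

    def summary(self) -> str:
        lines = [f"Kruskal-Wallis H = {self.statistic:.4g}, p = {self.pvalue:.3g}"]
        if self.letters:
            for g, let in self.letters.items():
                lines.append(f"  {g}: {let}")
        return "\n".join(lines)


def _compact_letters(groups_ordered: list, different: set) -> dict:
    """Insert-absorb compact letter display from significant pairs."""
    sets = [set(groups_ordered)]
    for a, b in sorted(different):
        for s in [s for s in sets if a in s and b in s]:
            sets.remove(s)
            sets.extend([s - {a}, s - {b}])
        # absorb subsets
        sets = [s for s in sets if s and not any(s < t for t in sets)]
        # deduplicate
        uniq = []
        for s in sets:
            if s not in uniq:
                uniq.append(s)
        sets = uniq
    sets.sort(key=lambda s: min(groups_ordered.index(g) for g in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in groups_ordered}
    for letter, s in zip(alphabet, sets):
        for g in s:
            letters[g] += letter
    return letters


def group_comparison(
    values: pd.Series,
    classes: pd.Series,
    method: str = "kruskal_posthoc",
    alpha: float = 0.05,
) -> GroupComparison:
    """Compare a per-species index across classes by ranks.

    Kruskal–Wallis H (tie-corrected) over all classes with at least two
    members, then pairwise two-sided Mann–Whitney tests with Bonferroni
    adjustment, summarised as compact letters.  All-tied values yield
    H = 0 with no letters.
    """
    if method != "kruskal_posthoc":
        raise ValueError(f"unknown method {method!r}")
    values = pd.Series(values, dtype=float)
    classes = pd.Series(classes).reindex(values.index).astype(object)
    ok = values.notna() & classes.notna()
    values, classes = values[ok], classes[ok]
    sizes = classes.value_counts()
    names = [g for g in sizes.index if sizes[g] >= 2]
    if len(names) < 2:
        raise ValueError("need >= 2 classes with >= 2 members")
    groups = [values[classes == g].to_numpy() for g in names]
    if values.nunique() == 1:
        return GroupComparison(0.0, 1.0, None, None)
    h, p = stats.kruskal(*groups)
    pairs = list(combinations(range(len(names)), 2))
    rows, different = [], set()
    for i, j in pairs:
        u, pu = stats.mannwhitneyu(groups[i], groups[j], alternative="two-sided")
        p_adj = min(1.0, pu * len(pairs))
        if p_adj < alpha:
            different.add((names[i], names[j]))
        rows.append({"a": names[i], "b": names[j], "u": u, "p": pu, "p_adj": p_adj})
    order = sorted(names, key=lambda g: np.median(values[classes == g]))
    letters = _compact_letters(order, different)
    return GroupComparison(float(h), float(p), pd.DataFrame(rows), letters)


def status_composition(profile: pd.DataFrame, status: pd.Series) -> pd.DataFrame:
    """Percentage of each rarity class in each status group (rows sum to 100).

    Empty classes are reported as all-NaN rows.
    """
    if set(profile.index) != set(status.index):
        raise ValueError("profile and status species sets differ")
    status = status.reindex(profile.index)
    counts = pd.crosstab(profile["rarity_class"], status, dropna=False)
    for g in ("TH", "LC", "NE"):
        if g not in counts.columns:
            counts[g] = 0
    counts = counts[["TH", "LC", "NE"]]
    totals = counts.sum(axis=1)
    pct = counts.div(totals, axis=0) * 100.0
    pct[totals == 0] = np.nan
    return pct
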