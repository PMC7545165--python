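"""Phylogenetic signal of a binary trait and evolutionary distinctiveness.

The Fritz–Purvis D statistic measures whether a binary trait (here:
membership of the ecologically rare class) is phylogenetically clumped.
The observed sum of state changes,

    d_obs = sum over edges of |nodal difference|,

with internal states estimated by recursive averaging of direct
descendants, is scaled between two nulls: tip-label permutations
(``d_R``, the no-signal reference) and a Brownian trait thresholded at
the observed prevalence (``d_B``, the clumped reference):

    D = (d_obs - mean(d_B)) / (mean(d_R) - mean(d_B)).

D ≈ 1 indicates a phylogenetically random trait, D ≈ 0 a Brownian-like
clumped one; values below 0 indicate even stronger clumping (e.g. the
trait confined to one clade).

Evolutionary distinctiveness (ED) apportions tree branch length to
tips: fair proportion divides each edge among its descendant tips,
equal splits halves (or 1/k's) the contribution at every split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import dendropy

from ._tree import TreeArrays, threshold_at_prevalence

__all__ = [
    "DResult",
    "d_statistic",
    "d_statistic_over_trees",
    "evolutionary_distinctiveness",
    "ed_by_class",
]


@dataclass
class DResult:
    """Outcome of the D-statistic calculation on one tree."""

    D: float
    d_obs: float
    mean_d_random: float
    sd_d_random: float
    mean_d_brownian: float
    sd_d_brownian: float
    n_perm: int
    p_random: float  # P(d_random <= d_obs): small = stronger signal than random
    p_brownian: float  # P(d_brownian >= d_obs): small = weaker clumping than Brownian


def _align_trait(trait, tip_labels) -> np.ndarray:
    trait = pd.Series(trait)
    missing = [t for t in tip_labels if t not in trait.index]
    if missing:
        raise ValueError(f"trait missing for tips {missing[:5]}")
    vals = trait.reindex(tip_labels).to_numpy()
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("trait must be binary 0/1")
    return vals.astype(np.int8)


def d_statistic(
    tree: dendropy.Tree | TreeArrays,
    trait,
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> DResult:
    """Fritz–Purvis D of a binary trait on a rooted tree.

    ``trait`` maps tip labels to {0, 1}; both states must be present.
    ``n_perm`` controls the size of both null ensembles (tip-label
    permutations and prevalence-matched Brownian-threshold draws).
    """
    ta = tree if isinstance(tree, TreeArrays) else TreeArrays.from_dendropy(tree)
    obs = _align_trait(trait, ta.tip_labels)
    k = int(obs.sum())
    if k == 0 or k == ta.n_tips:
        raise ValueError("trait is monomorphic on the tree")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    d_obs = float(ta.nodal_sum_of_changes(obs[:, None])[0])

    perms = rng.permuted(np.tile(obs, (n_perm, 1)), axis=1).T
    d_r = ta.nodal_sum_of_changes(perms)

    sims = ta.brownian_tips(rng, n_perm)
    d_b = ta.nodal_sum_of_changes(threshold_at_prevalence(sims, k))

    denom = d_r.mean() - d_b.mean()
    if abs(denom) < 1e-12:
        raise ValueError("mean(d_random) equals mean(d_brownian); D undefined")
    return DResult(
        D=float((d_obs - d_b.mean()) / denom),
        d_obs=d_obs,
        mean_d_random=float(d_r.mean()),
        sd_d_random=float(d_r.std(ddof=1)),
        mean_d_brownian=float(d_b.mean()),
        sd_d_brownian=float(d_b.std(ddof=1)),
        n_perm=n_perm,
        p_random=float((d_r <= d_obs).mean()),
        p_brownian=float((d_b >= d_obs).mean()),
    )


def d_statistic_over_trees(
    trees: list,
    trait,
    n_perm: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """D computed on each tree of an ensemble (e.g. posterior trees).

    All trees must share the trait's tip set.  Each tree uses an RNG
    stream derived from the master seed and the tree index, so any
    single tree's result can be reproduced in isolation.  Returns one
    row per tree; ``.attrs['summary']`` holds mean and quartiles of D.
    """
    rows = []
    for i, tree in enumerate(trees):
        rng = np.random.default_rng([0 if seed is None else seed, i])
        res = d_statistic(tree, trait, n_perm=n_perm, seed=rng)
        rows.append({"tree": i, "D": res.D, "d_obs": res.d_obs, "p_random": res.p_random})
    out = pd.DataFrame(rows).set_index("tree")
    q = out["D"].quantile([0.25, 0.5, 0.75])
    out.attrs["summary"] = {
        "mean": float(out["D"].mean()),
        "q25": float(q.loc[0.25]),
        "median": float(q.loc[0.5]),
        "q75": float(q.loc[0.75]),
    }
    return out


def evolutionary_distinctiveness(
    tree: dendropy.Tree | TreeArrays,
    method: str = "fair_proportion",
) -> pd.Series:
    """Per-tip ED: apportioned share of the tree's branch length.

    fair_proportion divides each edge by its number of descendant tips
    (tip values sum to the total tree length); equal_splits divides each
    edge by the product of split sizes between it and the tip.
    """
    ta = tree if isinstance(tree, TreeArrays) else TreeArrays.from_dendropy(tree)
    if ta.total_length <= 0:
        raise ValueError("tree has zero total branch length")
    if method == "fair_proportion":
        counts = ta.n_descendant_tips()
        share = np.zeros(ta.n_nodes)
        nonroot = ta.parent >= 0
        share[nonroot] = ta.blen[nonroot] / counts[nonroot]
        acc = np.zeros(ta.n_nodes)
        for i in range(ta.n_nodes):  # preorder: parent already accumulated
            p = ta.parent[i]
            acc[i] = share[i] + (acc[p] if p >= 0 else 0.0)
        ed = acc[ta.tip_idx]
    elif method == "equal_splits":
        ed = np.zeros(ta.n_tips)
        for t, i in enumerate(ta.tip_idx):
            divisor, total = 1.0, 0.0
            node = i
            while ta.parent[node] >= 0:
                total += ta.blen[node] / divisor
                node = ta.parent[node]
                divisor *= len(ta.children[node])
            ed[t] = total
    else:
        raise ValueError(f"unknown ED method {method!r}")
    return pd.Series(ed, index=ta.tip_labels, name=f"ED_{method}")


def ed_by_class(ed: pd.Series, profile: pd.DataFrame):
    """Compare evolutionary distinctiveness across rarity classes.

    Returns ``(summary, comparison)``: per-class count/mean/median, and
    a rank-based group comparison (None when fewer than two classes have
    at least two members).
    """
    from .conservation import group_comparison

    if set(ed.index) != set(profile.index):
        raise ValueError("ED and profile species sets differ")
    cls = profile["rarity_class"].reindex(ed.index)
    summary = (
        pd.DataFrame({"ED": ed, "rarity_class": cls})
        .groupby("rarity_class", observed=True)["ED"]
        .agg(["count", "mean", "median"])
    )
    sizes = cls.value_counts()
    if (sizes >= 2).sum() >= 2:
        usable = cls.isin(sizes[sizes >= 2].index)
        comparison = group_comparison(ed[usable], cls[usable])
    else:
        comparison = None
    return summary, comparison
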