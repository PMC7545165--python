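"""Array view of a rooted dendropy tree for batched computations.

Nodes are indexed in preorder (root first).  The representation supports
vectorised nodal averaging (many trait vectors at once), batched
Brownian simulation along branches, and descendant-tip counts — the
primitives behind the D statistic and evolutionary distinctiveness.
"""

from __future__ import annotations

import numpy as np
import dendropy


class TreeArrays:
    def __init__(self, parent, blen, children, tip_idx, tip_labels):
        self.parent = parent  # (n_nodes,) int, -1 at root
        self.blen = blen  # (n_nodes,) float, 0 at root
        self.children = children  # list[np.ndarray | None], None at tips
        self.tip_idx = tip_idx  # (n_tips,) int
        self.tip_labels = list(tip_labels)
        self.n_nodes = len(parent)
        self.n_tips = len(tip_idx)
        # internal nodes in postorder: children always precede parents in
        # reversed preorder
        self.postorder_internal = np.array(
            [i for i in range(self.n_nodes - 1, -1, -1) if children[i] is not None],
            dtype=int,
        )

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "TreeArrays":
        nodes = list(tree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        n = len(nodes)
        parent = np.full(n, -1, dtype=int)
        blen = np.zeros(n)
        children: list = [None] * n
        tip_idx, tip_labels = [], []
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                blen[i] = float(nd.edge.length or 0.0)
            kids = nd.child_nodes()
            if kids:
                children[i] = np.array([index[id(c)] for c in kids], dtype=int)
            else:
                tip_idx.append(i)
                label = nd.taxon.label if nd.taxon is not None else nd.label
                tip_labels.append(label)
        if len(set(tip_labels)) != len(tip_labels):
            raise ValueError("duplicate tip labels")
        return cls(parent, blen, children, np.array(tip_idx, dtype=int), tip_labels)

    @property
    def total_length(self) -> float:
        return float(self.blen[1:].sum() + (0.0 if self.parent[0] == -1 else self.blen[0]))

    def n_descendant_tips(self) -> np.ndarray:
        counts = np.zeros(self.n_nodes, dtype=int)
        counts[self.tip_idx] = 1
        for i in self.postorder_internal:
            counts[i] = counts[self.children[i]].sum()
        return counts

    def nodal_sum_of_changes(self, tip_values: np.ndarray) -> np.ndarray:
        """Sum over edges of |node value - parent value| for a batch of traits.

        ``tip_values`` has shape (n_tips, m) aligned to ``tip_labels``;
        internal values are the recursive mean of direct children,
        estimated tips-to-root.  Returns shape (m,).
        """
        tip_values = np.atleast_2d(np.asarray(tip_values, dtype=float))
        if tip_values.shape[0] != self.n_tips:
            tip_values = tip_values.T
        m = tip_values.shape[1]
        vals = np.empty((self.n_nodes, m))
        vals[self.tip_idx] = tip_values
        for i in self.postorder_internal:
            vals[i] = vals[self.children[i]].mean(axis=0)
        nonroot = np.flatnonzero(self.parent >= 0)
        return np.abs(vals[nonroot] - vals[self.parent[nonroot]]).sum(axis=0)

    def brownian_tips(self, rng: np.random.Generator, m: int, sigma2: float = 1.0) -> np.ndarray:
        """Simulate m Brownian traits along branches; returns (n_tips, m)."""
        sd = np.sqrt(sigma2 * self.blen)
        vals = np.zeros((self.n_nodes, m))
        for i in range(self.n_nodes):
            p = self.parent[i]
            if p >= 0:
                vals[i] = vals[p] + rng.standard_normal(m) * sd[i]
        return vals[self.tip_idx]


def threshold_at_prevalence(values: np.ndarray, k: int) -> np.ndarray:
    """Binary matrix marking, per column, the k largest values as 1."""
    values = np.atleast_2d(values)
    n = values.shape[0]
    out = np.zeros_like(values, dtype=np.int8)
    top = np.argpartition(values, n - k, axis=0)[n - k :]
    np.put_along_axis(out, top, 1, axis=0)
    return out
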