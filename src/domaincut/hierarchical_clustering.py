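"""Agglomerative clustering and the gap-based dendrogram cut.

The clustering is plain hierarchical agglomeration over a precomputed
distance matrix: at every step the globally closest pair of clusters is
merged, with inter-cluster distances maintained by the Lance-Williams
update for average or complete linkage. Ties are broken by the
lexicographically smallest (older id, younger id) pair so the whole
pipeline is reproducible bit-for-bit.

The cut procedure walks down from the dendrogram root looking for a height
gap: starting at the root height D, it stops without cutting if D falls
below the minimum cut height m; it cuts at D - s/2 if no merge node lies
in [D - s, D); otherwise it descends to the highest merge node in that
window and repeats. The partition is invariant to where inside the gap the
cut level is placed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CutParams",
    "Merge",
    "Dendrogram",
    "ClusterSet",
    "validate_distance_matrix",
    "agglomerate",
    "cut_dendrogram",
    "linkage_table",
]


@dataclass(frozen=True)
class CutParams:
    """Gap-cut parameters: minimum cut height m and step size s, in A.

    Defaults m=22, s=5 are the operating point used for both assignment
    algorithms.
    """

    m: float = 22.0
    s: float = 5.0

    def __post_init__(self):
        if self.m <= 0 or self.s <= 0:
            raise ValueError("m and s must be positive")


@dataclass(frozen=True)
class Merge:
    """One agglomeration step. Node ids: leaves 0..N-1, merges N..2N-2."""

    left: int
    right: int
    height: float
    count: int


@dataclass
class Dendrogram:
    n_leaves: int
    merges: list[Merge] = field(default_factory=list)

    def __post_init__(self):
        if len(self.merges) != self.n_leaves - 1:
            raise ValueError("a dendrogram over N leaves has N-1 merges")
        used: set[int] = set()
        for k, m in enumerate(self.merges):
            for child in (m.left, m.right):
                if child in used or child >= self.n_leaves + k:
                    raise ValueError("invalid merge tree")
                used.add(child)
        if self.merges and self.merges[-1].count != self.n_leaves:
            raise ValueError("root must contain all leaves")

    @property
    def root_height(self) -> float:
        return self.merges[-1].height if self.merges else 0.0

    def leaves_under(self, node: int) -> list[int]:
        """Leaf indices of the subtree rooted at ``node``."""
        stack = [node]
        out: list[int] = []
        while stack:
            x = stack.pop()
            if x < self.n_leaves:
                out.append(x)
            else:
                m = self.merges[x - self.n_leaves]
                stack.extend((m.left, m.right))
        return sorted(out)

    def partition_at(self, height: float) -> list[list[int]]:
        """Clusters obtained by keeping only merges strictly below ``height``."""
        parent = list(range(2 * self.n_leaves - 1))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for k, m in enumerate(self.merges):
            if m.height < height:
                node = self.n_leaves + k
                parent[find(m.left)] = node
                parent[find(m.right)] = node
        groups: dict[int, list[int]] = {}
        for leaf in range(self.n_leaves):
            groups.setdefault(find(leaf), []).append(leaf)
        return sorted(groups.values())


@dataclass
class ClusterSet:
    """A partition of leaf indices; cut_height is None when no cut was made."""

    clusters: list[list[int]]
    cut_height: float | None = None

    @property
    def k(self) -> int:
        return len(self.clusters)

    def labels(self, n: int) -> np.ndarray:
        """Per-leaf 1-based cluster labels, clusters ordered by smallest member."""
        lab = np.zeros(n, dtype=int)
        for idx, cl in enumerate(sorted(self.clusters), start=1):
            lab[cl] = idx
        return lab


def validate_distance_matrix(dm: np.ndarray) -> np.ndarray:
    dm = np.asarray(dm, dtype=float)
    if dm.ndim != 2 or dm.shape[0] != dm.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(dm, dm.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.diag(dm) != 0):
        raise ValueError("distance matrix diagonal must be zero")
    if np.any(dm < 0):
        raise ValueError("distances must be non-negative")
    return dm


def agglomerate(dm: np.ndarray, linkage: str = "average") -> Dendrogram:
    """Cluster N objects into a dendrogram of N-1 merges.

    ``average``: d(A u B, C) = (|A| d(A,C) + |B| d(B,C)) / (|A| + |B|).
    ``complete``: d(A u B, C) = max(d(A,C), d(B,C)).
    """
    if linkage not in ("average", "complete"):
        raise ValueError(f"unknown linkage {linkage!r}")
    dm = validate_distance_matrix(dm)
    n = dm.shape[0]
    if n < 1:
        raise ValueError("need at least one object")
    # working matrix indexed by slot; each active slot holds a cluster
    work = dm.copy()
    node_id = list(range(n))  # node id of the cluster in each slot
    sizes = np.ones(n, dtype=int)
    active = np.ones(n, dtype=bool)
    merges: list[Merge] = []
    for step in range(n - 1):
        best: tuple[float, int, int] | None = None
        idx = np.where(active)[0]
        sub = work[np.ix_(idx, idx)]
        iu = np.triu_indices(len(idx), k=1)
        dists = sub[iu]
        dmin = dists.min()
        # lexicographic (older, younger) node-id tie-break among minima
        for a_pos, b_pos in zip(iu[0][dists == dmin], iu[1][dists == dmin]):
            a, b = idx[a_pos], idx[b_pos]
            ids = tuple(sorted((node_id[a], node_id[b])))
            if best is None or ids < best[1:]:
                best = (float(dmin), *ids)
        assert best is not None
        _, id_lo, id_hi = best
        a = node_id.index(id_lo)
        b = node_id.index(id_hi)
        new_id = n + step
        height = float(work[a, b])
        merges.append(Merge(id_lo, id_hi, height, int(sizes[a] + sizes[b])))
        if linkage == "average":
            upd = (sizes[a] * work[a] + sizes[b] * work[b]) / (sizes[a] + sizes[b])
        else:
            upd = np.maximum(work[a], work[b])
        work[a] = upd
        work[:, a] = upd
        work[a, a] = 0.0
        active[b] = False
        sizes[a] += sizes[b]
        node_id[a] = new_id
        node_id[b] = -1
    return Dendrogram(n_leaves=n, merges=merges)


def cut_dendrogram(tree: Dendrogram, params: CutParams) -> ClusterSet:
    """Find the gap-cut partition of a dendrogram.

    Descends from the root height; returns a single cluster (no cut) if the
    descent drops below m, otherwise cuts in the first window [D - s, D)
    containing no merge node, at level D - s/2. Merge nodes at exactly D
    count as already traversed; nodes at exactly D - s are inside the
    window.
    """
    n = tree.n_leaves
    if n == 1 or not tree.merges:
        return ClusterSet(clusters=[[0]] if n == 1 else [], cut_height=None)
    heights = np.array([m.height for m in tree.merges])
    D = float(tree.root_height)
    while True:
        if D < params.m:
            return ClusterSet(clusters=[list(range(n))], cut_height=None)
        window = heights[(heights >= D - params.s) & (heights < D)]
        if window.size == 0:
            c = D - params.s / 2.0
            return ClusterSet(clusters=tree.partition_at(c), cut_height=c)
        D = float(window.max())


def linkage_table(tree: Dendrogram) -> str:
    """Dendrogram as tab-separated (left, right, height, count) lines."""
    lines = ["left\tright\theight\tcount"]
    for m in tree.merges:
        lines.append(f"{m.left}\t{m.right}\t{m.height:.6f}\t{m.count}")
    return "\n".join(lines) + "\n"
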