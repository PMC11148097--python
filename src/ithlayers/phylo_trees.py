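"""Per-patient phylogenetic, phylo-CNV and phyloepigenetic trees.

Trees over the sampled regions of one tumor (plus the matched normal, used
as the root) are inferred by ordinary-least-squares minimum evolution on
Euclidean distances: every unrooted binary topology on the leaves is
enumerated, branch lengths are fitted by OLS against the observed distance
matrix, negative fitted lengths are clamped to zero, and the topology with
the smallest total (clamped) tree length wins.  With the 4 leaves of a
typical 3-region + normal design there are only 3 topologies (10,395 at the
8-leaf cap), so the exhaustive search is exact and needs no heuristics.

Mutation and CNV trees use binary presence/absence matrices (the normal is
an all-zero row); methylation trees use purity-corrected window beta values
including the measured normal profile.  Concordance between trees of
different layers is the Robinson–Foulds distance on unrooted topologies.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "DistanceMatrix",
    "PhyloTree",
    "euclidean_distances",
    "minimum_evolution_tree",
    "tree_concordance",
]

MAX_EXACT_LEAVES = 8


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distance matrix with labelled rows/columns."""

    labels: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if d.shape != (n, n):
            raise ValueError(f"matrix shape {d.shape} does not match {n} labels")
        if not np.all(np.isfinite(d)):
            raise ValueError("distance matrix has non-finite entries")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(d), 0.0):
            raise ValueError("distance matrix diagonal is not zero")
        object.__setattr__(self, "d", d)

    def value(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.d[i, j])

    def reordered(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self.labels.index(lab) for lab in labels]
        return DistanceMatrix(tuple(labels), self.d[np.ix_(idx, idx)])


def euclidean_distances(rows: pd.DataFrame) -> DistanceMatrix:
    """Euclidean distance matrix between the rows of a feature matrix.

    Rows are samples (tumor regions plus the normal), columns are aligned
    features (variant keys, CNV event keys, or methylation windows).  For
    binary rows the Euclidean distance equals sqrt(Hamming count).
    """
    if rows.isna().any().any():
        raise ValueError("feature matrix contains missing values")
    labels = tuple(str(i) for i in rows.index)
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate sample labels")
    d = squareform(pdist(rows.to_numpy(dtype=float), metric="euclidean"))
    return DistanceMatrix(labels, d)


class PhyloTree:
    """Edge-weighted unrooted tree with a designated root leaf.

    Nodes are strings; leaves carry sample ids, internal nodes are
    auto-named.  The root, when set, is the normal-tissue leaf.
    """

    def __init__(
        self,
        adjacency: Mapping[str, Mapping[str, float]],
        root: str | None = None,
    ) -> None:
        adj: dict[str, dict[str, float]] = {
            u: dict(nbrs) for u, nbrs in adjacency.items()
        }
        for u, nbrs in list(adj.items()):
            for v, w in nbrs.items():
                adj.setdefault(v, {})
                if adj[v].get(u, w) != w:
                    raise ValueError(f"inconsistent length on edge {u}-{v}")
                adj[v][u] = w
        self.adjacency = adj
        self.leaves = frozenset(u for u, nbrs in adj.items() if len(nbrs) == 1)
        if root is not None and root not in adj:
            raise ValueError(f"root {root!r} is not a node of the tree")
        self.root = root
        self._check_connected()

    @classmethod
    def from_edges(
        cls, edges: Sequence[tuple[str, str, float]], root: str | None = None
    ) -> "PhyloTree":
        adj: dict[str, dict[str, float]] = {}
        for u, v, w in edges:
            adj.setdefault(u, {})[v] = float(w)
        return cls(adj, root=root)

    def _check_connected(self) -> None:
        if not self.adjacency:
            raise ValueError("empty tree")
        n_edges = sum(len(n) for n in self.adjacency.values()) // 2
        if n_edges != len(self.adjacency) - 1:
            raise ValueError("edge count inconsistent with a tree")
        seen = set()
        stack = [next(iter(self.adjacency))]
        while stack:
            u = stack.pop()
            if u in seen:
                continue
            seen.add(u)
            stack.extend(self.adjacency[u])
        if seen != set(self.adjacency):
            raise ValueError("tree is not connected")

    @property
    def edges(self) -> list[tuple[str, str, float]]:
        out = []
        for u in sorted(self.adjacency):
            for v, w in sorted(self.adjacency[u].items()):
                if u < v:
                    out.append((u, v, w))
        return out

    @property
    def total_length(self) -> float:
        return float(sum(w for _, _, w in self.edges))

    @property
    def root_edge_length(self) -> float:
        """Length of the edge incident to the root leaf (the displayed trunk
        of a region tree rooted at the matched normal)."""
        if self.root is None or self.root not in self.leaves:
            raise ValueError("tree has no root leaf")
        ((_, w),) = self.adjacency[self.root].items()
        return float(w)

    def path_length(self, a: str, b: str) -> float:
        prev: dict[str, str | None] = {a: None}
        stack = [a]
        while stack:
            u = stack.pop()
            if u == b:
                break
            for v in self.adjacency[u]:
                if v not in prev:
                    prev[v] = u
                    stack.append(v)
        total, u = 0.0, b
        while prev[u] is not None:
            p = prev[u]
            total += self.adjacency[u][p]
            u = p
        return total

    def splits(self) -> frozenset[frozenset[str]]:
        """Nontrivial leaf bipartitions (one canonical side per internal
        edge): the side not containing the lexicographically first leaf."""
        anchor = min(self.leaves)
        out = set()
        for u, v, _ in self.edges:
            side = self._leaves_behind(v, u)
            if anchor in side:
                side = self.leaves - side
            if len(side) >= 2 and len(self.leaves) - len(side) >= 2:
                out.add(frozenset(side))
        return frozenset(out)

    def _leaves_behind(self, start: str, blocked: str) -> frozenset[str]:
        seen, stack = {blocked, start}, [start]
        found = set()
        while stack:
            u = stack.pop()
            if u in self.leaves:
                found.add(u)
            for v in self.adjacency[u]:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        return frozenset(found)

    def _subtree_newick(self, node: str, parent: str) -> tuple[str, str]:
        # returns (min leaf label in subtree, newick string) for sorting
        length = self.adjacency[node][parent]
        if node in self.leaves:
            return node, f"{node}:{float(length)}"
        parts = sorted(
            self._subtree_newick(v, node)
            for v in self.adjacency[node]
            if v != parent
        )
        inner = ",".join(p[1] for p in parts)
        return parts[0][0], f"({inner}):{float(length)}"

    def to_newick(self) -> str:
        """Serialize with branch lengths; leaf labels are sample ids.

        The tree is written from the internal node adjacent to the root leaf
        (or the first internal node when unrooted), children ordered by
        their smallest leaf label so the output is deterministic.
        """
        internals = sorted(set(self.adjacency) - self.leaves)
        if not internals:
            # single-edge tree
            (u, v, w) = self.edges[0]
            return f"({v}:{float(w)}){u};"
        if self.root is not None and self.root in self.leaves:
            (anchor,) = self.adjacency[self.root]
        else:
            anchor = internals[0]
        parts = sorted(
            self._subtree_newick(v, anchor) for v in self.adjacency[anchor]
        )
        return "(" + ",".join(p[1] for p in parts) + ");"


# ---------------------------------------------------------------------------
# exhaustive OLS minimum evolution
# ---------------------------------------------------------------------------


def _enumerate_topologies(n_leaves: int) -> Iterator[list[tuple[int, int]]]:
    """All unrooted binary topologies on leaves 0..n-1 (internal node ids
    start at n_leaves), generated by stepwise leaf insertion."""
    base = [(0, n_leaves), (1, n_leaves), (2, n_leaves)]

    def rec(edges: list[tuple[int, int]], leaf: int, internal: int):
        if leaf == n_leaves:
            yield edges
            return
        for i in range(len(edges)):
            u, v = edges[i]
            w = internal
            new = edges[:i] + edges[i + 1 :] + [(u, w), (v, w), (leaf, w)]
            yield from rec(new, leaf + 1, internal + 1)

    yield from rec(base, 3, n_leaves + 1)


def _leaf_paths(
    edges: list[tuple[int, int]], n_leaves: int
) -> list[list[int]]:
    """Edge-index path for every leaf pair, in combinations(range(n), 2)
    order."""
    adj: dict[int, list[tuple[int, int]]] = {}
    for idx, (u, v) in enumerate(edges):
        adj.setdefault(u, []).append((v, idx))
        adj.setdefault(v, []).append((u, idx))
    paths = []
    for a, b in itertools.combinations(range(n_leaves), 2):
        prev: dict[int, tuple[int, int] | None] = {a: None}
        stack = [a]
        while stack:
            u = stack.pop()
            for v, idx in adj[u]:
                if v not in prev:
                    prev[v] = (u, idx)
                    stack.append(v)
        path, u = [], b
        while prev[u] is not None:
            p, idx = prev[u]
            path.append(idx)
            u = p
        paths.append(path)
    return paths


def _topology_splits(
    edges: list[tuple[int, int]], labels: Sequence[str]
) -> tuple[tuple[str, ...], ...]:
    """Canonical, sortable encoding of a topology's nontrivial splits."""
    n = len(labels)
    adj: dict[int, list[int]] = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    splits = []
    for u, v in edges:
        if u < n or v < n:  # pendant edge -> trivial split
            continue
        seen, stack, side = {u, v}, [v], set()
        while stack:
            x = stack.pop()
            if x < n:
                side.add(x)
            for y in adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        if 0 in side:
            side = set(range(n)) - side
        splits.append(tuple(sorted(labels[i] for i in side)))
    return tuple(sorted(splits))


def minimum_evolution_tree(
    dm: DistanceMatrix, root_label: str, clamp_negative: bool = True
) -> PhyloTree:
    """Exact OLS minimum-evolution tree for up to 8 leaves.

    Every unrooted binary topology is scored by the total (by default
    non-negativity-clamped) branch length of its OLS fit to ``dm``; the
    minimal topology wins, with ties broken by the lexicographically
    smallest split encoding.  The returned tree is rooted at ``root_label``
    (the normal sample).
    """
    if root_label not in dm.labels:
        raise ValueError(f"root label {root_label!r} not in distance matrix")
    labels = tuple(sorted(dm.labels))  # input-order invariance
    dm = dm.reordered(labels)
    n = len(labels)
    if n < 3:
        raise ValueError("minimum evolution needs >= 3 leaves")
    if n > MAX_EXACT_LEAVES:
        raise ValueError(
            f"{n} leaves exceeds the exact-search cap of {MAX_EXACT_LEAVES}; "
            "use a heuristic minimum-evolution implementation for larger trees"
        )
    dvec = np.array(
        [dm.d[i, j] for i, j in itertools.combinations(range(n), 2)]
    )
    best: tuple[float, tuple, list, np.ndarray] | None = None
    for edges in _enumerate_topologies(n):
        paths = _leaf_paths(edges, n)
        a_mat = np.zeros((len(dvec), len(edges)))
        for p_idx, path in enumerate(paths):
            a_mat[p_idx, path] = 1.0
        lengths, *_ = np.linalg.lstsq(a_mat, dvec, rcond=None)
        fitted = np.maximum(lengths, 0.0) if clamp_negative else lengths
        total = float(np.maximum(lengths, 0.0).sum())
        enc = _topology_splits(edges, labels)
        if (
            best is None
            or total < best[0] - 1e-12
            or (abs(total - best[0]) <= 1e-12 and enc < best[1])
        ):
            best = (total, enc, edges, fitted)
    assert best is not None
    _, _, edges, fitted = best

    def name(node: int) -> str:
        return labels[node] if node < n else f"_i{node - n + 1}"

    tree_edges = [
        (name(u), name(v), float(w)) for (u, v), w in zip(edges, fitted)
    ]
    return PhyloTree.from_edges(tree_edges, root=root_label)


def tree_concordance(t1: PhyloTree, t2: PhyloTree) -> tuple[int, bool]:
    """Robinson–Foulds distance between two trees on the same leaf set, and
    whether their unrooted topologies are identical (RF = 0)."""
    if t1.leaves != t2.leaves:
        raise ValueError("trees have different leaf sets")
    s1, s2 = t1.splits(), t2.splits()
    rf = len(s1 ^ s2)
    return rf, rf == 0
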