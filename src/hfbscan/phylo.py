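"""Distance-based protein phylogeny: p/Poisson distances, neighbor
joining, bootstrap support and Newick output.

The tree builder is the classic Saitou-Nei neighbor-joining
agglomeration on the Q-criterion, deterministic under ties (lowest
(row, col) pair in node-creation order) with negative branch lengths
clamped to zero; for an additive distance matrix the path lengths
reproduce the input exactly. Distances use pairwise deletion of gapped
columns. Bootstrap supports are the percentage of column-resampled
replicate trees containing each internal bipartition of the tree built
on the original alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, Iterator, List, Optional, Sequence, Tuple

import numpy as np
from Bio import SeqIO

__all__ = [
    "Alignment",
    "TreeNode",
    "PhyloTree",
    "read_alignment",
    "pairwise_distances",
    "nj_tree",
    "bipartitions",
    "bootstrap_support",
    "write_newick",
]

GAP = "-"


@dataclass(frozen=True)
class Alignment:
    """An MSA: ordered taxa and equal-length aligned rows ('-' = gap)."""

    ids: Tuple[str, ...]
    rows: Tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len(self.ids) < 3:
            raise ValueError("alignment needs at least 3 taxa")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate taxon ids")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError(f"rows have unequal lengths: {sorted(lengths)}")

    @property
    def n_taxa(self) -> int:
        return len(self.ids)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def to_matrix(self) -> np.ndarray:
        return np.array([list(r) for r in self.rows], dtype="<U1")

    def take_columns(self, idx: Sequence[int]) -> "Alignment":
        mat = self.to_matrix()[:, list(idx)]
        return Alignment(self.ids, tuple("".join(r) for r in mat))


def read_alignment(path: str | Path) -> Alignment:
    """Read an aligned FASTA into an :class:`Alignment`."""
    ids, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        rows.append(str(rec.seq).upper())
    return Alignment(tuple(ids), tuple(rows))


def _distances_from_matrix(mat: np.ndarray, model: str) -> np.ndarray:
    t = mat.shape[0]
    D = np.zeros((t, t))
    for i in range(t):
        for j in range(i + 1, t):
            ok = (mat[i] != GAP) & (mat[j] != GAP)
            n_comp = int(ok.sum())
            if n_comp == 0:
                raise ValueError(
                    f"taxa pair ({i}, {j}) share no ungapped columns"
                )
            p = float((mat[i][ok] != mat[j][ok]).sum()) / n_comp
            if model == "p":
                d = p
            elif model == "poisson":
                if p >= 1.0:
                    raise ValueError(
                        f"taxa pair ({i}, {j}): p-distance 1.0 not Poisson-correctable"
                    )
                d = -np.log(1.0 - p)
            else:
                raise ValueError(f"unknown distance model {model!r}")
            D[i, j] = D[j, i] = d
    return D


def pairwise_distances(aln: Alignment, model: str = "p") -> np.ndarray:
    """Symmetric distance matrix in ``aln.ids`` order.

    ``p`` is the proportion of mismatches over pairwise-ungapped columns;
    ``poisson`` applies the -ln(1-p) correction.
    """
    return _distances_from_matrix(aln.to_matrix(), model)


@dataclass
class TreeNode:
    """Node of an (un)rooted tree; children carry branch lengths."""

    name: Optional[str] = None
    children: List[Tuple["TreeNode", float]] = field(default_factory=list)
    support: Optional[int] = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> Iterator["TreeNode"]:
        if self.is_leaf:
            yield self
        else:
            for child, _ in self.children:
                yield from child.leaves()


@dataclass
class PhyloTree:
    """Unrooted tree, represented with a trifurcating root node."""

    root: TreeNode
    taxa: Tuple[str, ...]

    def leaf_names(self) -> List[str]:
        return [leaf.name for leaf in self.root.leaves()]


def nj_tree(D: np.ndarray, ids: Sequence[str]) -> PhyloTree:
    """Neighbor joining on a symmetric non-negative distance matrix.

    Joins the pair minimizing Q = (m-2) d(i,j) - r_i - r_j; ties go to
    the lowest (row, col) index pair, so the tree is deterministic.
    Negative branch lengths are clamped to 0.
    """
    D = np.asarray(D, dtype=float)
    n = len(ids)
    if D.shape != (n, n):
        raise ValueError("distance matrix shape does not match ids")
    if np.isnan(D).any():
        raise ValueError("distance matrix contains NaN")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix is not symmetric")
    if n < 3:
        raise ValueError("need at least 3 taxa")

    nodes: Dict[int, TreeNode] = {i: TreeNode(name=ids[i]) for i in range(n)}
    dist: Dict[Tuple[int, int], float] = {
        (i, j): float(D[i, j]) for i in range(n) for j in range(i + 1, n)
    }

    def d(a: int, b: int) -> float:
        return 0.0 if a == b else dist[(a, b) if a < b else (b, a)]

    active = list(range(n))
    next_id = n
    while len(active) > 3:
        m = len(active)
        r = {i: sum(d(i, k) for k in active) for i in active}
        best: Optional[Tuple[int, int]] = None
        best_q = np.inf
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d(i, j) - r[i] - r[j]
                if q < best_q - 1e-12:  # strict improvement; first pair wins ties
                    best_q = q
                    best = (i, j)
        i, j = best
        dij = d(i, j)
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        new = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        for k in active:
            if k in (i, j):
                continue
            dist[(k, next_id) if k < next_id else (next_id, k)] = max(
                0.5 * (d(i, k) + d(j, k) - dij), 0.0
            )
        nodes[next_id] = new
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1

    a, b, c = active
    la = max(0.5 * (d(a, b) + d(a, c) - d(b, c)), 0.0)
    lb = max(0.5 * (d(a, b) + d(b, c) - d(a, c)), 0.0)
    lc = max(0.5 * (d(a, c) + d(b, c) - d(a, b)), 0.0)
    root = TreeNode(
        children=[(nodes[a], la), (nodes[b], lb), (nodes[c], lc)]
    )
    _collapse_zero_internal_edges(root)
    return PhyloTree(root=root, taxa=tuple(ids))


def _collapse_zero_internal_edges(node: TreeNode, eps: float = 1e-12) -> None:
    """Contract internal edges of length ~0 (they carry no grouping
    signal), so e.g. an all-zero distance matrix yields a star tree."""
    new_children: List[Tuple[TreeNode, float]] = []
    for child, length in node.children:
        _collapse_zero_internal_edges(child, eps)
        if not child.is_leaf and length <= eps:
            new_children.extend(child.children)
        else:
            new_children.append((child, length))
    node.children = new_children


def _splits_with_nodes(
    tree: PhyloTree,
) -> List[Tuple[TreeNode, FrozenSet[str]]]:
    """(node, canonical split) for every internal edge.

    Each non-root internal node corresponds to one internal edge (the
    edge to its parent); the split is the leaf set below, canonicalized
    to the side not containing the first taxon.
    """
    all_taxa = frozenset(tree.taxa)
    ref = tree.taxa[0]
    out: List[Tuple[TreeNode, FrozenSet[str]]] = []

    def below(node: TreeNode) -> FrozenSet[str]:
        if node.is_leaf:
            return frozenset([node.name])
        leafset = frozenset().union(*(below(ch) for ch, _ in node.children))
        if node is not tree.root and 2 <= len(leafset) <= len(all_taxa) - 2:
            side = all_taxa - leafset if ref in leafset else leafset
            out.append((node, side))
        return leafset

    below(tree.root)
    return out


def bipartitions(tree: PhyloTree) -> FrozenSet[FrozenSet[str]]:
    """Non-trivial bipartitions of the unrooted tree (canonical sides)."""
    return frozenset(split for _, split in _splits_with_nodes(tree))


def bootstrap_support(
    aln: Alignment,
    n: int = 1000,
    seed: int = 0,
    model: str = "p",
) -> PhyloTree:
    """NJ tree on ``aln`` with bootstrap supports on internal edges.

    Columns are resampled with replacement ``n`` times; each replicate is
    rebuilt with the same distance model and NJ; an internal edge's
    support is the percentage of replicates whose tree contains the same
    bipartition. Reproducible for a fixed ``seed``.
    """
    if n < 1:
        raise ValueError("need at least one bootstrap replicate")
    mat = aln.to_matrix()
    tree = nj_tree(_distances_from_matrix(mat, model), aln.ids)
    node_splits = _splits_with_nodes(tree)
    hits = {split: 0 for _, split in node_splits}

    rng = np.random.default_rng(seed)
    n_cols = mat.shape[1]
    for _ in range(n):
        idx = rng.integers(0, n_cols, size=n_cols)
        rep = nj_tree(_distances_from_matrix(mat[:, idx], model), aln.ids)
        rep_splits = bipartitions(rep)
        for split in hits:
            if split in rep_splits:
                hits[split] += 1
    for node, split in node_splits:
        node.support = round(100.0 * hits[split] / n)
    return tree


def _newick_node(node: TreeNode, length: Optional[float]) -> str:
    if node.is_leaf:
        body = node.name
    else:
        inner = ",".join(_newick_node(ch, bl) for ch, bl in node.children)
        label = "" if node.support is None else str(int(node.support))
        body = f"({inner}){label}"
    return body if length is None else f"{body}:{length:.6g}"


def write_newick(tree: PhyloTree) -> str:
    """Serialize to Newick with branch lengths and integer support labels."""
    inner = ",".join(_newick_node(ch, bl) for ch, bl in tree.root.children)
    return f"({inner});"
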