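"""Independent oracles used by the test suite.

These deliberately avoid the package's own implementations: grammar
matching by exhaustive subset enumeration, tree splits and path-length
distances by direct graph traversal, and a pI oracle by dense pH grid
scan. They exist so the production code paths can be checked against
slow-but-obvious computations.
"""

from __future__ import annotations

from itertools import combinations
from typing import Dict, FrozenSet, List, Optional, Set, Tuple

import numpy as np

from hfbscan.grammars import CysGrammar
from hfbscan.phylo import PhyloTree, TreeNode


def brute_force_match(seq: str, grammar: CysGrammar) -> Optional[dict]:
    """Exhaustive 8-subset search over all cysteine positions.

    Returns the valid assignment with minimal leader (ties: smallest
    position tuple) as a dict, or None. No enumeration cap: the caller
    is responsible for keeping the cysteine count small.
    """
    cys = [i for i, ch in enumerate(seq) if ch == "C"]
    valid: List[Tuple[int, Tuple[int, ...], dict]] = []
    for pos in combinations(cys, 8):
        leader = pos[0]
        tail = len(seq) - pos[-1] - 1
        if not (grammar.leader[0] <= leader <= grammar.leader[1]):
            continue
        if not (grammar.tail[0] <= tail <= grammar.tail[1]):
            continue
        gaps = [b - a - 1 for a, b in zip(pos, pos[1:])]
        if any(
            not (lo <= g <= hi) for g, (lo, hi) in zip(gaps, grammar.gaps)
        ):
            continue
        if any(
            ch in grammar.forbid_in_gaps
            for a, b in zip(pos, pos[1:])
            for ch in seq[a + 1 : b]
        ):
            continue
        valid.append(
            (leader, pos, {"positions": pos, "gaps": tuple(gaps), "leader": leader, "tail": tail})
        )
    if not valid:
        return None
    valid.sort(key=lambda t: (t[0], t[1]))
    return valid[0][2]


def tree_splits(tree: PhyloTree) -> FrozenSet[FrozenSet[str]]:
    """Non-trivial bipartitions by direct traversal, canonicalized to the
    side not containing the first taxon."""
    all_taxa = frozenset(tree.taxa)
    ref = tree.taxa[0]
    splits: Set[FrozenSet[str]] = set()

    def below(node: TreeNode) -> FrozenSet[str]:
        if node.is_leaf:
            return frozenset([node.name])
        leafset = frozenset().union(*(below(c) for c, _ in node.children))
        if node is not tree.root and 2 <= len(leafset) <= len(all_taxa) - 2:
            splits.add(all_taxa - leafset if ref in leafset else leafset)
        return leafset

    below(tree.root)
    return frozenset(splits)


def tree_distance_matrix(tree: PhyloTree) -> np.ndarray:
    """Leaf-to-leaf path-length matrix (rows/cols in ``tree.taxa`` order)
    computed by breadth-first traversal of the tree graph."""
    adjacency: Dict[int, List[Tuple[int, float]]] = {}
    names: Dict[int, str] = {}

    def build(node: TreeNode) -> int:
        nid = id(node)
        adjacency.setdefault(nid, [])
        if node.is_leaf:
            names[nid] = node.name
        for child, length in node.children:
            cid = build(child)
            adjacency[nid].append((cid, length))
            adjacency[cid].append((nid, length))
        return nid

    build(tree.root)
    leaf_id = {name: nid for nid, name in names.items()}
    n = len(tree.taxa)
    D = np.zeros((n, n))
    for i, name in enumerate(tree.taxa):
        dist = {leaf_id[name]: 0.0}
        stack = [leaf_id[name]]
        while stack:
            cur = stack.pop()
            for nxt, length in adjacency[cur]:
                if nxt not in dist:
                    dist[nxt] = dist[cur] + length
                    stack.append(nxt)
        for j, other in enumerate(tree.taxa):
            D[i, j] = dist[leaf_id[other]]
    return D


def grid_scan_pi(seq: str, pka=None, step: float = 1e-4) -> float:
    """pI by dense pH grid scan of the net-charge function."""
    from hfbscan.physchem import PkaTable

    pka = pka or PkaTable()
    ph = np.arange(0.0, 14.0 + step, step)
    pos = 1.0 / (1.0 + 10 ** (ph - pka.n_term(seq[0])))
    for aa in ("H", "K", "R"):
        n = seq.count(aa)
        if n:
            pos += n / (1.0 + 10 ** (ph - pka.side_chain[aa]))
    neg = 1.0 / (1.0 + 10 ** (pka.c_term - ph))
    for aa in ("D", "E", "C", "Y"):
        n = seq.count(aa)
        if n:
            neg += n / (1.0 + 10 ** (pka.side_chain[aa] - ph))
    charge = pos - neg
    return float(ph[np.argmin(np.abs(charge))])


def random_protein(rng: np.random.Generator, length: int, cys_bias: float = 0.0) -> str:
    """Random sequence; ``cys_bias`` adds extra probability mass on C."""
    letters = "ACDEFGHIKLMNPQRSTVWY"
    p = np.full(20, (1.0 - cys_bias) / 20.0)
    p[letters.index("C")] += cys_bias
    idx = rng.choice(20, size=length, p=p)
    return "".join(letters[i] for i in idx)
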