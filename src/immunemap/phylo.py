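"""Maximum-parsimony trees from binary mutation presence/absence matrices.

Each patient's loci, plus an all-absent germline taxon, are the leaves; each
mutation is a binary character. For up to 8 leaves every unrooted topology is
scored exhaustively with Fitch counting ((2n-5)!! topologies, 10395 at n=8);
larger instances use a seeded parsimony ratchet (nearest-neighbor-interchange
hill climbing with character reweighting). Branch lengths are the per-edge
character changes under an accelerated-transformation (acctran) style
assignment with the tree rooted at the germline leaf; their sum equals the
parsimony score. Ties between equally parsimonious topologies are broken by
first-found in the deterministic stepwise-addition enumeration order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import ValidationError

EXHAUSTIVE_MAX_LEAVES = 8
GERMLINE = "germline"

# Fitch state sets as 2-bit masks: 1 = {absent}, 2 = {present}, 3 = {both}


@dataclass
class PhyloTree:
    """Unrooted tree over loci plus the germline leaf.

    ``edges`` maps an (node, node) pair to its integer branch length; leaf
    nodes are 0..n_leaves-1 in ``leaf_names`` order, internal nodes follow.
    """

    leaf_names: list[str]
    edges: dict[tuple[int, int], int]
    score: int

    @property
    def total_length(self) -> int:
        return sum(self.edges.values())

    def _adjacency(self) -> dict[int, list[int]]:
        adj: dict[int, list[int]] = {}
        for u, v in self.edges:
            adj.setdefault(u, []).append(v)
            adj.setdefault(v, []).append(u)
        return adj

    def to_newick(self) -> str:
        """Newick string rooted for display at the germline leaf."""
        adj = self._adjacency()
        lengths = {}
        for (u, v), w in self.edges.items():
            lengths[(u, v)] = w
            lengths[(v, u)] = w
        germ = self.leaf_names.index(GERMLINE) if GERMLINE in self.leaf_names else 0

        def render(node: int, parent: int) -> str:
            children = [n for n in adj[node] if n != parent]
            if not children:
                return f"{self.leaf_names[node]}:{lengths[(parent, node)]}"
            inner = ",".join(render(c, node) for c in sorted(children))
            blen = f":{lengths[(parent, node)]}" if parent >= 0 else ""
            return f"({inner}){blen}"

        hub = adj[germ][0]
        if len(adj[hub]) == 1:  # two-leaf tree: a single edge
            return (
                f"({self.leaf_names[germ]}:0,"
                f"{self.leaf_names[hub]}:{lengths[(germ, hub)]});"
            )
        return render(hub, -1) + ";"


def _enumerate_topologies(n_leaves: int):
    """Yield all unrooted binary topologies as edge lists (stepwise addition).

    Leaves are 0..n_leaves-1; internal nodes are numbered from n_leaves.
    The generation order is deterministic.
    """
    if n_leaves == 2:
        yield [(0, 1)]
        return
    first_internal = n_leaves
    base = [(0, first_internal), (1, first_internal), (2, first_internal)]

    def grow(edges: list[tuple[int, int]], next_leaf: int, next_internal: int):
        if next_leaf == n_leaves:
            yield list(edges)
            return
        for i in range(len(edges)):
            u, v = edges[i]
            new = edges[:i] + edges[i + 1:]
            new += [(u, next_internal), (v, next_internal), (next_leaf, next_internal)]
            yield from grow(new, next_leaf + 1, next_internal + 1)

    yield from grow(base, 3, first_internal + 1)


def _postorder(adj: dict[int, list[int]], root: int) -> list[tuple[int, int]]:
    """(node, parent) pairs, children before parents, deterministic order."""
    order: list[tuple[int, int]] = []
    stack = [(root, -1)]
    while stack:
        node, parent = stack.pop()
        order.append((node, parent))
        for nb in sorted(adj[node]):
            if nb != parent:
                stack.append((nb, node))
    return order[::-1]


def _fitch_score(edges: list[tuple[int, int]], leaf_masks: np.ndarray, n_leaves: int) -> int:
    """Fitch parsimony score over all characters (vectorized per node)."""
    adj: dict[int, list[int]] = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    n_nodes = max(max(u, v) for u, v in edges) + 1
    n_chars = leaf_masks.shape[1]
    masks = np.zeros((n_nodes, n_chars), dtype=np.uint8)
    masks[:n_leaves] = leaf_masks
    root = 0
    score = 0
    for node, parent in _postorder(adj, root):
        children = [n for n in adj[node] if n != parent]
        if not children or node < n_leaves:
            continue
        acc = masks[children[0]].copy()
        for c in children[1:]:
            inter = acc & masks[c]
            union_needed = inter == 0
            score += int(union_needed.sum())
            acc = np.where(union_needed, acc | masks[c], inter)
        masks[node] = acc
    # root is a leaf: one more union event wherever its state is absent
    # from its neighbor's set
    nb = adj[root][0]
    if nb >= n_leaves:
        score += int(((masks[root] & masks[nb]) == 0).sum())
    else:
        score += int((masks[root] != masks[nb]).sum())
    return score


def _acctran_lengths(
    edges: list[tuple[int, int]], leaf_masks: np.ndarray, n_leaves: int, root: int
) -> dict[tuple[int, int], int]:
    """Per-edge change counts from a deterministic Fitch refinement.

    The tree is rooted at ``root`` (a leaf, normally germline, whose state is
    known); the up-pass assigns each node its parent's state when compatible
    with the preliminary Fitch set, else the forced alternative, which places
    changes as high as the minimal assignment allows for binary characters.
    """
    adj: dict[int, list[int]] = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    n_nodes = max(max(u, v) for u, v in edges) + 1
    n_chars = leaf_masks.shape[1]
    prelim = np.zeros((n_nodes, n_chars), dtype=np.uint8)
    prelim[:n_leaves] = leaf_masks
    order = _postorder(adj, root)
    for node, parent in order:
        children = [n for n in adj[node] if n != parent]
        if not children or node < n_leaves:
            continue
        acc = prelim[children[0]].copy()
        for c in children[1:]:
            inter = acc & prelim[c]
            acc = np.where(inter == 0, acc | prelim[c], inter)
        prelim[node] = acc
    final = np.zeros_like(prelim)
    final[root] = prelim[root]
    lengths: dict[tuple[int, int], int] = {}
    for node, parent in order[::-1]:
        if parent < 0:
            continue
        compatible = (final[parent] & prelim[node]) != 0
        final[node] = np.where(compatible, final[parent], prelim[node])
        changes = int((final[node] != final[parent]).sum())
        key = (min(node, parent), max(node, parent))
        lengths[key] = changes
    return lengths


def _leaf_masks(presence: pd.DataFrame) -> tuple[list[str], np.ndarray]:
    """Leaf names (loci + germline) and their Fitch state masks."""
    loci = list(presence.columns)
    chars = presence.to_numpy().T  # loci x mutations
    names = loci + [GERMLINE]
    masks = np.empty((len(names), chars.shape[1]), dtype=np.uint8)
    masks[: len(loci)] = np.where(chars > 0, 2, 1)
    masks[len(loci)] = 1  # germline carries no somatic mutation
    return names, masks


def build_tree(presence: pd.DataFrame, seed: int = 0) -> PhyloTree:
    """Maximum-parsimony unrooted tree for one patient's presence matrix."""
    if presence.shape[0] == 0:
        raise ValidationError("presence matrix has no mutations")
    names, masks = _leaf_masks(presence)
    n = len(names)
    if n == 2:
        edges = [(0, 1)]
        score = _fitch_score(edges, masks, n)
        lengths = _acctran_lengths(edges, masks, n, root=n - 1)
        return PhyloTree(names, lengths, score)
    if n <= EXHAUSTIVE_MAX_LEAVES:
        best_edges, best_score = None, None
        for edges in _enumerate_topologies(n):
            score = _fitch_score(edges, masks, n)
            if best_score is None or score < best_score:
                best_edges, best_score = edges, score
    else:
        best_edges, best_score = _ratchet(masks, n, seed)
    lengths = _acctran_lengths(best_edges, masks, n, root=n - 1)
    return PhyloTree(names, lengths, best_score)


def parsimony_score(presence: pd.DataFrame) -> int:
    """Parsimony score of the best tree without acctran annotation."""
    return build_tree(presence).score


# -- ratchet search for > EXHAUSTIVE_MAX_LEAVES leaves ----------------------

def _nni_neighbors(edges: list[tuple[int, int]], n_leaves: int):
    """All trees one nearest-neighbor interchange away."""
    adj: dict[int, list[int]] = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    for u, v in edges:
        if u < n_leaves or v < n_leaves:
            continue  # internal edges only
        a, b = [x for x in adj[u] if x != v]
        c, d = [x for x in adj[v] if x != u]
        touched = ({u, v}, {u, a}, {u, b}, {v, c}, {v, d})
        others = [e for e in edges if set(e) not in touched]
        for swap_c in (c, d):
            keep = d if swap_c is c else c
            new = others + [(u, v), (a, u), (swap_c, u), (b, v), (keep, v)]
            yield new


def _ratchet(
    masks: np.ndarray, n_leaves: int, seed: int, n_ratchet: int = 20
) -> tuple[list[tuple[int, int]], int]:
    rng = np.random.default_rng(seed)
    first_internal = n_leaves
    edges = [(0, first_internal), (1, first_internal), (2, first_internal)]
    nxt = first_internal + 1
    for leaf in range(3, n_leaves):  # greedy stepwise addition
        best = None
        for i in range(len(edges)):
            u, v = edges[i]
            cand = edges[:i] + edges[i + 1:] + [(u, nxt), (v, nxt), (leaf, nxt)]
            s = _fitch_score(cand, masks, n_leaves)
            if best is None or s < best[1]:
                best = (cand, s)
        edges = best[0]
        nxt += 1

    def hill_climb(start: list[tuple[int, int]], m: np.ndarray):
        cur, cur_s = start, _fitch_score(start, masks, n_leaves)
        improved = True
        while improved:
            improved = False
            for cand in _nni_neighbors(cur, n_leaves):
                s = _fitch_score(cand, m, n_leaves)
                if s < cur_s:
                    cur, cur_s = cand, s
                    improved = True
                    break
        return cur, _fitch_score(cur, masks, n_leaves)

    best_edges, best_score = hill_climb(edges, masks)
    n_chars = masks.shape[1]
    for _ in range(n_ratchet):
        # perturbation phase: upweight a random quarter of the characters
        w = np.ones(n_chars, dtype=int)
        boost = rng.random(n_chars) < 0.25
        w[boost] = 3
        weighted = np.repeat(masks, w, axis=1)
        pert, _ = hill_climb(best_edges, weighted)
        cand_edges, cand_score = hill_climb(pert, masks)
        if cand_score < best_score:
            best_edges, best_score = cand_edges, cand_score
    return best_edges, best_score
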