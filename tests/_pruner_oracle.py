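"""Brute-force oracle for the paralogy pruner, plus tree/partition enumerators.

Everything here is independent of the package's search: feasibility of a
kept-leaf subset is checked directly from the definition (some hub node
around which every component is taxon-pure or taxon-free), and the optimum
is found by scanning every leaf subset.  Trees are edge lists over integer
nodes with leaves 0..n-1.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

Edge = tuple[int, int]


def topologies(n_leaves: int):
    """All labeled unrooted binary topologies on leaves 0..n-1 (edge lists)."""
    if n_leaves < 3:
        raise ValueError("need >= 3 leaves")
    base = [(0, n_leaves), (1, n_leaves), (2, n_leaves)]
    trees = [(base, n_leaves + 1)]
    for leaf in range(3, n_leaves):
        nxt = []
        for edges, next_node in trees:
            for i, (u, v) in enumerate(edges):
                new = edges[:i] + edges[i + 1 :]
                new = new + [(u, next_node), (v, next_node), (leaf, next_node)]
                nxt.append((new, next_node + 1))
        trees = nxt
    return [edges for edges, _ in trees]


def leaf_partitions(n_leaves: int, max_blocks: int):
    """Set partitions of 0..n-1 into at most ``max_blocks`` blocks.

    Yielded as tuples block_of[leaf] in restricted-growth form, so each
    partition appears exactly once up to block renaming.
    """
    def rec(prefix, used):
        i = len(prefix)
        if i == n_leaves:
            yield tuple(prefix)
            return
        for b in range(min(used + 1, max_blocks)):
            prefix.append(b)
            yield from rec(prefix, max(used, b + 1))
            prefix.pop()

    yield from rec([], 0)


def adjacency(edges: list[Edge]) -> dict[int, list[int]]:
    adj: dict[int, list[int]] = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    return adj


def component_masks(edges: list[Edge], n_leaves: int) -> dict[int, list[int]]:
    """node -> list of leaf bitmasks of the components of tree minus node."""
    adj = adjacency(edges)

    def mask_from(start: int, banned: int) -> int:
        seen = {banned, start}
        stack = [start]
        m = 1 << start if start < n_leaves else 0
        while stack:
            u = stack.pop()
            for w in adj[u]:
                if w not in seen:
                    seen.add(w)
                    if w < n_leaves:
                        m |= 1 << w
                    stack.append(w)
        return m

    return {v: [mask_from(nb, v) for nb in adj[v]] for v in adj}


def feasible(kept: int, taxon_masks: list[int], comps: dict[int, list[int]]) -> bool:
    """Every taxon's kept leaves could form a clade under some rooting/refinement."""
    for tmask in taxon_masks:
        k = kept & tmask
        if k == 0 or k & (k - 1) == 0:
            continue
        others = kept & ~tmask
        if others == 0:
            continue
        ok = False
        for comp_list in comps.values():
            if all(not ((c & k) and (c & others)) for c in comp_list):
                ok = True
                break
        if not ok:
            return False
    return True


def best_subtree(edges: list[Edge], blocks: tuple[int, ...], rank=None):
    """Exhaustive optimum: (taxa, leaves) max, then lex-smallest leaf set.

    ``rank`` maps leaf index -> position in the label order used for the
    lexicographic tie-break (identity by default).  Returns the objective,
    the lex key, and the kept leaf set.
    """
    n_leaves = len(blocks)
    if rank is None:
        rank = list(range(n_leaves))
    n_blocks = max(blocks) + 1
    taxon_masks = [0] * n_blocks
    for leaf, b in enumerate(blocks):
        taxon_masks[b] |= 1 << leaf
    comps = component_masks(edges, n_leaves)
    best = None
    best_lex = None
    best_kept = None
    for kept in range(1, 1 << n_leaves):
        if not feasible(kept, taxon_masks, comps):
            continue
        taxa = sum(1 for tm in taxon_masks if kept & tm)
        leaves = kept.bit_count()
        lex = tuple(sorted(rank[i] for i in range(n_leaves) if kept >> i & 1))
        obj = (taxa, leaves)
        if best is None or obj > best or (obj == best and lex < best_lex):
            best = obj
            best_lex = lex
            best_kept = kept
    return best, best_lex, best_kept


def canonical_form(edges: list[Edge], blocks: tuple[int, ...]) -> str:
    """AHU canonical string of the taxon-colored unrooted tree (centroid-rooted)."""
    adj = adjacency(edges)
    n_nodes = len(adj)
    # centroid(s): minimise the largest component after node removal
    sizes = {}
    def subtree_size(u, parent):
        s = 1
        for w in adj[u]:
            if w != parent:
                s += subtree_size(w, u)
        return s

    best_score = None
    centroids = []
    for v in adj:
        score = max(subtree_size(w, v) for w in adj[v])
        if best_score is None or score < best_score:
            best_score = score
            centroids = [v]
        elif score == best_score:
            centroids.append(v)

    n_leaves = len(blocks)

    def encode(u, parent):
        children = sorted(encode(w, u) for w in adj[u] if w != parent)
        label = f"c{blocks[u]}" if u < n_leaves else "i"
        return "(" + label + "".join(children) + ")"

    return min(encode(c, -1) for c in centroids)
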