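"""Paralogy screening of multi-labeled gene trees.

A gene tree whose leaves carry (taxon, sequence-id) labels shows evidence of
paralogy when some taxon's sequences are polyphyletic: no edge of the tree
separates them from every other taxon's sequences.  The screen prunes such a
tree to the maximal subtree in which every taxon's retained sequences are
non-polyphyletic, and the strict gene filter then discards any gene that
needed pruning at all.

Non-polyphyly is evaluated as "could be a clade under some rooting and some
resolution of polytomies": taxon T's retained leaves qualify iff there is a
node v such that every component of the tree minus v contains either only
T's retained leaves or none of them.  On a binary tree this is exactly the
split-side criterion; on a partially collapsed tree (weakly supported edges
turned into polytomies) it refrains from pruning when the conflict rests
only on weak edges, which is what makes the relaxed mode monotone.

Maximality is: most distinct taxa retained, then most leaves, with the
remaining tie broken by the lexicographically smallest leaf set (sorted by
(taxon, sequence-id) label).  The search is exact — a branch-and-bound over
candidate "regions" (unions of components around a hub node) per multi-copy
taxon — and the lex tie-break admits a tight bound (the smallest alive leaf
ranks), so degenerate tie spaces such as an ancestral duplication spanning
many taxa do not blow the search up.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy

from .errors import InvalidInputError, TooFewSequencesError
from .treekit import nj_tree

log = logging.getLogger(__name__)

Leaf = tuple[str, str]  # (taxon, sequence id)


@dataclass
class PruneResult:
    gene_id: str
    retained_leaves: set[Leaf]
    removed_leaves: set[Leaf]
    is_clean: bool

    def __post_init__(self) -> None:
        if bool(self.removed_leaves) == self.is_clean:
            raise InvalidInputError("is_clean must hold exactly when nothing was removed")


def _popcount(x: int) -> int:
    return x.bit_count()


class LeafTree:
    """Unrooted leaf-labeled tree over bitmask leaf sets.

    ``leaves`` are (taxon, seqid) pairs; bit i corresponds to the i-th leaf
    in sorted order, which is also the order used for the lexicographic
    tie-break.  ``edges`` are (u, v, length) over node indices; leaf node u
    carries leaf index ``leaf_of_node[u]``.
    """

    def __init__(
        self,
        n_nodes: int,
        edges: Sequence[tuple[int, int, float]],
        leaf_of_node: Mapping[int, Leaf],
    ) -> None:
        order = sorted(leaf_of_node.values())
        if len(set(order)) != len(order):
            raise InvalidInputError("duplicate (taxon, sequence-id) leaf labels")
        self.leaves: list[Leaf] = order
        self.bit: dict[Leaf, int] = {lf: i for i, lf in enumerate(order)}
        self.n = len(order)
        self.full = (1 << self.n) - 1
        adj: dict[int, list[tuple[int, float]]] = {u: [] for u in range(n_nodes)}
        for u, v, ln in edges:
            adj[u].append((v, ln))
            adj[v].append((u, ln))
        self._adj = adj
        self._leaf_of_node = dict(leaf_of_node)
        # leaf mask under each directed edge, by iterative post-order from node 0
        down: dict[tuple[int, int], int] = {}
        root = 0
        stack = [(root, -1, False)]
        while stack:
            node, parent, done = stack.pop()
            if not done:
                stack.append((node, parent, True))
                for nb, _ in adj[node]:
                    if nb != parent:
                        stack.append((nb, node, False))
            else:
                m = 0
                if node in self._leaf_of_node:
                    m |= 1 << self.bit[self._leaf_of_node[node]]
                for nb, _ in adj[node]:
                    if nb != parent:
                        m |= down[(node, nb)]
                if parent >= 0:
                    down[(parent, node)] = m
        for (u, v), m in list(down.items()):
            down[(v, u)] = self.full ^ m
        self._down = down
        # components around each node, and undirected edges for Steiner length
        self.comps: list[list[int]] = [
            [down[(v, nb)] for nb, _ in adj[v]] for v in range(n_nodes)
        ]
        seen = set()
        self.edge_masks: list[tuple[int, float]] = []
        for u, v, ln in edges:
            key = (min(u, v), max(u, v))
            if key not in seen:
                seen.add(key)
                self.edge_masks.append((down[(u, v)] if (u, v) in down else down[(v, u)], ln))
        self.taxa: dict[str, int] = {}
        for lf, i in self.bit.items():
            self.taxa[lf[0]] = self.taxa.get(lf[0], 0) | (1 << i)

    # -- criterion ---------------------------------------------------------

    def taxon_ok(self, kept: int, tmask: int) -> bool:
        """Non-polyphyly of one taxon's kept leaves within the kept set."""
        k = kept & tmask
        if k & (k - 1) == 0:  # zero or one leaf
            return True
        others = kept & ~tmask & self.full
        if others == 0:
            return True
        for comps_v in self.comps:
            for c in comps_v:
                if (c & k) and (c & others):
                    break
            else:
                return True
        return False

    def all_ok(self, kept: int) -> bool:
        return all(self.taxon_ok(kept, tm) for tm in self.taxa.values())

    def steiner_length(self, kept: int) -> float:
        total = 0.0
        for mask, ln in self.edge_masks:
            if (kept & mask) and (kept & ~mask & self.full):
                total += ln
        return total

    def _lex_key(self, kept: int) -> tuple[int, ...]:
        return tuple(i for i in range(self.n) if kept >> i & 1)

    def objective(self, kept: int) -> tuple[int, int]:
        taxa = sum(1 for tm in self.taxa.values() if kept & tm)
        return (taxa, _popcount(kept))

    # -- candidate regions -------------------------------------------------

    def _candidate_regions(self, tmask: int) -> list[int]:
        """Minimal regions per realized own-subset (antichain under subset)."""
        by_own: dict[int, list[int]] = {}
        for comps_v in self.comps:
            tcomps = [c for c in comps_v if c & tmask]
            if len(tcomps) < 2:
                continue
            if len(tcomps) > 16:
                raise InvalidInputError("polytomy too large for exact pruning search")
            for r in range(1, len(tcomps) + 1):
                for sub in itertools.combinations(tcomps, r):
                    region = 0
                    for c in sub:
                        region |= c
                    by_own.setdefault(tmask & region, []).append(region)
        out: list[int] = []
        for own, regions in by_own.items():
            regions = sorted(set(regions), key=_popcount)
            minimal: list[int] = []
            for reg in regions:
                if not any(prev & reg == prev for prev in minimal):
                    minimal.append(reg)
            out.extend(minimal)
        return sorted(set(out), key=lambda m: (_popcount(m), m))

    # -- exact search ------------------------------------------------------

    def solve(self) -> int:
        """Kept-leaf bitmask of the maximal non-polyphyletic subtree.

        Phase 1 maximizes (distinct taxa, leaves) by branch-and-bound over
        per-taxon candidate regions.  Phase 2 resolves the remaining ties to
        the lexicographically smallest leaf set by fixing leaf ranks one at
        a time, each step a feasibility search for the phase-1 optimum under
        the accumulated forced-in/forced-out constraints.
        """
        if self.all_ok(self.full):
            return self.full
        taxa = sorted(self.taxa.items())
        single_mask = 0
        multi = [(t, m) for t, m in taxa if m & (m - 1) != 0]
        for t, m in taxa:
            if m & (m - 1) == 0:
                single_mask |= m
        cands = [
            sorted(self._candidate_regions(m), key=lambda r: (_popcount(r), r))
            for _, m in multi
        ]
        owns = [m for _, m in multi]
        order = sorted(range(len(multi)), key=lambda i: (len(cands[i]), multi[i][0]))
        cands = [cands[i] for i in order]
        owns = [owns[i] for i in order]

        best = self._search(single_mask, owns, cands, 0, 0, None)
        assert best is not None
        target, _ = best
        in_mask = 0
        out_mask = 0
        n_in = 0
        for r in range(self.n):
            if n_in == target[1]:
                out_mask |= self.full ^ in_mask
                break
            bit = 1 << r
            if self._search(single_mask, owns, cands, in_mask | bit, out_mask, target):
                in_mask |= bit
                n_in += 1
            else:
                out_mask |= bit
        return in_mask

    def _search(
        self,
        single_mask: int,
        owns: list[int],
        cands: list[list[int]],
        forced_in: int,
        forced_out: int,
        target: tuple[int, int] | None,
    ):
        """Branch-and-bound over region assignments.

        With ``target`` None, maximizes (taxa, leaves) and returns
        ((taxa, leaves), kept).  With a target, returns the first solution
        reaching it (a feasibility check), or None.
        """
        n_multi = len(owns)
        singles_eff = single_mask & ~forced_out
        owns_eff = [m & ~forced_out for m in owns]
        state: dict = {"best": None}
        chosen: list[int] = []
        contrib: list[int] = []

        class Found(Exception):
            pass

        def evaluate(s_multi: int) -> None:
            kept = singles_eff & ~s_multi
            for own, region in zip(owns_eff, chosen):
                kept |= own & region & ~s_multi
            if forced_in & ~kept:
                return
            obj = (
                _popcount(kept & singles_eff) + sum(1 for c in contrib if c),
                _popcount(kept),
            )
            if target is not None:
                if obj >= target:
                    state["best"] = (obj, kept)
                    raise Found
                return
            if state["best"] is None or obj > state["best"][0]:
                state["best"] = (obj, kept)

        def refined_leaf_cap(idx: int, ne: int) -> int:
            """Max leaves of any completion that keeps every live taxon alive.

            A region contributing more than one leaf for a remaining taxon in
            such a completion cannot cover a live singleton's leaf, cannot
            wipe out an assigned taxon's current contribution, and cannot
            swallow another remaining taxon whole; maximizing per taxon over
            regions passing those necessary checks bounds all of them at
            once.  Completions that let a taxon die are dominated through the
            taxa component of the objective, so the bound stays valid
            lexicographically.
            """
            single_ne = singles_eff & ne
            total = _popcount(single_ne) + sum(_popcount(c) for c in contrib)
            for i in range(idx, n_multi):
                cap = 0
                best_raw = 0
                for region in cands[i]:
                    raw = _popcount(owns_eff[i] & region & ne)
                    best_raw = max(best_raw, raw)
                    if raw <= cap:
                        continue
                    if region & single_ne:
                        continue
                    if any(c and not (c & ~region) for c in contrib):
                        continue
                    if any(
                        j != i and not (owns_eff[j] & ne & ~region)
                        for j in range(idx, n_multi)
                    ):
                        continue
                    cap = raw
                total += min(cap if cap else min(best_raw, 1), best_raw)
            return total

        def dfs(idx: int, s_once: int, s_multi: int) -> None:
            if forced_in & s_multi:
                return
            if idx == n_multi:
                evaluate(s_multi)
                return
            ne = ~s_multi
            ub_taxa = (
                _popcount(singles_eff & ne)
                + sum(1 for c in contrib if c)
                + (n_multi - idx)
            )
            ub_leaves = (
                _popcount(singles_eff & ne)
                + sum(_popcount(c) for c in contrib)
                + sum(_popcount(owns_eff[i] & ne) for i in range(idx, n_multi))
            )
            if target is not None:
                if (ub_taxa, ub_leaves) < target:
                    return
                if (ub_taxa, refined_leaf_cap(idx, ne)) < target:
                    return
            elif state["best"] is not None:
                if (ub_taxa, ub_leaves) <= state["best"][0]:
                    return
                if (ub_taxa, refined_leaf_cap(idx, ne)) <= state["best"][0]:
                    return
            must_cover = forced_in & owns[idx]
            for region in cands[idx]:
                if must_cover & ~region:
                    continue
                new_multi = s_multi | (s_once & region)
                delta = new_multi & ~s_multi
                saved = None
                if delta:
                    saved = contrib[:]
                    nm = ~new_multi
                    for i, reg in enumerate(chosen):
                        if contrib[i] & delta:
                            contrib[i] = owns_eff[i] & reg & nm
                chosen.append(region)
                contrib.append(owns_eff[idx] & region & ~new_multi)
                try:
                    dfs(idx + 1, s_once | region, new_multi)
                finally:
                    chosen.pop()
                    contrib.pop()
                    if saved is not None:
                        contrib[: len(saved)] = saved

        try:
            # singleton taxa hold their pendant regions from the start, so a
            # multi-taxon region overlapping one knocks its leaf out
            dfs(0, single_mask, 0)
        except Found:
            pass
        return state["best"]

    def kept_leaves(self, mask: int) -> set[Leaf]:
        return {self.leaves[i] for i in range(self.n) if mask >> i & 1}


def _parse_leaf_label(label: str) -> Leaf:
    if "|" in label:
        taxon, seqid = label.split("|", 1)
        return (taxon, seqid)
    return (label, label)


def leaf_tree_from_dendropy(tree: dendropy.Tree) -> LeafTree:
    """Convert a dendropy tree, suppressing degree-2 nodes (rooted seeds)."""
    nodes = list(tree.preorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(nodes)}
    adj: dict[int, dict[int, float]] = {i: {} for i in range(len(nodes))}
    leaf_of_node: dict[int, Leaf] = {}
    for nd in nodes:
        i = index[id(nd)]
        if nd.is_leaf():
            if nd.taxon is None or nd.taxon.label is None:
                raise InvalidInputError("unlabeled leaf in gene tree")
            leaf_of_node[i] = _parse_leaf_label(nd.taxon.label)
        for ch in nd.child_nodes():
            ln = ch.edge.length if ch.edge.length is not None else 1.0
            adj[i][index[id(ch)]] = ln
            adj[index[id(ch)]][i] = ln
    # suppress degree-2 internal nodes (e.g. the seed of a rooted newick)
    changed = True
    while changed:
        changed = False
        for u in list(adj):
            if u in leaf_of_node or len(adj[u]) != 2:
                continue
            (a, la), (b, lb) = adj[u].items()
            del adj[a][u]
            del adj[b][u]
            del adj[u]
            merged = la + lb
            if b in adj[a]:  # parallel edge would be degenerate
                merged = min(merged, adj[a][b])
            adj[a][b] = merged
            adj[b][a] = merged
            changed = True
    remap = {u: i for i, u in enumerate(sorted(adj))}
    edges = []
    for u in adj:
        for v, ln in adj[u].items():
            if remap[u] < remap[v]:
                edges.append((remap[u], remap[v], ln))
    leaves = {remap[u]: lf for u, lf in leaf_of_node.items() if u in remap}
    return LeafTree(len(remap), edges, leaves)


def _collapse_weak_edges(tree: dendropy.Tree, threshold: float) -> dendropy.Tree:
    clone = tree.clone(depth=1)

    def support_of(nd: dendropy.Node) -> float | None:
        if nd.label is None:
            return None
        try:
            return float(nd.label)
        except ValueError:
            return None

    to_collapse = []
    skip: set[int] = set()
    seed_children = clone.seed_node.child_nodes() if clone.seed_node else []
    if len(seed_children) == 2:
        # a bifurcating seed splits one unrooted edge across both child
        # edges; treat them as a single edge with the labeled support
        vals = [s for s in (support_of(nd) for nd in seed_children) if s is not None]
        skip.update(id(nd) for nd in seed_children)
        if vals and min(vals) < threshold:
            to_collapse.extend(nd.edge for nd in seed_children if not nd.is_leaf())
    for nd in clone.preorder_node_iter():
        if nd.is_leaf() or nd.parent_node is None or id(nd) in skip:
            continue
        support = support_of(nd)
        if support is not None and support < threshold:
            to_collapse.append(nd.edge)
    for edge in to_collapse:
        edge.collapse()
    return clone


def prune_paralogs(
    tree: dendropy.Tree,
    support_collapse_threshold: float | None = None,
    gene_id: str = "",
) -> PruneResult:
    """Prune a gene tree to the maximal subtree with no polyphyletic taxon.

    With ``support_collapse_threshold`` set, internal edges whose numeric
    support label is below the threshold are collapsed into polytomies
    before the criterion is checked, so weakly supported conflict does not
    trigger pruning.
    """
    if support_collapse_threshold is not None:
        tree = _collapse_weak_edges(tree, support_collapse_threshold)
    lt = leaf_tree_from_dendropy(tree)
    kept_mask = lt.solve()
    retained = lt.kept_leaves(kept_mask)
    removed = set(lt.leaves) - retained
    return PruneResult(
        gene_id=gene_id,
        retained_leaves=retained,
        removed_leaves=removed,
        is_clean=not removed,
    )


def estimate_gene_tree(rows: Mapping[str, str]) -> dendropy.Tree:
    """NJ gene tree on p-distances; row keys are ``taxon|seqid`` labels."""
    if len(rows) < 3:
        raise TooFewSequencesError(f"need >= 3 sequences, got {len(rows)}")
    return nj_tree(rows)


def strict_gene_filter(results: Sequence[PruneResult]) -> tuple[list[str], list[str]]:
    """Partition prune results into clean and flagged gene id lists."""
    seen = set()
    clean: list[str] = []
    flagged: list[str] = []
    for res in results:
        if res.gene_id in seen:
            raise InvalidInputError(f"duplicate gene id {res.gene_id!r}")
        seen.add(res.gene_id)
        (clean if res.is_clean else flagged).append(res.gene_id)
    return clean, flagged
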