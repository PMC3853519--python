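"""Deterministic tree machinery: neighbor-joining, bootstrap, Robinson-Foulds.

These are the desk-scale stand-ins for the external maximum-likelihood
machinery the full-size analysis would use: gene trees and the final
supermatrix tree are estimated by neighbor-joining on uncorrected p-distances,
split support comes from a nonparametric bootstrap, and tree recovery is
scored by the Robinson-Foulds distance.  All three are deterministic under a
fixed seed, with the tie-break rules spelled out below so that results are
reproducible bit-for-bit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import dendropy
import numpy as np

from .errors import InvalidInputError

log = logging.getLogger(__name__)

_ACGT = "ACGT"


@dataclass
class DistanceMatrix:
    """Symmetric distance matrix with ordered labels.

    Invariants checked on construction: symmetry, zero diagonal, finite and
    non-negative entries.
    """

    labels: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise InvalidInputError(
                f"distance matrix shape {self.values.shape} does not match {n} labels"
            )
        if not np.all(np.isfinite(self.values)):
            raise InvalidInputError("distance matrix contains non-finite entries")
        if np.any(self.values < 0):
            raise InvalidInputError("distance matrix contains negative entries")
        if np.any(np.diag(self.values) != 0):
            raise InvalidInputError("distance matrix diagonal must be zero")
        if not np.allclose(self.values, self.values.T, rtol=0, atol=1e-12):
            raise InvalidInputError("distance matrix must be symmetric")

    def __len__(self) -> int:
        return len(self.labels)


def _encode_rows(rows: Mapping[str, str]) -> tuple[list[str], np.ndarray]:
    labels = list(rows)
    lengths = {len(rows[l]) for l in labels}
    if len(lengths) > 1:
        raise InvalidInputError("alignment rows have unequal lengths")
    table = np.full(256, 255, dtype=np.uint8)
    for i, b in enumerate(_ACGT):
        table[ord(b)] = i
        table[ord(b.lower())] = i
    mat = np.vstack(
        [table[np.frombuffer(rows[l].encode("ascii"), dtype=np.uint8)] for l in labels]
    )
    return labels, mat


def p_distance_matrix(rows: Mapping[str, str]) -> DistanceMatrix:
    """Uncorrected p-distances with pairwise deletion.

    Sites where either row carries a gap or any ambiguity code are excluded
    from that pair's comparison.  A pair with no comparable site (e.g. two
    disjoint fragments) gets the triangle upper bound min_k d(i,k)+d(k,j)
    over rows comparable to both, or 0.0 if no such row exists.
    """
    labels, mat = _encode_rows(rows)
    n = len(labels)
    d = np.zeros((n, n))
    undefined: list[tuple[int, int]] = []
    valid_rows = mat != 255
    for i in range(n):
        for j in range(i + 1, n):
            ok = valid_rows[i] & valid_rows[j]
            m = int(ok.sum())
            if m == 0:
                undefined.append((i, j))
                continue
            diff = int(((mat[i] != mat[j]) & ok).sum())
            d[i, j] = d[j, i] = diff / m
    for i, j in undefined:
        candidates = [
            d[i, k] + d[k, j]
            for k in range(n)
            if k not in (i, j) and (i, k) not in undefined and (k, i) not in undefined
            and (j, k) not in undefined and (k, j) not in undefined
        ]
        est = min(candidates) if candidates else 0.0
        d[i, j] = d[j, i] = est
        log.debug("no comparable sites for (%s, %s); imputed %.4f", labels[i], labels[j], est)
    return DistanceMatrix(labels, d)


def neighbor_joining(d: DistanceMatrix) -> dendropy.Tree:
    """Standard neighbor-joining agglomeration.

    Ties in the Q criterion are broken by the lexicographically smallest
    (row, column) index pair, so the result is deterministic.  Negative
    branch-length estimates are clamped to zero and the deficit is logged.
    """
    n = len(d)
    if n < 3:
        raise InvalidInputError("neighbor joining requires at least 3 labels")
    tns = dendropy.TaxonNamespace(d.labels)
    nodes: list[dendropy.Node] = []
    for lab in d.labels:
        node = dendropy.Node()
        node.taxon = tns.get_taxon(lab)
        nodes.append(node)
    dm = d.values.copy()

    def clamp(x: float) -> float:
        if x < 0:
            log.debug("negative NJ branch length %.6g clamped to 0", x)
            return 0.0
        return x

    while len(nodes) > 3:
        m = len(nodes)
        r = dm.sum(axis=1)
        q = (m - 2) * dm - r[:, None] - r[None, :]
        iu = np.triu_indices(m, k=1)
        flat = q[iu]
        k = int(np.argmin(flat))  # first occurrence = smallest (i, j) pair
        i, j = int(iu[0][k]), int(iu[1][k])
        li = 0.5 * dm[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = dm[i, j] - li
        parent = dendropy.Node()
        ci, cj = nodes[i], nodes[j]
        parent.add_child(ci)
        parent.add_child(cj)
        ci.edge.length = clamp(li)
        cj.edge.length = clamp(lj)
        dnew = 0.5 * (dm[i, :] + dm[j, :] - dm[i, j])
        dm[i, :] = dnew
        dm[:, i] = dnew
        dm[i, i] = 0.0
        dm = np.delete(np.delete(dm, j, axis=0), j, axis=1)
        nodes[i] = parent
        del nodes[j]

    # resolve the final three-way join with the three-point formulas
    center = dendropy.Node()
    (a, b, c) = nodes
    la = 0.5 * (dm[0, 1] + dm[0, 2] - dm[1, 2])
    lb = 0.5 * (dm[0, 1] + dm[1, 2] - dm[0, 2])
    lc = 0.5 * (dm[0, 2] + dm[1, 2] - dm[0, 1])
    for node, ln in ((a, la), (b, lb), (c, lc)):
        center.add_child(node)
        node.edge.length = clamp(ln)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=center)
    tree.is_rooted = False
    return tree


def nj_tree(rows: Mapping[str, str]) -> dendropy.Tree:
    """Convenience: NJ on pairwise-deletion p-distances of an alignment."""
    return neighbor_joining(p_distance_matrix(rows))


def _split_masks(tree: dendropy.Tree, bits: dict[str, int]) -> dict[int, int]:
    """Map each tree node (by id) to its normalized leaf bitmask."""
    masks: dict[int, int] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            masks[id(node)] = 1 << bits[node.taxon.label]
        else:
            m = 0
            for ch in node.child_nodes():
                m |= masks[id(ch)]
            masks[id(node)] = m
    return masks


def tree_splits(tree: dendropy.Tree) -> set[int]:
    """Non-trivial splits of an (unrooted) tree as normalized bitmasks.

    A split is encoded by the side that does not contain leaf bit 0, over the
    sorted leaf labels.
    """
    bits = {lab: i for i, lab in enumerate(sorted(lf.taxon.label for lf in tree.leaf_node_iter()))}
    n = len(bits)
    full = (1 << n) - 1
    masks = _split_masks(tree, bits)
    out: set[int] = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        m = masks[id(node)]
        if m & 1:
            m = full ^ m
        if 2 <= bin(m).count("1") <= n - 2:
            out.add(m)
    return out


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Robinson-Foulds distance: splits present in exactly one tree."""
    l1 = {lf.taxon.label for lf in t1.leaf_node_iter()}
    l2 = {lf.taxon.label for lf in t2.leaf_node_iter()}
    if l1 != l2:
        raise InvalidInputError(
            f"leaf sets differ: {sorted(l1 ^ l2)[:5]}{'...' if len(l1 ^ l2) > 5 else ''}"
        )
    return len(tree_splits(t1) ^ tree_splits(t2))


TreeBuilder = Callable[[Mapping[str, str]], dendropy.Tree]


def bootstrap_support(
    alignment: Mapping[str, str],
    replicates: int,
    seed: int,
    builder: TreeBuilder | None = None,
    resample_unit: str = "site",
) -> dendropy.Tree:
    """Nonparametric bootstrap: resample columns, rebuild, map support.

    Support for each internal edge of the point-estimate tree is the
    percentage of replicate trees containing the same split, written as the
    internal node label.  ``resample_unit`` is ``"site"`` (single columns) or
    ``"codon"`` (whole triplets; appropriate for codon-structured matrices).
    """
    if replicates < 1:
        raise InvalidInputError("replicates must be >= 1")
    labels = list(alignment)
    if not labels:
        raise InvalidInputError("empty alignment")
    length = len(alignment[labels[0]])
    if length == 0:
        raise InvalidInputError("zero-length alignment")
    if builder is None:
        builder = nj_tree
    if resample_unit not in ("site", "codon"):
        raise InvalidInputError(f"unknown resample unit {resample_unit!r}")
    point = builder(alignment)
    point_splits = tree_splits(point)
    counts = {s: 0 for s in point_splits}
    rng = np.random.default_rng(seed)
    chars = {l: np.frombuffer(alignment[l].encode("ascii"), dtype=np.uint8) for l in labels}
    if resample_unit == "codon" and length % 3 != 0:
        raise InvalidInputError("codon resampling requires length divisible by 3")
    for _ in range(replicates):
        if resample_unit == "site":
            idx = rng.integers(0, length, size=length)
        else:
            codons = rng.integers(0, length // 3, size=length // 3)
            idx = (codons[:, None] * 3 + np.arange(3)[None, :]).ravel()
        rep = {l: chars[l][idx].tobytes().decode("ascii") for l in labels}
        rep_splits = tree_splits(builder(rep))
        for s in point_splits:
            if s in rep_splits:
                counts[s] += 1
    bits = {lab: i for i, lab in enumerate(sorted(lf.taxon.label for lf in point.leaf_node_iter()))}
    n = len(bits)
    full = (1 << n) - 1
    masks = _split_masks(point, bits)
    for node in point.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        m = masks[id(node)]
        if m & 1:
            m = full ^ m
        if m in counts:
            node.label = f"{100.0 * counts[m] / replicates:.1f}"
    return point


def read_newick(text: str) -> dendropy.Tree:
    """Parse one Newick tree (multi-labeled leaves encoded as ``taxon|seqid``)."""
    return dendropy.Tree.get(data=text, schema="newick", preserve_underscores=True)


def write_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", unquoted_underscores=True).strip()
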