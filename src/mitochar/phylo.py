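"""Distance-based phylogenetics for concatenated mitochondrial PCGs.

Desk-scale topology checks only: Jukes-Cantor distances on a concatenated
(pre-aligned) PCG supermatrix and the Saitou-Nei neighbor-joining algorithm
with deterministic lexicographic tie-breaking.  Likelihood and Bayesian
inference are deliberately out of scope — they belong to dedicated external
tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome_model import InputError, MitogenomeRecord
from .selection import jukes_cantor


def concatenate_pcgs(
    records: list[MitogenomeRecord], gene_order: list[str]
) -> tuple[list[str], list[str], dict[str, tuple[int, int]]]:
    """Concatenate the named genes of each record in a fixed order.

    Returns (taxon labels, concatenated sequences, partition map of 0-based
    half-open [start, end) column spans per gene).  Genes are extracted in
    coding-strand orientation.  Every record must carry every requested gene.
    """
    labels = [r.identifier for r in records]
    parts: dict[str, list[str]] = {g: [] for g in gene_order}
    for r in records:
        for g in gene_order:
            try:
                f = r.get_feature(g)
            except KeyError:
                raise InputError(f"record {r.identifier!r} is missing gene {g!r}")
            parts[g].append(r.feature_sequence(f, coding_strand=True))
    partitions: dict[str, tuple[int, int]] = {}
    offset = 0
    for g in gene_order:
        lengths = {len(s) for s in parts[g]}
        if len(lengths) > 1:
            raise InputError(f"gene {g!r}: unequal lengths {sorted(lengths)}; align first")
        width = lengths.pop()
        partitions[g] = (offset, offset + width)
        offset += width
    supermatrix = ["".join(parts[g][i] for g in gene_order) for i in range(len(records))]
    return labels, supermatrix, partitions


@dataclass
class DistanceMatrix:
    """Symmetric distance matrix with taxon labels; saturated JC pairs are
    flagged rather than silently capped."""

    labels: list[str]
    matrix: np.ndarray
    saturated: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise InputError("matrix shape does not match label count")
        if not np.allclose(m, m.T) or np.any(np.diag(m) != 0) or np.any(m < 0):
            raise InputError("distance matrix must be symmetric, non-negative, zero-diagonal")
        self.matrix = m

    def get(self, a: str, b: str) -> float:
        return float(self.matrix[self.labels.index(a), self.labels.index(b)])


def jc_distance_matrix(labels: list[str], sequences: list[str]) -> DistanceMatrix:
    """Pairwise Jukes-Cantor distances over equal-length sequences.

    Sites containing a gap or N in either sequence of a pair are excluded
    pairwise.  Saturated pairs (p >= 3/4) are recorded in ``saturated`` and
    assigned the distance of p just below saturation at their site count.
    """
    if len({len(s) for s in sequences}) > 1:
        raise InputError("sequences must be aligned to equal length")
    arrs = [np.frombuffer(s.upper().encode(), dtype="S1") for s in sequences]
    acgt = np.array(list("ACGT"), dtype="S1")
    valid = [np.isin(a, acgt) for a in arrs]
    n = len(labels)
    m = np.zeros((n, n))
    saturated = []
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            total = int(both.sum())
            if total == 0:
                raise InputError(
                    f"no comparable sites between {labels[i]!r} and {labels[j]!r}"
                )
            p = float((arrs[i][both] != arrs[j][both]).sum()) / total
            d = jukes_cantor(p)
            if d is None:
                saturated.append((labels[i], labels[j]))
                d = jukes_cantor((total * 0.75 - 1) / total)  # just below saturation
            m[i, j] = m[j, i] = d
    return DistanceMatrix(labels=list(labels), matrix=m, saturated=saturated)


@dataclass
class TreeNode:
    """Node of an unrooted tree; leaves carry labels, edges carry lengths."""

    label: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def leaf_labels(self) -> list[str]:
        if self.is_leaf():
            return [self.label]
        out = []
        for child, _ in self.children:
            out.extend(child.leaf_labels())
        return out

    def to_newick(self) -> str:
        return self._newick_inner() + ";"

    def _newick_inner(self) -> str:
        if self.is_leaf():
            label = self.label or ""
            if any(ch.isspace() for ch in label):
                label = f"'{label}'"
            return label
        inner = ",".join(
            f"{child._newick_inner()}:{length:.6g}" for child, length in self.children
        )
        return f"({inner})"


@dataclass
class PhyloTree:
    """Unrooted tree with branch lengths from neighbor-joining."""

    root: TreeNode
    labels: list[str]
    clamped: int = 0  # negative branch-length estimates clamped to zero

    def to_newick(self) -> str:
        return self.root.to_newick()


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining with Q-criterion joins.

    Ties in the Q matrix are broken deterministically by the lexicographically
    smallest label pair.  Negative branch-length estimates are clamped to
    zero.  On an additive matrix the tree reproduces all pairwise path
    lengths exactly.
    """
    n = len(dm.labels)
    if n < 3:
        raise InputError("neighbor joining needs at least 3 taxa")
    import warnings

    nodes: dict[str, TreeNode] = {lab: TreeNode(label=lab) for lab in dm.labels}
    # active distances keyed by frozen label pair
    d: dict[frozenset, float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            d[frozenset((dm.labels[i], dm.labels[j]))] = dm.matrix[i, j]
    active = list(dm.labels)
    clamped = 0
    inner_count = 0

    def dist(a: str, b: str) -> float:
        return d[frozenset((a, b))]

    while len(active) > 3:
        r = len(active)
        net = {a: sum(dist(a, b) for b in active if b != a) for a in active}
        best = None
        for i in range(r):
            for j in range(i + 1, r):
                a, b = active[i], active[j]
                q = (r - 2) * dist(a, b) - net[a] - net[b]
                key = (q, *sorted((a, b)))
                if best is None or key < best[0]:
                    best = (key, a, b)
        _, a, b = best
        dab = dist(a, b)
        la = 0.5 * dab + (net[a] - net[b]) / (2 * (r - 2))
        lb = dab - la
        if la < 0 or lb < 0:
            clamped += 1
            warnings.warn("negative NJ branch length clamped to 0", stacklevel=2)
            la, lb = max(la, 0.0), max(lb, 0.0)
        inner_count += 1
        u = f"\x00inner{inner_count}"  # internal key, never printed
        nodes[u] = TreeNode(children=[(nodes[a], la), (nodes[b], lb)])
        for c in active:
            if c in (a, b):
                continue
            d[frozenset((u, c))] = 0.5 * (dist(a, c) + dist(b, c) - dab)
        active = [c for c in active if c not in (a, b)] + [u]

    a, b, c = sorted(active)
    dab, dac, dbc = dist(a, b), dist(a, c), dist(b, c)
    # three-point formulas for the final star join
    la = 0.5 * (dab + dac - dbc)
    lb = 0.5 * (dab + dbc - dac)
    lc = 0.5 * (dac + dbc - dab)
    lengths = []
    for l in (la, lb, lc):
        if l < 0:
            clamped += 1
            l = 0.0
        lengths.append(l)
    root = TreeNode(
        children=[(nodes[a], lengths[0]), (nodes[b], lengths[1]), (nodes[c], lengths[2])]
    )
    return PhyloTree(root=root, labels=list(dm.labels), clamped=clamped)


def tree_path_lengths(tree: PhyloTree) -> dict[frozenset, float]:
    """Leaf-to-leaf path lengths of a tree (for additivity checks)."""
    # record each leaf's chain of (node, incoming edge) from the root; the
    # path between two leaves drops their shared prefix
    parent_chain: dict[str, list[tuple[TreeNode, float]]] = {}

    def _chain(node: TreeNode, acc: list[tuple[TreeNode, float]]) -> None:
        if node.is_leaf():
            parent_chain[node.label] = list(acc)
            return
        for child, length in node.children:
            _chain(child, acc + [(child, length)])

    _chain(tree.root, [])
    out: dict[frozenset, float] = {}
    labels = tree.root.leaf_labels()
    for i, x in enumerate(labels):
        for y in labels[i + 1 :]:
            cx, cy = parent_chain[x], parent_chain[y]
            k = 0
            while k < min(len(cx), len(cy)) and cx[k][0] is cy[k][0]:
                k += 1
            out[frozenset((x, y))] = sum(s for _, s in cx[k:]) + sum(
                s for _, s in cy[k:]
            )
    return out


__all__ = [
    "concatenate_pcgs",
    "jc_distance_matrix",
    "neighbor_joining",
    "tree_path_lengths",
    "DistanceMatrix",
    "PhyloTree",
    "TreeNode",
]
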