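"""Distance matrices, neighbor-joining trees, hierarchical clustering of
RSCU matrices, and Robinson-Foulds tree comparison.

Neighbor joining is the Saitou-Nei agglomeration with the standard
Q-criterion; ties break deterministically toward the smallest (i, j) pair
in current label order, and negative branch lengths are clamped to zero
with the deficit transferred to the sister branch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .codonio import CDSRecord
from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class TreeNode:
    """A (possibly multifurcating) tree node; children carry branch lengths."""

    label: Optional[str] = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def leaf_labels(self) -> tuple[str, ...]:
        if self.is_leaf():
            return (self.label,)
        out: tuple[str, ...] = ()
        for child, _ in self.children:
            out += child.leaf_labels()
        return out

    def to_newick(self, precision: int = 6) -> str:
        return self._newick(precision) + ";"

    def _newick(self, precision: int) -> str:
        if self.is_leaf():
            return self.label or ""
        parts = [
            f"{child._newick(precision)}:{length:.{precision}f}"
            for child, length in self.children
        ]
        return "(" + ",".join(parts) + ")" + (self.label or "")

    def bipartitions(self, trivial: bool = False) -> set[frozenset[str]]:
        """Edge-induced splits, each normalized to the side that excludes
        the lexicographically smallest leaf label."""
        all_leaves = frozenset(self.leaf_labels())
        anchor = min(all_leaves)
        splits: set[frozenset[str]] = set()

        def walk(node: TreeNode) -> frozenset[str]:
            if node.is_leaf():
                return frozenset({node.label})
            below: frozenset[str] = frozenset()
            for child, _ in node.children:
                clade = walk(child)
                side = clade if anchor not in clade else all_leaves - clade
                if trivial or 2 <= len(side) <= len(all_leaves) - 2:
                    splits.add(side)
                below |= clade
            return below

        walk(self)
        return splits

    def edge_lengths(self) -> dict[frozenset[str], float]:
        """Split -> branch length for every edge (pendant edges included).
        Branch lengths of edges mapping to the same split are summed (this
        merges the two root-adjacent edges of a rooted binary tree, making
        the map invariant to root placement)."""
        all_leaves = frozenset(self.leaf_labels())
        anchor = min(all_leaves)
        lengths: dict[frozenset[str], float] = {}

        def walk(node: TreeNode) -> frozenset[str]:
            if node.is_leaf():
                return frozenset({node.label})
            below: frozenset[str] = frozenset()
            for child, length in node.children:
                clade = walk(child)
                side = clade if anchor not in clade else all_leaves - clade
                if 1 <= len(side) <= len(all_leaves) - 1:
                    lengths[side] = lengths.get(side, 0.0) + length
                below |= clade
            return below

        walk(self)
        return lengths


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise ValidationError("matrix shape must match label count")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-12):
            raise ValidationError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.matrix), 0.0, atol=1e-12):
            raise ValidationError("distance matrix diagonal must be zero")
        if (self.matrix < -1e-12).any():
            raise ValidationError("distances must be non-negative")

    def __len__(self) -> int:
        return len(self.labels)


def p_distance(records: Sequence[CDSRecord]) -> DistanceMatrix:
    """Proportion of differing sites between pre-aligned sequences, with
    pairwise deletion of positions where either sequence has N or a gap."""
    if len(records) < 2:
        raise ValidationError("p_distance needs at least 2 sequences")
    lengths = {r.length_nt for r in records}
    if len(lengths) != 1:
        raise ValidationError(
            "sequences have unequal lengths; alignment required before p-distance"
        )
    seqs = [np.frombuffer(r.sequence.encode(), dtype="S1") for r in records]
    missing = [np.isin(s, [b"N", b"-"]) for s in seqs]
    n = len(records)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            valid = ~(missing[i] | missing[j])
            n_valid = int(valid.sum())
            if n_valid == 0:
                raise ValidationError(
                    f"no comparable sites between {records[i].id} and {records[j].id}"
                )
            diffs = int((seqs[i][valid] != seqs[j][valid]).sum())
            d[i, j] = d[j, i] = diffs / n_valid
    return DistanceMatrix([r.id for r in records], d)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining; returns an unrooted tree whose root is
    the final trifurcation (or the 3-taxon star for 3 inputs)."""
    m = len(dm)
    if m < 3:
        raise ValidationError("neighbor joining needs at least 3 taxa")
    nodes: list[TreeNode] = [TreeNode(label=lab) for lab in dm.labels]
    d = dm.matrix.astype(float).copy()

    def clamp_pair(li: float, lj: float) -> tuple[float, float]:
        # negative length is clamped to 0, deficit moved to the sister
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return li, max(lj, 0.0)

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        best = None
        best_q = np.inf
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - r[i] - r[j]
                if q < best_q:  # strict: first (i, j) in row-major order wins ties
                    best_q = q
                    best = (i, j)
        i, j = best  # first (i, j) in row-major order wins ties
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        li, lj = clamp_pair(li, lj)
        parent = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])

        new_row = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d_new = np.zeros((m - 1, m - 1))
        d_new[:-1, :-1] = d[np.ix_(keep, keep)]
        d_new[-1, :-1] = d_new[:-1, -1] = new_row[keep]
        d = d_new
        nodes = [nodes[k] for k in keep] + [parent]

    (a, b, c) = nodes
    la = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    lb = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    lc = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    la, lb, lc = (max(v, 0.0) for v in (la, lb, lc))
    return TreeNode(children=[(a, la), (b, lb), (c, lc)])


@dataclass
class HierarchicalClustering:
    tree: TreeNode
    merges: pd.DataFrame  # columns: left, right, height, size
    leaf_order: list[str]
    linkage_matrix: np.ndarray


def hierarchical_cluster(
    matrix: np.ndarray | pd.DataFrame,
    labels: Optional[Sequence[str]] = None,
    distance: str = "euclidean",
    linkage: str = "complete",
) -> HierarchicalClustering:
    """Agglomerative clustering of row vectors (e.g. species x codon RSCU).

    Branch lengths are set so the path between two leaves equals their
    cophenetic (merge) height.
    """
    if isinstance(matrix, pd.DataFrame):
        if labels is None:
            labels = list(matrix.index.astype(str))
        matrix = matrix.to_numpy(dtype=float)
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] < 2:
        raise ValidationError("need at least 2 rows to cluster")
    if labels is None:
        labels = [f"row{i}" for i in range(matrix.shape[0])]
    if len(labels) != matrix.shape[0]:
        raise ValidationError("label count must match row count")
    if np.isnan(matrix).any():
        raise ValidationError("matrix contains missing cells; impute first")
    if linkage not in ("complete", "average"):
        raise ValidationError(f"unsupported linkage {linkage!r}")
    if distance != "euclidean":
        raise ValidationError(f"unsupported distance {distance!r}")

    z = hierarchy.linkage(pdist(matrix, metric=distance), method=linkage)
    n = matrix.shape[0]
    nodes = {i: (TreeNode(label=str(labels[i])), 0.0) for i in range(n)}
    merges = []
    for step, (a, b, height, size) in enumerate(z):
        a, b = int(a), int(b)
        na, ha = nodes.pop(a)
        nb, hb = nodes.pop(b)
        parent = TreeNode(
            children=[(na, (height - ha) / 2.0), (nb, (height - hb) / 2.0)]
        )
        nodes[n + step] = (parent, float(height))
        merges.append(
            {"left": a, "right": b, "height": float(height), "size": int(size)}
        )
    root = nodes[n + len(z) - 1][0]
    leaf_order = [str(labels[i]) for i in hierarchy.leaves_list(z)]
    return HierarchicalClustering(
        tree=root,
        merges=pd.DataFrame(merges),
        leaf_order=leaf_order,
        linkage_matrix=z,
    )


def compare_trees(t1: TreeNode, t2: TreeNode) -> int:
    """Robinson-Foulds distance: bipartitions present in exactly one tree."""
    l1, l2 = set(t1.leaf_labels()), set(t2.leaf_labels())
    if l1 != l2:
        raise ValidationError(
            f"leaf sets differ: {sorted(l1 ^ l2)} not shared"
        )
    return len(t1.bipartitions() ^ t2.bipartitions())


def read_phylip_distances(path: str | Path) -> DistanceMatrix:
    """PHYLIP square distance-matrix format (relaxed label widths)."""
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError) as exc:
        raise FormatError(f"{path}: first line must be the taxon count") from exc
    if len(lines) - 1 != n:
        raise FormatError(f"{path}: expected {n} matrix rows, found {len(lines) - 1}")
    labels, rows = [], []
    for ln in lines[1:]:
        parts = ln.split()
        if len(parts) != n + 1:
            raise FormatError(f"{path}: row {parts[0]!r} has wrong column count")
        labels.append(parts[0])
        rows.append([float(v) for v in parts[1:]])
    return DistanceMatrix(labels, np.array(rows))


def write_phylip_distances(dm: DistanceMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{len(dm)}\n")
        for label, row in zip(dm.labels, dm.matrix):
            fh.write(label + "  " + "  ".join(f"{v:.6f}" for v in row) + "\n")
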