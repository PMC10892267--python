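"""Distance-based phylogenetics: p-distances, neighbor joining, bootstraps.

Works on pre-aligned nucleotide sequences (alignment itself is out of
scope). Distances are uncorrected proportions of differing sites
(p-distance); trees are built with the Saitou-Nei neighbor-joining
algorithm using the Studier-Keppler Q-criterion, and branch supports come
from column-resampling bootstrap replicates.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from Bio import SeqIO

from .errors import EmptyInputError, UndefinedMetricError, ValidationError

log = logging.getLogger(__name__)

GAP = "-"
GapMode = Literal["complete_deletion", "pairwise_deletion"]


@dataclass
class Alignment:
    """Equal-length aligned nucleotide rows with '-' as the gap symbol."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValidationError("ids and rows differ in length")
        if len(self.rows) < 2:
            raise ValidationError("alignment needs at least 2 sequences")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValidationError(f"rows are not equal length: {sorted(lengths)}")
        self.rows = [r.upper().replace("U", "T") for r in self.rows]

    @property
    def n_sites(self) -> int:
        return len(self.rows[0])

    def sorted_by_id(self) -> "Alignment":
        order = sorted(range(len(self.ids)), key=lambda i: self.ids[i])
        return Alignment(ids=[self.ids[i] for i in order], rows=[self.rows[i] for i in order])

    def subset_columns(self, cols: Sequence[int]) -> "Alignment":
        return Alignment(
            ids=list(self.ids),
            rows=["".join(r[c] for c in cols) for r in self.rows],
        )


def read_alignment_fasta(path: str | Path) -> Alignment:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise EmptyInputError(f"no FASTA records in {path}")
    return Alignment(ids=[r.id for r in records], rows=[str(r.seq) for r in records])


@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValidationError("matrix shape does not match ids")
        if not np.allclose(m, m.T):
            raise ValidationError("distance matrix is not symmetric")
        if np.any(np.diag(m) != 0):
            raise ValidationError("distance matrix diagonal must be zero")
        self.matrix = m


def p_distance(aln: Alignment, gap_mode: GapMode = "complete_deletion") -> DistanceMatrix:
    """Proportion of differing sites between every pair of rows.

    ``complete_deletion`` (default) first removes every column containing a
    gap in *any* row; ``pairwise_deletion`` drops gapped columns per pair.
    """
    n = len(aln.rows)
    rows = aln.rows
    if gap_mode == "complete_deletion":
        cols = [c for c in range(aln.n_sites) if all(r[c] != GAP for r in rows)]
        if not cols:
            raise UndefinedMetricError("no gap-free columns under complete deletion")
        rows = ["".join(r[c] for c in cols) for r in rows]

    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = rows[i], rows[j]
            if gap_mode == "pairwise_deletion":
                pairs = [(x, y) for x, y in zip(a, b) if x != GAP and y != GAP]
                if not pairs:
                    raise UndefinedMetricError(
                        f"no comparable columns between {aln.ids[i]} and {aln.ids[j]}"
                    )
                diffs = sum(x != y for x, y in pairs)
                d[i, j] = d[j, i] = diffs / len(pairs)
            else:
                diffs = sum(x != y for x, y in zip(a, b))
                d[i, j] = d[j, i] = diffs / len(a)
    return DistanceMatrix(ids=list(aln.ids), matrix=d)


@dataclass
class TreeNode:
    """Node of an (internally unrooted) phylogeny."""

    label: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)
    support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaf_set(self) -> frozenset[str]:
        if self.is_leaf:
            return frozenset([self.label or ""])
        out: set[str] = set()
        for child, _ in self.children:
            out |= child.leaf_set()
        return frozenset(out)


@dataclass
class PhyloTree:
    """Unrooted tree (root node of degree >= 3) with optional supports."""

    root: TreeNode
    taxa: list[str]

    def newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                return node.label or ""
            inner = ",".join(f"{fmt(ch)}:{ln:.6g}" for ch, ln in node.children)
            sup = "" if node.support is None else f"{node.support:g}"
            return f"({inner}){sup}"
        return fmt(self.root) + ";"

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits, each canonicalised as the side *not*
        containing the lexicographically smallest taxon."""
        ref = min(self.taxa)
        all_taxa = frozenset(self.taxa)
        splits: set[frozenset[str]] = set()

        def visit(node: TreeNode) -> None:
            for child, _ in node.children:
                side = child.leaf_set()
                if 2 <= len(side) <= len(all_taxa) - 2:
                    canon = side if ref not in side else all_taxa - side
                    splits.add(canon)
                visit(child)

        visit(self.root)
        return splits


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining with the Studier-Keppler Q-matrix.

    Ties in Q resolve to the smallest (i, j) index pair, so results are
    deterministic. Negative branch lengths are clamped to zero and the
    clamped amount logged.
    """
    n = len(dm.ids)
    if n < 3:
        raise EmptyInputError("neighbor joining requires at least 3 taxa")
    D = dm.matrix.copy()
    nodes: list[TreeNode] = [TreeNode(label=t) for t in dm.ids]
    active = list(range(n))

    def clamp(length: float, where: str) -> float:
        if length < 0:
            log.debug("clamping negative branch length %.3g at %s", length, where)
            return 0.0
        return length

    while len(active) > 3:
        m = len(active)
        r = {i: sum(D[i, k] for k in active if k != i) for i in active}
        best = None
        best_q = np.inf
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * D[i, j] - r[i] - r[j]
                if q < best_q - 1e-12:
                    best_q, best = q, (i, j)
        i, j = best
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (len(active) - 2))
        lj = D[i, j] - li
        li = clamp(li, f"join({dm.ids[i] if i < n else i})")
        lj = clamp(lj, f"join({dm.ids[j] if j < n else j})")
        new = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        # grow matrix with the new node's distances
        old = D.shape[0]
        du = np.zeros(old)
        for k in active:
            if k in (i, j):
                continue
            du[k] = 0.5 * (D[i, k] + D[j, k] - D[i, j])
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :old] = du
        D[:old, -1] = du
        nodes.append(new)
        active = [k for k in active if k not in (i, j)] + [D.shape[0] - 1]

    # resolve the final three nodes around a central vertex (closed form)
    i, j, k = active
    li = clamp(0.5 * (D[i, j] + D[i, k] - D[j, k]), "final-i")
    lj = clamp(0.5 * (D[i, j] + D[j, k] - D[i, k]), "final-j")
    lk = clamp(0.5 * (D[i, k] + D[j, k] - D[i, j]), "final-k")
    root = TreeNode(children=[(nodes[i], li), (nodes[j], lj), (nodes[k], lk)])
    return PhyloTree(root=root, taxa=list(dm.ids))


def bootstrap_support(
    aln: Alignment,
    replicates: int = 1000,
    seed: int | None = None,
    gap_mode: GapMode = "complete_deletion",
) -> PhyloTree:
    """NJ tree from the full alignment with bootstrap supports (0-100).

    Columns are resampled with replacement ``replicates`` times; each
    internal split of the full-data tree is scored by the percentage of
    replicate trees containing it. Rows are sorted by id internally so
    supports do not depend on input order. A replicate whose resampled
    columns are unusable (all gapped) is redrawn and logged.
    """
    if len(aln.ids) < 4:
        raise EmptyInputError("bootstrap requires at least 4 sequences")
    if seed is None:
        raise ValueError("bootstrap_support requires an explicit seed")
    aln = aln.sorted_by_id()
    rng = np.random.default_rng(seed)
    full_tree = neighbor_joining(p_distance(aln, gap_mode))
    target_splits = full_tree.bipartitions()
    counts = {s: 0 for s in target_splits}

    done = 0
    while done < replicates:
        cols = rng.integers(0, aln.n_sites, size=aln.n_sites)
        rep = aln.subset_columns(list(cols))
        try:
            rep_tree = neighbor_joining(p_distance(rep, gap_mode))
        except UndefinedMetricError:
            log.warning("bootstrap replicate had no usable columns; redrawn")
            continue
        rep_splits = rep_tree.bipartitions()
        for s in target_splits:
            if s in rep_splits:   # each replicate contributes at most 1 per split
                counts[s] += 1
        done += 1

    def annotate(node: TreeNode) -> None:
        for child, _ in node.children:
            if not child.is_leaf:
                side = child.leaf_set()
                ref = min(full_tree.taxa)
                canon = side if ref not in side else frozenset(full_tree.taxa) - side
                if canon in counts:
                    child.support = 100.0 * counts[canon] / replicates
            annotate(child)

    annotate(full_tree.root)
    return full_tree


def write_newick(tree: PhyloTree, path: str | Path) -> None:
    """Serialise to single-line Newick (supports as internal node labels)."""
    Path(path).write_text(tree.newick() + "\n")
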