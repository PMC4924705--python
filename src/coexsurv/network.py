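"""Weighted co-expression network core.

Implements the unsigned WGCNA-style pipeline: soft-thresholded adjacency
``a_ij = |cor(x_i, x_j)|^beta`` (default beta = 10), the topological overlap
measure (TOM), average-linkage hierarchical clustering of the TOM
dissimilarity ``1 - TOM``, module extraction by a dynamic tree cut, and a
protein-protein-interaction filter that keeps only module members with at
least one interaction partner inside their own module.

The TOM for i != j is

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)

with ``l_ij = sum_u a_iu a_uj`` over u not in {i, j} and connectivity
``k_i = sum_u a_iu`` over u != i; the diagonal is 1 by convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from coexsurv.io import ExpressionMatrix, InteractionSet, ValidationError

__all__ = [
    "AdjacencyMatrix",
    "TOMatrix",
    "ModulePartition",
    "soft_adjacency",
    "topological_overlap",
    "average_linkage_tree",
    "dynamic_tree_cut",
    "filter_modules_by_ppi",
    "detect_modules",
]


@dataclass
class AdjacencyMatrix:
    """Symmetric soft-thresholded adjacency in [0, 1], diagonal 1."""

    gene_ids: list[str]
    values: np.ndarray
    power: int = 10

    def __post_init__(self) -> None:
        a = np.asarray(self.values, dtype=float)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValidationError("adjacency must be square")
        if a.shape[0] != len(self.gene_ids):
            raise ValidationError("gene_ids length does not match adjacency size")
        if not np.allclose(a, a.T, atol=1e-10):
            raise ValidationError("adjacency must be symmetric")
        if a.min() < -1e-12 or a.max() > 1 + 1e-12:
            raise ValidationError("adjacency entries must lie in [0, 1]")
        np.fill_diagonal(a, 1.0)
        self.values = np.clip(a, 0.0, 1.0)


@dataclass
class TOMatrix:
    """Topological overlap matrix; dissimilarity is ``1 - TOM``."""

    gene_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.values, dtype=float)
        if not np.allclose(t, t.T, atol=1e-10):
            raise ValidationError("TOM must be symmetric")
        if t.min() < -1e-12 or t.max() > 1 + 1e-12:
            raise ValidationError("TOM entries must lie in [0, 1]")
        self.values = np.clip(t, 0.0, 1.0)

    @property
    def dissimilarity(self) -> np.ndarray:
        d = 1.0 - self.values
        np.fill_diagonal(d, 0.0)
        return d


@dataclass
class ModulePartition:
    """Gene -> module label; positive integers, 0 = unassigned.

    Labels are contiguous from 1 and ordered by decreasing module size.
    ``stages`` optionally carries a module -> developmental stage mapping
    (used by the synthetic generator to record planted truth).
    """

    assignment: dict[str, int]
    stages: dict[int, str] | None = field(default=None)

    def __post_init__(self) -> None:
        labels = sorted({m for m in self.assignment.values() if m != 0})
        if any(m < 0 for m in self.assignment.values()):
            raise ValidationError("module labels must be non-negative")
        if labels and labels != list(range(1, len(labels) + 1)):
            raise ValidationError(f"module labels must be contiguous from 1, got {labels}")

    @property
    def labels(self) -> list[int]:
        return sorted({m for m in self.assignment.values() if m != 0})

    @property
    def module_sizes(self) -> dict[int, int]:
        sizes: dict[int, int] = {}
        for m in self.assignment.values():
            if m != 0:
                sizes[m] = sizes.get(m, 0) + 1
        return sizes

    def members(self, label: int) -> list[str]:
        return sorted(g for g, m in self.assignment.items() if m == label)

    def assigned_genes(self) -> list[str]:
        return sorted(g for g, m in self.assignment.items() if m != 0)

    def labels_for(self, genes: list[str]) -> np.ndarray:
        return np.array([self.assignment.get(g, 0) for g in genes])

    def relabeled_by_size(self) -> "ModulePartition":
        """Renumber labels 1..k by decreasing size (ties: old label order)."""
        sizes = self.module_sizes
        order = sorted(sizes, key=lambda m: (-sizes[m], m))
        mapping = {old: new for new, old in enumerate(order, start=1)}
        mapping[0] = 0
        stages = None
        if self.stages is not None:
            stages = {mapping[m]: s for m, s in self.stages.items() if m in mapping}
        return ModulePartition(
            {g: mapping[m] for g, m in self.assignment.items()}, stages=stages
        )


def soft_adjacency(expr: ExpressionMatrix, power: int = 10) -> AdjacencyMatrix:
    """Unsigned soft-thresholded adjacency ``|PCC|^power`` with unit diagonal."""
    if power < 1:
        raise ValidationError("power must be >= 1")
    if expr.n_samples < 3:
        raise ValidationError("need at least 3 samples to correlate")
    x = expr.values
    sd = x.std(axis=1)
    degenerate = np.where(sd == 0)[0]
    if degenerate.size:
        bad = [expr.gene_ids[i] for i in degenerate]
        raise ValidationError(f"zero-variance genes (filter before networking): {bad}")
    corr = np.corrcoef(x)
    a = np.abs(np.clip(corr, -1.0, 1.0)) ** power
    np.fill_diagonal(a, 1.0)
    return AdjacencyMatrix(expr.gene_ids, a, power=power)


def topological_overlap(adj: AdjacencyMatrix) -> TOMatrix:
    """Topological overlap from adjacency (matrix formulation, O(n^3))."""
    a = adj.values.copy()
    np.fill_diagonal(a, 0.0)  # sums in the TOM formula exclude i and j
    l = a @ a  # l[i, j] = sum_u a_iu a_uj, u != i (diag 0); subtract nothing: a_ii = 0
    k = a.sum(axis=1)
    n = a.shape[0]
    kmin = np.minimum.outer(k, k)
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (l + a) / (kmin + 1.0 - a)
    tom = np.where(np.isfinite(tom), tom, 0.0)
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    return TOMatrix(adj.gene_ids, tom)


def average_linkage_tree(diss: np.ndarray) -> np.ndarray:
    """Average-linkage (UPGMA) agglomeration of a square dissimilarity matrix.

    Returns a scipy linkage matrix (merge topology + non-decreasing heights).
    """
    d = np.asarray(diss, dtype=float)
    if np.isnan(d).any():
        raise ValidationError("dissimilarity contains NaN")
    if not np.allclose(d, d.T, atol=1e-10) or (np.diag(d) != 0).any() or d.min() < 0:
        raise ValidationError("dissimilarity must be symmetric, non-negative, zero-diagonal")
    return linkage(squareform(d, checks=False), method="average")


def dynamic_tree_cut(
    tree: np.ndarray,
    diss: np.ndarray,
    min_module_size: int = 5,
    cut_height: float | None = None,
) -> ModulePartition:
    """Extract modules as dendrogram branches with a minimum-size constraint.

    The dendrogram is cut at ``cut_height``; by default the cut is placed in
    the middle of the largest gap of the sorted merge heights, which
    separates the tight within-branch merges from the few high between-
    branch joins.  Each resulting branch of size >= ``min_module_size``
    becomes a module.  Genes in smaller branches are merged into the module
    with the smallest average dissimilarity, provided that average does not
    exceed the cut height; otherwise they stay unassigned (label 0).  Labels
    are renumbered by decreasing module size.

    ``gene_ids`` for the returned partition are taken as stringified row
    indices; use :func:`detect_modules` for the id-aware entry point.
    """
    if min_module_size < 2:
        raise ValidationError("min_module_size must be >= 2")
    n = diss.shape[0]
    if n < min_module_size:
        raise ValidationError("fewer items than min_module_size")
    heights = tree[:, 2]
    if cut_height is None:
        hs = np.sort(heights)
        gaps = np.diff(hs)
        if gaps.size == 0 or gaps.max() <= 0:
            cut_height = float(hs.max())
        else:
            g = int(np.argmax(gaps))
            cut_height = float((hs[g] + hs[g + 1]) / 2.0)
    flat = fcluster(tree, t=cut_height, criterion="distance")
    labels = np.zeros(n, dtype=int)
    next_label = 1
    small_clusters: list[np.ndarray] = []
    for c in np.unique(flat):
        idx = np.where(flat == c)[0]
        if idx.size >= min_module_size:
            labels[idx] = next_label
            next_label += 1
        else:
            small_clusters.append(idx)
    if next_label == 1:
        # no branch reaches min_module_size (e.g. uniform dissimilarity):
        # the whole dendrogram is a single module rather than all-unassigned
        labels[:] = 1
        small_clusters = []
        next_label = 2
    # merge undersized branches into the nearest module, if close enough
    for idx in small_clusters:
        best_label, best_d = 0, np.inf
        for m in range(1, next_label):
            members = np.where(labels == m)[0]
            avg = float(diss[np.ix_(idx, members)].mean())
            if avg < best_d:
                best_label, best_d = m, avg
        if best_d <= cut_height:
            labels[idx] = best_label
    assignment = {str(i): int(labels[i]) for i in range(n)}
    return ModulePartition(_compact(assignment)).relabeled_by_size()


def _compact(assignment: dict[str, int]) -> dict[str, int]:
    """Renumber module labels to be contiguous from 1, preserving order."""
    labels = sorted({m for m in assignment.values() if m != 0})
    mapping = {old: new for new, old in enumerate(labels, start=1)}
    mapping[0] = 0
    return {g: mapping[m] for g, m in assignment.items()}


def filter_modules_by_ppi(
    partition: ModulePartition, interactions: InteractionSet
) -> ModulePartition:
    """Keep only module members with an interaction partner inside their module.

    Modules left without any internally interacting member are dropped
    entirely; surviving labels are re-compacted and re-ranked by size.
    """
    nbrs = interactions.neighbors()
    assignment: dict[str, int] = {}
    for label in partition.labels:
        members = set(partition.members(label))
        kept = {g for g in members if nbrs.get(g, set()) & (members - {g})}
        for g in members:
            assignment[g] = label if g in kept else 0
    for g, m in partition.assignment.items():
        assignment.setdefault(g, 0)
    return ModulePartition(_compact(assignment)).relabeled_by_size()


def detect_modules(
    expr: ExpressionMatrix,
    power: int = 10,
    min_module_size: int = 5,
    cut_height: float | None = None,
    interactions: InteractionSet | None = None,
) -> ModulePartition:
    """Full module-detection pipeline on an expression matrix.

    adjacency -> TOM -> 1-TOM average-linkage tree -> dynamic cut
    (-> optional PPI filter).  Deterministic: no internal randomness.
    """
    adj = soft_adjacency(expr, power=power)
    tom = topological_overlap(adj)
    d = tom.dissimilarity
    tree = average_linkage_tree(d)
    part = dynamic_tree_cut(tree, d, min_module_size=min_module_size, cut_height=cut_height)
    assignment = {
        expr.gene_ids[int(i)]: m for i, m in part.assignment.items()
    }
    part = ModulePartition(assignment)
    if interactions is not None:
        part = filter_modules_by_ppi(part, interactions)
    return part
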