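"""Module activity over developmental time and early/middle/late grouping.

A module's activity at a time point is the arithmetic mean of its members'
expression there.  Modules are grouped by average-linkage clustering of the
z-scored activity rows (Euclidean distance), the tree is cut into
``n_groups`` clusters, and each cluster is named early / middle / late by
which block of the time axis maximizes its mean standardized activity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from coexsurv.io import ExpressionMatrix, ValidationError
from coexsurv.network import ModulePartition

logger = logging.getLogger(__name__)

STAGES = ("early", "middle", "late")

__all__ = ["ModuleActivity", "StageGroups", "module_activity", "group_modules", "default_stage_blocks"]


@dataclass
class ModuleActivity:
    """Module x time-point mean member expression."""

    table: pd.DataFrame  # index: module labels (int), columns: time points

    @property
    def module_labels(self) -> list[int]:
        return list(self.table.index)


@dataclass
class StageGroups:
    """Module label -> developmental stage ('early' | 'middle' | 'late')."""

    assignment: dict[int, str]
    cluster_of: dict[int, int] | None = None

    def modules_in(self, stage: str) -> list[int]:
        return sorted(m for m, s in self.assignment.items() if s == stage)


def module_activity(expr: ExpressionMatrix, partition: ModulePartition) -> ModuleActivity:
    """Mean member expression per time point for every surviving module."""
    rows = {}
    for label in partition.labels:
        members = partition.members(label)
        missing = [g for g in members if g not in expr.data.index]
        if missing:
            raise ValidationError(f"module {label} members absent from matrix: {missing}")
        rows[label] = expr.data.loc[members].mean(axis=0)
    return ModuleActivity(pd.DataFrame(rows).T)


def default_stage_blocks(n_timepoints: int) -> list[list[int]]:
    """Split the time axis into three contiguous, near-equal ordered blocks."""
    edges = np.linspace(0, n_timepoints, 4).round().astype(int)
    return [list(range(edges[i], edges[i + 1])) for i in range(3)]


def group_modules(
    activity: ModuleActivity,
    n_groups: int = 3,
    stage_blocks: list[list[int]] | None = None,
) -> StageGroups:
    """Cluster modules on z-scored activity and name clusters by peak block.

    ``stage_blocks`` gives the column-index blocks of the time axis, in
    developmental order (default: thirds).  Each of the ``n_groups`` clusters
    is assigned the stage whose block maximizes its mean standardized
    activity; if two clusters claim the same stage, the cluster with the
    larger block mean keeps it and the other takes its next-best block.
    """
    act = activity.table
    if len(act) < n_groups:
        raise ValidationError(f"need >= {n_groups} modules to form {n_groups} groups")
    if stage_blocks is None:
        stage_blocks = default_stage_blocks(act.shape[1])
    if len(stage_blocks) != 3:
        raise ValidationError("stage_blocks must have exactly 3 ordered blocks")
    x = act.to_numpy(dtype=float)
    sd = x.std(axis=1, ddof=0)
    if (sd == 0).all():
        raise ValidationError("all module activities are constant; no shape to cluster")
    sd = np.where(sd == 0, 1.0, sd)
    z = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
    if len(act) == n_groups:
        flat = np.arange(1, n_groups + 1)
    else:
        tree = linkage(z, method="average", metric="euclidean")
        flat = fcluster(tree, t=n_groups, criterion="maxclust")
    # mean standardized activity of each cluster within each stage block
    block_means = np.zeros((n_groups, 3))
    for ci in range(n_groups):
        zc = z[flat == ci + 1]
        for bi, block in enumerate(stage_blocks):
            block_means[ci, bi] = zc[:, block].mean()
    stage_of_cluster = _assign_stages(block_means)
    assignment = {
        int(label): stage_of_cluster[flat[i] - 1] for i, label in enumerate(act.index)
    }
    cluster_of = {int(label): int(flat[i]) for i, label in enumerate(act.index)}
    return StageGroups(assignment, cluster_of=cluster_of)


def _assign_stages(block_means: np.ndarray) -> list[str]:
    """Greedy stage naming: clusters claim blocks in order of peak strength.

    Conflicts are resolved in favor of the cluster with the larger block
    mean; the loser falls back to its next-best unclaimed-or-shared block.
    With more clusters than stages, several clusters may share a stage.
    """
    n = block_means.shape[0]
    stage_of: list[str | None] = [None] * n
    if n <= 3:
        # at most one cluster per stage: resolve claims greedily by strength
        claimed: dict[int, int] = {}
        order = np.argsort(-block_means, axis=None)
        for flat_idx in order:
            ci, bi = divmod(int(flat_idx), 3)
            if stage_of[ci] is None and bi not in claimed.values():
                stage_of[ci] = STAGES[bi]
                claimed[ci] = bi
            if all(s is not None for s in stage_of):
                break
        for ci in range(n):
            if stage_of[ci] is None:
                bi = int(np.argmax(block_means[ci]))
                stage_of[ci] = STAGES[bi]
                logger.warning("cluster %d fell back to stage %s", ci, STAGES[bi])
    else:
        for ci in range(n):
            stage_of[ci] = STAGES[int(np.argmax(block_means[ci]))]
    return [s for s in stage_of if s is not None]
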