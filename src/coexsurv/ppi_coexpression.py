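"""Co-expression of interacting protein pairs: protein vs mRNA profiles.

For every protein-protein interaction, the Pearson correlation of the two
partners' expression profiles is computed twice — once on the protein-level
matrix and once on the mRNA-level matrix — and the two sets of per-edge
correlations are compared with a paired Student t-test.  A higher mean
correlation on the protein side indicates that protein profiles track the
interaction structure more faithfully than transcript profiles do.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from coexsurv.io import ExpressionMatrix, InteractionSet

__all__ = [
    "EdgeCorrelations",
    "PairedComparison",
    "pairwise_pcc",
    "edge_correlations",
    "compare_pcc_paired",
    "qq_table",
]


@dataclass
class EdgeCorrelations:
    """Per-interaction Pearson correlations in both expression layers."""

    edges: list[tuple[str, str]]
    r_protein: np.ndarray
    r_mrna: np.ndarray
    n_points: int
    n_skipped_missing: int = 0
    n_skipped_degenerate: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_a": [a for a, _ in self.edges],
                "gene_b": [b for _, b in self.edges],
                "r_protein": self.r_protein,
                "r_mrna": self.r_mrna,
            }
        )


@dataclass
class PairedComparison:
    """Paired t-test summary of protein vs mRNA per-edge correlations."""

    mean_protein: float
    mean_mrna: float
    t_statistic: float
    p_value: float
    n_pairs: int


def pairwise_pcc(
    expr: ExpressionMatrix, interactions: InteractionSet
) -> tuple[list[tuple[str, str]], np.ndarray, int, int]:
    """Pearson correlation per interaction edge over the ordered samples.

    Returns ``(edges, r, n_missing, n_degenerate)``: edges with an endpoint
    absent from the matrix are skipped and counted in ``n_missing``; edges
    where either profile has zero variance (PCC undefined) are skipped and
    counted in ``n_degenerate``.
    """
    idx = {g: i for i, g in enumerate(expr.gene_ids)}
    x = expr.values
    edges: list[tuple[str, str]] = []
    rs: list[float] = []
    n_missing = n_degenerate = 0
    for a, b in interactions.pairs():
        if a not in idx or b not in idx:
            n_missing += 1
            continue
        pa, pb = x[idx[a]], x[idx[b]]
        mask = np.isfinite(pa) & np.isfinite(pb)
        if mask.sum() < 3:
            n_degenerate += 1
            continue
        pa, pb = pa[mask], pb[mask]
        if pa.std() == 0 or pb.std() == 0:
            n_degenerate += 1
            continue
        r = float(np.corrcoef(pa, pb)[0, 1])
        edges.append((a, b))
        rs.append(r)
    return edges, np.asarray(rs), n_missing, n_degenerate


def edge_correlations(
    protein: ExpressionMatrix, mrna: ExpressionMatrix, interactions: InteractionSet
) -> EdgeCorrelations:
    """Per-edge PCCs in both layers, pairwise-complete over the edges.

    An edge enters the result only if its correlation is defined in *both*
    matrices (the paired test needs complete pairs); exclusions are counted.
    """
    ep, rp, miss_p, deg_p = pairwise_pcc(protein, interactions)
    em, rm, miss_m, deg_m = pairwise_pcc(mrna, interactions)
    rp_map = dict(zip(ep, rp))
    rm_map = dict(zip(em, rm))
    common = [e for e in interactions.pairs() if e in rp_map and e in rm_map]
    return EdgeCorrelations(
        edges=common,
        r_protein=np.array([rp_map[e] for e in common]),
        r_mrna=np.array([rm_map[e] for e in common]),
        n_points=protein.n_samples,
        n_skipped_missing=max(miss_p, miss_m),
        n_skipped_degenerate=len(interactions) - len(common) - max(miss_p, miss_m),
    )


def compare_pcc_paired(r_protein: np.ndarray, r_mrna: np.ndarray) -> PairedComparison:
    """Two-sided paired Student t-test on per-edge correlation differences."""
    rp = np.asarray(r_protein, dtype=float)
    rm = np.asarray(r_mrna, dtype=float)
    if rp.shape != rm.shape:
        raise ValueError("correlation lists must be aligned (equal length)")
    if rp.size < 2:
        raise ValueError("need at least 2 paired correlations")
    d = rp - rm
    if np.all(d == 0):
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_rel(rp, rm)
        t, p = float(t), float(p)
    return PairedComparison(
        mean_protein=float(rp.mean()),
        mean_mrna=float(rm.mean()),
        t_statistic=t,
        p_value=p,
        n_pairs=int(rp.size),
    )


def qq_table(r_protein: np.ndarray, r_mrna: np.ndarray) -> pd.DataFrame:
    """Rank-paired sorted quantiles of the two correlation sets (Q-Q data).

    Unequal lengths are handled by linear interpolation of the longer set's
    empirical quantile function onto the shorter set's plotting positions.
    """
    rp = np.sort(np.asarray(r_protein, dtype=float))
    rm = np.sort(np.asarray(r_mrna, dtype=float))
    if rp.size == 0 or rm.size == 0:
        raise ValueError("empty correlation list")
    n = min(rp.size, rm.size)
    if rp.size != rm.size:
        q = (np.arange(n) + 0.5) / n
        if rp.size != n:
            rp = np.quantile(rp, q)
        if rm.size != n:
            rm = np.quantile(rm, q)
    return pd.DataFrame({"q_protein": rp, "q_mrna": rm})
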