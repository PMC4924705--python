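"""Drug-sensitivity association in an NCI-60-style cell-line panel.

Per compound, log10(IC50) values are normalized across cell lines, lines
are classified as sensitive (< mu - SD), resistant (> mu + SD) or
intermediate, compounds with at least 10 sensitive and 10 resistant lines
are retained, and each gene is tested for differential expression between
the sensitive and resistant lines with a Welch t-test (intermediate lines
excluded); p < 0.05 flags an association.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from coexsurv.io import ExpressionMatrix, ValidationError

__all__ = [
    "DrugResponseMatrix",
    "SensitivityLabels",
    "normalize_response",
    "classify_cell_lines",
    "classify_all",
    "filter_compounds",
    "gene_drug_association",
]

SENSITIVE, RESISTANT, INTERMEDIATE = "sensitive", "resistant", "intermediate"


@dataclass
class DrugResponseMatrix:
    """Compound x cell-line log10(IC50); NaN marks a missing assay."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            raise ValidationError("duplicate compound ids")
        if self.data.columns.duplicated().any():
            raise ValidationError("duplicate cell-line ids")
        self.data = self.data.astype(float)

    @property
    def compounds(self) -> list[str]:
        return list(self.data.index)

    @property
    def cell_lines(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class SensitivityLabels:
    """Per-compound sensitive/resistant/intermediate call per cell line."""

    labels: pd.DataFrame  # compound x cell line; NaN where IC50 missing
    mu: pd.Series
    sd: pd.Series
    degenerate: list[str] = field(default_factory=list)

    def counts(self) -> pd.DataFrame:
        out = {}
        for lab in (SENSITIVE, RESISTANT, INTERMEDIATE):
            out[f"n_{lab}"] = (self.labels == lab).sum(axis=1)
        return pd.DataFrame(out)

    def groups(self, compound: str) -> tuple[list[str], list[str]]:
        row = self.labels.loc[compound]
        return (
            list(row.index[row == SENSITIVE]),
            list(row.index[row == RESISTANT]),
        )


def normalize_response(response: DrugResponseMatrix) -> DrugResponseMatrix:
    """Per-compound z-score across cell lines; missing values stay missing.

    Compounds with zero variance are excluded (reported via a warning).
    """
    data = response.data
    mu = data.mean(axis=1)
    sd = data.std(axis=1, ddof=1)
    degenerate = list(data.index[(sd == 0) | sd.isna()])
    if degenerate:
        warnings.warn(f"excluding zero-variance compounds: {degenerate}", stacklevel=2)
    kept = data.drop(index=degenerate)
    z = kept.sub(mu[kept.index], axis=0).div(sd[kept.index], axis=0)
    return DrugResponseMatrix(z)


def classify_cell_lines(values: pd.Series) -> tuple[pd.Series, float, float, bool]:
    """mu +/- SD classification of one compound's log10(IC50) vector.

    Returns ``(labels, mu, sd, degenerate)``; labels use strict
    inequalities, so values exactly at mu +/- SD are intermediate.  SD is
    the sample (n-1) standard deviation.  A zero-SD vector is flagged
    degenerate and labeled all-intermediate.
    """
    finite = values.dropna()
    if len(finite) < 3:
        raise ValidationError("need >= 3 non-missing values to classify")
    mu = float(finite.mean())
    sd = float(finite.std(ddof=1))
    labels = pd.Series(np.nan, index=values.index, dtype=object)
    if sd == 0:
        labels[finite.index] = INTERMEDIATE
        return labels, mu, sd, True
    labels[finite.index] = INTERMEDIATE
    labels[finite.index[finite > mu + sd]] = RESISTANT
    labels[finite.index[finite < mu - sd]] = SENSITIVE
    return labels, mu, sd, False


def classify_all(response: DrugResponseMatrix) -> SensitivityLabels:
    """Classify every compound's cell lines; collects degenerate compounds."""
    rows, mus, sds, degenerate = {}, {}, {}, []
    for compound in response.compounds:
        labels, mu, sd, degen = classify_cell_lines(response.data.loc[compound])
        rows[compound] = labels
        mus[compound] = mu
        sds[compound] = sd
        if degen:
            degenerate.append(compound)
    return SensitivityLabels(
        labels=pd.DataFrame(rows).T,
        mu=pd.Series(mus),
        sd=pd.Series(sds),
        degenerate=degenerate,
    )


def filter_compounds(
    labels: SensitivityLabels, min_sensitive: int = 10, min_resistant: int = 10
) -> list[str]:
    """Compounds with at least ``min_sensitive`` and ``min_resistant`` lines."""
    counts = labels.counts()
    kept = list(
        counts.index[
            (counts["n_sensitive"] >= min_sensitive)
            & (counts["n_resistant"] >= min_resistant)
        ]
    )
    if not kept:
        warnings.warn("no compound passes the sensitive/resistant count filter", stacklevel=2)
    return kept


def gene_drug_association(
    expr: ExpressionMatrix,
    labels: SensitivityLabels,
    genes: list[str] | None = None,
    compounds: list[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Welch t-test of each gene between sensitive and resistant lines.

    Intermediate lines are excluded.  Pairs where either group has fewer
    than 2 expression values are skipped (reported with NaN statistics).
    Returns a long DataFrame: gene, compound, t, p, group means, significant.
    """
    if genes is None:
        genes = expr.gene_ids
    if compounds is None:
        compounds = list(labels.labels.index)
    missing = [g for g in genes if g not in expr.data.index]
    if missing:
        raise ValidationError(f"genes absent from expression matrix: {missing}")
    records = []
    for compound in compounds:
        sens, res = labels.groups(compound)
        sens = [c for c in sens if c in expr.data.columns]
        res = [c for c in res if c in expr.data.columns]
        for gene in genes:
            if len(sens) < 2 or len(res) < 2:
                records.append((gene, compound, np.nan, np.nan, np.nan, np.nan, False))
                continue
            xs = expr.data.loc[gene, sens].to_numpy()
            xr = expr.data.loc[gene, res].to_numpy()
            if xs.std() == 0 and xr.std() == 0 and xs.mean() == xr.mean():
                t, p = 0.0, 1.0
            else:
                t, p = stats.ttest_ind(xs, xr, equal_var=False)
                t, p = float(t), float(p)
            records.append(
                (gene, compound, t, p, float(xs.mean()), float(xr.mean()), bool(p < alpha))
            )
    return pd.DataFrame(
        records,
        columns=[
            "gene",
            "compound",
            "t_statistic",
            "p_value",
            "mean_sensitive",
            "mean_resistant",
            "significant",
        ],
    )
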