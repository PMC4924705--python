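"""Typed containers and readers/writers for every table the pipeline touches.

All on-disk formats are plain text: tab-separated expression matrices with a
header row of sample ids and a first column of gene ids, STRING-style
whitespace-separated interaction edge lists with per-channel confidence
scores, GMT-like module membership files, and TSV clinical tables.  Readers
validate aggressively so downstream code can assume well-formed input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

AXIS_KINDS = ("timepoints", "patients", "cell_lines")


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


# ---------------------------------------------------------------------------
# Expression matrices


@dataclass
class ExpressionMatrix:
    """Genes x ordered samples, continuous abundance values.

    ``axis_kind`` declares what the columns are: developmental ``timepoints``
    (ordered), ``patients`` or ``cell_lines``.  Row/column ids must be unique
    and every row must contain at least one finite value.
    """

    data: pd.DataFrame
    axis_kind: str = "timepoints"

    def __post_init__(self) -> None:
        if self.axis_kind not in AXIS_KINDS:
            raise ValidationError(
                f"axis_kind must be one of {AXIS_KINDS}, got {self.axis_kind!r}"
            )
        idx = self.data.index
        cols = self.data.columns
        if idx.duplicated().any():
            dups = sorted(set(idx[idx.duplicated()]))
            raise ValidationError(f"duplicate gene ids: {dups}")
        if cols.duplicated().any():
            dups = sorted(set(cols[cols.duplicated()]))
            raise ValidationError(f"duplicate sample ids: {dups}")
        if any(str(c).strip() == "" for c in cols):
            raise ValidationError("empty column label in header")
        values = self.data.to_numpy(dtype=float)
        self.data = pd.DataFrame(values, index=idx.astype(str), columns=cols.astype(str))
        all_nan = ~np.isfinite(values).any(axis=1)
        if all_nan.any():
            bad = list(self.data.index[all_nan])
            raise ValidationError(f"rows with no finite value: {bad}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def profile(self, gene: str) -> np.ndarray:
        return self.data.loc[gene].to_numpy()

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        genes = list(genes)
        missing = [g for g in genes if g not in self.data.index]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing}")
        return ExpressionMatrix(self.data.loc[genes], self.axis_kind)


def read_expression_matrix(path: str | Path, axis_kind: str = "timepoints") -> ExpressionMatrix:
    """Read a TSV expression matrix (header = sample ids, first col = gene ids)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, comment="#")
    df.index = df.index.astype(str)
    numeric = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        converted = pd.to_numeric(df[col].replace("NA", np.nan), errors="coerce")
        bad = converted.isna() & df[col].notna() & (df[col] != "NA")
        if bad.any():
            row = df.index[bad][0]
            raise ValidationError(
                f"{path}: non-numeric value {df.loc[row, col]!r} at row {row!r}, column {col!r}"
            )
        numeric[col] = converted
    return ExpressionMatrix(numeric, axis_kind=axis_kind)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path, header: str | None = None) -> None:
    """Write a TSV matrix; missing values are written as ``NA``."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        matrix.data.to_csv(fh, sep="\t", na_rep="NA", index_label="gene_id")


# ---------------------------------------------------------------------------
# Protein-protein interactions


def _canonical(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass
class InteractionSet:
    """Undirected, scored gene pairs (STRING-style).

    ``edges`` is a DataFrame with columns ``gene_a``, ``gene_b``,
    ``experimental``, ``combined``; pairs are stored in canonical (sorted)
    orientation, without self-loops or duplicates.
    """

    edges: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["gene_a", "gene_b", "experimental", "combined"]
        missing = [c for c in required if c not in self.edges.columns]
        if missing:
            raise ValidationError(f"interaction table missing columns {missing}")
        e = self.edges[required].copy()
        e["gene_a"] = e["gene_a"].astype(str)
        e["gene_b"] = e["gene_b"].astype(str)
        swap = e["gene_a"] > e["gene_b"]
        e.loc[swap, ["gene_a", "gene_b"]] = e.loc[swap, ["gene_b", "gene_a"]].to_numpy()
        if (e["gene_a"] == e["gene_b"]).any():
            raise ValidationError("self-loop in interaction set")
        if e.duplicated(subset=["gene_a", "gene_b"]).any():
            raise ValidationError("duplicate unordered pair in interaction set")
        if (e[["experimental", "combined"]].to_numpy() < 0).any():
            raise ValidationError("negative interaction score")
        self.edges = e.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.edges)

    def pairs(self) -> list[tuple[str, str]]:
        return list(zip(self.edges["gene_a"], self.edges["gene_b"]))

    def pair_set(self) -> set[tuple[str, str]]:
        return set(self.pairs())

    def genes(self) -> set[str]:
        return set(self.edges["gene_a"]) | set(self.edges["gene_b"])

    def has_edge(self, a: str, b: str) -> bool:
        return _canonical(a, b) in self.pair_set()

    def neighbors(self) -> dict[str, set[str]]:
        nbrs: dict[str, set[str]] = {}
        for a, b in self.pairs():
            nbrs.setdefault(a, set()).add(b)
            nbrs.setdefault(b, set()).add(a)
        return nbrs


def read_interactions(
    path: str | Path,
    experimental_min: int = 200,
    combined_min: int = 400,
    universe: Iterable[str] | None = None,
) -> InteractionSet:
    """Read a STRING-style edge list and apply the confidence filters.

    Keeps only edges with experimental score strictly above
    ``experimental_min`` AND combined score strictly above ``combined_min``
    AND (if ``universe`` is given) both endpoints in the universe.  Duplicate
    unordered pairs are collapsed keeping the maximum of each score channel;
    self-loops are dropped.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    df.columns = [str(c).strip().lower().replace(" ", "_") for c in df.columns]
    colmap = {}
    for want, aliases in {
        "gene_a": ("protein1", "gene_a", "gene1", "node1"),
        "gene_b": ("protein2", "gene_b", "gene2", "node2"),
        "experimental": ("experimental", "experimental_score", "exp"),
        "combined": ("combined", "combined_score", "total", "total_score", "score"),
    }.items():
        for alias in aliases:
            if alias in df.columns:
                colmap[want] = alias
                break
        else:
            raise ValidationError(f"{path}: cannot find a column for {want!r}")
    out = pd.DataFrame(
        {
            "gene_a": df[colmap["gene_a"]].astype(str),
            "gene_b": df[colmap["gene_b"]].astype(str),
        }
    )
    for score in ("experimental", "combined"):
        converted = pd.to_numeric(df[colmap[score]], errors="coerce")
        if converted.isna().any():
            i = int(np.where(converted.isna())[0][0])
            raise ValidationError(
                f"{path}: malformed {score} score {df[colmap[score]].iloc[i]!r} on data row {i}"
            )
        out[score] = converted.astype(int)
    return filter_interactions(out, experimental_min, combined_min, universe)


def filter_interactions(
    edges: pd.DataFrame,
    experimental_min: int = 200,
    combined_min: int = 400,
    universe: Iterable[str] | None = None,
) -> InteractionSet:
    """Apply score thresholds (strict), universe restriction and dedup to raw edges."""
    e = edges.copy()
    e = e[e["gene_a"] != e["gene_b"]]
    e = e[(e["experimental"] > experimental_min) & (e["combined"] > combined_min)]
    if universe is not None:
        uni = set(map(str, universe))
        e = e[e["gene_a"].isin(uni) & e["gene_b"].isin(uni)]
    swap = e["gene_a"] > e["gene_b"]
    e = e.copy()
    e.loc[swap, ["gene_a", "gene_b"]] = e.loc[swap, ["gene_b", "gene_a"]].to_numpy()
    e = (
        e.groupby(["gene_a", "gene_b"], as_index=False)[["experimental", "combined"]]
        .max()
        .sort_values(["gene_a", "gene_b"])
        .reset_index(drop=True)
    )
    if len(e) == 0:
        warnings.warn("interaction filtering produced an empty edge set", stacklevel=2)
    return InteractionSet(e)


def write_interactions(interactions: InteractionSet, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    interactions.edges.rename(
        columns={"gene_a": "protein1", "gene_b": "protein2"}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Module membership (GMT-like)


def write_modules(partition: "ModulePartitionLike", path: str | Path, descriptions: Mapping[int, str] | None = None) -> None:
    """Write module membership as GMT-like lines: label, description, members.

    Unassigned genes (label 0) are not written.
    """
    assignment = getattr(partition, "assignment", partition)
    labels = sorted({m for m in assignment.values() if m != 0})
    if not labels:
        raise ValidationError("cannot write an empty partition")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for label in labels:
            members = sorted(g for g, m in assignment.items() if m == label)
            desc = (descriptions or {}).get(label, f"module_{label}")
            fh.write("\t".join([f"module_{label}", desc, *members]) + "\n")


def read_modules(path: str | Path) -> dict[str, int]:
    """Read a GMT-like module file back into a gene -> label assignment."""
    assignment: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(f"malformed module line: {line!r}")
            label = int(fields[0].removeprefix("module_"))
            for gene in fields[2:]:
                if gene in assignment:
                    raise ValidationError(f"gene {gene!r} appears in two modules")
                assignment[gene] = label
    return assignment


# ---------------------------------------------------------------------------
# Clinical tables


@dataclass
class ClinicalTable:
    """Per-sample survival data: time, event indicator, optional covariates.

    ``time`` is a non-negative real in a unit consistent within the cohort
    (e.g. days); ``event`` is 1 when the endpoint was observed and 0 when
    censored.  Optional covariates: ``age`` (real), ``gender`` and ``race``
    (categorical strings).
    """

    table: pd.DataFrame
    covariate_columns: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        t = self.table
        for col in ("time", "event"):
            if col not in t.columns:
                raise ValidationError(f"clinical table missing column {col!r}")
        if t.index.duplicated().any():
            raise ValidationError("duplicate sample ids in clinical table")
        time = pd.to_numeric(t["time"], errors="raise")
        if (time < 0).any():
            raise ValidationError("negative survival time")
        event = pd.to_numeric(t["event"], errors="raise")
        if not set(event.unique()) <= {0, 1}:
            raise ValidationError("event indicator must be 0/1")
        t = t.copy()
        t.index = t.index.astype(str)
        t["time"] = time.astype(float)
        t["event"] = event.astype(int)
        self.table = t
        self.covariate_columns = tuple(
            c for c in t.columns if c not in ("time", "event")
        )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def time(self) -> np.ndarray:
        return self.table["time"].to_numpy()

    @property
    def event(self) -> np.ndarray:
        return self.table["event"].to_numpy()

    def aligned_to(self, sample_ids: Iterable[str]) -> "ClinicalTable":
        ids = [s for s in sample_ids if s in self.table.index]
        return ClinicalTable(self.table.loc[ids])


def read_clinical_table(path: str | Path) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    return ClinicalTable(df)


def write_clinical_table(clinical: ClinicalTable, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    clinical.table.to_csv(path, sep="\t", index_label="sample_id")


# forward-declared protocol for write_modules typing
ModulePartitionLike = object
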