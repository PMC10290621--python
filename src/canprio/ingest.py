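"""Reading expression matrices and region lists; replicate collapsing; CAN subsetting.

Expression matrices arrive as TSV with a ``gene_id`` first column (optionally
followed by an ``experiment_id`` column when a gene has several ISH
experiments) and one column per brain region. Region lists arrive as CSV with
``region_id, acronym, can_role`` where the role is ``feedforward`` or
``feedback`` within the central autonomic network.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ParseError

__all__ = [
    "ExpressionMatrix",
    "RegionSet",
    "IngestReport",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_region_set",
    "collapse_replicates",
    "subset_regions",
]

CAN_ROLES = ("feedforward", "feedback")


@dataclass
class ExpressionMatrix:
    """Gene × region grid of non-negative expression energies.

    ``values`` is a DataFrame indexed by gene id with region-id columns.
    """

    values: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            raise ParseError(f"duplicate gene ids: {sorted(idx[idx.duplicated()])}")
        if cols.has_duplicates:
            raise ParseError(f"duplicate region ids: {sorted(cols[cols.duplicated()])}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ParseError("expression values must be numeric")
        bad = np.argwhere(~np.isfinite(arr) | (arr < 0))
        if bad.size:
            g, r = bad[0]
            raise ParseError(
                f"invalid expression value {arr[g, r]!r} at gene "
                f"{idx[g]!r}, region {cols[r]!r} (must be finite and >= 0)"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def region_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def energies(self) -> np.ndarray:
        return self.values.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class RegionSet:
    """Ordered list of (region_id, acronym, can_role) entries."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["region_id", "acronym", "can_role"]
        missing = [c for c in required if c not in self.frame.columns]
        if missing:
            raise ParseError(f"region set missing columns: {missing}")
        ids = self.frame["region_id"]
        if ids.duplicated().any():
            raise ParseError(
                f"duplicate region ids: {sorted(ids[ids.duplicated()])}"
            )
        bad_roles = set(self.frame["can_role"]) - set(CAN_ROLES)
        if bad_roles:
            raise ParseError(
                f"unknown can_role values {sorted(bad_roles)}; expected {CAN_ROLES}"
            )

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def region_ids(self) -> list[str]:
        return list(self.frame["region_id"])

    def roles(self) -> dict[str, str]:
        return dict(zip(self.frame["region_id"], self.frame["can_role"]))


@dataclass
class IngestReport:
    requested_genes: int
    retained_genes: int
    missing_genes: list[str]
    collapsed_replicates: dict[str, int] = field(default_factory=dict)
    kept_experiment: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.retained_genes + len(self.missing_genes) != self.requested_genes:
            raise ParseError(
                "ingest report inconsistent: retained + missing != requested"
            )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "requested_genes": self.requested_genes,
                    "retained_genes": self.retained_genes,
                    "missing_genes": self.missing_genes,
                    "collapsed_replicates": self.collapsed_replicates,
                    "kept_experiment": self.kept_experiment,
                },
                indent=2,
                sort_keys=True,
            )
        )


def collapse_replicates(
    df: pd.DataFrame,
) -> tuple[pd.DataFrame, dict[str, int], dict[str, str]]:
    """One profile per gene from replicate experiment rows.

    ``df`` has columns ``gene_id``, ``experiment_id`` plus numeric region
    columns. Rule: keep the experiment with the largest total energy across
    regions; ties go to the lexicographically smallest experiment id.
    Idempotent. Returns (collapsed frame indexed by gene_id, replicate counts,
    kept experiment per collapsed gene).
    """
    value_cols = [c for c in df.columns if c not in ("gene_id", "experiment_id")]
    totals = df[value_cols].sum(axis=1)
    work = df.assign(_total=totals)
    counts: dict[str, int] = {}
    kept: dict[str, str] = {}
    keep_rows = []
    for gene, grp in work.groupby("gene_id", sort=False):
        if len(grp) > 1:
            counts[str(gene)] = len(grp)
        best = grp.sort_values(
            ["_total", "experiment_id"], ascending=[False, True], kind="mergesort"
        ).iloc[0]
        if len(grp) > 1:
            kept[str(gene)] = str(best["experiment_id"])
        keep_rows.append(best)
    out = pd.DataFrame(keep_rows).set_index("gene_id")[value_cols]
    out.index.name = "gene_id"
    return out, counts, kept


def read_expression_matrix(
    path: str | Path,
    gene_whitelist: Sequence[str] | None = None,
    provenance: str | None = None,
) -> tuple[ExpressionMatrix, IngestReport]:
    """Read a TSV expression matrix, collapse replicates, apply a whitelist.

    Whitelist genes absent from the file are reported as missing, never
    fabricated; retained genes follow whitelist order (file order otherwise).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.columns[0] != "gene_id":
        raise ParseError(
            f"{path}: first column must be 'gene_id', found {df.columns[0]!r}"
        )
    has_exp = len(df.columns) > 1 and df.columns[1] == "experiment_id"
    if has_exp:
        df["experiment_id"] = df["experiment_id"].astype(str)
    else:
        df.insert(1, "experiment_id", [f"row{i}" for i in range(len(df))])
    value_cols = list(df.columns[2:])
    if not value_cols:
        raise ParseError(f"{path}: no region columns in header")
    if len(set(value_cols)) != len(value_cols):
        raise ParseError(f"{path}: duplicate region ids in header")

    for col in value_cols:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() | ~np.isfinite(numeric) | (numeric < 0)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"{path}: invalid cell value {df[col].iloc[row]!r} at gene "
                f"{df['gene_id'].iloc[row]!r}, region {col!r} "
                f"(row {row + 2}, must be a non-negative number)"
            )
        df[col] = numeric

    collapsed, counts, kept = collapse_replicates(df)
    if collapsed.index.has_duplicates:
        dup = sorted(collapsed.index[collapsed.index.duplicated()])
        raise ParseError(f"{path}: duplicate gene rows after collapsing: {dup}")

    if gene_whitelist is not None:
        requested = list(dict.fromkeys(gene_whitelist))
        present = [g for g in requested if g in collapsed.index]
        missing = [g for g in requested if g not in collapsed.index]
        collapsed = collapsed.loc[present]
        report = IngestReport(
            requested_genes=len(requested),
            retained_genes=len(present),
            missing_genes=missing,
            collapsed_replicates=counts,
            kept_experiment=kept,
        )
    else:
        report = IngestReport(
            requested_genes=len(collapsed),
            retained_genes=len(collapsed),
            missing_genes=[],
            collapsed_replicates=counts,
            kept_experiment=kept,
        )
    matrix = ExpressionMatrix(collapsed, provenance=provenance or str(path))
    return matrix, report


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    out = matrix.values.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_region_set(path: str | Path) -> RegionSet:
    return RegionSet(pd.read_csv(path, dtype=str))


def subset_regions(
    matrix: ExpressionMatrix, regions: RegionSet, strict: bool = True
) -> ExpressionMatrix:
    """Restrict columns to the region set, in region-set order.

    With ``strict`` a listed region missing from the matrix is an error;
    otherwise it is dropped with a warning. Idempotent.
    """
    if len(regions) == 0:
        raise ParseError("region set is empty")
    wanted = regions.region_ids
    have = set(matrix.region_ids)
    missing = [r for r in wanted if r not in have]
    if missing and strict:
        raise ParseError(f"region {missing[0]} not in matrix")
    if missing:
        warnings.warn(f"dropping regions absent from matrix: {missing}", stacklevel=2)
    keep = [r for r in wanted if r in have]
    if not keep:
        raise ParseError("no overlap between region set and matrix columns")
    return ExpressionMatrix(matrix.values[keep], provenance=matrix.provenance)
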