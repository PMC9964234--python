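"""Reading, combining and cleaning expression profiles.

Expression values live in a probe/gene × sample :class:`ExpressionMatrix`
(a thin wrapper over a pandas DataFrame).  Sample metadata — which subject,
condition and replicate each column belongs to — comes from a
:class:`SampleSheet`.  The three study conditions are labelled ``Pre``,
``In`` and ``Post`` (before launch, aboard the station, after return), but
any label set in the sheet is accepted.

Input dialects
--------------
* Expression TSV: header ``probe_id<TAB>sample1<TAB>...``; UTF-8, decimal
  point.  Non-numeric tokens (``NA``, ``NaN``, empty fields, stray text)
  parse to NaN and are removed by :func:`drop_null_rows`.
* Sample sheet TSV: columns ``sample_id``, ``subject_id``, ``condition``,
  ``replicate``.
* Probe map TSV: columns ``probe_id``, ``gene_symbol``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "SampleSheet",
    "ProbeMap",
    "read_expression_profiles",
    "read_sample_sheet",
    "read_probe_map",
    "drop_null_rows",
    "map_probe_ids",
    "split_by_condition",
    "collapse_to_genes",
    "log2_transform",
]


@dataclass
class ExpressionMatrix:
    """Probe/gene × sample matrix of (log2) expression intensities.

    ``data`` is a float DataFrame indexed by row identifier with one column
    per sample.  ``gene_symbols`` optionally annotates each row with a gene
    symbol; rows stay at probe level (several probes may share a symbol).
    """

    data: pd.DataFrame
    gene_symbols: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate row ids: {dups[:5]}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        if self.gene_symbols is not None and not self.gene_symbols.index.equals(
            self.data.index
        ):
            raise ValueError("gene_symbols index does not match row ids")

    @property
    def row_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def col_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def row_labels(self) -> pd.Series:
        """Gene symbols where annotated, else the row (probe) ids."""
        if self.gene_symbols is None:
            return pd.Series(self.data.index, index=self.data.index, dtype=object)
        return self.gene_symbols.fillna(pd.Series(self.data.index, index=self.data.index))

    def to_tsv(self, path: str | Path, id_header: str = "probe_id") -> None:
        self.data.to_csv(path, sep="\t", index_label=id_header)


@dataclass
class SampleSheet:
    """Per-sample condition/subject/replicate assignments."""

    table: pd.DataFrame  # columns: sample_id, subject_id, condition, replicate

    REQUIRED = ("sample_id", "subject_id", "condition", "replicate")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"sample sheet missing columns: {missing}")
        sid = self.table["sample_id"]
        if sid.duplicated().any():
            raise ValueError(
                f"duplicate sample ids in sheet: {sid[sid.duplicated()].tolist()}"
            )
        trip = self.table[["subject_id", "condition", "replicate"]]
        if trip.duplicated().any():
            raise ValueError("duplicate (subject, condition, replicate) triples")
        if (self.table["replicate"].astype(int) < 1).any():
            raise ValueError("replicate numbers must be positive")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def conditions(self) -> list[str]:
        """Distinct condition labels in order of first appearance."""
        return list(dict.fromkeys(self.table["condition"]))

    def samples_for(self, condition: str) -> list[str]:
        rows = self.table[self.table["condition"] == condition]
        return list(rows["sample_id"])


@dataclass
class ProbeMap:
    """Probe → gene-symbol mapping (many probes may share a gene)."""

    table: pd.DataFrame  # columns: probe_id, gene_symbol

    def __post_init__(self) -> None:
        for col in ("probe_id", "gene_symbol"):
            if col not in self.table.columns:
                raise ValueError(f"probe map missing column {col!r}")
        pid = self.table["probe_id"]
        if pid.duplicated().any():
            raise ValueError(
                f"duplicate probe ids in map: {pid[pid.duplicated()].tolist()[:5]}"
            )

    def as_series(self) -> pd.Series:
        return self.table.set_index("probe_id")["gene_symbol"]


def read_sample_sheet(path: str | Path) -> SampleSheet:
    return SampleSheet(pd.read_csv(path, sep="\t", dtype={"sample_id": str}))


def read_probe_map(path: str | Path) -> ProbeMap:
    return ProbeMap(pd.read_csv(path, sep="\t", dtype=str))


def read_expression_profiles(
    paths: Iterable[str | Path], sheet: SampleSheet
) -> ExpressionMatrix:
    """Combine one or more expression TSVs into a single matrix.

    Files may each carry one or several sample columns; the probe universe
    is the union across files (probes absent from a file get NaN, removed
    later by :func:`drop_null_rows`).  Output columns are exactly the sheet's
    sample ids, in sheet order.
    """
    paths = [Path(p) for p in paths]
    if not paths:
        raise ValueError("no input profiles")

    frames: list[pd.DataFrame] = []
    seen: dict[str, Path] = {}
    for p in paths:
        df = pd.read_csv(p, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        df = df.apply(pd.to_numeric, errors="coerce")
        for col in df.columns:
            if col in seen:
                raise ValueError(
                    f"duplicate sample id {col!r} in {p} (already in {seen[col]})"
                )
            seen[col] = p
        frames.append(df)

    combined = pd.concat(frames, axis=1)  # outer join on probe index
    missing = [s for s in sheet.sample_ids if s not in combined.columns]
    if missing:
        raise ValueError(f"samples in sheet with no data column: {missing}")
    return ExpressionMatrix(combined.loc[:, sheet.sample_ids])


def drop_null_rows(m: ExpressionMatrix) -> ExpressionMatrix:
    """Remove rows containing any null or non-finite reading."""
    finite = np.isfinite(m.data.to_numpy(dtype=float)).all(axis=1)
    if not finite.any():
        raise ValueError("empty matrix after null filtering")
    data = m.data.loc[finite]
    syms = m.gene_symbols.loc[finite] if m.gene_symbols is not None else None
    return ExpressionMatrix(data, syms)


def map_probe_ids(
    m: ExpressionMatrix,
    pm: ProbeMap,
    unmapped_policy: Literal["keep", "drop"] = "keep",
) -> ExpressionMatrix:
    """Annotate rows with gene symbols; rows stay at probe level.

    The probe id remains the unique row key; the symbol is an annotation
    (several probes may map to the same gene).  Unmapped probes are kept
    with the probe id standing in as the label, or dropped, per policy.
    """
    if unmapped_policy not in ("keep", "drop"):
        raise ValueError(f"unknown unmapped_policy {unmapped_policy!r}")
    mapping = pm.as_series()
    symbols = pd.Series(m.data.index, index=m.data.index).map(mapping)
    if unmapped_policy == "drop":
        keep = symbols.notna()
        return ExpressionMatrix(m.data.loc[keep], symbols[keep])
    symbols = symbols.fillna(pd.Series(m.data.index, index=m.data.index))
    return ExpressionMatrix(m.data.copy(), symbols)


def split_by_condition(
    m: ExpressionMatrix, sheet: SampleSheet
) -> dict[str, ExpressionMatrix]:
    """Partition columns into one matrix per condition, in sheet order."""
    unknown = [c for c in m.col_ids if c not in set(sheet.sample_ids)]
    if unknown:
        raise ValueError(f"columns absent from sample sheet: {unknown}")
    out: dict[str, ExpressionMatrix] = {}
    for cond in sheet.conditions:
        cols = [s for s in sheet.samples_for(cond) if s in set(m.col_ids)]
        if not cols:
            raise ValueError(f"condition {cond!r} has zero samples")
        out[cond] = ExpressionMatrix(m.data.loc[:, cols], m.gene_symbols)
    return out


def collapse_to_genes(m: ExpressionMatrix) -> ExpressionMatrix:
    """Optionally collapse probe rows to genes by averaging (off by default
    in the pipeline; analyses normally stay at transcript level)."""
    labels = m.row_labels()
    data = m.data.groupby(labels).mean()
    data.index = data.index.astype(str)
    return ExpressionMatrix(data, pd.Series(data.index, index=data.index))


def log2_transform(m: ExpressionMatrix, pseudo: float = 1.0) -> ExpressionMatrix:
    """log2(x + pseudo) for matrices supplied on linear scale."""
    if (m.data.to_numpy() + pseudo <= 0).any():
        raise ValueError("non-positive values after pseudo-count; cannot log2")
    return ExpressionMatrix(np.log2(m.data + pseudo), m.gene_symbols)
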