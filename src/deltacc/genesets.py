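"""Pathway gene sets and per-pathway expression subsets.

Pathway membership is an input (GMT format); the package ships reference
fixtures from the ten-astronaut spaceflight study (accession E-GEOD-74708):
the DEG membership of its top 11 enriched pathways and the published
pre-flight/in-flight correlation values for the rewired pairs in each
pathway block.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal

import pandas as pd

from .io import ExpressionMatrix

__all__ = [
    "GeneSet",
    "load_gene_sets",
    "subset_matrix",
    "sets_gene_union",
    "reference_pathways",
    "reference_pair_correlations",
]


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: tuple[str, ...]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.name!r} has duplicates")

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)

    def __len__(self) -> int:
        return len(self.genes)


def load_gene_sets(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file: ``name<TAB>description<TAB>gene1<TAB>...`` per line.

    Duplicate genes within a line are collapsed, first occurrence kept.
    """
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: malformed GMT line (need name, "
                    f"description and at least one gene)"
                )
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            sets.append(GeneSet(name, tuple(dict.fromkeys(genes)), desc))
    return sets


def subset_matrix(
    m: ExpressionMatrix,
    gs: GeneSet,
    missing_policy: Literal["warn", "error"] = "warn",
) -> ExpressionMatrix:
    """Rows of ``m`` whose gene label belongs to the set, original order."""
    labels = m.row_labels()
    members = set(gs.genes)
    keep = labels.isin(members)
    missing = sorted(members - set(labels))
    if missing:
        msg = f"genes in set {gs.name!r} absent from matrix: {missing}"
        if missing_policy == "error":
            raise ValueError(msg)
        warnings.warn(msg, stacklevel=2)
    if not keep.any():
        raise ValueError(f"no genes of set {gs.name!r} found in matrix")
    syms = m.gene_symbols.loc[keep.to_numpy()] if m.gene_symbols is not None else None
    return ExpressionMatrix(m.data.loc[keep.to_numpy()], syms)


def sets_gene_union(sets: Iterable[GeneSet]) -> list[str]:
    """Sorted distinct union of member genes across sets."""
    genes: set[str] = set()
    for gs in sets:
        genes.update(gs.genes)
    return sorted(genes)


def reference_pathways() -> list[GeneSet]:
    """The 11 enriched-pathway DEG sets from the spaceflight study."""
    path = resources.files("deltacc").joinpath("data/pathways.gmt")
    with resources.as_file(path) as p:
        return load_gene_sets(p)


def reference_pair_correlations() -> pd.DataFrame:
    """Published per-pathway pair correlations (columns: pathway, gene_a,
    gene_b, cc_pre, cc_in, dcc_printed) for the rewired pairs of the
    spaceflight study."""
    path = resources.files("deltacc").joinpath("data/pair_correlations.tsv")
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t", comment="#")
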