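"""Gene-pair transition classification and biomarker-panel selection.

A pair's correlation in each condition is trichotomized by |CC| into
weak (< 0.36), moderate (0.36–0.68) and strong (>= 0.68); the boundaries
follow a published convention for correlation strength, made half-open so
every value classifies uniquely while agreeing with the convention's
two-decimal bounds.  Sign changes define four transition categories:

1. nonnegative → nonnegative      3. negative → nonnegative
2. nonnegative → negative         4. negative → negative

The panel screen is two-stage: keep pairs whose correlation differential
satisfies |ΔCC| >= 0.70, then keep only transitions that flip the pair's
class decisively — strong→weak, weak→strong, or strong→opposite-sign
strong.  The monitoring panel is the distinct-gene union of the surviving
pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # avoids an import cycle with .correlation
    from .correlation import CorrelationMatrix

__all__ = [
    "StrengthClass",
    "CLASS_BOUNDS",
    "DELTA_CUT",
    "PairRecord",
    "strength_class",
    "transition_category",
    "changed_pairs",
    "pairs_from_table",
    "is_panel_transition",
    "select_panel",
    "panel_genes",
    "category_counts",
    "pairs_to_frame",
]

#: |CC| boundaries: weak < 0.36 <= moderate < 0.68 <= strong
CLASS_BOUNDS: tuple[float, float] = (0.36, 0.68)

#: differential cut-off; applied as |ΔCC| >= DELTA_CUT
DELTA_CUT = 0.70


class StrengthClass(str, Enum):
    WEAK = "weak"
    MODERATE = "moderate"
    STRONG = "strong"


@dataclass(frozen=True)
class PairRecord:
    """One annotated gene pair (stored with gene_a < gene_b)."""

    gene_a: str
    gene_b: str
    cc_a: float
    cc_b: float
    dcc: float
    category: int
    class_a: StrengthClass
    class_b: StrengthClass
    selected: bool = False

    @property
    def pair_id(self) -> str:
        return f"{self.gene_a}--{self.gene_b}"


def strength_class(cc: float) -> StrengthClass:
    if math.isnan(cc):
        raise ValueError("undefined correlation has no strength class")
    a = abs(cc)
    if a > 1 + 1e-9:
        raise ValueError(f"|cc| > 1: {cc}")
    weak_hi, strong_lo = CLASS_BOUNDS
    if a < weak_hi:
        return StrengthClass.WEAK
    if a < strong_lo:
        return StrengthClass.MODERATE
    return StrengthClass.STRONG


def transition_category(cc_a: float, cc_b: float) -> int:
    """Sign-based category of a (before, after) correlation pair.

    Zero counts as nonnegative, so an exact 0.00 after-value with a
    positive before-value stays in category 1.
    """
    for v in (cc_a, cc_b):
        if math.isnan(v) or abs(v) > 1 + 1e-9:
            raise ValueError(f"correlation outside [-1, 1]: {v}")
    if cc_a >= 0:
        return 1 if cc_b >= 0 else 2
    return 3 if cc_b >= 0 else 4


def is_panel_transition(
    class_a: StrengthClass, cc_a: float, class_b: StrengthClass, cc_b: float
) -> bool:
    """True for strong→weak, weak→strong, or strong→opposite-sign strong."""
    s, w = StrengthClass.STRONG, StrengthClass.WEAK
    if (class_a, class_b) in ((s, w), (w, s)):
        return True
    if class_a == s and class_b == s:
        return (cc_a >= 0) != (cc_b >= 0)
    return False


def _make_record(gene_a: str, gene_b: str, cc_a: float, cc_b: float) -> PairRecord:
    if gene_b < gene_a:
        gene_a, gene_b = gene_b, gene_a
    return PairRecord(
        gene_a=gene_a,
        gene_b=gene_b,
        cc_a=cc_a,
        cc_b=cc_b,
        dcc=cc_b - cc_a,
        category=transition_category(cc_a, cc_b),
        class_a=strength_class(cc_a),
        class_b=strength_class(cc_b),
    )


def _sorted(pairs: list[PairRecord]) -> list[PairRecord]:
    return sorted(pairs, key=lambda p: (-abs(p.dcc), p.gene_a, p.gene_b))


def changed_pairs(
    cc_from: "CorrelationMatrix",
    cc_to: "CorrelationMatrix",
    delta_cut: float = DELTA_CUT,
) -> list[PairRecord]:
    """All unordered pairs with |ΔCC| >= delta_cut, fully annotated.

    Pairs with an undefined correlation in either condition are skipped.
    Output is ordered by |ΔCC| descending, then pair id.
    """
    if cc_from.ids != cc_to.ids:
        raise ValueError("correlation matrices cover different id lists")
    ids = cc_from.ids
    dcc = cc_to.cc - cc_from.cc
    iu, ju = np.triu_indices(len(ids), k=1)
    out: list[PairRecord] = []
    for i, j in zip(iu, ju):
        d = dcc[i, j]
        if not np.isfinite(d) or abs(d) < delta_cut - 1e-12:
            continue
        out.append(_make_record(ids[i], ids[j], float(cc_from.cc[i, j]), float(cc_to.cc[i, j])))
    return _sorted(out)


def pairs_from_table(
    table: pd.DataFrame, delta_cut: float = DELTA_CUT
) -> list[PairRecord]:
    """Annotate precomputed pair-level correlations (columns ``gene_a``,
    ``gene_b``, ``cc_pre``/``cc_from``, ``cc_in``/``cc_to``); applies the
    same |ΔCC| cut and ordering as :func:`changed_pairs`."""
    cols = {c.lower(): c for c in table.columns}
    a_col = cols.get("cc_from") or cols.get("cc_pre")
    b_col = cols.get("cc_to") or cols.get("cc_in")
    if a_col is None or b_col is None:
        raise ValueError("table needs cc_from/cc_pre and cc_to/cc_in columns")
    out = []
    for _, row in table.iterrows():
        cc_a, cc_b = float(row[a_col]), float(row[b_col])
        if abs(cc_b - cc_a) < delta_cut - 1e-12:
            continue
        out.append(_make_record(str(row["gene_a"]), str(row["gene_b"]), cc_a, cc_b))
    return _sorted(out)


def select_panel(pairs: list[PairRecord]) -> list[PairRecord]:
    """Keep pairs whose strength-class transition qualifies for the panel;
    returned records carry ``selected=True``."""
    return [
        replace(p, selected=True)
        for p in pairs
        if is_panel_transition(p.class_a, p.cc_a, p.class_b, p.cc_b)
    ]


def panel_genes(pairs: list[PairRecord]) -> list[str]:
    """Sorted distinct genes across the given pairs — the monitoring panel."""
    genes: set[str] = set()
    for p in pairs:
        genes.add(p.gene_a)
        genes.add(p.gene_b)
    return sorted(genes)


def category_counts(pairs: list[PairRecord]) -> dict[int, int]:
    counts = {1: 0, 2: 0, 3: 0, 4: 0}
    for p in pairs:
        counts[p.category] += 1
    return counts


def pairs_to_frame(pairs: list[PairRecord]) -> pd.DataFrame:
    """Tabular pair report: one row per pair with CCs, ΔCC, category,
    classes and the selected flag."""
    return pd.DataFrame(
        [
            {
                "gene_a": p.gene_a,
                "gene_b": p.gene_b,
                "cc_from": p.cc_a,
                "cc_to": p.cc_b,
                "dcc": p.dcc,
                "category": p.category,
                "class_from": p.class_a.value,
                "class_to": p.class_b.value,
                "selected": p.selected,
            }
            for p in pairs
        ],
        columns=[
            "gene_a",
            "gene_b",
            "cc_from",
            "cc_to",
            "dcc",
            "category",
            "class_from",
            "class_to",
            "selected",
        ],
    )
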