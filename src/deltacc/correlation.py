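"""Per-condition Pearson correlation matrices and their differentials.

The rewiring measure is the elementwise differential
``ΔCC = CC(to) − CC(from)`` between two conditions' correlation matrices,
so each entry lies in [−2, 2].  Rows with zero variance have undefined
correlations (NaN); they are carried through explicitly and excluded from
summaries.

For genome-scale inputs the full all-pairs matrix is a memory hazard;
:func:`correlation_summary_blocked` streams the upper triangle in row
blocks and never materializes the matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix
from .panel import CLASS_BOUNDS

__all__ = [
    "CorrelationMatrix",
    "DeltaMatrix",
    "CorrelationSummary",
    "pearson",
    "correlation_matrix",
    "delta_matrix",
    "correlation_summary",
    "correlation_summary_blocked",
]

#: rows below this count may be held as a full matrix; above it, use the
#: blocked summary path
FULL_MATRIX_CAP = 5000


@dataclass
class CorrelationMatrix:
    """Symmetric all-pairs Pearson matrix for one condition."""

    ids: list[str]
    cc: np.ndarray
    condition_label: str = ""

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.cc.shape != (n, n):
            raise ValueError("cc shape does not match ids")
        finite = np.isfinite(self.cc)
        if not np.allclose(
            self.cc[finite], np.clip(self.cc[finite], -1.0, 1.0), atol=1e-9
        ):
            raise ValueError("correlation entries outside [-1, 1]")

    def lookup(self, a: str, b: str) -> float:
        i, j = self.ids.index(a), self.ids.index(b)
        return float(self.cc[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.cc, index=self.ids, columns=self.ids)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="id")


@dataclass
class DeltaMatrix:
    """Elementwise CC differential between two conditions."""

    ids: list[str]
    dcc: np.ndarray
    from_label: str = ""
    to_label: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dcc, index=self.ids, columns=self.ids)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="id")


@dataclass(frozen=True)
class CorrelationSummary:
    """Global correlation landscape of one condition.

    ``mean_abs_cc`` and the weak/moderate/strong fractions are taken over
    the defined off-diagonal upper-triangle entries; ``n_pairs`` counts
    them and ``n_undefined`` the pairs dropped for zero variance.
    """

    mean_abs_cc: float
    frac_weak: float
    frac_moderate: float
    frac_strong: float
    n_pairs: int
    n_undefined: int = 0


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson correlation r = Σ(xᵢ−x̄)(yᵢ−ȳ) / √(Σ(xᵢ−x̄)² Σ(yᵢ−ȳ)²).

    Returns NaN when either vector is constant (undefined correlation).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    dx, dy = x - x.mean(), y - y.mean()
    denom = np.sqrt((dx @ dx) * (dy @ dy))
    if denom == 0:
        return float("nan")
    return float(np.clip((dx @ dy) / denom, -1.0, 1.0))


def correlation_matrix(
    m: ExpressionMatrix, condition_label: str = "", use_gene_labels: bool = True
) -> CorrelationMatrix:
    """All-pairs Pearson matrix over the rows of an expression matrix.

    Zero-variance rows yield NaN off-diagonal entries (and NaN diagonal);
    they are excluded from summaries downstream.  Row labels are gene
    symbols where annotated.
    """
    if m.shape[1] < 2:
        raise ValueError("need at least 2 samples to correlate")
    vals = m.values
    sd = vals.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cc = np.corrcoef(vals)
    cc = np.atleast_2d(cc)
    bad = sd == 0
    cc[bad, :] = np.nan
    cc[:, bad] = np.nan
    good = ~bad
    cc[np.ix_(good, good)] = np.clip(cc[np.ix_(good, good)], -1.0, 1.0)
    np.fill_diagonal(cc, np.where(bad, np.nan, 1.0))
    ids = list(m.row_labels()) if use_gene_labels else m.row_ids
    return CorrelationMatrix(ids=ids, cc=cc, condition_label=condition_label)


def delta_matrix(cc_from: CorrelationMatrix, cc_to: CorrelationMatrix) -> DeltaMatrix:
    """ΔCC = CC(to) − CC(from), by matrix subtraction."""
    if cc_from.ids != cc_to.ids:
        raise ValueError("correlation matrices cover different id lists")
    return DeltaMatrix(
        ids=list(cc_from.ids),
        dcc=cc_to.cc - cc_from.cc,
        from_label=cc_from.condition_label,
        to_label=cc_to.condition_label,
    )


def _summarize(abs_vals: np.ndarray, n_undefined: int) -> CorrelationSummary:
    weak_hi, strong_lo = CLASS_BOUNDS
    n = abs_vals.size
    if n == 0:
        raise ValueError("no defined off-diagonal pairs to summarize")
    return CorrelationSummary(
        mean_abs_cc=float(abs_vals.mean()),
        frac_weak=float((abs_vals < weak_hi).mean()),
        frac_moderate=float(((abs_vals >= weak_hi) & (abs_vals < strong_lo)).mean()),
        frac_strong=float((abs_vals >= strong_lo).mean()),
        n_pairs=int(n),
        n_undefined=int(n_undefined),
    )


def correlation_summary(cc: CorrelationMatrix) -> CorrelationSummary:
    """Mean |CC| and strength-class fractions over defined upper-triangle
    pairs — a quantitative proxy for how coordinated a condition's
    transcriptome is."""
    iu = np.triu_indices(len(cc.ids), k=1)
    vals = cc.cc[iu]
    defined = np.isfinite(vals)
    return _summarize(np.abs(vals[defined]), int((~defined).sum()))


def correlation_summary_blocked(
    m: ExpressionMatrix, block_size: int = 512
) -> CorrelationSummary:
    """Streaming equivalent of ``correlation_summary(correlation_matrix(m))``
    that processes row blocks and never forms the full matrix."""
    if m.shape[1] < 2:
        raise ValueError("need at least 2 samples to correlate")
    vals = m.values
    n = vals.shape[0]
    mean = vals.mean(axis=1, keepdims=True)
    centered = vals - mean
    norms = np.linalg.norm(centered, axis=1)
    defined_rows = norms > 0

    weak_hi, strong_lo = CLASS_BOUNDS
    total = 0
    undefined = 0
    sum_abs = 0.0
    n_weak = n_moderate = 0

    for i0 in range(0, n, block_size):
        i1 = min(i0 + block_size, n)
        block = centered[i0:i1] @ centered.T  # (i1-i0) × n cross-products
        for irow, i in enumerate(range(i0, i1)):
            row = block[irow, i + 1 :]
            nb = norms[i + 1 :]
            ok = defined_rows[i] & (nb > 0)
            undefined += int((~ok).sum())
            r = np.abs(row[ok]) / (norms[i] * nb[ok])
            r = np.clip(r, 0.0, 1.0)
            total += r.size
            sum_abs += float(r.sum())
            n_weak += int((r < weak_hi).sum())
            n_moderate += int(((r >= weak_hi) & (r < strong_lo)).sum())

    if total == 0:
        raise ValueError("no defined off-diagonal pairs to summarize")
    return CorrelationSummary(
        mean_abs_cc=sum_abs / total,
        frac_weak=n_weak / total,
        frac_moderate=n_moderate / total,
        frac_strong=(total - n_weak - n_moderate) / total,
        n_pairs=total,
        n_undefined=undefined,
    )
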