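"""Differential expression between two conditions.

Genes are called differentially expressed (DEGs) when |log2FC| >= 3.00 and
p < 0.05 between two conditions.  The test is a Poisson likelihood-ratio
test of equal per-sample rate applied to per-condition totals of the
intensities rescaled to nonnegative pseudo-counts — the same quantity a
count-model LRT computes — with a Welch two-sample t-test available for
users who prefer a variance-based test on intensities.

No multiple-testing correction is applied by default (selection is on raw
p-values); Benjamini–Hochberg adjustment is available via ``adjust="bh"``.
"""

from __future__ import annotations

import math

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix

__all__ = ["DEGRecord", "log2_fold_change", "lrt_test", "call_degs"]

#: default thresholds for DEG calling
LFC_CUT = 3.00
P_CUT = 0.05


@dataclass(frozen=True)
class DEGRecord:
    row_id: str
    gene_symbol: str
    log2fc: float
    p_value: float
    is_deg: bool
    degenerate: bool = False  # zero total signal in both groups


def log2_fold_change(
    values_a: Sequence[float],
    values_b: Sequence[float],
    scale: Literal["log2", "linear"] = "log2",
    eps: float = 1e-6,
) -> float:
    """log2 fold change of condition b over condition a.

    On log2 scale this is the difference of group means; on linear scale it
    is log2 of the ratio of group means with pseudo-value ``eps`` added to
    both means.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if scale == "log2":
        return float(b.mean() - a.mean())
    if scale == "linear":
        ma, mb = a.mean() + eps, b.mean() + eps
        if ma <= 0 or mb <= 0:
            raise ValueError("non-positive mean on linear scale; increase eps")
        return float(np.log2(mb / ma))
    raise ValueError(f"unknown scale {scale!r}")


def lrt_test(
    sum_a: float, sum_b: float, n_a: int, n_b: int
) -> tuple[float, float]:
    """Poisson likelihood-ratio test of equal per-sample rate.

    With totals C_a, C_b over n_a and n_b samples, the null expects C_a to
    be a Binomial(T, pi) draw with T = C_a + C_b and pi = n_a/(n_a+n_b).
    The deviance D = 2[C_a ln(C_a/(pi T)) + C_b ln(C_b/((1-pi) T))]
    (zero-count terms contribute 0) is referred to a chi-square with one
    degree of freedom.  Returns ``(statistic, p_value)``; a zero total is
    degenerate and yields (0.0, 1.0).
    """
    if sum_a < 0 or sum_b < 0:
        raise ValueError("sums must be nonnegative")
    if n_a <= 0 or n_b <= 0:
        raise ValueError("sample counts must be positive")
    total = sum_a + sum_b
    if total == 0:
        return 0.0, 1.0
    pi = n_a / (n_a + n_b)
    d = 0.0
    # log of the ratio taken as a difference of logs: robust to underflow
    # when one total is many orders of magnitude below the other
    if sum_a > 0:
        d += sum_a * (math.log(sum_a) - math.log(pi) - math.log(total))
    if sum_b > 0:
        d += sum_b * (math.log(sum_b) - math.log(1.0 - pi) - math.log(total))
    d = max(2.0 * d, 0.0)
    return float(d), float(stats.chi2.sf(d, df=1))


def _welch(a: np.ndarray, b: np.ndarray) -> float:
    res = stats.ttest_ind(b, a, equal_var=False)
    p = float(res.pvalue)
    return 1.0 if np.isnan(p) else p


def call_degs(
    cond_a: ExpressionMatrix,
    cond_b: ExpressionMatrix,
    lfc_cut: float = LFC_CUT,
    p_cut: float = P_CUT,
    scale: Literal["log2", "linear"] = "log2",
    test: Literal["lrt", "welch"] = "lrt",
    adjust: Literal["none", "bh"] = "none",
    eps: float = 1e-6,
) -> list[DEGRecord]:
    """Call DEGs of condition b relative to condition a, row by row.

    Rows must be identical in both matrices.  For the LRT, log2-scale
    intensities are rescaled to linear pseudo-counts (2**x) and summed per
    condition.  The report is ordered by |log2fc| descending, then p
    ascending, then row id.
    """
    ids_a, ids_b = list(cond_a.data.index), list(cond_b.data.index)
    if ids_a != ids_b:
        off = sorted(set(ids_a).symmetric_difference(ids_b))
        raise ValueError(f"row sets differ between conditions: {off[:10]}")

    a = cond_a.values
    b = cond_b.values
    n_a, n_b = a.shape[1], b.shape[1]

    if scale == "log2":
        lfc = b.mean(axis=1) - a.mean(axis=1)
        counts_a, counts_b = np.exp2(a), np.exp2(b)
    elif scale == "linear":
        ma, mb = a.mean(axis=1) + eps, b.mean(axis=1) + eps
        if (ma <= 0).any() or (mb <= 0).any():
            raise ValueError("non-positive mean on linear scale; increase eps")
        lfc = np.log2(mb / ma)
        counts_a, counts_b = a, b
    else:
        raise ValueError(f"unknown scale {scale!r}")

    pvals = np.empty(len(ids_a))
    degenerate = np.zeros(len(ids_a), dtype=bool)
    if test == "lrt":
        sums_a = counts_a.sum(axis=1)
        sums_b = counts_b.sum(axis=1)
        for i in range(len(ids_a)):
            _, pvals[i] = lrt_test(sums_a[i], sums_b[i], n_a, n_b)
            degenerate[i] = sums_a[i] + sums_b[i] == 0
    elif test == "welch":
        for i in range(len(ids_a)):
            pvals[i] = _welch(a[i], b[i])
    else:
        raise ValueError(f"unknown test {test!r}")

    if adjust == "bh":
        pvals = _benjamini_hochberg(pvals)
    elif adjust != "none":
        raise ValueError(f"unknown adjust {adjust!r}")

    labels = cond_a.row_labels()
    records = [
        DEGRecord(
            row_id=rid,
            gene_symbol=str(labels[rid]),
            log2fc=float(lfc[i]),
            p_value=float(pvals[i]),
            is_deg=bool(abs(lfc[i]) >= lfc_cut and pvals[i] < p_cut),
            degenerate=bool(degenerate[i]),
        )
        for i, rid in enumerate(ids_a)
    ]
    records.sort(key=lambda r: (-abs(r.log2fc), r.p_value, r.row_id))
    return records


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(adj, 0, 1)
    return out


def degs_to_frame(records: list[DEGRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "row_id": r.row_id,
                "gene_symbol": r.gene_symbol,
                "log2fc": r.log2fc,
                "p_value": r.p_value,
                "is_deg": r.is_deg,
            }
            for r in records
        ]
    )
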