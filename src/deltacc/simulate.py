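"""Synthetic three-condition expression studies with planted structure.

The generator emulates the shape of a spaceflight transcriptome study:
three conditions (Pre/In/Post), each with ``n_subjects × n_replicates``
sample columns, approximately Gaussian log2 intensities, pairwise
correlations planted per condition, and mean shifts planting chosen log2
fold changes.  A :class:`SyntheticTruth` ledger records what was planted so
recovery by the correlation and panel-selection stages can be scored.

Correlation targets are assembled as a background-correlation matrix with
planted entries overwritten, then repaired to positive semidefinite by
eigenvalue clipping and diagonal rescaling so it can parameterize a
multivariate normal.  Planted entries must survive the repair within a
small drift tolerance (default ±0.02) or generation aborts.

Columns are exchangeable within a condition (no subject random effect by
default, mirroring the treatment of replicate profiles as independent
samples); an optional per-subject intercept can be switched on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .io import ExpressionMatrix, SampleSheet
from .panel import (
    DELTA_CUT,
    PairRecord,
    is_panel_transition,
    strength_class,
    transition_category,
)

__all__ = [
    "PlantedPair",
    "PlantedDEG",
    "SyntheticConfig",
    "SyntheticTruth",
    "build_target_correlation",
    "nearest_psd",
    "sample_condition",
    "generate_study",
    "evaluate_recovery",
]

CONDITIONS = ("Pre", "In", "Post")


@dataclass(frozen=True)
class PlantedPair:
    """A gene pair with one target correlation per condition."""

    i: int
    j: int
    cc: Mapping[str, float]  # condition -> target correlation

    def __post_init__(self) -> None:
        if self.i == self.j:
            raise ValueError("planted pair indices must differ")
        for cond, v in self.cc.items():
            if abs(v) >= 1:
                raise ValueError(f"|target cc| must be < 1, got {v} for {cond}")


@dataclass(frozen=True)
class PlantedDEG:
    gene: int
    log2fc: float  # In vs Pre mean shift on log2 scale


@dataclass
class SyntheticConfig:
    n_genes: int = 40
    n_subjects: int = 10
    n_replicates: int = 2
    baseline_mean: float = 8.0  # log2 intensity
    noise_sd: float = 0.5
    planted_pairs: list[PlantedPair] = field(default_factory=list)
    planted_degs: list[PlantedDEG] = field(default_factory=list)
    background_cc: float = 0.0
    subject_sd: float = 0.0  # per-subject random intercept, off by default
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 2 or self.n_subjects < 1 or self.n_replicates < 1:
            raise ValueError("n_genes >= 2 and positive subject/replicate counts required")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not -1 < self.background_cc < 1:
            raise ValueError("background_cc must be in (-1, 1)")
        for p in self.planted_pairs:
            if not (0 <= p.i < self.n_genes and 0 <= p.j < self.n_genes):
                raise ValueError(f"planted pair ({p.i},{p.j}) out of range")
        for d in self.planted_degs:
            if not 0 <= d.gene < self.n_genes:
                raise ValueError(f"planted DEG gene {d.gene} out of range")

    @property
    def n_samples_per_condition(self) -> int:
        return self.n_subjects * self.n_replicates

    @classmethod
    def from_file(cls, path: str | Path) -> "SyntheticConfig":
        """Load a flat YAML/JSON config.  ``planted_pairs`` entries are
        ``[i, j, cc_pre, cc_in, cc_post]``; ``planted_degs`` entries are
        ``[gene, log2fc]``."""
        text = Path(path).read_text()
        raw = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        pairs = [
            PlantedPair(int(e[0]), int(e[1]), dict(zip(CONDITIONS, map(float, e[2:5]))))
            for e in raw.pop("planted_pairs", [])
        ]
        degs = [PlantedDEG(int(e[0]), float(e[1])) for e in raw.pop("planted_degs", [])]
        return cls(planted_pairs=pairs, planted_degs=degs, **raw)


@dataclass
class SyntheticTruth:
    """Ledger of planted structure, labelled by the selection rule itself."""

    gene_ids: list[str]
    target_cc: dict[str, np.ndarray]  # post-repair target matrices
    planted_records: list[PairRecord]  # Pre->In annotation of planted pairs
    should_be_selected: set[str]  # pair ids expected to pass the panel screen
    planted_log2fc: dict[str, float]
    seed: int

    def planted_pair_ids(self) -> set[str]:
        return {p.pair_id for p in self.planted_records}


def nearest_psd(matrix: np.ndarray, eigen_floor: float = 1e-6) -> np.ndarray:
    """Clip eigenvalues at ``eigen_floor`` and rescale to unit diagonal."""
    sym = (matrix + matrix.T) / 2.0
    w, v = np.linalg.eigh(sym)
    if w.min() >= eigen_floor:
        return sym
    w = np.clip(w, eigen_floor, None)
    repaired = (v * w) @ v.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    return (repaired + repaired.T) / 2.0


def build_target_correlation(
    n_genes: int,
    planted: Sequence[tuple[int, int, float]],
    background_cc: float = 0.0,
    eigen_floor: float = 1e-6,
    drift_tol: float = 0.02,
) -> np.ndarray:
    """Target correlation matrix with planted entries and background fill.

    The raw construction may be indefinite; it is repaired to PSD, and the
    planted entries must survive within ``drift_tol`` or a ValueError is
    raised (mutually inconsistent targets).
    """
    target = np.full((n_genes, n_genes), float(background_cc))
    np.fill_diagonal(target, 1.0)
    for i, j, cc in planted:
        if abs(cc) >= 1:
            raise ValueError(f"|target cc| must be < 1, got {cc}")
        target[i, j] = target[j, i] = cc
    repaired = nearest_psd(target, eigen_floor)
    for i, j, cc in planted:
        if abs(repaired[i, j] - cc) > drift_tol:
            raise ValueError(
                f"planted correlation ({i},{j})={cc} drifted to "
                f"{repaired[i, j]:.4f} after PSD repair; targets inconsistent"
            )
    return repaired


def sample_condition(
    target_corr: np.ndarray,
    means: np.ndarray,
    noise_sd: float,
    n_samples: int,
    seed: int,
) -> np.ndarray:
    """Draw ``n_samples`` columns from N(means, noise_sd² · target_corr)."""
    w, v = np.linalg.eigh((target_corr + target_corr.T) / 2.0)
    if w.min() < -1e-8:
        raise ValueError("target correlation matrix is not PSD")
    rng = np.random.default_rng(seed)
    root = v * np.sqrt(np.clip(w, 0.0, None))
    z = rng.standard_normal((target_corr.shape[0], n_samples))
    return means[:, None] + noise_sd * (root @ z)


def generate_study(
    cfg: SyntheticConfig,
) -> tuple[dict[str, ExpressionMatrix], SampleSheet, SyntheticTruth]:
    """Generate Pre/In/Post matrices, a sample sheet, and the truth ledger.

    Planted DEG shifts apply to the In condition (and persist Post,
    mimicking effects that do not revert on return).  Truth labels are
    derived from the post-repair target matrices with the same rule the
    panel-selection stage applies, so labelling and selection agree by
    construction on noise-free input.
    """
    gene_ids = [f"G{k:04d}" for k in range(cfg.n_genes)]
    targets: dict[str, np.ndarray] = {}
    for cond in CONDITIONS:
        planted = [(p.i, p.j, p.cc.get(cond, cfg.background_cc)) for p in cfg.planted_pairs]
        targets[cond] = build_target_correlation(
            cfg.n_genes, planted, cfg.background_cc
        )

    means = {c: np.full(cfg.n_genes, cfg.baseline_mean, dtype=float) for c in CONDITIONS}
    for d in cfg.planted_degs:
        means["In"][d.gene] += d.log2fc
        means["Post"][d.gene] += d.log2fc

    n_cols = cfg.n_samples_per_condition
    rows = []
    matrices: dict[str, ExpressionMatrix] = {}
    ss = np.random.SeedSequence(cfg.seed)
    cond_seeds = ss.generate_state(2 * len(CONDITIONS)) % (2**31)
    for k, cond in enumerate(CONDITIONS):
        vals = sample_condition(
            targets[cond], means[cond], cfg.noise_sd, n_cols, int(cond_seeds[2 * k])
        )
        if cfg.subject_sd > 0:
            rng = np.random.default_rng(int(cond_seeds[2 * k + 1]))
            intercepts = rng.normal(0.0, cfg.subject_sd, size=cfg.n_subjects)
            vals += np.repeat(intercepts, cfg.n_replicates)[None, :]
        col_ids = []
        for s in range(1, cfg.n_subjects + 1):
            for r in range(1, cfg.n_replicates + 1):
                col_ids.append(f"{cond}_S{s:02d}R{r}")
                rows.append(
                    {
                        "sample_id": col_ids[-1],
                        "subject_id": f"S{s:02d}",
                        "condition": cond,
                        "replicate": r,
                    }
                )
        matrices[cond] = ExpressionMatrix(
            pd.DataFrame(vals, index=gene_ids, columns=col_ids)
        )

    sheet = SampleSheet(pd.DataFrame(rows))
    truth = _label_truth(cfg, gene_ids, targets)
    return matrices, sheet, truth


def _label_truth(
    cfg: SyntheticConfig, gene_ids: list[str], targets: dict[str, np.ndarray]
) -> SyntheticTruth:
    records: list[PairRecord] = []
    selectable: set[str] = set()
    for p in cfg.planted_pairs:
        cc_a = float(targets["Pre"][p.i, p.j])
        cc_b = float(targets["In"][p.i, p.j])
        a, b = sorted((gene_ids[p.i], gene_ids[p.j]))
        rec = PairRecord(
            gene_a=a,
            gene_b=b,
            cc_a=cc_a,
            cc_b=cc_b,
            dcc=cc_b - cc_a,
            category=transition_category(cc_a, cc_b),
            class_a=strength_class(cc_a),
            class_b=strength_class(cc_b),
        )
        records.append(rec)
        if abs(rec.dcc) >= DELTA_CUT - 1e-12 and is_panel_transition(
            rec.class_a, cc_a, rec.class_b, cc_b
        ):
            selectable.add(rec.pair_id)
    return SyntheticTruth(
        gene_ids=gene_ids,
        target_cc=targets,
        planted_records=records,
        should_be_selected=selectable,
        planted_log2fc={gene_ids[d.gene]: d.log2fc for d in cfg.planted_degs},
        seed=cfg.seed,
    )


def evaluate_recovery(
    selected: Sequence[PairRecord], truth: SyntheticTruth
) -> tuple[float, float]:
    """Score a selection against the truth ledger.

    Returns ``(sensitivity, false_positive_rate)``: sensitivity over the
    planted-selectable pairs, FPR over all pairs that were not planted as
    selectable.  Sensitivity is NaN when nothing selectable was planted.
    """
    selected_ids = {p.pair_id for p in selected}
    positives = truth.should_be_selected
    n = len(truth.gene_ids)
    n_pairs = n * (n - 1) // 2
    negatives = n_pairs - len(positives)
    fp = len(selected_ids - positives)
    fpr = fp / negatives if negatives else 0.0
    if not positives:
        return float("nan"), fpr
    sens = len(selected_ids & positives) / len(positives)
    return sens, fpr
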