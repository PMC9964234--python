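"""End-to-end orchestration: expression input → DEGs → per-pathway CC/ΔCC
matrices → pair report → selected panel, with a run manifest.

Two input modes:

* expression mode — TSV profiles plus a sample sheet (and optionally a
  probe map and a GMT of pathways);
* precomputed-CC mode — a pair-level table of per-condition correlations
  (columns ``pathway``, ``gene_a``, ``gene_b``, ``cc_pre``, ``cc_in``),
  which skips straight to transition classification and selection.  The
  packaged reference table from the spaceflight study runs this way.

Every stage logs a banner and row counts to stderr (suppressed by
``quiet``); outputs are deterministically sorted TSVs; the manifest records
config, seed and the row count of every file written.  A stage failure
leaves a ``FAILED`` marker naming the stage.
"""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .correlation import (
    FULL_MATRIX_CAP,
    correlation_matrix,
    correlation_summary,
    delta_matrix,
)
from .diffexpr import LFC_CUT, P_CUT, call_degs, degs_to_frame
from .genesets import load_gene_sets, subset_matrix
from .io import (
    drop_null_rows,
    log2_transform,
    map_probe_ids,
    read_expression_profiles,
    read_probe_map,
    read_sample_sheet,
    split_by_condition,
)
from .panel import (
    DELTA_CUT,
    pairs_from_table,
    pairs_to_frame,
    panel_genes,
    select_panel,
)

__all__ = ["PipelineConfig", "run_pipeline"]

KNOWN_CONDITIONS = {"Pre", "In", "Post"}


@dataclass
class PipelineConfig:
    out_dir: str = "deltacc_out"
    # expression mode inputs
    expression_paths: list[str] = field(default_factory=list)
    sample_sheet: str | None = None
    probe_map: str | None = None
    gene_sets: str | None = None  # GMT
    # precomputed-CC mode input
    pair_cc_table: str | None = None
    # analysis settings
    deg_from: str = "Pre"
    deg_to: str = "In"
    dcc_from: str = "Pre"
    dcc_to: str = "In"
    lfc_cut: float = LFC_CUT
    p_cut: float = P_CUT
    delta_cut: float = DELTA_CUT
    scale: str = "log2"  # or "linear" (triggers log2(x+1) on input)
    full_matrix_cap: int = FULL_MATRIX_CAP
    seed: int = 0
    quiet: bool = False

    def __post_init__(self) -> None:
        for thr in (self.lfc_cut, self.p_cut, self.delta_cut):
            if thr <= 0:
                raise ValueError("thresholds must be positive")
        for label in (self.deg_from, self.deg_to, self.dcc_from, self.dcc_to):
            if label not in KNOWN_CONDITIONS:
                raise ValueError(
                    f"unknown condition label {label!r}; expected one of "
                    f"{sorted(KNOWN_CONDITIONS)}"
                )
        if self.pair_cc_table is None and not self.expression_paths:
            raise ValueError("need expression_paths or pair_cc_table")
        if self.expression_paths and self.sample_sheet is None:
            raise ValueError("expression mode requires a sample sheet")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        return cls(**raw)


def _log(cfg: PipelineConfig, msg: str) -> None:
    if not cfg.quiet:
        print(f"[deltacc] {msg}", file=sys.stderr)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every configured stage; returns the manifest (also written to
    ``manifest.json`` in the output directory)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "config": asdict(cfg),
        "counts": {},
    }
    stage = "setup"
    try:
        if cfg.pair_cc_table is not None:
            stage = "select"
            _run_precomputed(cfg, out, manifest)
        else:
            _run_expression(cfg, out, manifest)
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\ncause: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _write_pairs(
    cfg: PipelineConfig, out: Path, manifest: dict, all_pairs, selected
) -> None:
    report = pairs_to_frame(all_pairs)
    sel_ids = {p.pair_id for p in selected}
    report["selected"] = [
        f"{a}--{b}" in sel_ids for a, b in zip(report["gene_a"], report["gene_b"])
    ]
    report.to_csv(out / "pair_report.tsv", sep="\t", index=False)
    pairs_to_frame(selected).to_csv(out / "selected_pairs.tsv", sep="\t", index=False)
    genes = panel_genes(selected)
    (out / "panel_genes.txt").write_text("".join(g + "\n" for g in genes))
    manifest["counts"]["pair_report"] = len(report)
    manifest["counts"]["selected_pairs"] = len(selected)
    manifest["counts"]["panel_genes"] = len(genes)
    _log(cfg, f"select: {len(selected)}/{len(all_pairs)} pairs -> {len(genes)} genes")


def _run_precomputed(cfg: PipelineConfig, out: Path, manifest: dict) -> None:
    _log(cfg, f"precomputed-CC mode: {cfg.pair_cc_table}")
    table = pd.read_csv(cfg.pair_cc_table, sep="\t", comment="#")
    blocks = (
        [(name, grp) for name, grp in table.groupby("pathway", sort=False)]
        if "pathway" in table.columns
        else [("all", table)]
    )
    all_pairs, selected, per_block = [], [], {}
    for name, grp in blocks:
        pairs = pairs_from_table(grp, delta_cut=cfg.delta_cut)
        sel = select_panel(pairs)
        all_pairs.extend(pairs)
        selected.extend(sel)
        per_block[str(name)] = len(sel)
        _log(cfg, f"{name}: {len(sel)}/{len(pairs)} pairs selected")
    manifest["counts"]["selected_per_block"] = per_block
    # pooled panel: deduplicate pairs repeated across pathway blocks
    seen: set[str] = set()
    unique_selected = [
        p for p in selected if not (p.pair_id in seen or seen.add(p.pair_id))
    ]
    _write_pairs(cfg, out, manifest, all_pairs, unique_selected)


def _run_expression(cfg: PipelineConfig, out: Path, manifest: dict) -> None:
    stage = "assemble"
    _log(cfg, f"assemble: {len(cfg.expression_paths)} profile file(s)")
    sheet = read_sample_sheet(cfg.sample_sheet)
    m = read_expression_profiles(cfg.expression_paths, sheet)
    if cfg.scale == "linear":
        m = log2_transform(m)
    m = drop_null_rows(m)
    if cfg.probe_map:
        m = map_probe_ids(m, read_probe_map(cfg.probe_map))
    m.to_tsv(out / "cleaned_matrix.tsv")
    manifest["counts"]["cleaned_matrix"] = m.shape[0]
    _log(cfg, f"assemble: {m.shape[0]} rows x {m.shape[1]} samples retained")

    conditions = split_by_condition(m, sheet)
    for cond, cm in conditions.items():
        manifest["counts"][f"samples_{cond}"] = cm.shape[1]

    # DEG stage (input already on log2 scale at this point)
    degs = call_degs(
        conditions[cfg.deg_from],
        conditions[cfg.deg_to],
        lfc_cut=cfg.lfc_cut,
        p_cut=cfg.p_cut,
        scale="log2",
    )
    deg_frame = degs_to_frame(degs)
    deg_frame.to_csv(out / "deg_table.tsv", sep="\t", index=False)
    manifest["counts"]["degs"] = int(deg_frame["is_deg"].sum())
    _log(cfg, f"deg: {manifest['counts']['degs']} DEGs "
              f"({cfg.deg_to} vs {cfg.deg_from})")

    gene_sets = load_gene_sets(cfg.gene_sets) if cfg.gene_sets else None
    cond_from, cond_to = conditions[cfg.dcc_from], conditions[cfg.dcc_to]

    from .panel import changed_pairs  # local to avoid cycle at import time

    all_pairs, selected, per_block = [], [], {}
    if gene_sets:
        for gs in gene_sets:
            sub_from = subset_matrix(cond_from, gs)
            sub_to = subset_matrix(cond_to, gs)
            cc_from = correlation_matrix(sub_from, cfg.dcc_from)
            cc_to = correlation_matrix(sub_to, cfg.dcc_to)
            safe = gs.name.replace(" ", "_")
            cc_from.to_tsv(out / f"cc_{cfg.dcc_from}_{safe}.tsv")
            cc_to.to_tsv(out / f"cc_{cfg.dcc_to}_{safe}.tsv")
            delta_matrix(cc_from, cc_to).to_tsv(
                out / f"dcc_{cfg.dcc_from}_{cfg.dcc_to}_{safe}.tsv"
            )
            pairs = changed_pairs(cc_from, cc_to, delta_cut=cfg.delta_cut)
            sel = select_panel(pairs)
            all_pairs.extend(pairs)
            selected.extend(sel)
            per_block[gs.name] = len(sel)
            _log(cfg, f"{gs.name}: {len(sel)}/{len(pairs)} pairs selected")
    else:
        if m.shape[0] <= cfg.full_matrix_cap:
            cc_from = correlation_matrix(cond_from, cfg.dcc_from)
            cc_to = correlation_matrix(cond_to, cfg.dcc_to)
            cc_from.to_tsv(out / f"cc_{cfg.dcc_from}.tsv")
            cc_to.to_tsv(out / f"cc_{cfg.dcc_to}.tsv")
            delta_matrix(cc_from, cc_to).to_tsv(
                out / f"dcc_{cfg.dcc_from}_{cfg.dcc_to}.tsv"
            )
            all_pairs = changed_pairs(cc_from, cc_to, delta_cut=cfg.delta_cut)
            selected = select_panel(all_pairs)
            per_block["all"] = len(selected)
        else:
            # genome scale: stream summaries instead of materializing matrices
            from .correlation import correlation_summary_blocked

            for cond, cm in conditions.items():
                s = correlation_summary_blocked(cm)
                pd.Series(asdict(s)).to_csv(
                    out / f"cc_summary_{cond}.tsv", sep="\t", header=False
                )
            _log(cfg, "corr: row count above full-matrix cap; wrote summaries only")

    manifest["counts"]["selected_per_block"] = per_block
    seen: set[str] = set()
    unique_selected = [
        p for p in selected if not (p.pair_id in seen or seen.add(p.pair_id))
    ]
    _write_pairs(cfg, out, manifest, all_pairs, unique_selected)
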