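"""Orchestration: configuration, the full read -> QC -> reference -> screen
-> spatial -> report pipeline, and tab-delimited report emission."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import TableDialect, read_manifest, read_nuclei_table, to_newick
from .model import EmbryoRecording, build_lineage
from .reference import WTReference, build_pair_reference, select_async_pairs
from .screen import GeneScreenResult, buffering_test, qc_embryo, screen_gene
from .spatial import normalize_axes, position_deviation
from .timing import ads_table, analysis_cutoff_frame, cycle_lengths

logger = logging.getLogger("lineatime")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "write_reports"]


@dataclass
class PipelineConfig:
    """Thresholds and paths for one pipeline run (defaults follow the study
    design: 5-minute asynchrony threshold, 50% reduction, two replicates,
    alpha 0.05/0.01, buffering alpha 0.01, QC at 300/350 cells and frame
    240, 1.5-minute frames)."""

    manifest: str = ""
    output_dir: str = "out"
    annotations: str = ""
    async_threshold_min: float = 5.0
    reduction: float = 0.5
    alphas: tuple[float, float] = (0.05, 0.01)
    min_replicates: int = 2
    buffering_alpha: float = 0.01
    qc_min_cells_last: int = 300
    qc_min_cells_by_frame: int = 350
    qc_frame: int = 240
    cell_target: int = 350
    frame_interval_min: float = 1.5
    min_n: int = 8
    xy_um_per_pixel: float = 1.0
    z_um_per_plane: float = 0.71
    position_cells: tuple[str, ...] = ()
    seed: int = 0
    write_newick: bool = True

    def __post_init__(self):
        if not (0 < self.reduction < 1):
            raise ValueError("reduction must be in (0, 1)")
        for a in self.alphas:
            if not (0 < a < 1):
                raise ValueError("alphas must be in (0, 1)")
        if self.frame_interval_min <= 0 or self.async_threshold_min <= 0:
            raise ValueError("minutes must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update(overrides)
        if "alphas" in data:
            data["alphas"] = tuple(data["alphas"])
        if "position_cells" in data:
            data["position_cells"] = tuple(data["position_cells"])
        return cls(**data)

    def dialect(self) -> TableDialect:
        return TableDialect(
            xy_um_per_pixel=self.xy_um_per_pixel,
            z_um_per_plane=self.z_um_per_plane,
        )


@dataclass
class PipelineResult:
    config: PipelineConfig
    reference: WTReference
    qc: pd.DataFrame
    gene_results: dict[str, GeneScreenResult]
    cycle_table: pd.DataFrame
    ads_by_embryo: pd.DataFrame
    buffering: pd.DataFrame
    spatial: pd.DataFrame
    exclusions: pd.DataFrame
    trees: dict = field(default_factory=dict, repr=False)
    recordings: dict = field(default_factory=dict, repr=False)


def _load_recordings(config: PipelineConfig) -> list[EmbryoRecording]:
    manifest = read_manifest(config.manifest)
    base = Path(config.manifest).parent
    dialect = config.dialect()
    recs = []
    for row in manifest.itertuples(index=False):
        path = Path(row.path)
        if not path.is_absolute():
            path = base / path
        recs.append(
            read_nuclei_table(
                path,
                dialect,
                id=str(row.recording_id),
                target_gene=str(row.target_gene),
                replicate=int(row.replicate),
                marker=str(row.marker),
                frame_interval_min=config.frame_interval_min,
            )
        )
    return recs


def run_pipeline(
    config: PipelineConfig,
    recordings: list[EmbryoRecording] | None = None,
) -> PipelineResult:
    """Execute the full screen pipeline.

    ``recordings`` may be passed directly (e.g. from the simulator);
    otherwise they are read from the manifest. Deterministic given inputs.
    """
    t_start = time.time()
    if recordings is None:
        recordings = _load_recordings(config)
    logger.info("loaded %d recordings", len(recordings))

    # --- QC -------------------------------------------------------------------
    qc_rows, exclusion_rows = [], []
    passing: list[EmbryoRecording] = []
    for rec in recordings:
        qc = qc_embryo(
            rec,
            min_cells_last=config.qc_min_cells_last,
            min_cells_by_frame=config.qc_min_cells_by_frame,
            qc_frame=config.qc_frame,
        )
        qc_rows.append(
            {
                "recording_id": rec.id,
                "target_gene": rec.target_gene,
                "passed": qc.passed,
                "reasons": ";".join(qc.reasons),
                "cells_at_last_frame": qc.cells_at_last_frame,
            }
        )
        if qc.passed:
            passing.append(rec)
        else:
            exclusion_rows.append(
                {"kind": "recording", "id": rec.id, "reason": ";".join(qc.reasons)}
            )
    qc_table = pd.DataFrame(qc_rows)

    # --- timing tables --------------------------------------------------------
    trees, cutoffs, cyc_tables, ads_tables = {}, {}, {}, {}
    for rec in passing:
        tree = build_lineage(rec)
        cutoff = analysis_cutoff_frame(tree, config.cell_target)
        trees[rec.id] = tree
        cutoffs[rec.id] = cutoff
        cyc_tables[rec.id] = cycle_lengths(tree, cutoff_frame=cutoff)
        ads_tables[rec.id] = ads_table(tree, cutoff_frame=cutoff)
    logger.info("built %d lineage trees", len(trees))

    wt = [r for r in passing if r.target_gene == "wild-type"]
    perturbed = [r for r in passing if r.target_gene != "wild-type"]
    if len(wt) < config.min_n:
        raise ValueError(
            f"only {len(wt)} QC-passing wild-type embryos; need >= {config.min_n}"
        )

    # --- wild-type reference --------------------------------------------------
    ref = build_pair_reference(
        [trees[r.id] for r in wt],
        alpha=config.alphas[0],
        min_n=config.min_n,
        cohort_ids=[r.id for r in wt],
    )
    select_async_pairs(ref, config.async_threshold_min)
    if config.annotations:
        from .reference import assign_pair_categories

        ann = pd.read_csv(config.annotations, sep="\t")
        assign_pair_categories(ref, zip(ann["parent"], ann["category"]))
    logger.info(
        "reference: %d pairs, %d monitored", len(ref.pairs), len(ref.monitored_pairs)
    )

    # --- screen ---------------------------------------------------------------
    genes: dict[str, list[EmbryoRecording]] = {}
    for rec in perturbed:
        genes.setdefault(rec.target_gene, []).append(rec)
    # genes whose every replicate failed QC still need an unscreenable row
    for rec in recordings:
        if rec.target_gene != "wild-type" and rec.target_gene not in genes:
            genes[rec.target_gene] = []

    wt_cycles = [cyc_tables[r.id] for r in wt]
    gene_results: dict[str, GeneScreenResult] = {}
    buffering_rows = []
    for gene in sorted(genes):
        recs = genes[gene]
        result = screen_gene(
            gene,
            recs,
            ref,
            cell_target=config.cell_target,
            reduction=config.reduction,
            alphas=config.alphas,
            min_replicates=config.min_replicates,
        )
        if recs:
            p_tabs = [cyc_tables[r.id] for r in recs]
            buf_table, buf_flag = buffering_test(
                p_tabs, wt_cycles, alpha=config.buffering_alpha
            )
            result.buffering = buf_table
            result.buffering_flag = buf_flag
            for row in buf_table.to_dict("records"):
                buffering_rows.append({"gene": gene, **row})
        else:
            exclusion_rows.append(
                {"kind": "gene", "id": gene, "reason": "no-qc-passing-replicate"}
            )
        gene_results[gene] = result
    logger.info("screened %d genes", len(gene_results))

    # --- spatial --------------------------------------------------------------
    spatial_rows = []
    if config.position_cells:
        wt_norm = [normalize_axes(r)[0] for r in wt]
        for rec in perturbed:
            norm, _ = normalize_axes(rec)
            for cell in config.position_cells:
                try:
                    dev = position_deviation(norm, wt_norm, cell, min_n=config.min_n)
                except (KeyError, ValueError) as exc:
                    spatial_rows.append(
                        {"recording_id": rec.id, "gene": rec.target_gene,
                         "cell": cell, "distance": np.nan, "p": np.nan,
                         "note": str(exc)}
                    )
                    continue
                spatial_rows.append(
                    {"recording_id": rec.id, "gene": rec.target_gene, "cell": cell,
                     "distance": dev["distance"], "p": dev["p"], "note": ""}
                )

    # --- long tables ----------------------------------------------------------
    cyc_long = pd.concat(
        [t.assign(recording_id=rid).reset_index() for rid, t in cyc_tables.items()],
        ignore_index=True,
    )
    ads_long = pd.concat(
        [t.assign(recording_id=rid).reset_index() for rid, t in ads_tables.items()],
        ignore_index=True,
    )

    logger.info("pipeline finished in %.1f s", time.time() - t_start)
    return PipelineResult(
        config=config,
        reference=ref,
        qc=qc_table,
        gene_results=gene_results,
        cycle_table=cyc_long,
        ads_by_embryo=ads_long,
        buffering=pd.DataFrame(
            buffering_rows,
            columns=["gene", "generation", "n_perturbed", "n_wildtype",
                     "f_stat", "p", "skipped"],
        ),
        spatial=pd.DataFrame(
            spatial_rows,
            columns=["recording_id", "gene", "cell", "distance", "p", "note"],
        ),
        exclusions=pd.DataFrame(exclusion_rows, columns=["kind", "id", "reason"]),
        trees=trees,
        recordings={r.id: r for r in recordings},
    )


def hit_matrix(result: PipelineResult) -> pd.DataFrame:
    """Gene x monitored-pair matrix with entries "", "0.05" or "0.01"."""
    pairs = list(result.reference.monitored_pairs)
    rows = {}
    for gene, gr in sorted(result.gene_results.items()):
        rows[gene] = {
            p: ("" if gr.hit_levels.get(p) is None else f"{gr.hit_levels[p]:g}")
            for p in pairs
        }
    return pd.DataFrame.from_dict(rows, orient="index", columns=pairs)


def write_reports(result: PipelineResult, output_dir: str | Path | None = None) -> dict:
    """Write the report bundle as tab-delimited tables plus a run log.

    Returns a mapping of report name -> path.
    """
    out = Path(output_dir or result.config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    def save(name: str, df: pd.DataFrame, index: bool = False):
        p = out / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=index, float_format="%.6g")
        paths[name] = p

    save("cycle_lengths", result.cycle_table)
    save("ads_by_embryo", result.ads_by_embryo)
    save("pair_reference", result.reference.pair_table(), index=True)
    save("hit_matrix", hit_matrix(result), index=True)
    save("qc_log", result.qc)
    save("buffering", result.buffering)
    save("spatial_deviations", result.spatial)
    save("exclusions", result.exclusions)
    save("cell_stats", result.reference.cell_stats, index=True)

    if result.config.write_newick and result.trees:
        tree_dir = out / "trees"
        tree_dir.mkdir(exist_ok=True)
        for rid, tree in result.trees.items():
            (tree_dir / f"{rid}.nwk").write_text(to_newick(tree) + "\n")
        paths["trees"] = tree_dir

    meta = {
        "version": __version__,
        "seed": result.config.seed,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(result.config).items()
        },
        "n_recordings": len(result.recordings),
        "n_genes": len(result.gene_results),
        "monitored_pairs": list(result.reference.monitored_pairs),
    }
    meta_path = out / "run_meta.json"
    meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    paths["run_meta"] = meta_path

    log_path = out / "run_log.txt"
    lines = [
        f"lineatime {__version__}",
        f"seed: {result.config.seed}",
        f"recordings: {len(result.recordings)}",
        f"qc passed: {int(result.qc['passed'].sum())} / {len(result.qc)}",
        f"monitored pairs: {len(result.reference.monitored_pairs)}",
        f"genes screened: {len(result.gene_results)}",
    ]
    log_path.write_text("\n".join(lines) + "\n")
    paths["run_log"] = log_path
    return paths
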