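"""End-to-end orchestration: validate → normalize → pool → map → report.

:func:`run_pipeline` is the in-memory engine used by tests and the
acceptance machinery; :func:`run_map_analysis` is the file-based front door
behind ``txmap run``.  A "sex"-style comparison and an "FGF"-style
comparison are just two run configurations differing in the pool labels —
there is no special-casing of either.
"""

from __future__ import annotations

import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import PipelineError, ValidationError
from .gene_table import (
    PoolProfile,
    call_tail_genes,
    collapse_probes,
    gene_ratio,
    pool_genes,
)
from .io_manifest import (
    GeneLocusMap,
    InclusionCriteria,
    PlatformAnnotation,
    ProbeMatrix,
    SampleManifest,
    apply_inclusion_filters,
    load_expression,
    load_gene_loci,
    load_platform,
    parse_manifest,
)
from .mapper import (
    MapConfig,
    assign_genes,
    build_windows,
    merge_significant_spans,
    segment_significance,
    segment_stats,
    single_gene_map,
)
from .normalize import (
    NormalizationConfig,
    linearize,
    quantile_normalize_within,
    scale_across_datasets,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    manifest_path: str = "manifest.tsv"
    platform_dir: str = "platforms"
    loci_path: str = "loci.tsv"
    expression_dir: str = "expression"
    output_dir: str = "txmap_out"
    pool_a: str = "A"
    pool_b: str = "B"
    map_config: MapConfig = field(default_factory=MapConfig)
    normalization: NormalizationConfig = field(default_factory=NormalizationConfig)
    inclusion: InclusionCriteria = field(default_factory=InclusionCriteria)
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        if self.pool_a == self.pool_b:
            raise ValidationError("pool_a and pool_b must be distinct")


@dataclass
class MapResult:
    """Everything one comparison produces."""

    segments: pd.DataFrame          # default-resolution windows with stats
    regions: pd.DataFrame           # merged significant spans (default map)
    single_gene: pd.DataFrame       # merged spans at single-gene resolution
    ratios: pd.DataFrame            # per-gene ratio table with tail calls
    profile_a: PoolProfile
    profile_b: PoolProfile
    summary: dict


def run_pipeline(
    manifest: SampleManifest,
    matrices: dict[str, ProbeMatrix],
    annotations: dict[str, PlatformAnnotation],
    loci: GeneLocusMap,
    pool_a: str = "A",
    pool_b: str = "B",
    map_cfg: MapConfig | None = None,
    norm_cfg: NormalizationConfig | None = None,
    single_gene_cfg: MapConfig | None = None,
    run_single_gene: bool = True,
) -> MapResult:
    """Run the full meta-analysis comparison of two pools in memory."""
    map_cfg = map_cfg or MapConfig()
    norm_cfg = norm_cfg or NormalizationConfig()

    gene_tables: dict[str, pd.DataFrame] = {}
    for ds_id, matrix in matrices.items():
        linear = linearize(matrix)
        normed = quantile_normalize_within(linear, norm_cfg)
        ann = annotations[matrix.platform_id]
        gene_tables[ds_id] = collapse_probes(normed, ann)
    gene_tables = scale_across_datasets(gene_tables, norm_cfg)

    profile_a = pool_genes(gene_tables, manifest, pool_a, map_cfg.sample_number)
    profile_b = pool_genes(gene_tables, manifest, pool_b, map_cfg.sample_number)
    ratios = gene_ratio(profile_a, profile_b)
    ratios = call_tail_genes(ratios, map_cfg.tail_fraction)

    grid = build_windows(loci.chromosome_lengths, map_cfg.window_bp, map_cfg.shift_bp)
    assignment = assign_genes(grid, loci)
    segments = segment_stats(grid, assignment, profile_a, profile_b)
    segments = segment_significance(segments, ratios, map_cfg)
    regions = merge_significant_spans(segments)

    if run_single_gene:
        sg_cfg = single_gene_cfg or MapConfig.single_gene(
            tail_fraction=map_cfg.tail_fraction,
            q_threshold=map_cfg.q_threshold,
            sample_number=map_cfg.sample_number,
        )
        sg = single_gene_map(loci, profile_a, profile_b, ratios, sg_cfg)
    else:
        sg = pd.DataFrame(columns=["chromosome", "start", "end", "genes",
                                   "ratio", "q", "direction", "n_windows"])

    summary = {
        "pool_a": pool_a,
        "pool_b": pool_b,
        "data_points_a": profile_a.total_data_points,
        "data_points_b": profile_b.total_data_points,
        "mapped_loci": int(len(ratios)),
        "n_windows": int(len(segments)),
        "n_significant_windows": int(segments["significant"].sum())
        if not segments.empty else 0,
        "n_significant_regions": int(len(regions)),
        "n_regions_over": int((regions["direction"] == "over").sum())
        if not regions.empty else 0,
        "n_regions_under": int((regions["direction"] == "under").sum())
        if not regions.empty else 0,
        "n_single_gene_spans": int(len(sg)),
    }
    logger.info("pools %s vs %s: %d + %d data points over %d mapped loci; "
                "%d/%d significant windows",
                pool_a, pool_b, summary["data_points_a"], summary["data_points_b"],
                summary["mapped_loci"], summary["n_significant_windows"],
                summary["n_windows"])
    return MapResult(segments, regions, sg, ratios, profile_a, profile_b, summary)


# ---------------------------------------------------------------------------
# reporting


def _format_gene_list(row: pd.Series, ratios: pd.DataFrame) -> str:
    """Gene list with +/- marks (value above/below the median ratio) and
    ``*`` wrapping for tail genes, mirroring the printed segment tables."""
    med = float(ratios["ratio"].median())
    parts = []
    for g in row["genes"]:
        if g in ratios.index:
            mark = "+" if ratios.at[g, "ratio"] > med else "-"
            if ratios.at[g, "tail"] != "none":
                parts.append(f"*{g}*{mark}")
            else:
                parts.append(f"{g}{mark}")
        else:
            parts.append(g)
    return " ".join(parts)


def segments_to_table(segments: pd.DataFrame, ratios: pd.DataFrame) -> pd.DataFrame:
    """Flatten segment records for TSV export (Chr, start, end, ratio, q, genes)."""
    if segments.empty:
        return pd.DataFrame(columns=[
            "chromosome", "start", "end", "n_genes", "value_a", "value_b",
            "ratio", "n_over", "n_under", "p", "q", "direction", "significant",
            "genes"])
    out = segments.copy()
    out["genes"] = out.apply(lambda r: _format_gene_list(r, ratios), axis=1)
    cols = ["chromosome", "start", "end", "n_genes", "value_a", "value_b",
            "ratio", "n_over", "n_under", "p", "q", "direction", "significant",
            "genes"]
    return out[cols]


def spans_to_table(spans: pd.DataFrame) -> pd.DataFrame:
    if spans.empty:
        return pd.DataFrame(columns=["chromosome", "start", "end", "genes",
                                     "ratio", "q", "direction", "n_windows"])
    out = spans.copy()
    out["genes"] = out["genes"].map(lambda gs: ",".join(gs))
    return out


def write_bed(spans: pd.DataFrame, path: str | Path) -> None:
    """BED6 export of significant spans; 1-based inclusive -> 0-based half-open."""
    with open(path, "w") as fh:
        for i, row in spans.reset_index(drop=True).iterrows():
            score = min(1000, int(round(-10 * _log10(max(row["q"], 1e-300)))))
            fh.write(
                f"{row['chromosome']}\t{row['start'] - 1}\t{row['end']}\t"
                f"region_{i + 1}_{row['direction']}\t{score}\t.\n"
            )


def _log10(x: float) -> float:
    import math

    return math.log10(x)


def write_report(result: MapResult, outdir: str | Path) -> dict[str, Path]:
    """Write the report bundle; overwriting an existing bundle is idempotent."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "segments_default": outdir / "segments_default.tsv",
        "segments_single_gene": outdir / "segments_single_gene.tsv",
        "significant_bed": outdir / "significant.bed",
        "ratios": outdir / "gene_ratios.tsv",
        "summary": outdir / "summary.json",
    }
    segments_to_table(result.segments, result.ratios).to_csv(
        paths["segments_default"], sep="\t", index=False, float_format="%.6g")
    spans_to_table(result.single_gene).to_csv(
        paths["segments_single_gene"], sep="\t", index=False, float_format="%.6g")
    write_bed(result.regions, paths["significant_bed"])
    result.ratios.to_csv(paths["ratios"], sep="\t", float_format="%.10g")
    with open(paths["summary"], "w") as fh:
        json.dump(result.summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths


# ---------------------------------------------------------------------------
# file-based run


def _load_inputs(cfg: RunConfig):
    manifest = parse_manifest(cfg.manifest_path)
    manifest = apply_inclusion_filters(manifest, cfg.inclusion)
    loci = load_gene_loci(cfg.loci_path)
    lengths_path = Path(cfg.loci_path).parent / "chromosome_lengths.tsv"
    if lengths_path.exists():
        lengths = pd.read_csv(lengths_path, sep="\t")
        loci = load_gene_loci(
            cfg.loci_path,
            dict(zip(lengths["chromosome"], lengths["length"].astype(int))),
        )
    annotations: dict[str, PlatformAnnotation] = {}
    for pid in manifest.platform_ids:
        path = Path(cfg.platform_dir) / f"{pid}.tsv"
        if not path.exists():
            raise ValidationError(f"no annotation table for platform '{pid}'")
        annotations[pid] = load_platform(path, pid)
    expr_dir = Path(cfg.expression_dir)
    matrices: dict[str, ProbeMatrix] = {}
    scales = {r.sample_id: r.scale for r in manifest}
    for ds_id in manifest.dataset_ids:
        path = expr_dir / f"{ds_id}.tsv"
        if not path.exists():
            raise ValidationError(f"no expression table for dataset '{ds_id}'")
        platform = next(r.platform_id for r in manifest if r.dataset_id == ds_id)
        matrices[ds_id] = load_expression(path, ds_id, platform, scales)
    if not matrices:
        raise ValidationError("no expression data found")
    return manifest, matrices, annotations, loci


def run_map_analysis(cfg: RunConfig) -> MapResult:
    """Validate inputs, run both map resolutions, write the report bundle.

    Any stage error aborts with the stage name; partial outputs are removed.
    """
    outdir = Path(cfg.output_dir)
    stage = "validate"
    try:
        manifest, matrices, annotations, loci = _load_inputs(cfg)
        stage = "analyze"
        result = run_pipeline(
            manifest, matrices, annotations, loci,
            pool_a=cfg.pool_a, pool_b=cfg.pool_b,
            map_cfg=cfg.map_config, norm_cfg=cfg.normalization,
        )
        stage = "report"
        outdir.mkdir(parents=True, exist_ok=True)
        log_path = outdir / "run.log"
        with open(log_path, "w") as fh:
            json.dump(
                {
                    "samples": len(manifest),
                    "datasets": len(matrices),
                    "pool_counts": manifest.pool_counts(),
                    **result.summary,
                },
                fh, indent=2, sort_keys=True,
            )
            fh.write("\n")
        write_report(result, outdir)
        return result
    except Exception as exc:
        if stage != "validate" and outdir.exists():
            shutil.rmtree(outdir, ignore_errors=True)
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, exc) from exc
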