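"""Synthetic multi-platform expression studies with known spiked segments.

The generator emulates the structure of a pooled microarray meta-analysis:
several datasets measured on different platforms, one to several probes per
gene, a mixture of linear and log2 encodings, unequal pool sizes, and
contiguous gene blocks carrying a known fold change in one pool.  Everything
is deterministic given the design seed, so full-pipeline recovery tests need
no stored fixtures.

Baseline gene expression is lognormal; per-sample, per-probe measurement
noise is multiplicative lognormal (microarray intensities are positive and
the pipeline is ratio-based, so additive Gaussian noise would be the wrong
model).  Genes are placed at regular spacing by default so window membership
counts are analytically known.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_manifest import (
    GeneLocus,
    GeneLocusMap,
    PlatformAnnotation,
    ProbeMatrix,
    SampleManifest,
    SampleRecord,
    write_gene_loci,
    write_manifest,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PlatformDesign:
    platform_id: str
    probes_per_gene: tuple[int, int] = (1, 3)  # inclusive range
    dropout_rate: float = 0.05

    def __post_init__(self):
        if not 0 <= self.dropout_rate < 1:
            raise ValidationError("dropout_rate must be in [0, 1)")


@dataclass(frozen=True)
class DatasetDesign:
    dataset_id: str
    platform_id: str
    scale: str  # "linear" | "log2"
    #: pool label -> number of samples; labels C/D imply pool B females
    n_samples: dict[str, int] = field(default_factory=dict)


@dataclass(frozen=True)
class StudyDesign:
    n_chromosomes: int = 2
    genes_per_chromosome: int = 150
    gene_spacing_bp: int = 100_000
    platforms: tuple[PlatformDesign, ...] = ()
    datasets: tuple[DatasetDesign, ...] = ()
    baseline_log_mean: float = 3.0  # natural-log scale of lognormal baseline
    baseline_log_sd: float = 1.0
    noise_sd: float = 0.2  # natural-log sd of multiplicative sample noise
    seed: int = 0

    def __post_init__(self):
        if self.n_chromosomes < 1 or self.genes_per_chromosome < 1:
            raise ValidationError("counts must be positive")
        if self.gene_spacing_bp < 1:
            raise ValidationError("gene_spacing_bp must be positive")
        if self.noise_sd < 0 or self.baseline_log_sd < 0:
            raise ValidationError("standard deviations must be nonnegative")

    def platform(self, platform_id: str) -> PlatformDesign:
        for p in self.platforms:
            if p.platform_id == platform_id:
                return p
        raise KeyError(platform_id)


@dataclass(frozen=True)
class SpikeBlock:
    """A contiguous block of genes given a fold change in one pool."""

    chromosome: str
    start_gene_index: int  # 0-based index into the chromosome's gene order
    n_genes: int
    fold: float
    pool: str

    def __post_init__(self):
        if self.n_genes < 1 or self.fold <= 0:
            raise ValidationError("spike block needs n_genes >= 1 and fold > 0")


@dataclass
class SyntheticStudy:
    manifest: SampleManifest
    matrices: dict[str, ProbeMatrix]
    annotations: dict[str, PlatformAnnotation]
    genome: GeneLocusMap
    #: pool label -> per-gene true expression (after spiking)
    pool_values: dict[str, pd.Series]
    truth: tuple[SpikeBlock, ...]


def reference_study_design(**overrides) -> StudyDesign:
    """A design mirroring the real study's structure.

    Eleven datasets on five platforms; pool A (male) holds 12 samples and
    pool B (female) 33, of which 9 are subpool C and 24 subpool D; scales are
    a mixture of linear and log2.
    """
    platforms = (
        PlatformDesign("P1", (1, 3), 0.05),
        PlatformDesign("P2", (2, 2), 0.02),
        PlatformDesign("P3", (1, 2), 0.10),
        PlatformDesign("P4", (1, 1), 0.0),
        PlatformDesign("P5", (2, 3), 0.05),
    )
    datasets = (
        DatasetDesign("DS01", "P1", "linear", {"A": 2, "D": 2}),
        DatasetDesign("DS02", "P1", "linear", {"A": 1, "C": 1}),
        DatasetDesign("DS03", "P1", "linear", {"A": 1, "C": 2}),
        DatasetDesign("DS04", "P2", "log2", {"D": 2}),
        DatasetDesign("DS05", "P3", "linear", {"D": 1}),
        DatasetDesign("DS06", "P4", "log2", {"A": 7, "C": 6}),
        DatasetDesign("DS07", "P5", "linear", {"D": 6}),
        DatasetDesign("DS08", "P2", "log2", {"D": 3}),
        DatasetDesign("DS09", "P3", "linear", {"D": 3}),
        DatasetDesign("DS10", "P1", "linear", {"A": 1, "D": 3}),
        DatasetDesign("DS11", "P5", "linear", {"D": 4}),
    )
    base = StudyDesign(platforms=platforms, datasets=datasets)
    return replace(base, **overrides)


def noise_free_design(**overrides) -> StudyDesign:
    """Pool-pure, noise-free design used for exact-recovery checks.

    Every dataset holds samples of a single pool and all scales are linear,
    so quantile normalization within a dataset is the identity and the
    pipeline should recover spiked folds exactly.
    """
    platforms = (
        PlatformDesign("P1", (1, 3), 0.0),
        PlatformDesign("P2", (2, 2), 0.0),
    )
    datasets = (
        DatasetDesign("DS01", "P1", "linear", {"A": 3}),
        DatasetDesign("DS02", "P2", "linear", {"A": 2}),
        DatasetDesign("DS03", "P1", "linear", {"D": 4}),
        DatasetDesign("DS04", "P2", "linear", {"D": 3}),
    )
    base = StudyDesign(platforms=platforms, datasets=datasets, noise_sd=0.0)
    return replace(base, **overrides)


def generate_genome(design: StudyDesign) -> GeneLocusMap:
    """Regularly spaced genes: start 1 + i*spacing, length spacing/2."""
    loci: dict[str, GeneLocus] = {}
    lengths: dict[str, int] = {}
    spacing = design.gene_spacing_bp
    for c in range(design.n_chromosomes):
        chrom = f"chr{c + 1}"
        for i in range(design.genes_per_chromosome):
            start = 1 + i * spacing
            end = start + max(spacing // 2, 1) - 1
            loci[f"G{c + 1:02d}_{i:04d}"] = GeneLocus(chrom, start, end)
        lengths[chrom] = design.genes_per_chromosome * spacing
    return GeneLocusMap(loci, lengths)


def _gene_order(genome: GeneLocusMap) -> list[str]:
    order: list[str] = []
    for chrom in genome.chromosome_lengths:
        order.extend(genome.genes_on(chrom))
    return order


def spike_segments(
    pool_values: dict[str, pd.Series],
    truth: tuple[SpikeBlock, ...] | list[SpikeBlock],
    genome: GeneLocusMap,
) -> dict[str, pd.Series]:
    """Apply spike folds to the named pools' true gene values.

    Blocks must be contiguous gene runs within genome bounds and must not
    overlap.  A fold of 1 leaves the study unchanged.
    """
    occupied: set[tuple[str, int]] = set()
    out = {p: v.copy() for p, v in pool_values.items()}
    for block in truth:
        genes = genome.genes_on(block.chromosome)
        if not genes:
            raise ValidationError(f"spike block on unknown chromosome "
                                  f"'{block.chromosome}'")
        stop = block.start_gene_index + block.n_genes
        if block.start_gene_index < 0 or stop > len(genes):
            raise ValidationError("spike block outside genome bounds")
        for i in range(block.start_gene_index, stop):
            key = (block.chromosome, i)
            if key in occupied:
                raise ValidationError("overlapping spike blocks")
            occupied.add(key)
        target = genes[block.start_gene_index:stop]
        if block.pool not in out:
            raise ValidationError(f"spike names unknown pool '{block.pool}'")
        out[block.pool].loc[target] *= block.fold
    return out


def block_genes(block: SpikeBlock, genome: GeneLocusMap) -> list[str]:
    genes = genome.genes_on(block.chromosome)
    return genes[block.start_gene_index:block.start_gene_index + block.n_genes]


def pick_high_block(
    base_values: pd.Series, genome: GeneLocusMap, chromosome: str, n_genes: int
) -> int:
    """First gene index on ``chromosome`` starting a run of ``n_genes``
    consecutive genes all above the genome-wide median expression.

    Spiking such a block upward cannot move a dataset's median, which keeps
    median scaling — and therefore fold recovery — exact in noise-free
    studies.
    """
    med = float(base_values.median())
    genes = genome.genes_on(chromosome)
    above = [base_values[g] > med for g in genes]
    for i in range(len(genes) - n_genes + 1):
        if all(above[i:i + n_genes]):
            return i
    raise ValidationError("no run of above-median genes found")


def generate_study(
    design: StudyDesign,
    genome: GeneLocusMap | None = None,
    truth: tuple[SpikeBlock, ...] | list[SpikeBlock] = (),
    seed: int | None = None,
) -> SyntheticStudy:
    """Generate manifest, platform annotations and probe matrices.

    Per gene a true baseline expression is drawn lognormal(baseline); spike
    folds are applied to the named pools before probe emission; each probe
    measurement is the pool's true gene value times lognormal(0, noise_sd)
    noise, dropped out at the platform's dropout rate.  log2-scale datasets
    are emitted as log2 of the values.  Deterministic given the seed.
    """
    genome = genome or generate_genome(design)
    rng = np.random.default_rng(design.seed if seed is None else seed)
    order = _gene_order(genome)
    base = pd.Series(
        np.exp(rng.normal(design.baseline_log_mean, design.baseline_log_sd,
                          len(order))),
        index=order,
    )
    pools_used = sorted({p for ds in design.datasets for p in ds.n_samples})
    pool_values = {p: base.copy() for p in pools_used}
    if truth:
        pool_values = spike_segments(pool_values, truth, genome)

    # per-platform probe layout, independent of dataset order
    annotations: dict[str, PlatformAnnotation] = {}
    for pl in design.platforms:
        lo, hi = pl.probes_per_gene
        counts = rng.integers(lo, hi + 1, len(order))
        mapping = {
            f"{pl.platform_id}:{g}:{j}": g
            for g, c in zip(order, counts)
            for j in range(int(c))
        }
        annotations[pl.platform_id] = PlatformAnnotation(pl.platform_id, mapping)

    records: list[SampleRecord] = []
    matrices: dict[str, ProbeMatrix] = {}
    for ds in design.datasets:
        pl = design.platform(ds.platform_id)
        probes = list(annotations[pl.platform_id].probe_to_gene)
        probe_genes = [annotations[pl.platform_id].probe_to_gene[p] for p in probes]
        cols: dict[str, np.ndarray] = {}
        for pool_label, n in ds.n_samples.items():
            pool, subpool = ("B", pool_label) if pool_label in ("C", "D") else (pool_label, None)
            sex = "M" if pool == "A" else "F"
            truth_vec = pool_values[pool_label].loc[probe_genes].to_numpy()
            for i in range(n):
                sid = f"{ds.dataset_id}_{pool_label}{i + 1}"
                noise = (np.exp(rng.normal(0.0, design.noise_sd, len(probes)))
                         if design.noise_sd > 0 else np.ones(len(probes)))
                vals = truth_vec * noise
                if pl.dropout_rate > 0:
                    drop = rng.random(len(probes)) < pl.dropout_rate
                    vals = np.where(drop, np.nan, vals)
                cols[sid] = vals
                records.append(
                    SampleRecord(
                        sample_id=sid,
                        dataset_id=ds.dataset_id,
                        platform_id=ds.platform_id,
                        sex=sex,
                        pool=pool,
                        subpool=subpool,
                        scale=ds.scale,
                        age_years=float(25 + (len(records) % 40)),
                    )
                )
        data = pd.DataFrame(cols, index=pd.Index(probes, name="probe_id"))
        if ds.scale == "log2":
            data = np.log2(data)
        matrices[ds.dataset_id] = ProbeMatrix(
            ds.dataset_id, ds.platform_id, data,
            {s: ds.scale for s in data.columns},
        )
    manifest = SampleManifest(records)
    return SyntheticStudy(manifest, matrices, annotations, genome,
                          pool_values, tuple(truth))


def write_study(study: SyntheticStudy, outdir: str | Path) -> None:
    """Write manifest, loci, platform and expression TSVs plus truth.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_manifest(study.manifest, outdir / "manifest.tsv")
    write_gene_loci(study.genome, outdir / "loci.tsv")
    lengths = pd.DataFrame(
        list(study.genome.chromosome_lengths.items()),
        columns=["chromosome", "length"],
    )
    lengths.to_csv(outdir / "chromosome_lengths.tsv", sep="\t", index=False)
    platform_dir = outdir / "platforms"
    platform_dir.mkdir(exist_ok=True)
    for pid, ann in study.annotations.items():
        pd.DataFrame(
            list(ann.probe_to_gene.items()), columns=["probe_id", "gene_symbol"]
        ).to_csv(platform_dir / f"{pid}.tsv", sep="\t", index=False)
    expr_dir = outdir / "expression"
    expr_dir.mkdir(exist_ok=True)
    for ds_id, matrix in study.matrices.items():
        matrix.data.to_csv(expr_dir / f"{ds_id}.tsv", sep="\t",
                           float_format="%.10g")
    truth_rows = [
        {
            "chromosome": b.chromosome,
            "start_gene_index": b.start_gene_index,
            "n_genes": b.n_genes,
            "fold": b.fold,
            "pool": b.pool,
            "genes": ",".join(block_genes(b, study.genome)),
        }
        for b in study.truth
    ]
    pd.DataFrame(
        truth_rows,
        columns=["chromosome", "start_gene_index", "n_genes", "fold", "pool", "genes"],
    ).to_csv(outdir / "truth.tsv", sep="\t", index=False)
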