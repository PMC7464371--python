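"""Gene-level tables: probe collapsing, pooling, ratios and tail calls.

After normalization, probe-level matrices are collapsed to gene level (mean
of a gene's present probes per sample), samples are pooled by study arm, and
a per-gene expression ratio between the two pools is computed.  A "data
point" is one sample-level gene value; the Sample Number filter drops genes
supported by fewer than ``sample_number`` data points in a pool, so that a
pooled mean never rests on a single measurement when several datasets are
combined.

Tail genes — the genes whose pool ratio falls in the extreme
``tail_fraction`` (default 2.5%) at either end of the genome-wide ratio
distribution — are flagged here; the mapper later asks how many tail genes
each genomic segment contains.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_manifest import PlatformAnnotation, ProbeMatrix, SampleManifest

logger = logging.getLogger(__name__)


def collapse_probes(matrix: ProbeMatrix, ann: PlatformAnnotation) -> pd.DataFrame:
    """Collapse a probe matrix to a gene x sample table.

    Per sample, a gene's value is the arithmetic mean of its mapped probes'
    present values; a gene with no present probe in a sample has NaN there.
    Probes without a gene symbol are dropped.
    """
    if ann.platform_id != matrix.platform_id:
        raise ValidationError(
            f"annotation platform '{ann.platform_id}' does not match dataset "
            f"platform '{matrix.platform_id}'"
        )
    genes = matrix.data.index.map(ann.probe_to_gene)
    keep = genes.notna()
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dataset '%s': %d unmapped probes dropped",
                    matrix.dataset_id, n_dropped)
    mapped = matrix.data.loc[keep]
    table = mapped.groupby(genes[keep]).mean()  # skipna mean per gene
    table.index.name = "gene"
    return table


@dataclass
class PoolProfile:
    """Pooled per-gene expression: mean value and contributing data points."""

    pool_id: str
    table: pd.DataFrame  # index gene; columns: value, data_points

    def __len__(self) -> int:
        return len(self.table)

    @property
    def genes(self) -> pd.Index:
        return self.table.index

    def value(self, gene: str) -> float:
        return float(self.table.at[gene, "value"])

    @property
    def total_data_points(self) -> int:
        return int(self.table["data_points"].sum())


def pool_genes(
    tables: dict[str, pd.DataFrame],
    manifest: SampleManifest,
    pool_id: str,
    sample_number: int = 2,
) -> PoolProfile:
    """Pool gene-level sample values across all datasets of one study arm.

    Per gene: value = mean over every present sample-level value of pool
    members across datasets; data_points = count of those values.  Genes with
    fewer than ``sample_number`` data points are removed.
    """
    members = {r.sample_id for r in manifest.samples_in_pool(pool_id)}
    if not members:
        raise ValidationError(f"pool '{pool_id}' has no samples")
    pieces = []
    for table in tables.values():
        cols = [c for c in table.columns if c in members]
        if cols:
            pieces.append(table[cols])
    if not pieces:
        raise ValidationError(f"pool '{pool_id}': no expression data found")
    stacked = pd.concat(pieces, axis=1)
    counts = stacked.notna().sum(axis=1)
    values = stacked.mean(axis=1)
    keep = counts >= sample_number
    dropped = int((~keep & (counts > 0)).sum())
    if dropped:
        logger.info("pool '%s': %d genes below sample_number=%d dropped",
                    pool_id, dropped, sample_number)
    out = pd.DataFrame({"value": values[keep], "data_points": counts[keep].astype(int)})
    out = out.dropna(subset=["value"]).sort_index()
    return PoolProfile(pool_id, out)


def gene_ratio(a: PoolProfile, b: PoolProfile) -> pd.DataFrame:
    """Per-gene expression ratio a/b on the genes present in both profiles.

    Genes whose value is zero in either pool are excluded (with a logged
    count): a ratio is only defined for positive expression on both sides.
    Returns a DataFrame indexed by gene with columns ``ratio`` and ``tail``
    (initially "none").
    """
    shared = a.genes.intersection(b.genes)
    va = a.table.loc[shared, "value"]
    vb = b.table.loc[shared, "value"]
    ok = (va > 0) & (vb > 0)
    n_zero = int((~ok).sum())
    if n_zero:
        logger.warning("gene_ratio: %d genes with zero value excluded", n_zero)
    ratio = (va[ok] / vb[ok]).astype(float)
    out = pd.DataFrame({"ratio": ratio, "tail": "none"})
    out.index.name = "gene"
    return out.sort_index()


def call_tail_genes(table: pd.DataFrame, tail_fraction: float = 0.025) -> pd.DataFrame:
    """Flag the extreme ``tail_fraction`` of ratios as over/under tail genes.

    Exactly ``ceil(tail_fraction * N)`` genes are flagged per tail (largest
    ratios -> "over", smallest -> "under"); ties are broken by gene symbol so
    the call is deterministic.  When the table is too small for the nominal
    fraction a warning is emitted and one gene per tail is still flagged.
    """
    if table.empty:
        raise ValidationError("cannot call tails on an empty ratio table")
    if not 0 < tail_fraction < 0.5:
        raise ValidationError("tail_fraction must be in (0, 0.5)")
    n = len(table)
    k = math.ceil(tail_fraction * n)
    if n < 1.0 / tail_fraction:
        logger.warning("ratio table of %d genes is small for tail_fraction=%g; "
                       "flagging one gene per tail", n, tail_fraction)
        k = max(k, 1)
    out = table.copy()
    out["tail"] = "none"
    ratios = out["ratio"]
    if ratios.nunique() < n:
        logger.warning("tail calling: tied ratios broken by gene symbol order")
    # deterministic tie-breaks: over tail prefers lexicographically first
    # symbols, under tail the last, so fully tied tables still yield two
    # disjoint tails
    df = ratios.rename("r").rename_axis("gene").reset_index()
    over_idx = df.sort_values(["r", "gene"], ascending=[False, True],
                              kind="mergesort")["gene"].iloc[:k].tolist()
    under_idx = df.sort_values(["r", "gene"], ascending=[True, False],
                               kind="mergesort")["gene"].iloc[:k].tolist()
    out.loc[over_idx, "tail"] = "over"
    # a gene already flagged "over" keeps that flag in degenerate tiny tables
    under_idx = [g for g in under_idx if out.at[g, "tail"] == "none"]
    out.loc[under_idx, "tail"] = "under"
    return out
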