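"""Sliding-window transcriptome maps and segment significance.

A transcriptome map partitions every chromosome into overlapping windows
("segments"): window k starts at ``1 + k * shift_bp`` and spans ``window_bp``
bases.  The default map uses 500,000 bp windows sliding by 250,000 bp; the
single-gene map uses 12,500 bp windows sliding by 6,250 bp so that a
significant segment usually corresponds to one gene.

Each segment's expression value per pool is the mean of the pooled values of
the genes whose start coordinate lies inside the window, and the segment
ratio is the ratio of those two means (mean-then-ratio, not mean of per-gene
ratios).  Significance asks whether a segment is unexpectedly rich in tail
genes: with N genes genome-wide of which K are flagged in one direction, the
probability that a segment of n genes contains at least k of them is the
hypergeometric upper tail

    P(X >= k),  X ~ Hypergeom(N, K, n).

The smaller of the over/under tail probabilities is corrected across all
segments of one map by the Benjamini–Hochberg procedure; a segment is
reported significant when q < ``q_threshold``, the winning direction carries
at least ``min_tail_genes`` tail genes, and the segment ratio points the
same way.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .gene_table import PoolProfile
from .io_manifest import GeneLocusMap

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_BP = 500_000
DEFAULT_SHIFT_BP = 250_000
SINGLE_GENE_WINDOW_BP = 12_500
SINGLE_GENE_SHIFT_BP = 6_250


@dataclass(frozen=True)
class MapConfig:
    """Parameters of one map analysis; defaults are the standard map."""

    window_bp: int = DEFAULT_WINDOW_BP
    shift_bp: int = DEFAULT_SHIFT_BP
    tail_fraction: float = 0.025
    min_tail_genes: int = 3
    q_threshold: float = 0.05
    sample_number: int = 2
    mode: str = "default"

    def __post_init__(self):
        if self.mode not in ("default", "single_gene"):
            raise ValidationError(f"unknown map mode {self.mode!r}")

    @classmethod
    def single_gene(cls, **kwargs) -> "MapConfig":
        """The single-gene-resolution configuration (12.5 kb / 6.25 kb).

        One 12.5 kb window rarely holds more than one gene, so the
        minimum-tail-genes rule of the default map is relaxed to 1 here.
        """
        kwargs.setdefault("min_tail_genes", 1)
        return cls(window_bp=SINGLE_GENE_WINDOW_BP, shift_bp=SINGLE_GENE_SHIFT_BP,
                   mode="single_gene", **kwargs)


@dataclass
class WindowGrid:
    window_bp: int
    shift_bp: int
    #: chromosome -> array of 1-based window starts (ends = start+window_bp-1)
    starts: dict[str, np.ndarray]

    def ends(self, chromosome: str) -> np.ndarray:
        return self.starts[chromosome] + self.window_bp - 1

    def n_windows(self) -> int:
        return int(sum(len(s) for s in self.starts.values()))


def build_windows(
    chromosome_lengths: dict[str, int],
    window_bp: int = DEFAULT_WINDOW_BP,
    shift_bp: int = DEFAULT_SHIFT_BP,
) -> WindowGrid:
    """Build the sliding-window grid: starts 1, 1+shift, 1+2*shift, ...

    Windows are generated while their start lies within the chromosome; the
    final window may extend past the chromosome end (gene assignment is what
    enforces bounds).
    """
    if window_bp < shift_bp or shift_bp < 1:
        raise ValidationError("require window_bp >= shift_bp >= 1")
    starts = {}
    for chrom, length in chromosome_lengths.items():
        if length < 1:
            raise ValidationError(f"chromosome '{chrom}' has nonpositive length")
        n = (length - 1) // shift_bp + 1
        starts[chrom] = 1 + shift_bp * np.arange(n, dtype=np.int64)
    return WindowGrid(window_bp, shift_bp, starts)


def assign_genes(
    grid: WindowGrid, loci: GeneLocusMap
) -> dict[str, list[list[str]]]:
    """Assign each gene to every window containing its start coordinate.

    Membership is by gene start (both window boundaries inclusive), so away
    from the chromosome start each gene appears in ``window_bp / shift_bp``
    windows.  Genes are ordered by start within each window.
    """
    missing = sorted({l.chromosome for l in loci.loci.values()}
                     - set(grid.starts))
    if missing:
        raise ValidationError(
            f"loci on chromosomes absent from the grid: {', '.join(missing)}"
        )
    assignment: dict[str, list[list[str]]] = {}
    for chrom, win_starts in grid.starts.items():
        genes = loci.genes_on(chrom)  # ordered by start
        gene_starts = np.array([loci[g].start for g in genes], dtype=np.int64)
        win_ends = win_starts + grid.window_bp - 1
        lo = np.searchsorted(gene_starts, win_starts, side="left")
        hi = np.searchsorted(gene_starts, win_ends, side="right")
        assignment[chrom] = [genes[a:b] for a, b in zip(lo, hi)]
    return assignment


def segment_stats(
    grid: WindowGrid,
    assignment: dict[str, list[list[str]]],
    a: PoolProfile,
    b: PoolProfile,
) -> pd.DataFrame:
    """Per-window pooled expression and ratio (mean-then-ratio).

    Only genes with a positive value in both pools contribute; windows with
    no such gene produce no record.  Returns a DataFrame with one row per
    populated window: chromosome, start, end, genes (tuple), n_genes,
    value_a, value_b, ratio.
    """
    shared = a.genes.intersection(b.genes)
    va = a.table.loc[shared, "value"]
    vb = b.table.loc[shared, "value"]
    ok = (va > 0) & (vb > 0)
    val_a = va[ok].to_dict()
    val_b = vb[ok].to_dict()
    rows = []
    for chrom, win_starts in grid.starts.items():
        lists = assignment.get(chrom, [])
        for start, genes in zip(win_starts, lists):
            present = [g for g in genes if g in val_a]
            if not present:
                continue
            mean_a = float(np.mean([val_a[g] for g in present]))
            mean_b = float(np.mean([val_b[g] for g in present]))
            rows.append(
                {
                    "chromosome": chrom,
                    "start": int(start),
                    "end": int(start) + grid.window_bp - 1,
                    "genes": tuple(present),
                    "n_genes": len(present),
                    "value_a": mean_a,
                    "value_b": mean_b,
                    "ratio": mean_a / mean_b,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["chromosome", "start", "end", "genes", "n_genes",
                 "value_a", "value_b", "ratio"],
    )


def segment_significance(
    records: pd.DataFrame, ratios: pd.DataFrame, cfg: MapConfig
) -> pd.DataFrame:
    """Hypergeometric tail-gene enrichment per segment, BH-corrected.

    ``ratios`` must already carry tail calls.  Adds columns n_over, n_under,
    p_over, p_under, p, q, direction, significant.  The FDR family is the
    full record list of one map; over/under are tested jointly through the
    minimum of the two one-sided probabilities.
    """
    out = records.copy()
    if out.empty:
        for col in ("n_over", "n_under", "p_over", "p_under", "p", "q"):
            out[col] = pd.Series(dtype=float)
        out["direction"] = pd.Series(dtype=object)
        out["significant"] = pd.Series(dtype=bool)
        return out
    tails = ratios["tail"]
    over_set = set(tails.index[tails == "over"])
    under_set = set(tails.index[tails == "under"])
    n_universe = len(ratios)
    k_over, k_under = len(over_set), len(under_set)
    n_over = out["genes"].map(lambda gs: sum(g in over_set for g in gs)).astype(int)
    n_under = out["genes"].map(lambda gs: sum(g in under_set for g in gs)).astype(int)
    n_seg = out["n_genes"].to_numpy()
    p_over = hypergeom.sf(n_over.to_numpy() - 1, n_universe, k_over, n_seg)
    p_under = hypergeom.sf(n_under.to_numpy() - 1, n_universe, k_under, n_seg)
    p = np.minimum(p_over, p_under)
    q = multipletests(p, method="fdr_bh")[1]
    direction = np.where(
        p_over < p_under, "over", np.where(p_under < p_over, "under", "none")
    )
    win_tail = np.where(direction == "over", n_over,
                        np.where(direction == "under", n_under, 0)).astype(int)
    ratio = out["ratio"].to_numpy()
    dir_ok = np.where(direction == "over", ratio > 1,
                      np.where(direction == "under", ratio < 1, False))
    significant = (q < cfg.q_threshold) & (win_tail >= cfg.min_tail_genes) & dir_ok
    out["n_over"] = n_over
    out["n_under"] = n_under
    out["p_over"] = p_over
    out["p_under"] = p_under
    out["p"] = p
    out["q"] = q
    out["direction"] = direction
    out["significant"] = significant
    return out


def merge_significant_spans(records: pd.DataFrame) -> pd.DataFrame:
    """Merge runs of overlapping/adjacent significant windows of one direction.

    Windows are scanned in genomic order per chromosome; consecutive
    significant windows with the same direction whose intervals touch are
    fused into one span (start = min start, end = max end).  The span keeps
    the union of the windows' genes (ordered as encountered), the most
    extreme window ratio for its direction, and the smallest q.
    """
    sig = records[records["significant"]].sort_values(["chromosome", "start"])
    spans = []
    current = None
    for _, row in sig.iterrows():
        if (
            current is not None
            and row["chromosome"] == current["chromosome"]
            and row["direction"] == current["direction"]
            and row["start"] <= current["end"] + 1
        ):
            current["end"] = max(current["end"], row["end"])
            for g in row["genes"]:
                if g not in current["genes"]:
                    current["genes"].append(g)
            better = (row["ratio"] > current["ratio"]
                      if row["direction"] == "over"
                      else row["ratio"] < current["ratio"])
            if better:
                current["ratio"] = row["ratio"]
            current["q"] = min(current["q"], row["q"])
            current["n_windows"] += 1
        else:
            if current is not None:
                spans.append(current)
            current = {
                "chromosome": row["chromosome"],
                "start": int(row["start"]),
                "end": int(row["end"]),
                "genes": list(row["genes"]),
                "ratio": float(row["ratio"]),
                "q": float(row["q"]),
                "direction": row["direction"],
                "n_windows": 1,
            }
    if current is not None:
        spans.append(current)
    df = pd.DataFrame(
        spans,
        columns=["chromosome", "start", "end", "genes", "ratio", "q",
                 "direction", "n_windows"],
    )
    if not df.empty:
        df["genes"] = df["genes"].map(tuple)
        df = df.sort_values("ratio", ascending=False, kind="mergesort")
        df = df.reset_index(drop=True)
    return df


def single_gene_map(
    loci: GeneLocusMap,
    a: PoolProfile,
    b: PoolProfile,
    ratios: pd.DataFrame,
    cfg: MapConfig | None = None,
) -> pd.DataFrame:
    """Run the 12.5 kb / 6.25 kb map and merge significant windows into spans.

    Output rows are spans attributed to the gene(s) they contain, sorted by
    decreasing ratio.  The reported ratio of a span is the most extreme
    window ratio in its direction.
    """
    cfg = cfg or MapConfig.single_gene()
    if cfg.mode != "single_gene":
        raise ValidationError("single_gene_map requires a single_gene MapConfig")
    grid = build_windows(loci.chromosome_lengths, cfg.window_bp, cfg.shift_bp)
    assignment = assign_genes(grid, loci)
    records = segment_stats(grid, assignment, a, b)
    records = segment_significance(records, ratios, cfg)
    return merge_significant_spans(records)


def top_k_intersection(x: pd.DataFrame, y: pd.DataFrame, k: int = 20) -> set[str]:
    """Shared symbols among the top/bottom-k rows (by ratio) of two gene tables.

    For each table, the gene sets of the k highest-ratio rows and the k
    lowest-ratio rows are united; the function returns the intersection of
    the two unions.  Tables shorter than k are used whole, with a warning.
    """

    def extreme_genes(table: pd.DataFrame) -> set[str]:
        if table.empty:
            return set()
        if len(table) < k:
            logger.warning("gene table has %d rows (< k=%d); using all",
                           len(table), k)
        srt = table.sort_values("ratio", ascending=False, kind="mergesort")
        rows = pd.concat([srt.iloc[:k], srt.iloc[-k:]])
        genes: set[str] = set()
        for gs in rows["genes"]:
            genes.update(gs if isinstance(gs, (tuple, list)) else (gs,))
        return genes

    return extreme_genes(x) & extreme_genes(y)
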