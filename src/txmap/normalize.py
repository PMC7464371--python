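"""Two-level normalization for heterogeneous microarray datasets.

Datasets from different platforms arrive on different scales (linear
intensities or log2) and with different within-study distributions.  The
pipeline brings them onto one common linear scale in three steps:

1. :func:`linearize` — undo log2 encoding so all values are linear
   intensities;
2. :func:`quantile_normalize_within` — quantile-normalize the samples of one
   dataset against the sorted-mean reference distribution of that dataset,
   removing per-sample intensity distribution differences while preserving
   within-sample rank order;
3. :func:`scale_across_datasets` — multiply every dataset's gene-level table
   by one positive constant so that its overall median equals
   ``target_median``, making pooled means comparable across platforms.

Absent values (NaN) are carried through untouched: they take no part in rank
or reference computation and remain absent afterwards.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_manifest import ProbeMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NormalizationConfig:
    target_median: float = 1.0
    reference: str = "sorted-mean"

    def __post_init__(self):
        if not self.target_median > 0:
            raise ValidationError("target_median must be positive")
        if self.reference != "sorted-mean":
            raise ValidationError(f"unknown reference rule {self.reference!r}")


def linearize(matrix: ProbeMatrix) -> ProbeMatrix:
    """Return a copy of ``matrix`` with every sample on the linear scale.

    log2 samples are transformed value -> 2**value; linear samples pass
    through unchanged but are checked for negative intensities.
    """
    data = matrix.data.copy()
    for sample in data.columns:
        scale = matrix.scales.get(sample)
        if scale == "log2":
            data[sample] = np.power(2.0, data[sample])
        elif scale == "linear":
            col = data[sample]
            if (col.dropna() < 0).any():
                raise ValidationError(
                    f"sample '{sample}': negative values on declared linear scale"
                )
        else:
            raise ValidationError(f"sample '{sample}': scale not declared")
    return ProbeMatrix(matrix.dataset_id, matrix.platform_id, data,
                       {s: "linear" for s in data.columns})


def _reference_distribution(cols: list[np.ndarray]) -> np.ndarray:
    """Sorted-mean reference: mean of sorted sample vectors.

    Samples with unequal numbers of present values are interpolated onto a
    common quantile grid whose length is the largest present count.
    """
    grid_len = max(len(c) for c in cols)
    grid = np.linspace(0.0, 1.0, grid_len)
    acc = np.zeros(grid_len)
    for c in cols:
        srt = np.sort(c)
        if len(c) == grid_len:
            acc += srt
        else:
            acc += np.interp(grid, np.linspace(0.0, 1.0, len(c)), srt)
    return acc / len(cols)


def quantile_normalize_within(
    matrix: ProbeMatrix, cfg: NormalizationConfig | None = None
) -> ProbeMatrix:
    """Quantile-normalize the samples of one dataset (linear scale expected).

    Every sample's sorted present-value vector is mapped onto the dataset
    reference (mean of sorted vectors); ties within a sample receive the mean
    of the reference values at their tied ranks.  Samples with fewer than two
    present values are passed through with a warning.
    """
    cfg = cfg or NormalizationConfig()
    data = matrix.data.copy()
    present_cols = []
    for sample in data.columns:
        vals = data[sample].dropna().to_numpy()
        if len(vals) >= 2:
            present_cols.append(vals)
    if not present_cols:
        logger.warning("dataset '%s': no sample with >=2 present values; "
                       "quantile normalization skipped", matrix.dataset_id)
        return ProbeMatrix(matrix.dataset_id, matrix.platform_id, data,
                           dict(matrix.scales))
    reference = _reference_distribution(present_cols)
    ref_grid = np.linspace(0.0, 1.0, len(reference))
    for sample in data.columns:
        col = data[sample]
        mask = col.notna()
        vals = col[mask].to_numpy()
        m = len(vals)
        if m < 2:
            logger.warning("dataset '%s', sample '%s': <2 present values, "
                           "passed through unscaled", matrix.dataset_id, sample)
            continue
        ref_s = np.interp(np.linspace(0.0, 1.0, m), ref_grid, reference)
        order = np.argsort(vals, kind="stable")
        out = np.empty(m)
        out[order] = ref_s
        # ties: mean of the reference values at the tied ranks
        tied = pd.Series(out).groupby(pd.Series(vals)).transform("mean").to_numpy()
        new_col = col.copy()
        new_col[mask] = tied
        data[sample] = new_col
    return ProbeMatrix(matrix.dataset_id, matrix.platform_id, data,
                       dict(matrix.scales))


def scale_across_datasets(
    tables: dict[str, pd.DataFrame], cfg: NormalizationConfig | None = None
) -> dict[str, pd.DataFrame]:
    """Median-scale each dataset's gene-level table to a common target.

    Each table (genes x samples, NaN allowed) is multiplied by one positive
    factor so that the median of its present values equals
    ``cfg.target_median``.  Relative values within a dataset are unchanged.
    """
    cfg = cfg or NormalizationConfig()
    out: dict[str, pd.DataFrame] = {}
    for dataset_id, table in tables.items():
        values = table.to_numpy(dtype=float)
        present = values[~np.isnan(values)]
        med = float(np.median(present)) if present.size else 0.0
        if med <= 0:
            raise ValidationError(
                f"dataset '{dataset_id}': non-positive overall median ({med}); "
                "cannot scale"
            )
        out[dataset_id] = table * (cfg.target_median / med)
    return out
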