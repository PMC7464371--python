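"""Seeded recovery and null-control experiments on synthetic studies.

These functions run the full pipeline many times on independently generated
studies and summarize how often a known spiked segment is recovered
(statistical power under the study's pool sizes) and how many windows are
called significant when nothing is spiked (false-positive control).  Study
conditions follow the emulated design: pools of 12 and 33 samples across 11
datasets, a 3-gene block at fold 2.4, multiplicative noise sd 0.2.
"""

from __future__ import annotations

import numpy as np

from .pipeline import run_pipeline
from .synthetic_data import (
    SpikeBlock,
    block_genes,
    generate_genome,
    generate_study,
    reference_study_design,
)

DEFAULT_BLOCK = SpikeBlock("chr1", 40, 3, 2.4, "A")


def _replicate_seeds(seed: int, n_replicates: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, n_replicates)]


def spike_recovery_rate(
    n_replicates: int = 50,
    seed: int = 0,
    block: SpikeBlock = DEFAULT_BLOCK,
    noise_sd: float = 0.2,
) -> float:
    """Fraction of replicates in which the spiked block is recovered.

    Recovery means some significant merged region of the default map has the
    block's direction and contains every spiked gene.
    """
    want = "over" if block.fold > 1 else "under"
    hits = 0
    for rep_seed in _replicate_seeds(seed, n_replicates):
        design = reference_study_design(seed=rep_seed, noise_sd=noise_sd)
        genome = generate_genome(design)
        study = generate_study(design, genome, truth=[block])
        res = run_pipeline(study.manifest, study.matrices, study.annotations,
                           genome, run_single_gene=False)
        spiked = set(block_genes(block, genome))
        hits += any(
            row["direction"] == want and spiked <= set(row["genes"])
            for _, row in res.regions.iterrows()
        )
    return hits / n_replicates


def null_significant_fraction(
    n_replicates: int = 50,
    seed: int = 0,
    noise_sd: float = 0.2,
) -> float:
    """Mean fraction of windows called significant with nothing spiked."""
    fractions = []
    for rep_seed in _replicate_seeds(seed, n_replicates):
        design = reference_study_design(seed=rep_seed, noise_sd=noise_sd)
        genome = generate_genome(design)
        study = generate_study(design, genome)
        res = run_pipeline(study.manifest, study.matrices, study.annotations,
                           genome, run_single_gene=False)
        n = res.summary["n_windows"]
        fractions.append(res.summary["n_significant_windows"] / n if n else 0.0)
    return float(np.mean(fractions))
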