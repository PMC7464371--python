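# Methods

## Problem setting

Public microarray series on the same biological contrast are individually
small (often 1–7 samples per arm) and measured on different platforms with
different probe sets, dynamic ranges and value encodings. `txmap` combines
such series into one genome-ordered analysis: pooled per-gene expression
per study arm, and sliding-window maps that call chromosomal segments
over- or under-expressed between arms. The package is cell-type agnostic;
the bundled example design describes a 45-sample comparison of male (pool
A, 12 samples) and female (pool B, 33 samples) adipose-derived stem cell
datasets, with the female pool further split by culture medium (9 FGF-
supplemented, C; 24 standard, D).

## Inclusion rules

Donor-level criteria are strict inequalities: age > 18 years, BMI < 30
kg/m², culture passage 1–4. A record that does not state a field passes
that criterion — public metadata frequently reports "Adult", an age range,
or nothing, and such samples belong to the intended study population.
Interval ages pass when the interval's lower bound reaches the threshold
(a declared "(18–39)" donor is an adult by declaration); point ages remain
strictly compared. Pool membership is validated against sex (A ⇒ male,
B ⇒ female).

## Normalization

Three stages, in order:

1. **Linearization** — samples declared log2 are transformed v → 2^v.
   Samples without a declared scale are rejected rather than guessed,
   mirroring the inclusion rule that excludes series with unstated
   encodings.
2. **Within-dataset quantile normalization** (probe level, before
   collapsing). The reference is the sorted-mean distribution of the
   dataset's samples. Absent values take no part: a sample's present
   values are ranked and mapped onto the reference interpolated at its own
   quantile grid, so unequal presence patterns are handled by linear
   interpolation on [0, 1]. Ties receive the mean of the reference values
   at their tied ranks. Samples with fewer than two present values pass
   through unscaled with a warning. Normalizing at probe level rather
   than gene level was an open choice; probe level was selected because
   the distributional artifacts being removed are properties of the raw
   hybridization, not of the collapsed summary.
3. **Across-dataset median scaling** (gene level, after collapsing). Each
   dataset's gene table is multiplied by one constant so its overall
   median of present values equals `target_median` (default 1.0). A
   single multiplicative factor preserves all within-dataset ratios; the
   median is robust to a handful of differentially expressed genes.

## Pooling and ratios

A gene's pooled value is the unweighted mean of every sample-level value
across all datasets in the pool — every data point counts once, which
matches the additive data-point accounting the map reports. Genes with
fewer than `sample_number` (default 2) data points in a pool are dropped.
Ratios are defined only for genes with positive values in both pools;
zero-valued genes are excluded (with a logged count) rather than
pseudo-counted, because a fabricated ratio has no defensible magnitude.

Tail genes are called on the genome-wide distribution of gene ratios:
exactly `ceil(0.025·N)` genes per tail, ties broken by symbol
(lexicographically first for the over tail, last for the under tail, so a
fully tied table still yields disjoint tails). Calling tails on ratios
rather than raw expression is the reading consistent with a differential
map; it is the one place where the underlying tooling convention is not
published, and the choice is isolated in `call_tail_genes` should it need
revisiting.

## Windows and significance

Window k on a chromosome spans `[1 + k·shift, k·shift + window]`,
1-based inclusive, for starts within the chromosome; the last window may
overhang. Genes belong to every window containing their start coordinate
— membership by start, not overlap, keeps each gene in exactly
window/shift windows and matches the convention that a segment is
annotated by its first mapped gene. Segment values are mean-then-ratio:
the pool means over the segment's genes are computed first and then
divided, which is not the mean of per-gene ratios.

Significance is hypergeometric enrichment of tail genes: a window of n
ratio-bearing genes containing k tail genes of one direction gets
P(X ≥ k) for X ~ Hypergeom(N, K, n) over the N-gene ratio universe. The
test statistic behind the original mapping tool is not published; the
hypergeometric reading is the standard regional-enrichment formulation
consistent with the "at least three over/under-expressed genes" rule, and
it is isolated in `segment_significance` so a permutation null could be
substituted. The FDR family is all populated windows of one map
(Benjamini–Hochberg, q < 0.05). A significant window must additionally
carry ≥ `min_tail_genes` tail genes in the winning direction (3 by
default) and a ratio on the same side of 1. Overlapping significant
windows of one direction merge into a reported region spanning their
union; the region inherits the most extreme window ratio of its
direction and the smallest q. In single-gene mode (12.5 kb / 6.25 kb)
the tail-gene minimum drops to 1, since a window that small rarely holds
more than one gene and the 3-gene rule belongs to the 500 kb analysis.

## Synthetic studies

The generator emulates the structure of the motivating meta-analysis:
11 datasets on 5 platforms, pools A/C/D of 12/9/24 samples, mixed
linear/log2 encodings, 1–3 probes per gene, per-platform dropout of
0–10%. Baseline gene expression is lognormal (ln-mean 3, ln-sd 1);
measurement noise is multiplicative lognormal per probe and sample
(ln-sd 0.2 by default) — intensities are positive and the pipeline is
ratio-based, so additive Gaussian noise would be the wrong model. Genes
sit at regular 100 kb spacing (150 per chromosome, 2 chromosomes) so
window occupancy is analytically known; these sizes keep a full pipeline
replicate under 0.2 s, and 50-replicate experiments are the package's
standard power/null measurements. Spiked blocks multiply a contiguous
run of genes by a known fold in one pool before probe emission, and the
truth is written next to the generated files.

What the generator does **not** model: platform-specific probe-sequence
effects, spatial artifacts, correlated probe noise, donor covariates
driving expression, and genes with multiple or overlapping loci. Passing
recovery tests therefore demonstrate the pipeline's statistical
behaviour under its own assumptions, not performance on any real
dataset.

### Exactness caveat

With zero noise and dropout, gene ratios recover spiked folds to machine
precision only when (a) every dataset holds samples of a single pool —
otherwise rank-based quantile normalization redistributes the spiked
values across samples — and (b) the spiked block does not move a
dataset's median, since median scaling would then apply unequal factors.
The noise-free design used for exactness checks is pool-pure, and
`pick_high_block` places upward spikes among above-median genes. Mixed-
pool designs (the realistic case) attenuate the recovered fold (≈1.7
observed for a 2.4-fold spike) without harming detection: tails and
enrichment depend on ranks, not magnitudes.

## Numerical and determinism choices

- Hypergeometric tails via `scipy.stats.hypergeom.sf`; BH via
  `statsmodels`; both are cross-checked against naive enumeration in the
  test suite.
- Chromosomes keep their input order; windows are ordered by start;
  output tables sort by decreasing ratio with stable sorts; all random
  draws flow from one `numpy` Generator seeded by the design, so repeated
  runs are byte-identical.
- Degenerate inputs: empty window → no record; empty record list → empty
  significance table; ratio table smaller than 1/tail_fraction → one gene
  per tail with a warning; dataset with non-positive median → error.

## Known limitations

- The significance model treats genes as exchangeable draws; local
  co-expression (for example tandem paralog clusters) inflates regional
  enrichment beyond what the hypergeometric null expects.
- Pool means weight every sample equally, so one large dataset can
  dominate a pool.
- Genes are mapped to a single locus; families with unresolvable multi-
  locus symbols are rejected at load.
- Printed gene-level results of any specific published analysis are not
  reproduction targets: they depend on the original raw series and on
  unpublished internals of the original tool.
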