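"""Window grids, segment statistics, significance and span merging."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from txmap.errors import ValidationError
from txmap.gene_table import PoolProfile, call_tail_genes, gene_ratio
from txmap.io_manifest import GeneLocus, GeneLocusMap
from txmap.mapper import (
    MapConfig,
    assign_genes,
    build_windows,
    merge_significant_spans,
    segment_significance,
    segment_stats,
    single_gene_map,
    top_k_intersection,
)


def _profile(pool_id, mapping):
    t = pd.DataFrame({"value": pd.Series(mapping, dtype=float), "data_points": 2})
    t.index.name = "gene"
    return PoolProfile(pool_id, t.sort_index())


# ---------------------------------------------------------------------------
# oracles


def hypergeom_upper_tail_oracle(n_drawn_tail, N, K, n):
    """P(X >= k) by exhaustive enumeration of the hypergeometric mass."""
    total = 0.0
    for k in range(n_drawn_tail, min(K, n) + 1):
        total += math.comb(K, k) * math.comb(N - K, n - k) / math.comb(N, n)
    return total


def bh_oracle(pvals):
    """Textbook Benjamini–Hochberg adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = m - rank_from_end
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj


def segment_oracle(loci, window_bp, shift_bp, a, b):
    """Re-scan every locus for every window; average shared positive genes."""
    shared = {
        g for g in a.genes.intersection(b.genes)
        if a.value(g) > 0 and b.value(g) > 0
    }
    rows = []
    for chrom, length in loci.chromosome_lengths.items():
        start = 1
        while start <= length:
            end = start + window_bp - 1
            genes = [g for g in loci.genes_on(chrom)
                     if g in shared and start <= loci[g].start <= end]
            if genes:
                va = np.mean([a.value(g) for g in genes])
                vb = np.mean([b.value(g) for g in genes])
                rows.append((chrom, start, end, tuple(genes),
                             float(va), float(vb), float(va / vb)))
            start += shift_bp
    return rows


def random_genome(rng, n_chrom=2, max_genes=12):
    loci, lengths = {}, {}
    for c in range(n_chrom):
        chrom = f"chr{c + 1}"
        length = int(rng.integers(400_000, 2_000_000))
        lengths[chrom] = length
        for i in range(int(rng.integers(1, max_genes + 1))):
            start = int(rng.integers(1, length + 1))
            loci[f"g{c}_{i}"] = GeneLocus(chrom, start,
                                          min(start + 10_000, length))
    return GeneLocusMap(loci, lengths)


# ---------------------------------------------------------------------------


class TestBuildWindows:
    def test_default_grid_contains_printed_boundaries(self):
        """The default 500 kb / 250 kb grid reproduces published segment
        coordinates such as 48,250,001-48,750,000."""
        grid = build_windows({"chr4": 190_000_000})
        starts = grid.starts["chr4"]
        i = np.searchsorted(starts, 48_250_001)
        assert starts[i] == 48_250_001
        assert grid.ends("chr4")[i] == 48_750_000

    def test_short_chromosome_grid_arithmetic(self):
        grid = build_windows({"c": 600_000})
        assert grid.starts["c"].tolist() == [1, 250_001, 500_001]

    def test_single_gene_grid_start_sequence(self):
        grid = build_windows({"c": 20_000}, 12_500, 6_250)
        assert grid.starts["c"].tolist()[:3] == [1, 6_251, 12_501]

    def test_last_window_may_overhang(self):
        grid = build_windows({"c": 300_000})
        assert grid.ends("c")[-1] == 750_000

    def test_nonpositive_sizes_rejected(self):
        with pytest.raises(ValidationError):
            build_windows({"c": 1000}, 100, 0)
        with pytest.raises(ValidationError):
            build_windows({"c": 1000}, 100, 200)


class TestAssignGenes:
    LOCI = GeneLocusMap(
        {
            "at_start": GeneLocus("c", 250_001, 260_000),
            "at_end": GeneLocus("c", 500_000, 510_000),
            "mid": GeneLocus("c", 300_000, 310_000),
        },
        {"c": 1_000_000},
    )

    def test_window_boundaries_inclusive(self):
        grid = build_windows(self.LOCI.chromosome_lengths)
        assignment = assign_genes(grid, self.LOCI)
        # window 2 spans 250,001..750,000: includes both boundary genes
        genes = assignment["c"][1]
        assert "at_start" in genes and "at_end" in genes

    def test_gene_appears_in_window_per_shift_copies(self):
        loci = GeneLocusMap({"g": GeneLocus("c", 300_000, 310_000)},
                            {"c": 1_000_000})
        grid = build_windows(loci.chromosome_lengths)
        assignment = assign_genes(grid, loci)
        hosting = [grid.starts["c"][i] for i, gs in enumerate(assignment["c"])
                   if "g" in gs]
        assert hosting == [1, 250_001]

    def test_genes_ordered_by_start(self):
        grid = build_windows(self.LOCI.chromosome_lengths)
        windows = assign_genes(grid, self.LOCI)["c"]
        genes = windows[1]
        starts = [self.LOCI[g].start for g in genes]
        assert starts == sorted(starts)

    def test_unknown_chromosome_rejected(self):
        grid = build_windows({"other": 1_000_000})
        with pytest.raises(ValidationError, match="c"):
            assign_genes(grid, self.LOCI)


class TestSegmentStats:
    def test_mean_then_ratio_not_mean_of_ratios(self):
        """a=(1,8), b=(1,2) gives segment ratio 3.0, not mean-of-ratios 2.5."""
        loci = GeneLocusMap(
            {"g1": GeneLocus("c", 10, 20), "g2": GeneLocus("c", 30, 40)},
            {"c": 200_000},
        )
        grid = build_windows(loci.chromosome_lengths)
        records = segment_stats(grid, assign_genes(grid, loci),
                                _profile("A", {"g1": 1.0, "g2": 8.0}),
                                _profile("B", {"g1": 1.0, "g2": 2.0}))
        assert records.iloc[0]["ratio"] == 3.0
        assert records.iloc[0]["value_a"] == 4.5

    def test_window_without_shared_genes_omitted(self):
        loci = GeneLocusMap({"g1": GeneLocus("c", 10, 20)}, {"c": 1_000_000})
        grid = build_windows(loci.chromosome_lengths)
        records = segment_stats(grid, assign_genes(grid, loci),
                                _profile("A", {"g1": 2.0}),
                                _profile("B", {"g1": 1.0}))
        # only the windows containing the lone gene produce records
        assert set(records["start"]) == {1}

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_locus_scan(self, seed):
        rng = np.random.default_rng(seed)
        loci = random_genome(rng)
        genes = list(loci.loci)
        a = _profile("A", {g: float(v) for g, v in
                           zip(genes, rng.lognormal(0, 1, len(genes)))})
        b = _profile("B", {g: float(v) for g, v in
                           zip(genes, rng.lognormal(0, 1, len(genes)))})
        window, shift = 300_000, 150_000
        grid = build_windows(loci.chromosome_lengths, window, shift)
        got = segment_stats(grid, assign_genes(grid, loci), a, b)
        expected = segment_oracle(loci, window, shift, a, b)
        assert len(got) == len(expected)
        for row, exp in zip(got.itertuples(index=False), expected):
            assert (row.chromosome, row.start, row.end) == exp[:3]
            assert row.genes == exp[3]
            assert row.value_a == pytest.approx(exp[4], rel=1e-12)
            assert row.ratio == pytest.approx(exp[6], rel=1e-12)


class TestHypergeometricAndBH:
    def test_p_matches_exhaustive_enumeration_example(self):
        """N=1000, K=25, n=5, k=3: upper tail equals the brute-force sum."""
        expected = hypergeom_upper_tail_oracle(3, 1000, 25, 5)
        assert hypergeom.sf(2, 1000, 25, 5) == pytest.approx(expected, abs=1e-15)

    def test_p_matches_enumeration_on_small_grids(self):
        for N in (5, 17, 50):
            for K in (0, 1, N // 3, N):
                for n in (1, N // 2, N):
                    for k in range(0, min(K, n) + 1):
                        expected = hypergeom_upper_tail_oracle(k, N, K, n)
                        got = float(hypergeom.sf(k - 1, N, K, n))
                        assert got == pytest.approx(expected, abs=1e-12)

    def test_bh_hand_example(self):
        got = multipletests([0.001, 0.02, 0.9], method="fdr_bh")[1]
        assert np.allclose(got, [0.003, 0.03, 0.9], atol=1e-12)

    def test_bh_matches_reference_on_random_vectors(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            p = rng.random(rng.integers(1, 40))
            got = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(got, bh_oracle(p), atol=1e-12)

    def test_bh_monotone_and_dominates_p(self):
        rng = np.random.default_rng(4)
        p = np.sort(rng.random(30))
        q = multipletests(p, method="fdr_bh")[1]
        assert np.all(np.diff(q) >= -1e-15)
        assert np.all(q >= p - 1e-15)


def _simple_map(ratio_values, spiked):
    """Two-chromosome setup with an over-expressed 3-gene block on chr1."""
    genes = [f"g{i:03d}" for i in range(len(ratio_values))]
    loci = {}
    half = len(genes) // 2
    for i, g in enumerate(genes):
        chrom = "chr1" if i < half else "chr2"
        start = 1 + (i % half) * 100_000
        loci[g] = GeneLocus(chrom, start, start + 40_000)
    lmap = GeneLocusMap(loci, {"chr1": half * 100_000, "chr2": half * 100_000})
    a = _profile("A", {g: float(r) for g, r in zip(genes, ratio_values)})
    b = _profile("B", {g: 1.0 for g in genes})
    ratios = call_tail_genes(gene_ratio(a, b))
    grid = build_windows(lmap.chromosome_lengths)
    records = segment_stats(grid, assign_genes(grid, lmap), a, b)
    return records, ratios, lmap, a, b


class TestSegmentSignificance:
    def _setup(self):
        rng = np.random.default_rng(7)
        vals = rng.lognormal(0, 0.05, 200)
        vals[10:13] = 4.0  # spiked block on chr1
        return _simple_map(vals, spiked=range(10, 13))

    def test_spiked_block_significant_with_correct_direction(self):
        records, ratios, *_ = self._setup()
        out = segment_significance(records, ratios, MapConfig())
        sig = out[out["significant"]]
        assert not sig.empty
        assert (sig["direction"] == "over").all()
        assert all("g010" in gs for gs in sig["genes"])
        assert (sig["n_over"] >= 3).all()

    def test_no_tail_genes_means_p_one(self):
        records, ratios, *_ = self._setup()
        out = segment_significance(records, ratios, MapConfig())
        clean = out[(out["n_over"] == 0) & (out["n_under"] == 0)]
        assert not clean.empty
        assert (clean["p"] == 1.0).all()
        assert not clean["significant"].any()

    def test_q_dominates_p(self):
        records, ratios, *_ = self._setup()
        out = segment_significance(records, ratios, MapConfig())
        assert (out["q"] >= out["p"] - 1e-15).all()

    def test_min_tail_genes_gate(self):
        records, ratios, *_ = self._setup()
        strict = segment_significance(records, ratios,
                                      MapConfig(min_tail_genes=4))
        assert not strict["significant"].any()

    def test_pool_swap_inverts_ratios_and_swaps_tail_counts(self):
        records, ratios, lmap, a, b = self._setup()
        out = segment_significance(records, ratios, MapConfig())
        grid = build_windows(lmap.chromosome_lengths)
        rev_ratios = call_tail_genes(gene_ratio(b, a))
        rev_records = segment_stats(grid, assign_genes(grid, lmap), b, a)
        rev = segment_significance(rev_records, rev_ratios, MapConfig())
        assert np.allclose(out["ratio"] * rev["ratio"], 1.0, rtol=1e-12)
        assert (out["n_over"].to_numpy() == rev["n_under"].to_numpy()).all()
        assert np.allclose(out["p_over"], rev["p_under"], atol=1e-12)
        assert (out["significant"].to_numpy() == rev["significant"].to_numpy()).all()

    def test_empty_record_list_passes_through(self):
        records, ratios, *_ = self._setup()
        out = segment_significance(records.iloc[0:0], ratios, MapConfig())
        assert out.empty


class TestMergeSpans:
    def _records(self, rows):
        df = pd.DataFrame(rows, columns=["chromosome", "start", "end", "genes",
                                         "ratio", "q", "direction",
                                         "significant"])
        return df

    def test_adjacent_overlapping_windows_merge(self):
        """Windows 6,251-18,750 and 12,501-25,000 fuse into 6,251-25,000."""
        df = self._records([
            ("c", 6_251, 18_750, ("g1",), 3.0, 0.01, "over", True),
            ("c", 12_501, 25_000, ("g1", "g2"), 4.0, 0.005, "over", True),
        ])
        spans = merge_significant_spans(df)
        assert len(spans) == 1
        row = spans.iloc[0]
        assert (row["start"], row["end"]) == (6_251, 25_000)
        assert row["genes"] == ("g1", "g2")
        assert row["ratio"] == 4.0 and row["q"] == 0.005

    def test_direction_change_breaks_run(self):
        df = self._records([
            ("c", 1, 12_500, ("g1",), 3.0, 0.01, "over", True),
            ("c", 6_251, 18_750, ("g2",), 0.3, 0.01, "under", True),
        ])
        assert len(merge_significant_spans(df)) == 2

    def test_isolated_window_is_its_own_span(self):
        df = self._records([("c", 1, 12_500, ("g1",), 3.0, 0.01, "over", True)])
        spans = merge_significant_spans(df)
        assert len(spans) == 1
        assert spans.iloc[0]["end"] == 12_500

    def test_no_significant_windows_gives_empty_table(self):
        df = self._records([("c", 1, 12_500, ("g1",), 3.0, 0.5, "over", False)])
        assert merge_significant_spans(df).empty

    def test_output_sorted_by_decreasing_ratio(self):
        df = self._records([
            ("c", 1, 12_500, ("g1",), 2.0, 0.01, "over", True),
            ("c", 100_001, 112_500, ("g2",), 5.0, 0.01, "over", True),
        ])
        spans = merge_significant_spans(df)
        assert spans["ratio"].tolist() == [5.0, 2.0]


class TestSingleGeneMap:
    def test_requires_single_gene_config(self, tiny_loci):
        a = _profile("A", {"AAA": 1.0})
        b = _profile("B", {"AAA": 1.0})
        ratios = pd.DataFrame({"ratio": [1.0], "tail": ["none"]}, index=["AAA"])
        with pytest.raises(ValidationError):
            single_gene_map(tiny_loci, a, b, ratios, MapConfig())

    def test_dense_block_recovered_as_merged_span(self):
        """Genes packed at 6 kb spacing: a strong block yields one span
        covering the whole block."""
        n = 120
        loci = {f"g{i:03d}": GeneLocus("c", 1 + i * 6_000, 4_000 + i * 6_000)
                for i in range(n)}
        lmap = GeneLocusMap(loci, {"c": n * 6_000})
        vals = {g: 1.0 for g in loci}
        for i in range(50, 53):
            vals[f"g{i:03d}"] = 6.0
        a = _profile("A", vals)
        b = _profile("B", {g: 1.0 for g in loci})
        ratios = call_tail_genes(gene_ratio(a, b))
        spans = single_gene_map(lmap, a, b, ratios)
        assert len(spans) == 1
        row = spans.iloc[0]
        assert row["direction"] == "over"
        assert {f"g{i:03d}" for i in range(50, 53)} <= set(row["genes"])
        assert row["n_windows"] > 1


class TestTopKIntersection:
    def _table(self, genes, ratios):
        return pd.DataFrame({"genes": [(g,) for g in genes], "ratio": ratios})

    def test_identical_tables_share_both_tails(self):
        genes = [f"g{i}" for i in range(10)]
        t = self._table(genes, np.linspace(5.0, 0.1, 10))
        shared = top_k_intersection(t, t, k=2)
        assert shared == {"g0", "g1", "g8", "g9"}

    def test_disjoint_universes_share_nothing(self):
        x = self._table(["a", "b"], [2.0, 0.5])
        y = self._table(["c", "d"], [2.0, 0.5])
        assert top_k_intersection(x, y, k=1) == set()

    def test_short_tables_used_whole(self):
        x = self._table(["a", "b"], [2.0, 0.5])
        y = self._table(["b", "c"], [2.0, 0.5])
        assert top_k_intersection(x, y, k=20) == {"b"}
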