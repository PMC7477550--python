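import numpy as np
import pandas as pd
import pytest

from rhythmix import (
    GeneAnnotation,
    GeneSetCollection,
    PeakTable,
    SiteTable,
    build_target_set,
    fisher_enrichment,
    gene_set_enrichment,
    genes_with_site,
    meta_exclusive_tfs,
)
from rhythmix.enrichment import (
    ENRICHMENT_WINDOW,
    TARGET_WINDOW,
    EnrichmentRecord,
    PromoterWindow,
    SiteFilter,
)

from oracles import hypergeom_tail


def _sites(rows):
    return SiteTable(pd.DataFrame(rows, columns=list(SiteTable.COLUMNS)))


def _peaks(rows):
    return PeakTable(pd.DataFrame(rows, columns=list(PeakTable.COLUMNS)))


class TestGenesWithSite:
    ann = GeneAnnotation({
        "plus": ("chr1", 100_000, "+"),
        "minus": ("chr1", 500_000, "-"),
    })

    def test_plus_strand_window_boundaries(self):
        inside = _sites([("chr1", 95_000, 95_010, "TF", 2.0, 0.1)])
        assert genes_with_site("TF", inside, self.ann) == {"plus"}
        # the window is [tss-10000, tss+2000): a site starting at +2000
        # touches only the excluded end
        boundary = _sites([("chr1", 102_000, 102_001, "TF", 2.0, 0.1)])
        assert genes_with_site("TF", boundary, self.ann) == set()

    def test_minus_strand_upstream_is_rightward(self):
        site = _sites([("chr1", 501_999, 502_005, "TF", 2.0, 0.1)])
        assert genes_with_site("TF", site, self.ann) == {"minus"}
        # 10 kb upstream of a minus-strand gene reaches tss + 10000
        far = _sites([("chr1", 509_990, 510_000, "TF", 2.0, 0.1)])
        assert genes_with_site("TF", far, self.ann) == {"minus"}

    def test_strand_window_by_brute_force(self):
        # every 1-bp site across both promoters, against a direct
        # offset-arithmetic check
        win = PromoterWindow(50, 20)
        for gene, (chrom, tss, strand) in self.ann.records.items():
            for pos in range(tss - 60, tss + 61):
                st = _sites([(chrom, pos, pos + 1, "TF", 2.0, 0.1)])
                got = gene in genes_with_site("TF", st, self.ann, window=win)
                offset = pos - tss if strand == "+" else tss - pos
                expect = -win.upstream_bp <= offset < win.downstream_bp
                assert got == expect, (gene, pos, offset)

    def test_strict_filter_boundaries(self):
        at_bbls = _sites([("chr1", 95_000, 95_010, "TF", 1.0, 0.1)])
        assert genes_with_site("TF", at_bbls, self.ann) == set()
        at_fdr = _sites([("chr1", 95_000, 95_010, "TF", 2.0, 0.25)])
        assert genes_with_site("TF", at_fdr, self.ann) == set()

    def test_unknown_tf_empty(self):
        st = _sites([("chr1", 95_000, 95_010, "TF", 2.0, 0.1)])
        assert genes_with_site("NOPE", st, self.ann) == set()


def _random_annotation(n, rng):
    return GeneAnnotation({
        f"g{i}": ("chr1", 20_000 * i + 10_000, "+" if i % 2 == 0 else "-")
        for i in range(n)
    })


class TestFisherEnrichment:
    def test_matches_hypergeometric_oracle_exactly(self):
        # construct a site table realising k=20/50 in-set vs 80/950 out
        ann = _random_annotation(1000, None)
        genes = [f"g{i}" for i in range(1000)]
        gene_set = set(genes[:50])
        with_site = genes[:20] + genes[50:130]  # 20 in set, 80 outside
        rows = []
        for g in with_site:
            chrom, tss, strand = ann.tss(g)
            rows.append((chrom, tss - 100, tss - 90, "TF", 2.0, 0.1))
        recs = fisher_enrichment(gene_set, set(genes), ["TF"], _sites(rows),
                                 ann)
        rec = recs[0]
        assert (rec.k, rec.m, rec.big_k, rec.big_m) == (20, 30, 80, 870)
        assert rec.p_one_sided == pytest.approx(
            hypergeom_tail(20, 1000, 100, 50), rel=1e-9)

    def test_no_enrichment_when_proportions_match(self):
        ann = _random_annotation(1000, None)
        genes = [f"g{i}" for i in range(1000)]
        gene_set = set(genes[:100])
        with_site = genes[:10] + genes[100:190]  # 10% in both margins
        rows = []
        for g in with_site:
            chrom, tss, strand = ann.tss(g)
            rows.append((chrom, tss - 100, tss - 90, "TF", 2.0, 0.1))
        rec = fisher_enrichment(gene_set, set(genes), ["TF"], _sites(rows),
                                ann)[0]
        assert rec.odds_ratio == pytest.approx(1.0)
        assert rec.p_one_sided > 0.5

    def test_degenerate_motif_excluded(self):
        ann = GeneAnnotation({"g0": ("chr1", 10_000, "+")})
        rows = [("chr1", i * 20, i * 20 + 10, "HOT", 2.0, 0.1)
                for i in range(50_001)]
        rec = fisher_enrichment({"g0"}, {"g0"}, ["HOT"], _sites(rows), ann,
                                site_filter=SiteFilter())[0]
        assert rec.excluded_reason is not None
        assert rec.neg_log10_p == 0.0

    def test_set_not_in_background_errors(self):
        ann = _random_annotation(10, None)
        with pytest.raises(ValueError, match="subset"):
            fisher_enrichment({"g0"}, {"g1"}, ["TF"], _sites([]), ann)

    def test_random_tables_match_oracle(self):
        # the scipy-backed 2x2 test against the independent comb() sum
        rng = np.random.default_rng(12)
        from scipy import stats
        for _ in range(200):
            n_bg = int(rng.integers(20, 2000))
            n_set = int(rng.integers(1, n_bg // 2))
            n_marked = int(rng.integers(0, n_bg))
            k = int(rng.integers(max(0, n_marked - (n_bg - n_set)),
                                 min(n_set, n_marked) + 1))
            table = [[k, n_set - k], [n_marked - k, n_bg - n_set - n_marked + k]]
            _, p = stats.fisher_exact(table, alternative="greater")
            assert p == pytest.approx(
                hypergeom_tail(k, n_bg, n_marked, n_set), rel=1e-9, abs=1e-300)


class TestMetaExclusive:
    def _rec(self, tf, p):
        import math
        return EnrichmentRecord(tf_name=tf, k=1, m=1, big_k=1, big_m=1,
                                odds_ratio=1.0, p_one_sided=p,
                                neg_log10_p=-math.log10(p))

    def test_exclusive_to_single_condition(self):
        recs = {c: [self._rec("TF", p)] for c, p in
                zip("abcd", (0.001, 0.2, 0.8, 0.5))}
        meta = meta_exclusive_tfs(recs, alpha_tf=0.01)
        assert meta.loc["TF", "exclusive_to"] == "a"

    def test_shared_and_none_labels(self):
        recs = {c: [self._rec("X", p), self._rec("Y", 0.9)]
                for c, p in zip("ab", (0.001, 0.002))}
        meta = meta_exclusive_tfs(recs, alpha_tf=0.01)
        assert meta.loc["X", "exclusive_to"] == "shared"
        assert meta.loc["Y", "exclusive_to"] == "none"

    def test_excluded_counts_as_nonsignificant(self):
        ex = EnrichmentRecord(tf_name="TF", k=0, m=1, big_k=0, big_m=1,
                              odds_ratio=float("nan"), p_one_sided=1.0,
                              neg_log10_p=0.0, excluded_reason="degenerate")
        recs = {"a": [self._rec("TF", 0.001)], "b": [ex]}
        meta = meta_exclusive_tfs(recs, alpha_tf=0.01)
        assert meta.loc["TF", "exclusive_to"] == "a"

    def test_disjoint_universes_error(self):
        recs = {"a": [self._rec("X", 0.5)], "b": [self._rec("Y", 0.5)]}
        with pytest.raises(ValueError, match="shares no TFs"):
            meta_exclusive_tfs(recs)


class TestBuildTargetSet:
    ann = GeneAnnotation({"g0": ("chr1", 10_000, "+"), "g1": ("chr1", 50_000, "+")})
    motif = _sites([("chr1", 9_000, 9_010, "TF", 2.0, 0.1),
                    ("chr1", 49_000, 49_010, "TF", 2.0, 0.1)])

    def test_empty_peaks_with_requirement(self):
        assert build_target_set("TF", self.motif, _peaks([]), self.ann) == set()

    def test_peak_must_overlap_window(self):
        peaks = _peaks([("chr1", 8_500, 9_500),      # inside g0's window
                        ("chr1", 60_000, 61_000)])   # outside g1's window
        got = build_target_set("TF", self.motif, peaks, self.ann)
        assert got == {"g0"}

    def test_without_peaks_reduces_to_motif_lookup(self):
        got = build_target_set("TF", self.motif, _peaks([]), self.ann,
                               require_peak=False)
        assert got == genes_with_site("TF", self.motif, self.ann,
                                      window=TARGET_WINDOW)
        assert got == {"g0", "g1"}

    def test_peak_subset_invariant(self):
        rng = np.random.default_rng(3)
        ann = _random_annotation(50, rng)
        rows, prows = [], []
        for i in range(50):
            chrom, tss, strand = ann.tss(f"g{i}")
            if rng.random() < 0.5:
                rows.append((chrom, tss - 500, tss - 490, "TF",
                             float(rng.exponential(2)), float(rng.uniform(0, 0.5))))
            if rng.random() < 0.5:
                prows.append((chrom, tss - 600, tss - 300))
        with_peak = build_target_set("TF", _sites(rows), _peaks(prows), ann)
        without = build_target_set("TF", _sites(rows), _peaks(prows), ann,
                                   require_peak=False)
        assert with_peak <= without


class TestGeneSetEnrichment:
    def test_exact_overlap_ranks_first(self):
        bg = {f"g{i}" for i in range(100)}
        gene_set = {f"g{i}" for i in range(10)}
        coll = GeneSetCollection(sets={"hit": set(gene_set),
                                       "half": {f"g{i}" for i in range(5, 15)},
                                       "miss": {f"g{i}" for i in range(50, 60)}})
        df = gene_set_enrichment(gene_set, bg, coll)
        assert df.index[0] == "hit"
        assert df.loc["miss", "p"] == pytest.approx(1.0)
        assert df.loc["hit", "p"] == pytest.approx(
            hypergeom_tail(10, 100, 10, 10), rel=1e-9)

    def test_bh_stepup_hand_example(self):
        # p = (.01, .02, .03, .04) -> q = (.04, .04, .04, .04)
        from scipy import stats
        q = stats.false_discovery_control([0.01, 0.02, 0.03, 0.04], method="bh")
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_members_outside_background_ignored(self):
        bg = {f"g{i}" for i in range(20)}
        coll = GeneSetCollection(sets={"s": {"g0", "g1", "nope"}})
        df = gene_set_enrichment({"g0", "g1"}, bg, coll)
        assert df.loc["s", "n_members"] == 2

    def test_empty_effective_collection(self):
        coll = GeneSetCollection(sets={"s": {"absent"}})
        df = gene_set_enrichment({"g0"}, {"g0", "g1"}, coll)
        assert len(df) == 0
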