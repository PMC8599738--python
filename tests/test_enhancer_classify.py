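import pandas as pd
import pytest
from math import comb

from enhancerkit import (
    DiffResult,
    RegionSet,
    assign_target_genes,
    call_lineage_enhancers,
    classify_temporal,
    filter_distal,
    gene_class_composition,
    overlap_fraction,
)
from enhancerkit.io_formats import GenomicInterval
from conftest import CHROM_SIZES


def regions(spans, ids=None, summits=None):
    ivs = []
    for k, (start, end) in enumerate(spans):
        ivs.append(
            GenomicInterval(
                "chr1", start, end,
                ids[k] if ids else f"r{k}",
                ".", summits[k] if summits else None,
            )
        )
    return RegionSet(ivs, CHROM_SIZES)


def tss_at(positions, ids=None):
    return RegionSet(
        [
            GenomicInterval("chr1", p, p + 1, ids[k] if ids else f"g{k}")
            for k, p in enumerate(positions)
        ],
        CHROM_SIZES,
    )


class TestFilterDistal:
    def test_distance_rules(self):
        peaks = regions([(10_000, 10_500),   # 3000 bp from TSS at 13500 -> kept
                         (13_400, 13_600),   # overlaps the TSS -> removed
                         (16_000, 16_400)])  # exactly 2500 bp -> removed (strict >)
        tss = tss_at([13_500])
        kept = filter_distal(peaks, tss, min_dist=2500)
        assert [iv.id for iv in kept] == ["r0"]

    def test_exact_boundary_is_removed(self):
        # edge-to-point distance exactly 2500 -> strictly-greater rule drops it
        peaks = regions([(13_000, 13_500)])
        tss = tss_at([16_000])  # distance = 16000 - 13500 + 1 = 2501 > 2500
        assert len(filter_distal(peaks, tss, min_dist=2500)) == 1
        tss = tss_at([15_999])  # distance = 2500 -> removed
        assert len(filter_distal(peaks, tss, min_dist=2500)) == 0

    def test_empty_tss_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            filter_distal(regions([(0, 100)]), tss_at([]))


def make_diff(rows):
    frame = pd.DataFrame(rows, columns=["log2fc", "padj"]).assign(
        base_mean=100.0, dispersion=0.05, stat=0.0, pvalue=0.01
    )
    frame.index = [f"r{k}" for k in range(len(rows))]
    return DiffResult(frame)


class TestCallLineageEnhancers:
    def test_threshold_rules(self):
        peaks = regions([(0, 100), (200, 300), (400, 500)])
        diff = make_diff([(2.5, 0.001), (0.8, 0.001), (3.0, 0.2)])
        kept = call_lineage_enhancers(peaks, diff, fc=2, fdr=0.05)
        assert [iv.id for iv in kept] == ["r0"]

    def test_exact_twofold_is_kept(self):
        peaks = regions([(0, 100)])
        assert len(call_lineage_enhancers(peaks, make_diff([(1.0, 0.05)]))) == 1

    def test_missing_region_rejected(self):
        peaks = regions([(0, 100), (200, 300)])
        with pytest.raises(ValueError, match="missing"):
            call_lineage_enhancers(peaks, make_diff([(2.0, 0.01)]))


class TestClassifyTemporal:
    def _stage_peaks(self, spans):
        return {"FOXA1": regions(spans, ids=[f"f{k}" for k in range(len(spans))])}

    def test_class_assignment(self):
        enh = regions([(1000, 1600), (3000, 3600), (5000, 5600), (7000, 7600)])
        stage1 = self._stage_peaks([(1200, 1400), (5200, 5400)])
        stage2 = self._stage_peaks([(1200, 1400), (3200, 3400)])
        catalog = classify_temporal(enh, stage1, stage2)
        got = catalog.table["temporal_class"].to_dict()
        assert got == {"r0": "I", "r1": "II", "r2": "III"}  # r3 unbound -> excluded

    def test_counts_partition_bound_enhancers(self, small_landscape):
        truth = small_landscape.truth
        bound_ids = truth.index[truth.bound_GT | truth.bound_PP2]
        catalog = classify_temporal(
            small_landscape.enhancers,
            {tf: small_landscape.tf_peaks[(tf, "GT")] for tf in ("FOXA1", "FOXA2")},
            {tf: small_landscape.tf_peaks[(tf, "PP2")] for tf in ("FOXA1", "FOXA2")},
        )
        counts = catalog.class_counts()
        assert sum(counts.values()) == len(bound_ids)

    def test_full_recovery_on_planted_truth(self, small_landscape):
        catalog = classify_temporal(
            small_landscape.enhancers,
            {tf: small_landscape.tf_peaks[(tf, "GT")] for tf in ("FOXA1", "FOXA2")},
            {tf: small_landscape.tf_peaks[(tf, "PP2")] for tf in ("FOXA1", "FOXA2")},
        )
        truth = small_landscape.truth.loc[catalog.table.index, "true_class"]
        assert (catalog.table["temporal_class"] == truth).all()

    def test_union_vs_intersection_rule(self):
        enh = regions([(1000, 1600)])
        s1 = {
            "FOXA1": regions([(1200, 1400)], ids=["a"]),
            "FOXA2": regions([(900_000, 900_200)], ids=["b"]),
        }
        s2 = {
            "FOXA1": regions([(1200, 1400)], ids=["c"]),
            "FOXA2": regions([(1200, 1400)], ids=["d"]),
        }
        union = classify_temporal(enh, s1, s2, bound_rule="union")
        inter = classify_temporal(enh, s1, s2, bound_rule="intersection")
        assert union.table["temporal_class"].iloc[0] == "I"
        assert inter.table["temporal_class"].iloc[0] == "II"


class TestOverlapFraction:
    def test_identical_classes_symmetric(self):
        cls = regions([(1000, 1600), (3000, 3600)])
        features = regions([(1100, 1200)], ids=["f0"])
        fa, fb, odds, p = overlap_fraction(cls, cls, features)
        assert fa == fb and p == pytest.approx(1.0)

    def test_slop_boundary(self):
        enh = regions([(1000, 1600)])
        other = regions([(5000, 5600)])
        # feature 80 bp beyond the edge: counted at slop=100
        near = regions([(1680, 1780)], ids=["n"])
        fa, *_ = overlap_fraction(enh, other, near, slop=100)
        assert fa == 1.0
        # feature 120 bp beyond the edge: not counted
        far = regions([(1720, 1820)], ids=["f"])
        fa, *_ = overlap_fraction(enh, other, far, slop=100)
        assert fa == 0.0

    def test_fisher_p_matches_hypergeometric_oracle(self):
        # 40/60 vs 10/90 overlap table
        from enhancerkit import fisher_exact_2x2

        _, p = fisher_exact_2x2([[40, 60], [10, 90]])
        lo, hi = max(0, 50 - 100), min(100, 50)
        ws = [comb(100, k) * comb(100, 50 - k) for k in range(lo, hi + 1)]
        w_obs = ws[40 - lo]
        oracle = sum(w for w in ws if w <= w_obs) / sum(ws)
        assert p == pytest.approx(oracle, abs=1e-12)

    def test_swapping_classes_inverts_odds(self):
        a = regions([(1000, 1600), (3000, 3600), (5000, 5600)])
        b = regions([(7000, 7600), (9000, 9600)])
        feats = regions([(1100, 1200), (7100, 7200)], ids=["x", "y"])
        fa, fb, odds_ab, p_ab = overlap_fraction(a, b, feats)
        fb2, fa2, odds_ba, p_ba = overlap_fraction(b, a, feats)
        assert (fa, fb) == (fa2, fb2)
        assert p_ab == pytest.approx(p_ba)
        assert odds_ab == pytest.approx(1.0 / odds_ba)

    def test_empty_class_rejected(self):
        a = regions([(1000, 1600)])
        with pytest.raises(ValueError, match="non-empty"):
            overlap_fraction(a, RegionSet([], CHROM_SIZES), a)


class TestAssignTargetGenes:
    def test_nearest_expressed_beats_closer_silent(self):
        enh = regions([(10_000, 10_600)])
        genes = tss_at([11_600, 15_600], ids=["silent", "expressed"])
        expr = pd.Series({"silent": 0.2, "expressed": 8.0})
        out = assign_target_genes(enh, genes, expr)
        assert out.loc["r0", "target_gene"] == "expressed"

    def test_tie_breaks_lexicographically(self):
        enh = regions([(10_000, 10_600)])
        genes = tss_at([9_000, 11_599], ids=["gB", "gA"])  # both 1000 bp away
        expr = pd.Series({"gA": 5.0, "gB": 5.0})
        out = assign_target_genes(enh, genes, expr)
        assert out.loc["r0", "target_gene"] == "gA"

    def test_fpkm_below_threshold_never_assigned(self):
        enh = regions([(10_000, 10_600)])
        genes = tss_at([11_600], ids=["g0"])
        out = assign_target_genes(enh, genes, pd.Series({"g0": 0.9}))
        assert out.loc["r0", "unassigned"]

    def test_recovers_planted_targets(self, small_landscape):
        truth = small_landscape.truth
        with_genes = truth[truth.gene.notna()]
        expressed = with_genes[
            with_genes.gene.map(small_landscape.expression) >= 1.0
        ]
        enh = small_landscape.enhancers.subset(expressed.index)
        out = assign_target_genes(
            enh, small_landscape.tss, small_landscape.expression
        )
        agree = (out["target_gene"] == expressed.loc[out.index, "gene"]).mean()
        assert agree == 1.0

    def test_gene_class_composition_fractions(self):
        enh = regions([(10_000, 10_600), (30_000, 30_600), (50_000, 50_600)])
        genes = tss_at([11_600, 31_600, 51_600], ids=["gI", "gII", "gBoth"])
        expr = pd.Series({"gI": 5.0, "gII": 5.0, "gBoth": 5.0})
        assignments = assign_target_genes(enh, genes, expr)
        assignments.loc["r2", "target_gene"] = "gBoth"

        from enhancerkit import EnhancerCatalog

        table = pd.DataFrame(
            {"temporal_class": ["I", "II", "I"]}, index=["r0", "r1", "r2"]
        )
        table.index.name = "enhancer_id"
        # r2 shares gBoth with a class II enhancer
        assignments2 = pd.concat(
            [
                assignments,
                pd.DataFrame(
                    {"target_gene": ["gBoth"], "distance": [100], "unassigned": [False]},
                    index=pd.Index(["r3"], name="enhancer_id"),
                ),
            ]
        )
        table2 = pd.concat(
            [table, pd.DataFrame({"temporal_class": ["II"]}, index=["r3"])]
        )
        catalog = EnhancerCatalog(enh, table2)
        comp = gene_class_composition(assignments2, catalog)
        assert comp == {
            "only_I": pytest.approx(1 / 3),
            "only_II": pytest.approx(1 / 3),
            "both": pytest.approx(1 / 3),
        }
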