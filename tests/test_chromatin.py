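import numpy as np
import pandas as pd
import pytest

from smoltreg import chromatin, expression
from smoltreg.chromatin import merge_peak_sets
from smoltreg.formats import CoverageTrack, GenomicInterval
from oracles import interval_union_mask, nearest_tss_all_pairs


def iv(chrom, start, end, name="."):
    return GenomicInterval(chrom, start, end, name)


@pytest.fixture(scope="module")
def unified(atac):
    return merge_peak_sets(atac.peaks_per_week)


@pytest.fixture(scope="module")
def peak_counts(atac, unified):
    return chromatin.count_reads_in_peaks(unified, atac.sample_coverage)


@pytest.fixture(scope="module")
def links(unified, annotation):
    return chromatin.link_peaks_to_genes(unified, annotation)


class TestMerge:
    def test_overlapping_intervals_merge(self):
        out = merge_peak_sets({"w1": [iv("c", 0, 100)], "w2": [iv("c", 50, 150)]})
        assert [(p.interval.start, p.interval.end) for p in out] == [(0, 150)]
        assert out[0].weeks == frozenset({"w1", "w2"})

    def test_book_ended_intervals_merge(self):
        out = merge_peak_sets({"w1": [iv("c", 0, 100)], "w2": [iv("c", 100, 200)]})
        assert [(p.interval.start, p.interval.end) for p in out] == [(0, 200)]

    def test_union_matches_boolean_mask_oracle(self, rng):
        per_week = {}
        raw = {}
        for w in range(4):
            ivs = []
            for _ in range(40):
                s = int(rng.integers(0, 1900))
                e = s + int(rng.integers(1, 120))
                ivs.append(iv("c", s, min(e, 2000)))
            per_week[f"w{w}"] = ivs
            raw[f"w{w}"] = [(i.start, i.end) for i in ivs]
        got = [
            (p.interval.start, p.interval.end)
            for p in merge_peak_sets(per_week)
        ]
        want = interval_union_mask(raw.values(), 2000)
        # mask oracle does not merge book-ended runs separated by a 0-gap;
        # both describe the same covered set, and ours merges gap<=0, so
        # re-merge the oracle output the same way for comparison
        merged_want = []
        for (s, e) in want:
            if merged_want and s <= merged_want[-1][1]:
                merged_want[-1] = (merged_want[-1][0], max(merged_want[-1][1], e))
            else:
                merged_want.append((s, e))
        assert got == merged_want

    def test_merge_is_idempotent(self, unified):
        again = merge_peak_sets(
            {"all": [p.interval for p in unified]}
        )
        assert [
            (p.interval.chrom, p.interval.start, p.interval.end) for p in again
        ] == [
            (p.interval.chrom, p.interval.start, p.interval.end)
            for p in unified
        ]


class TestCounting:
    def test_flat_coverage_rectangle_integral(self):
        peaks = merge_peak_sets({"w": [iv("c", 100, 200, "p")]})
        track = CoverageTrack([("c", 0, 500, 2.0)])
        counts = chromatin.count_reads_in_peaks(peaks, {"s1": track})
        assert counts.iloc[0, 0] == 200.0

    def test_zero_coverage_counts_zero(self):
        peaks = merge_peak_sets({"w": [iv("c", 100, 200, "p")]})
        counts = chromatin.count_reads_in_peaks(
            peaks, {"s1": CoverageTrack([])}
        )
        assert counts.iloc[0, 0] == 0.0

    def test_unmatched_chromosome_warns(self):
        peaks = merge_peak_sets({"w": [iv("c1", 0, 10, "p")]})
        track = CoverageTrack([("c2", 0, 10, 1.0)])
        with pytest.warns(UserWarning, match="c2"):
            chromatin.count_reads_in_peaks(peaks, {"s1": track})


class TestDifferentialAccessibility:
    def test_planted_peaks_recovered_with_direction(
        self, peak_counts, atac, truth, unified
    ):
        res = chromatin.test_da(peak_counts, atac.sample_weeks, "w10_w19")
        # map planted original peaks to unified ids by coordinates
        planted = {
            pid: rec for pid, rec in truth.da_peaks.items()
            if rec["contrast"] == "week_10:week_19"
        }
        orig = {
            p.name: p for w in atac.peaks_per_week.values() for p in w
        }
        hits, correct = 0, 0
        for pid, rec in planted.items():
            o = orig[pid]
            uid = next(
                u.peak_id for u in unified
                if u.interval.chrom == o.chrom
                and u.interval.start <= o.start and o.end <= u.interval.end
            )
            if res.loc[uid, "significant"]:
                hits += 1
                if res.loc[uid, "direction"] == rec["direction"]:
                    correct += 1
        assert hits >= 0.9 * len(planted)
        assert correct == hits

    def test_reversing_weeks_flips_directions(self, peak_counts, atac):
        res = chromatin.test_da(peak_counts, atac.sample_weeks, "w10_w19")
        flipped_weeks = {
            s: {"week_10": "week_19", "week_19": "week_10"}.get(w, w)
            for s, w in atac.sample_weeks.items()
        }
        res2 = chromatin.test_da(peak_counts, flipped_weeks, "w10_w19")
        assert np.allclose(res2["logFC"], -res["logFC"])

    def test_unknown_contrast_rejected(self, peak_counts, atac):
        with pytest.raises(ValueError, match="w1_w10"):
            chromatin.test_da(peak_counts, atac.sample_weeks, "bogus")


class TestLinking:
    def test_midpoint_on_tss_gives_distance_zero(self, annotation):
        g = annotation.genes[0]
        peaks = merge_peak_sets(
            {"w": [iv(g.chrom, g.tss - 10, g.tss + 10, "p")]}
        )
        res = chromatin.link_peaks_to_genes(peaks, annotation)
        assert res.loc[0, "gene_id"] == g.gene_id
        assert res.loc[0, "distance"] == 0

    def test_equidistant_tie_takes_smaller_gene_id(self):
        from smoltreg.formats import Gene, GenomeAnnotation

        ann = GenomeAnnotation([
            Gene("gB", "c", 100, 200, "+"),
            Gene("gA", "c", 300, 400, "+"),
        ])
        # midpoint 200 is equidistant (100) from TSS 100 and 300
        peaks = merge_peak_sets({"w": [iv("c", 195, 205, "p")]})
        res = chromatin.link_peaks_to_genes(peaks, ann)
        assert res.loc[0, "gene_id"] == "gA"

    def test_matches_all_pairs_search(self, annotation, rng):
        tss_by_chrom = {}
        for g in annotation.genes:
            tss_by_chrom.setdefault(g.chrom, []).append((g.gene_id, g.tss))
        peaks = []
        for i in range(1000):
            chrom = f"chr{int(rng.integers(1, 3))}"
            s = int(rng.integers(0, 900_000))
            peaks.append(iv(chrom, s, s + int(rng.integers(10, 400)), f"p{i}"))
        unified = [
            chromatin.UnifiedPeak(p, frozenset({"w"})) for p in peaks
        ]
        res = chromatin.link_peaks_to_genes(unified, annotation)
        for p, (_, row) in zip(unified, res.iterrows()):
            want_gene, want_d = nearest_tss_all_pairs(
                p.interval.midpoint, tss_by_chrom[p.interval.chrom]
            )
            assert row["gene_id"] == want_gene
            assert abs(row["distance"]) == want_d

    def test_signed_distance_respects_strand(self):
        from smoltreg.formats import Gene, GenomeAnnotation

        ann = GenomeAnnotation([Gene("g1", "c", 1000, 2000, "-")])
        # TSS = 1999; midpoint 1499 is downstream of TSS (inside gene body)
        peaks = merge_peak_sets({"w": [iv("c", 1494, 1505, "p")]})
        res = chromatin.link_peaks_to_genes(peaks, ann)
        assert res.loc[0, "distance"] == 1999 - 1499


class TestLocationAnnotation:
    def test_promoter_upstream_window(self, annotation):
        g = next(g for g in annotation.genes if g.strand == "+")
        got = chromatin.annotate_location(
            g.chrom, g.tss - 100, annotation, promoter_window=(1500, 500)
        )
        assert got == "promoter"

    def test_exon_and_intron_classification(self, annotation):
        g = annotation.genes[0]
        exon_mid = (g.exons[0][0] + g.exons[0][1]) // 2
        intron_pos = g.exons[0][1] + 1  # between exon 1 and exon 2
        annot = chromatin.LocationAnnotator(annotation, (200, 100))
        # guard against promoter overlap for genes near the window
        if annot.classify(g.chrom, exon_mid) != "promoter":
            assert annot.classify(g.chrom, exon_mid) == "exon"
        assert annot.classify(g.chrom, intron_pos) in ("intron", "promoter")

    def test_counts_match_interval_sweep_oracle(self, annotation, rng):
        annot = chromatin.LocationAnnotator(annotation, (1500, 500))
        genes = annotation.by_chrom()["chr1"]

        def oracle(pos):
            for g in genes:
                if g.strand == "+":
                    if g.tss - 1500 <= pos < g.tss + 500:
                        return "promoter"
                else:
                    if g.tss - 500 < pos <= g.tss + 1500:
                        return "promoter"
            for g in genes:
                if g.start <= pos < g.end:
                    for (a, b) in g.exons:
                        if a <= pos < b:
                            return "exon"
                    return "intron"
            return "intergenic"

        for pos in rng.integers(0, 900_000, size=500):
            assert annot.classify("chr1", int(pos)) == oracle(int(pos))


class TestDaDegAssociation:
    @staticmethod
    def _fake_inputs(up_cluster_counts, down_cluster_counts):
        rows, links, clusters = [], [], []
        pid = 0
        for direction, counts in (("up", up_cluster_counts),
                                  ("down", down_cluster_counts)):
            for cluster, n in counts.items():
                for _ in range(n):
                    peak = f"p{pid}"
                    gene = f"g{pid}"
                    pid += 1
                    rows.append({"peak_id": peak, "significant": True,
                                 "direction": direction, "contrast": "x"})
                    links.append({"peak_id": peak, "gene_id": gene,
                                  "distance": 0})
                    clusters.append({"gene_id": gene, "cluster": cluster,
                                     "correlation": 1.0})
        da = pd.DataFrame(rows).set_index("peak_id")
        return da, pd.DataFrame(links), pd.DataFrame(clusters)

    def test_identical_composition_gives_p_one(self):
        da, links, cl = self._fake_inputs({1: 5, 2: 5}, {1: 5, 2: 5})
        res = chromatin.da_deg_association(da, links, cl)
        assert (res["PValue"] == 1.0).all()

    def test_planted_coupling_detected(self):
        da, links, cl = self._fake_inputs({3: 20, 1: 2}, {3: 2, 1: 20})
        res = chromatin.da_deg_association(da, links, cl).set_index("cluster")
        assert res.loc[3, "PValue"] < 0.01
        assert res.loc[3, "odds_ratio"] > 1

    def test_margins_conserved(self):
        da, links, cl = self._fake_inputs({1: 4, 2: 7}, {1: 3, 2: 6})
        res = chromatin.da_deg_association(da, links, cl)
        totals = res[["a", "b", "c", "d"]].sum(axis=1)
        assert (totals == 20).all()

    def test_pipeline_planted_da_cluster_coupling(
        self, peak_counts, atac, truth, unified, links, matrix
    ):
        # up-peaks of w10->w19 were planted at cluster-3 gene promoters
        de = expression.run_anova_de(matrix)
        degs = de.index[de["deg"]].tolist()
        clusters = expression.cluster_degs(matrix, degs)
        da = chromatin.test_da(peak_counts, atac.sample_weeks, "w10_w19")
        res = chromatin.da_deg_association(da, links, clusters)
        # identify which discovered cluster id the planted cluster 3 maps to
        truth_c3 = {g for g, c in truth.gene_clusters.items() if c == 3}
        m = clusters.dropna(subset=["cluster"])
        mapped = (
            m[m["gene_id"].isin(truth_c3)]["cluster"].mode().iloc[0]
        )
        row = res.set_index("cluster").loc[int(mapped)]
        assert row["odds_ratio"] > 1
        assert row["PValue"] < 0.01
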