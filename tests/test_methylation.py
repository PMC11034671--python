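import numpy as np
import pandas as pd
import pytest

from smoltreg import methylation, synthio
from smoltreg.formats import CpGRecord
from smoltreg.synthio import GroundTruth, SimDesign


def sample_weeks_of(design):
    return {
        f"{w}_r{r}": w
        for w in design.weeks
        for r in range(1, design.replicates_per_week + 1)
    }


@pytest.fixture(scope="module")
def meth_pipeline():
    """High-coverage planted study through filter -> merge -> call."""
    design = SimDesign(seed=41)
    truth = GroundTruth()
    recs = synthio.simulate_methylation(
        design, truth, n_cpgs=400, n_dmcs=60, delta=40.0,
        mean_coverage=100.0, coverage_sigma=0.3,
    )
    filtered = methylation.filter_cpgs(recs, chrom_whitelist={"chr1", "chr2"})
    consensus = methylation.merge_replicates(filtered, sample_weeks_of(design))
    dmcs = methylation.call_dmcs(consensus)
    return design, truth, dmcs


class TestFilter:
    def test_low_coverage_dropped_per_sample(self):
        recs = {"s1": [CpGRecord("chr1", 10, 4, 5), CpGRecord("chr1", 20, 8, 4)]}
        out = methylation.filter_cpgs(recs, min_cov=10)
        assert [r.position for r in out["s1"]] == [20]
        assert out.drop_reasons["s1"]["chr1:10"] == "low_coverage"

    def test_equal_coverage_percentile_drops_none(self):
        recs = {"s1": [CpGRecord("chr1", i, 10, 10) for i in range(1, 50)]}
        out = methylation.filter_cpgs(recs, min_cov=10)
        assert len(out["s1"]) == 49

    def test_off_whitelist_dropped(self):
        recs = {"s1": [CpGRecord("scaffold_1", 5, 10, 10),
                       CpGRecord("chr1", 5, 10, 10)]}
        out = methylation.filter_cpgs(recs, chrom_whitelist={"chr1"})
        assert [r.chrom for r in out["s1"]] == ["chr1"]

    def test_empty_whitelist_rejected(self):
        with pytest.raises(ValueError, match="whitelist"):
            methylation.filter_cpgs({"s1": []}, chrom_whitelist=set())

    def test_matches_bruteforce_filter(self, rng):
        recs = {}
        for s in ("s1", "s2"):
            recs[s] = [
                CpGRecord("chr1", i + 1, int(rng.integers(0, 40)) + 1,
                          int(rng.integers(0, 40)))
                for i in range(500)
            ]
        out = methylation.filter_cpgs(recs, min_cov=10, max_percentile=95.0)
        for s in recs:
            covs = np.array([r.coverage for r in recs[s]])
            cut = sorted(covs)[int(np.ceil(0.95 * (len(covs) - 1)))]
            want = [
                r.position for r in recs[s]
                if 10 <= r.coverage <= cut
            ]
            assert [r.position for r in out[s]] == want

    def test_drops_sum_to_input_minus_kept(self, rng):
        recs = {"s1": [
            CpGRecord("chr1", i + 1, int(rng.integers(0, 30)) + 1,
                      int(rng.integers(0, 30)))
            for i in range(300)
        ]}
        out = methylation.filter_cpgs(recs, min_cov=10)
        assert len(out["s1"]) + len(out.drop_reasons["s1"]) == 300


class TestMergeReplicates:
    @staticmethod
    def _samples(presence):
        """presence: {sample: bool} for one locus across 4 reps x 4 weeks."""
        out = {}
        for w in ("week_1", "week_10", "week_19", "week_25"):
            for r in range(1, 5):
                name = f"{w}_r{r}"
                recs = [CpGRecord("chr1", 99, 5, 5)]
                if presence.get(name, True):
                    recs.append(CpGRecord("chr1", 10, 6, 4))
                out[name] = recs
        return out

    def test_locus_in_three_of_four_kept(self):
        samples = self._samples({"week_1_r1": False})
        sw = {s: s.rsplit("_r", 1)[0] for s in samples}
        consensus = methylation.merge_replicates(samples, sw)
        assert "chr1:10" in set(consensus["locus"])

    def test_locus_in_two_of_four_dropped(self):
        samples = self._samples({"week_1_r1": False, "week_1_r2": False})
        sw = {s: s.rsplit("_r", 1)[0] for s in samples}
        consensus = methylation.merge_replicates(samples, sw)
        assert "chr1:10" not in set(consensus["locus"])

    def test_min_present_above_replicates_rejected(self):
        samples = self._samples({})
        sw = {s: s.rsplit("_r", 1)[0] for s in samples}
        with pytest.raises(ValueError, match="min_present"):
            methylation.merge_replicates(samples, sw, min_present=5)

    def test_consensus_size_matches_bruteforce(self, meth, design):
        filtered = methylation.filter_cpgs(meth)
        sw = sample_weeks_of(design)
        consensus = methylation.merge_replicates(filtered, sw)
        # brute-force recount
        want = None
        for w in design.weeks:
            tally = {}
            for s, recs in filtered.items():
                if sw[s] != w:
                    continue
                for r in recs:
                    tally[f"{r.chrom}:{r.position}"] = tally.get(
                        f"{r.chrom}:{r.position}", 0
                    ) + 1
            present = {k for k, n in tally.items() if n >= 3}
            want = present if want is None else want & present
        assert set(consensus["locus"]) == want


class TestCallDmcs:
    def test_constant_scores_never_called(self):
        rows = []
        for w in ("week_1", "week_10", "week_19", "week_25"):
            for r in range(1, 4):
                rows.append(
                    {"chrom": "chr1", "position": 5, "locus": "chr1:5",
                     "sample": f"{w}_r{r}", "week": w,
                     "count_m": 10, "count_u": 10, "score": 50.0}
                )
        res = methylation.call_dmcs(pd.DataFrame(rows))
        assert not res["is_dmc"].any()
        assert res["PValue"].iloc[0] == 1.0

    def test_planted_dmcs_recovered(self, meth_pipeline):
        design, truth, dmcs = meth_pipeline
        called = set(dmcs.index[dmcs["is_dmc"]])
        planted = set(truth.dmcs)
        present = planted & set(dmcs.index)
        assert len(present) >= 0.9 * len(planted)
        sens = len(called & present) / len(present)
        assert sens >= 0.9

    def test_effect_gate_blocks_small_deltas(self):
        # strong p (huge counts) but only 10-point shift
        rng = np.random.default_rng(0)
        rows = []
        for w in ("week_1", "week_10", "week_19", "week_25"):
            p = 0.5 + (0.10 if w == "week_25" else 0.0)
            for r in range(1, 5):
                m = rng.binomial(5000, p)
                rows.append(
                    {"chrom": "chr1", "position": 5, "locus": "chr1:5",
                     "sample": f"{w}_r{r}", "week": w,
                     "count_m": int(m), "count_u": int(5000 - m),
                     "score": 100 * m / 5000}
                )
        res = methylation.call_dmcs(pd.DataFrame(rows))
        assert res["FDR"].iloc[0] < 0.05
        assert res["max_abs_delta"].iloc[0] < 25
        assert not res["is_dmc"].iloc[0]

    def test_null_dmc_rate_bounded_by_alpha(self):
        design = SimDesign(seed=43)
        recs = synthio.simulate_methylation(
            design, GroundTruth(), n_cpgs=800, n_dmcs=0,
        )
        filtered = methylation.filter_cpgs(recs)
        consensus = methylation.merge_replicates(
            filtered, sample_weeks_of(design)
        )
        res = methylation.call_dmcs(consensus)
        assert res["is_dmc"].mean() <= 0.05


class TestAnnotate:
    def test_promoter_and_intergenic_positions(self, annotation):
        g = next(g for g in annotation.genes if g.strand == "+")
        df = pd.DataFrame(
            {
                "chr": [g.chrom, g.chrom],
                "locus_pos": [g.tss + 1 - 200, 999_900],
                "is_dmc": [True, True],
            },
            index=["a", "b"],
        )
        out = methylation.annotate_dmcs(df, annotation)
        assert out.loc["a", "genomic_feature"] == "promoter"
        assert out.loc["b", "genomic_feature"] == "intergenic"

    def test_feature_counts_match_sweep_oracle(self, meth_pipeline, annotation):
        _, _, dmcs = meth_pipeline
        from smoltreg.chromatin import LocationAnnotator

        out = methylation.annotate_dmcs(dmcs, annotation)
        annot = LocationAnnotator(annotation, (1500, 500))
        want = [
            annot.classify(c, int(p) - 1)
            for c, p in zip(out["chr"], out["locus_pos"])
        ]
        assert list(out["genomic_feature"]) == want


class TestCorrelation:
    def test_affine_coupling_is_significant(self, meth_pipeline, annotation):
        design, truth, dmcs = meth_pipeline
        ann = methylation.annotate_dmcs(dmcs, annotation)
        called = ann[ann["is_dmc"]]
        # construct expression profiles exactly affine in methylation
        genes = sorted(set(called["gene_id"].dropna()))
        weeks = list(design.weeks)
        expr = pd.DataFrame(
            0.0, index=pd.Index(genes, name="gene_id"), columns=weeks
        )
        gene_to_locus = {}
        for locus, row in called.iterrows():
            if row["gene_id"] in expr.index:
                gene_to_locus.setdefault(row["gene_id"], locus)
        for g, locus in gene_to_locus.items():
            prof = called.loc[locus, [f"{w}_score" for w in weeks]]
            expr.loc[g] = 2.0 * prof.to_numpy(dtype=float) + 1.0
        res = methylation.correlate_dmc_expression(ann, expr, seed=1,
                                                   n_random_pairs=200)
        obs = res.observed.set_index("cpg_id")
        for g, locus in list(gene_to_locus.items())[:20]:
            if locus in obs.index:
                row = obs.loc[locus]
                if isinstance(row, pd.DataFrame):
                    row = row.iloc[0]
                assert row["r"] == pytest.approx(1.0)
                assert row["significant"]

    def test_uncoupled_data_ks_nonsignificant(self, meth_pipeline,
                                              annotation, matrix):
        design, truth, dmcs = meth_pipeline
        ann = methylation.annotate_dmcs(dmcs, annotation)
        week_means = methylation.expression_week_means(matrix)
        # the methylation study and expression matrix share no planted
        # coupling, so observed correlations look like random pairs
        res = methylation.correlate_dmc_expression(
            ann, week_means, seed=3, n_random_pairs=500
        )
        assert res.ks_pvalue > 0.05

    def test_fixed_seed_reproducible_null(self, meth_pipeline, annotation,
                                          matrix):
        design, truth, dmcs = meth_pipeline
        ann = methylation.annotate_dmcs(dmcs, annotation)
        week_means = methylation.expression_week_means(matrix)
        r1 = methylation.correlate_dmc_expression(ann, week_means, seed=5)
        r2 = methylation.correlate_dmc_expression(ann, week_means, seed=5)
        assert np.array_equal(r1.null_r, r2.null_r)
        pd.testing.assert_frame_equal(r1.observed, r2.observed)
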