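"""Nearest-TSS mapping, enrichment tests, entropy, composition, classification."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import scregseg as sg
from scregseg.enrichment import GeneAnnotation, state_coverage
from scregseg.hmm import Segmentation

from oracles import hypergeom_upper_tail_oracle


def _segmentation(calls, n_states=None, binsize=1000):
    calls = np.asarray(calls)
    S = n_states or int(calls.max()) + 1
    post = np.zeros((len(calls), S))
    post[np.arange(len(calls)), calls] = 1.0
    bins = sg.make_bins({"chr1": binsize * len(calls)}, binsize)
    return Segmentation(state_call=calls, posteriors=post, loglik=0.0, bins=bins)


def _annotation(tss_rows, sets=None):
    tss = pd.DataFrame(tss_rows, columns=["chrom", "pos", "gene", "strand"])
    gb = pd.DataFrame(
        {
            "chrom": tss["chrom"],
            "start": tss["pos"],
            "end": tss["pos"] + 1000,
            "gene": tss["gene"],
        }
    )
    return GeneAnnotation(tss=tss, gene_body=gb, gene_sets=sets or {})


class TestNearestTss:
    def test_exact_hit_distance_zero(self):
        ann = _annotation([("chr1", 500, "g1", "+"), ("chr1", 5000, "g2", "+")])
        regions = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [1000]})
        out = sg.nearest_tss(regions, ann)
        assert out.iloc[0]["gene"] == "g1"
        assert out.iloc[0]["distance"] == 0

    def test_equidistant_tie_goes_to_lower_coordinate(self):
        ann = _annotation([("chr1", 400, "hi", "+"), ("chr1", 200, "lo", "+")])
        regions = pd.DataFrame({"chrom": ["chr1"], "start": [250], "end": [350]})
        out = sg.nearest_tss(regions, ann)  # midpoint 300, both at distance 100
        assert out.iloc[0]["gene"] == "lo"

    def test_chromosome_without_tss_flagged(self):
        ann = _annotation([("chr1", 100, "g1", "+")])
        regions = pd.DataFrame({"chrom": ["chrX"], "start": [0], "end": [10]})
        out = sg.nearest_tss(regions, ann)
        assert not out.iloc[0]["assigned"]

    def test_matches_all_pairs_search(self):
        rng = np.random.default_rng(8)
        tss_rows = [
            ("chr1", int(p), f"g{i}", "+")
            for i, p in enumerate(np.sort(rng.choice(100_000, size=30, replace=False)))
        ]
        ann = _annotation(tss_rows)
        starts = rng.integers(0, 99_000, size=25)
        regions = pd.DataFrame(
            {"chrom": "chr1", "start": starts, "end": starts + 500}
        )
        out = sg.nearest_tss(regions, ann)
        pos = np.array([r[1] for r in tss_rows])
        genes = [r[2] for r in tss_rows]
        for i, (start, end) in enumerate(zip(regions["start"], regions["end"])):
            mid = (start + end) // 2
            d = np.abs(pos - mid)
            best = min(range(len(pos)), key=lambda j: (d[j], pos[j]))
            assert out.iloc[i]["gene"] == genes[best]


class TestHypergeom:
    def test_printed_example(self):
        # M=10, n=5, N=4, k=4 -> C(5,4)C(5,0)/C(10,4) = 5/210
        assert sg.hypergeom_enrichment(4, 5, 4, 10) == pytest.approx(5 / 210)

    def test_set_equals_universe_gives_one(self):
        assert sg.hypergeom_enrichment(4, 10, 4, 10) == pytest.approx(1.0)

    def test_zero_hits_gives_one(self):
        assert sg.hypergeom_enrichment(0, 5, 4, 10) == pytest.approx(1.0)

    def test_matches_enumeration_small_universes(self):
        for M in range(1, 9):
            for n in range(M + 1):
                for N in range(M + 1):
                    for k in range(min(n, N) + 1):
                        assert sg.hypergeom_enrichment(k, n, N, M) == pytest.approx(
                            hypergeom_upper_tail_oracle(k, n, N, M), abs=1e-12
                        )

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            sg.hypergeom_enrichment(5, 4, 4, 10)
        with pytest.raises(ValueError):
            sg.hypergeom_enrichment(1, 11, 4, 10)


class TestFeatureEnrichmentScore:
    def _setup(self):
        # 100 bins: state 1 occupies bins 10..19, state 0 the rest
        calls = np.zeros(100, dtype=int)
        calls[10:20] = 1
        return _segmentation(calls, n_states=2)

    def test_zero_when_observed_at_or_below_expected(self):
        seg = self._setup()
        regions = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [100_000]})
        # p matching observed frequencies exactly: o == e -> 0
        out = sg.feature_enrichment_score(seg, regions, p=np.array([0.9, 0.1]))
        assert np.allclose(out["score"], 0.0)
        # expected above observed -> still zero (depletion zeroed)
        out = sg.feature_enrichment_score(seg, regions, p=np.array([0.5, 0.5]))
        assert out["score"][1] == 0.0

    def test_score_one_at_twice_expected(self):
        seg = self._setup()
        regions = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [100_000]})
        out = sg.feature_enrichment_score(seg, regions, p=np.array([0.95, 0.05]))
        # o_1 = 10, e_1 = 100*0.05 = 5 -> ((10-5)^2)/25 = 1
        assert out["score"][1] == pytest.approx(1.0)

    def test_increasing_in_observed_above_expected(self):
        seg = self._setup()
        windows = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "start": [10_000, 0], "end": [20_000, 100_000]}
        )
        p = np.array([0.99, 0.01])
        narrow = sg.feature_enrichment_score(seg, windows.iloc[[0]], p)
        assert narrow["score"][1] > 0

    def test_zero_expected_with_hits_flagged_infinite(self):
        seg = self._setup()
        regions = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [100_000]})
        out = sg.feature_enrichment_score(seg, regions, p=np.array([1.0, 0.0]))
        assert np.isinf(out["score"][1])
        assert out["flagged"][1]


class TestMarkerGeneLogratio:
    def test_fully_covered_window_scores_minus_log_p(self):
        calls = np.ones(50, dtype=int)
        calls[:5] = 0
        seg = _segmentation(calls, n_states=2)
        ann = _annotation([("chr1", 30_000, "g1", "+")])
        p = np.array([0.5, 0.5])
        out = sg.marker_gene_logratio(seg, ann, state=1, p=p)
        assert out.iloc[0]["score"] == pytest.approx(np.log(1 / 0.5))

    def test_window_at_stationary_fraction_scores_zero(self):
        # flank chosen so the window covers an even number of alternating
        # bins: the state fraction is exactly the stationary probability
        calls = np.array([0, 1] * 25)
        seg = _segmentation(calls, n_states=2)
        ann = _annotation([("chr1", 25_000, "g1", "+")])
        out = sg.marker_gene_logratio(
            seg, ann, state=1, p=np.array([0.5, 0.5]), flank=9500
        )
        assert out.iloc[0]["n_bins"] % 2 == 0
        assert out.iloc[0]["score"] == pytest.approx(0.0, abs=1e-9)

    def test_matches_direct_window_tabulation(self):
        rng = np.random.default_rng(2)
        calls = rng.integers(0, 3, size=80)
        seg = _segmentation(calls, n_states=3)
        ann = _annotation(
            [("chr1", int(p), f"g{i}", "+") for i, p in enumerate([5000, 40_000, 70_000])]
        )
        p = np.array([0.2, 0.5, 0.3])
        out = sg.marker_gene_logratio(seg, ann, state=2, p=p, flank=10_000)
        for _, row in out.iterrows():
            tss = int(ann.tss.loc[ann.tss["gene"] == row["gene"], "pos"].iloc[0])
            lo, hi = max(0, tss - 10_000), min(80_000, tss + 1000 + 10_000)
            in_win = [
                i for i in range(80) if lo <= (i * 1000 + min(i * 1000 + 1000, 80_000)) // 2 < hi
            ]
            o = sum(1 for i in in_win if calls[i] == 2)
            expected = np.log((o / len(in_win)) / p[2]) if o else -np.inf
            assert row["score"] == pytest.approx(expected)


class TestShannonEntropy:
    def test_uniform_seventeen_clusters_is_log2_17(self):
        counts = np.full((3, 17), 5)
        res = sg.shannon_entropy(counts)
        assert np.allclose(res.entropy, np.log2(17), atol=1e-12)

    def test_two_equal_clusters_is_one_bit(self):
        res = sg.shannon_entropy(np.array([[9, 9]]))
        assert res.entropy[0] == pytest.approx(1.0)

    def test_concentrated_region_approaches_zero(self):
        # pseudocount keeps exact one-hot unreachable from raw counts, but
        # extreme concentration drives the entropy towards 0
        res = sg.shannon_entropy(np.array([[10**9, 1], [1, 10**9]]))
        assert (res.entropy < 1e-6).all()

    def test_bounds_and_cluster_order_invariance(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(5.0, size=(20, 6))
        res = sg.shannon_entropy(counts)
        assert (res.entropy >= 0).all() and (res.entropy <= np.log2(6) + 1e-12).all()
        perm = rng.permutation(6)
        res_p = sg.shannon_entropy(counts[:, perm])
        assert np.allclose(np.sort(res.entropy), np.sort(res_p.entropy))
        assert np.allclose(res.entropy, res_p.entropy)

    def test_depth_normalization_order(self):
        # one deep cluster: depth normalization must equalize before rowwise p
        counts = np.array([[100, 1], [100, 1]])
        res = sg.shannon_entropy(counts, pseudocount=1)
        assert np.allclose(res.entropy, 1.0)  # after depth norm both clusters equal


class TestCompositionBinomialTest:
    def test_success_probability_from_pooled_totals(self):
        out = sg.composition_binomial_test({"c1": 3769}, {"c1": 5207})
        assert out.attrs["p0"] == pytest.approx(3769 / 8976)
        assert out.attrs["total_cells"] == 8976
        assert round(100 * out.attrs["p0"]) == 42

    def test_fraction_at_p0_gives_pvalue_one(self):
        # pooled p0 = 0.5; cluster c1 sits exactly at p0
        out = sg.composition_binomial_test({"c1": 10, "c2": 40}, {"c1": 10, "c2": 40})
        row = out[out["cluster"] == "c1"].iloc[0]
        assert row["pvalue"] == pytest.approx(1.0)

    def test_closed_form_tail_for_extreme_cluster(self):
        # cluster of 20 cells with zero condition cells at p0 = 0.5:
        # two-sided exact p = 2 * 0.5^20
        out = sg.composition_binomial_test(
            {"c1": 0, "c2": 1000}, {"c1": 20, "c2": 980}
        )
        row = out[out["cluster"] == "c1"].iloc[0]
        assert row["pvalue"] == pytest.approx(2 * 0.5**20, rel=1e-6)
        assert row["direction"] == "depleted"

    def test_empty_cluster_skipped(self):
        out = sg.composition_binomial_test({"c1": 0, "c2": 5}, {"c1": 0, "c2": 5})
        assert bool(out[out["cluster"] == "c1"]["skipped"].iloc[0])

    def test_pvalues_uniform_under_null(self):
        """Kolmogorov-Smirnov sanity check on null simulations."""
        rng = np.random.default_rng(123)
        n_clusters, n_per = 2000, 2000
        ks = rng.binomial(n_per, 0.4, size=n_clusters)
        cond = {f"c{i}": int(k) for i, k in enumerate(ks)}
        ref = {f"c{i}": n_per - int(k) for i, k in enumerate(ks)}
        out = sg.composition_binomial_test(cond, ref)
        stat = stats.kstest(out["pvalue"], "uniform")
        assert stat.pvalue > 0.01


class TestClassifyRegions:
    def test_dominant_state_wins(self):
        # region fully covered by state 0; equal region-set totals and
        # equal genome probabilities for all states
        label, score, tie = sg.classify_region_by_state_coverage(
            [1000, 0, 0], [2000, 2000, 2000], [1 / 3, 1 / 3, 1 / 3]
        )
        assert label == 0 and not tie

    def test_proportional_coverage_ties_to_lowest_state(self):
        cov = np.array([300.0, 300.0])
        label, score, tie = sg.classify_region_by_state_coverage(
            cov, [900.0, 900.0], [0.5, 0.5]
        )
        assert label == 0 and tie

    def test_zero_coverage_is_background(self):
        label, score, tie = sg.classify_region_by_state_coverage(
            [0, 0], [10, 10], [0.5, 0.5]
        )
        assert label == "background"

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(4)
        cov = rng.integers(1, 500, size=4).astype(float)
        tot = cov + rng.integers(100, 1000, size=4)
        gp = rng.dirichlet(np.ones(4))
        L = float(cov.sum())
        label, score, _ = sg.classify_region_by_state_coverage(cov, tot, gp, region_length=L)
        direct = np.log((cov / tot) / (gp * L / tot.sum()))
        assert np.allclose(score, direct)
        assert label == int(np.argmax(direct))

    def test_state_coverage_overlap_arithmetic(self):
        regions = pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [400]})
        states = pd.DataFrame(
            {
                "chrom": ["chr1", "chr1", "chr1"],
                "start": [0, 200, 300],
                "end": [200, 300, 1000],
                "state": ["A", "B", "A"],
            }
        )
        cov, names = state_coverage(regions, states)
        assert names == ["A", "B"]
        assert cov[0].tolist() == [200.0, 100.0]

    def test_classify_regions_end_to_end(self):
        rng = np.random.default_rng(9)
        states = pd.DataFrame(
            {
                "chrom": "chr1",
                "start": np.arange(0, 50_000, 1000),
                "end": np.arange(1000, 51_000, 1000),
                "state": rng.choice(["promoter_like", "background"], size=50, p=[0.2, 0.8]),
            }
        )
        regions = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "start": [0, 30_000], "end": [5000, 33_000]}
        )
        out = sg.classify_regions(regions, states)
        assert len(out) == 2
        assert set(out["label"]) <= {"promoter_like", "background"}


class TestGenesetEnrichment:
    def test_planted_set_ranks_first(self):
        rng = np.random.default_rng(6)
        # genes g0..g9 near regions; decoys d0..d89 far away
        tss_rows = [("chr1", 1000 + 2000 * i, f"g{i}", "+") for i in range(10)]
        tss_rows += [("chr2", 1000 + 1000 * i, f"d{i}", "+") for i in range(90)]
        ann = _annotation(
            tss_rows, sets={"planted": [f"g{i}" for i in range(10)], "decoy": [f"d{i}" for i in range(10)]}
        )
        regions = pd.DataFrame(
            {"chrom": "chr1", "start": [2000 * i for i in range(10)], "end": [2000 * i + 500 for i in range(10)]}
        )
        out = sg.geneset_enrichment(regions, ann)
        out = out.set_index("gene_set")
        assert out.loc["planted", "pvalue"] < out.loc["decoy", "pvalue"]
        assert out.loc["planted", "pvalue"] < 1e-6
        assert ((out["pvalue"] >= 0) & (out["pvalue"] <= 1)).all()
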