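"""Feature partition, matched nulls, proportion tests, conservation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lofsplice.enrichment import (
    FEATURE_LABELS,
    NullMatchSpec,
    build_partition,
    conservation_test,
    feature_profile,
    match_null,
    median_conservation,
    overlap_test,
    proximity_flag,
    two_proportion_chi2,
)
from lofsplice.intervals import GenomicInterval, ScoredInterval, TranscriptModel


def _three_exon_gene(strand="+", gene_id="g1", offset=10_000):
    """Exons [0,200) [600,800) [1200,1400) + offset; CDS mid-exon1..mid-exon3."""
    iv = lambda s, e: GenomicInterval("1", offset + s, offset + e, strand)
    cds = [iv(100, 200), iv(600, 800), iv(1200, 1300)]
    return TranscriptModel(
        f"{gene_id}_t1", gene_id,
        exons=[iv(0, 200), iv(600, 800), iv(1200, 1400)],
        cds=cds,
    )


class TestBuildPartition:
    def test_plus_strand_layout(self):
        part = build_partition([_three_exon_gene("+")])
        feats = part.genes["g1"]
        assert [(i.start, i.end) for i in feats["five_prime_utr"]] == [(10_000, 10_100)]
        assert [(i.start, i.end) for i in feats["cds"]] == [
            (10_100, 10_200), (10_600, 10_800), (11_200, 11_300)]
        assert [(i.start, i.end) for i in feats["intron"]] == [
            (10_200, 10_600), (10_800, 11_200)]
        # annotated 3'UTR plus the 5 kb downstream extension
        assert [(i.start, i.end) for i in feats["three_prime_utr_ext"]] == [
            (11_300, 11_400), (11_400, 16_400)]
        (prom,) = feats["promoter_antisense"]
        assert (prom.start, prom.end, prom.strand) == (5_000, 10_000, "-")

    def test_extension_clamped_to_contig(self):
        part = build_partition([_three_exon_gene("+")], contig_lengths={"1": 12_000})
        ext = part.genes["g1"]["three_prime_utr_ext"][-1]
        assert ext.end == 12_000

    def test_minus_strand_promoter_inverted(self):
        part = build_partition([_three_exon_gene("-")])
        feats = part.genes["g1"]
        (prom,) = feats["promoter_antisense"]
        # gene on '-': promoter is downstream in genome coordinates, strand '+'
        assert (prom.start, prom.end, prom.strand) == (11_400, 16_400, "+")
        assert [(i.start, i.end) for i in feats["five_prime_utr"]] == [(11_300, 11_400)]

    def test_polya_assigns_utr_side(self):
        polya = [GenomicInterval("1", 10_050, 10_060, "+")]
        part = build_partition([_three_exon_gene("+")], polya=polya)
        # the exon-1 UTR overlaps the polyA site, so it is called 3'UTR
        assert not part.genes["g1"]["five_prime_utr"]

    def test_noncoding_gene_skipped_with_warning(self):
        iv = GenomicInterval("1", 0, 100, "+")
        m = TranscriptModel("t", "g", exons=[iv])
        with pytest.warns(UserWarning, match="no coding"):
            part = build_partition([m])
        assert "g" not in part.genes


class TestMatchNull:
    def _results(self, ids, p, id_col="gene_id"):
        return pd.DataFrame({id_col: ids, "p": p, "fdr": p})

    def test_bounds_hold_on_randomized_inputs(self, rng):
        for _ in range(10):
            test_ids = [f"t{i}" for i in range(30)]
            cand_ids = [f"c{i}" for i in range(200)]
            all_ids = test_ids + cand_ids
            lengths = {f: float(v) for f, v in zip(all_ids, rng.uniform(50, 5000, len(all_ids)))}
            expr = {f: float(v) for f, v in zip(all_ids, rng.lognormal(4, 1, len(all_ids)))}
            ko = self._results(all_ids, rng.uniform(size=len(all_ids)))
            nls = self._results(all_ids, rng.uniform(size=len(all_ids)))
            try:
                null = match_null(test_ids, ko, nls, lengths, expr)
            except ValueError:
                continue
            t_len = np.array([lengths[t] for t in test_ids])
            t_expr = np.array([expr[t] for t in test_ids])
            l_lo, l_hi = np.quantile(t_len, [0.25, 0.75])
            e_lo, e_hi = np.quantile(t_expr, [0.25, 0.75])
            for f in null:
                assert l_lo <= lengths[f] <= l_hi
                assert e_lo <= expr[f] <= e_hi
                assert f not in test_ids

    def test_boundary_candidate_included_and_sig_excluded(self):
        test_ids = ["t0", "t1", "t2", "t3"]
        lengths = {"t0": 100, "t1": 120, "t2": 180, "t3": 200,
                   "c_edge": 0.0, "c_sig": 150, "c_ok": 150}
        lengths["c_edge"] = np.quantile([100, 120, 180, 200], 0.75)  # exactly Q3
        expr = {k: 10.0 for k in lengths}
        ids = test_ids + ["c_edge", "c_sig", "c_ok"]
        ko = self._results(ids, [0.001] * 4 + [0.5, 0.01, 0.5])
        nls = self._results(ids, [0.001] * 4 + [0.5, 0.5, 0.5])
        null = match_null(test_ids, ko, nls, lengths, expr)
        assert "c_edge" in null  # closed bounds
        assert "c_sig" not in null  # p = 0.01 in one model
        assert "c_ok" in null

    def test_empty_null_errors(self):
        ids = ["t0", "t1", "t2"]
        ko = self._results(ids, [0.001] * 3)
        nls = self._results(ids, [0.001] * 3)
        with pytest.raises(ValueError, match="relax"):
            match_null(ids[:2], ko, nls, {i: 100 for i in ids}, {i: 1.0 for i in ids})


class TestOverlapTest:
    def test_strand_specific(self):
        region = [GenomicInterval("1", 100, 200, "+")]
        null = [GenomicInterval("1", 500, 600, "+")]
        opposite = [GenomicInterval("1", 150, 160, "-")]
        res = overlap_test(region, null, opposite)
        assert res.prop_test == 0.0
        same = [GenomicInterval("1", 150, 160, "+")]
        assert overlap_test(region, null, same).prop_test == 1.0

    def test_equal_proportions_near_one_p(self, rng):
        regions = [GenomicInterval("1", 1000 * i, 1000 * i + 500, "+") for i in range(40)]
        clusters = [GenomicInterval("1", 1000 * i + 10, 1000 * i + 20, "+")
                    for i in range(0, 40, 2)]
        res = overlap_test(regions[:20], regions[20:], clusters)
        assert res.p > 0.9

    def test_chi2_matches_closed_form(self):
        """30/100 vs 10/100 checked against the textbook two-proportion
        chi-square formula."""
        chi2, p = two_proportion_chi2(30, 100, 10, 100)
        x1, n1, x2, n2 = 30, 100, 10, 100
        phat = (x1 + x2) / (n1 + n2)
        expected_chi2 = ((x1 / n1 - x2 / n2) ** 2
                         / (phat * (1 - phat) * (1 / n1 + 1 / n2)))
        assert chi2 == pytest.approx(expected_chi2, abs=1e-10)
        assert p == pytest.approx(stats.chi2.sf(expected_chi2, 1), abs=1e-12)

    def test_chi2_matches_permutation(self, rng):
        """Permutation of overlap labels reproduces the chi-square p within
        Monte-Carlo error on a small fixture."""
        x1, n1, x2, n2 = 60, 200, 45, 200
        _, p = two_proportion_chi2(x1, n1, x2, n2)
        flags = np.zeros(n1 + n2, dtype=bool)
        flags[:x1 + x2] = True
        obs = abs(x1 / n1 - x2 / n2)
        n_perm = 10_000
        gt = eq = 0
        for _ in range(n_perm):
            rng.shuffle(flags)
            d = abs(flags[:n1].mean() - flags[n1:].mean())
            if d > obs + 1e-12:
                gt += 1
            elif abs(d - obs) < 1e-12:
                eq += 1
        # mid-p counting: the continuous chi-square tail corresponds to half
        # the discrete permutation atom at the observed value
        p_perm = (gt + 0.5 * eq) / n_perm
        assert abs(p_perm - p) < 0.02

    def test_empty_test_set_errors(self):
        with pytest.raises(ValueError, match="empty"):
            overlap_test([], [], [])


class TestFeatureProfile:
    def test_construction_oracle(self, rng):
        """Clusters placed only in introns of down-regulated genes light up
        exactly the intron/down test."""
        genes = {}
        models = []
        for i in range(60):
            m = _three_exon_gene("+", gene_id=f"g{i}", offset=50_000 * i)
            models.append(m)
        part = build_partition(models)
        down = [f"g{i}" for i in range(20)]
        up = [f"g{i}" for i in range(20, 40)]
        null = [f"g{i}" for i in range(40, 60)]
        clusters = []
        for g in down:
            intron = part.genes[g]["intron"][0]
            clusters.append(GenomicInterval(intron.chrom, intron.start + 5,
                                            intron.start + 30, intron.strand))
        results = feature_profile(up, down, null, part, clusters)
        by_name = {r.test_name: r for r in results}
        assert by_name["intron/down"].p_bonferroni < 0.05
        for name, r in by_name.items():
            if name != "intron/down":
                assert r.p_bonferroni > 0.5

    def test_bonferroni_is_min_one_mp(self):
        from lofsplice.enrichment import EnrichmentResult, bonferroni

        results = [EnrichmentResult(f"t{i}", 10, 10, 0.5, 0.5, 0.0, 0.2)
                   for i in range(10)]
        out = bonferroni(results)
        assert all(r.p_bonferroni == pytest.approx(min(1.0, 10 * r.p)) for r in out)


class TestConservation:
    def test_median_values(self):
        region = [GenomicInterval("1", 0, 100)]
        uniform = [ScoredInterval(GenomicInterval("1", 0, 100), 1.2)]
        assert median_conservation(region, uniform)[0] == pytest.approx(1.2)
        half = [ScoredInterval(GenomicInterval("1", 0, 50), 0.0),
                ScoredInterval(GenomicInterval("1", 50, 100), 2.0)]
        assert median_conservation(region, half)[0] == pytest.approx(1.0)
        assert np.isnan(median_conservation(region, [])[0])

    def test_split_invariance(self, rng):
        """Splitting a scored interval into adjacent same-score pieces does
        not change any region median."""
        regions = [GenomicInterval("1", int(s), int(s) + 120)
                   for s in rng.integers(0, 800, 10)]
        whole = [ScoredInterval(GenomicInterval("1", i * 100, (i + 1) * 100),
                                float(v))
                 for i, v in enumerate(rng.normal(size=10))]
        split = []
        for si in whole:
            mid = (si.interval.start + si.interval.end) // 2
            split.append(ScoredInterval(
                GenomicInterval("1", si.interval.start, mid), si.score))
            split.append(ScoredInterval(
                GenomicInterval("1", mid, si.interval.end), si.score))
        np.testing.assert_allclose(
            median_conservation(regions, whole),
            median_conservation(regions, split), equal_nan=True)

    def test_threshold_strictly_greater(self):
        region = [GenomicInterval("1", 0, 10)]
        null = [GenomicInterval("1", 100, 110)]
        scores = [ScoredInterval(GenomicInterval("1", 0, 10), 0.5),
                  ScoredInterval(GenomicInterval("1", 100, 110), 0.0)]
        res = conservation_test(region, null, scores, threshold=0.5)
        assert res.prop_test == 0.0  # median exactly 0.5 is not counted

    def test_separated_sets(self):
        test = [GenomicInterval("1", i * 20, i * 20 + 10) for i in range(10)]
        null = [GenomicInterval("1", 1000 + i * 20, 1010 + i * 20) for i in range(10)]
        scores = ([ScoredInterval(r, 1.5) for r in test]
                  + [ScoredInterval(r, 0.0) for r in null])
        res = conservation_test(test, null, scores)
        assert res.prop_test == 1.0 and res.prop_null == 0.0

    def test_all_na_errors(self):
        with pytest.raises(ValueError, match="NA"):
            conservation_test([GenomicInterval("1", 0, 10)],
                              [GenomicInterval("1", 20, 30)], [])


class TestProximity:
    def test_flags(self):
        intron = [GenomicInterval("1", 10_000, 12_000, "+")]
        inside = [GenomicInterval("1", 10_500, 10_550, "+")]
        near = [GenomicInterval("1", 9_400, 9_500, "+")]  # 500 bases upstream
        far = [GenomicInterval("1", 900, 950, "+")]
        assert proximity_flag(intron, inside)[0] == "overlapping"
        assert proximity_flag(intron, near, distance=1_000)[0] == "within_distance"
        assert proximity_flag(intron, far, distance=1_000)[0] == "none"

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            proximity_flag([], [], distance=-1)
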