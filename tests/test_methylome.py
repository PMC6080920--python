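"""Differential methylation calling, feature annotation, and permutation
enrichment, each checked against independent small-scale oracles."""

import math

import numpy as np
import pytest
from scipy import stats

from mammomics.genome_io import AnnotationSet, CpGSite, GeneModel, GenomicInterval
from mammomics.methylome import (
    _summarize_enrichment,
    annotate_site_features,
    benjamini_hochberg,
    call_dmcs,
    permutation_feature_enrichment,
    select_top_variance,
)


def fisher_two_sided_by_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Exact two-sided Fisher p by summing hypergeometric point masses no
    larger than the observed one (relative tolerance as in R/scipy)."""
    row1, col1, n = a + b, a + c, a + b + c + d
    kmin, kmax = max(0, row1 + col1 - n), min(row1, col1)
    pmf = {k: math.comb(col1, k) * math.comb(n - col1, row1 - k) / math.comb(n, row1)
           for k in range(kmin, kmax + 1)}
    p_obs = pmf[a]
    return min(1.0, sum(p for p in pmf.values() if p <= p_obs * (1 + 1e-7)))


def _site(m1, u1, m2, u2):
    return CpGSite("chr1", 100, "+", meth=np.array([m1, m2]), unmeth=np.array([u1, u2]))


class TestCallDmcs:
    LABELS = ["basal", "luminal"]

    def test_example_table_matches_enumeration(self):
        site = _site(5, 95, 30, 70)
        (dmc,) = call_dmcs([site], self.LABELS, delta_min=0.0, q_max=1.1)
        assert dmc.delta_beta == pytest.approx(-0.25)
        assert dmc.direction == "hypo_in_basal"
        assert dmc.p == pytest.approx(fisher_two_sided_by_enumeration(5, 95, 30, 70), rel=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_pvalues_match_enumeration_small_tables(self, seed):
        rng = np.random.default_rng(seed)
        sites = []
        tables = []
        for _ in range(20):
            a, b, c, d = rng.integers(0, 16, size=4)  # totals <= 60
            if a + b == 0 or c + d == 0:
                continue
            sites.append(_site(a, b, c, d))
            tables.append((a, b, c, d))
        dmcs = call_dmcs(sites, self.LABELS, delta_min=0.0, q_max=1.1)
        assert len(dmcs) == len(sites)
        for dmc, tab in zip(dmcs, tables):
            assert dmc.p == pytest.approx(
                fisher_two_sided_by_enumeration(*tab), rel=1e-7
            )

    def test_identical_groups_never_called(self):
        dmcs = call_dmcs([_site(10, 10, 10, 10)], self.LABELS)
        assert dmcs == []

    def test_delta_threshold_is_inclusive_at_exactly_015(self):
        below = call_dmcs([_site(0, 1000, 149, 851)], self.LABELS)
        assert below == []  # |delta| = 0.149, however significant
        at = call_dmcs([_site(0, 1000, 150, 850)], self.LABELS)
        assert len(at) == 1 and at[0].delta_beta == pytest.approx(-0.15)

    def test_direction_follows_lower_beta_group(self):
        (dmc,) = call_dmcs([_site(80, 20, 20, 80)], self.LABELS, delta_min=0.0, q_max=1.1)
        assert dmc.direction == "hypo_in_luminal"
        assert dmc.delta_beta > 0

    def test_zero_coverage_group_skipped(self):
        sites = [_site(0, 0, 10, 10), _site(90, 10, 10, 90)]
        dmcs = call_dmcs(sites, self.LABELS, delta_min=0.0, q_max=1.1)
        assert len(dmcs) == 1

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            call_dmcs([_site(1, 1, 1, 1)], ["basal", "basal"])

    def test_replicates_are_pooled_within_group(self):
        site = CpGSite(
            "chr1", 50, "+",
            meth=np.array([3, 2, 15, 15]),
            unmeth=np.array([47, 48, 35, 35]),
        )
        (dmc,) = call_dmcs(
            [site], ["basal", "basal", "luminal", "luminal"], delta_min=0.0, q_max=1.1
        )
        assert dmc.delta_beta == pytest.approx(5 / 100 - 30 / 100)
        assert dmc.p == pytest.approx(
            fisher_two_sided_by_enumeration(5, 95, 30, 70), rel=1e-7
        )


class TestBenjaminiHochberg:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            benjamini_hochberg([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(benjamini_hochberg([0.2]), [0.2])

    def test_equal_ps_unchanged(self):
        np.testing.assert_allclose(benjamini_hochberg([0.04] * 5), [0.04] * 5)

    def test_order_preserved(self):
        q = benjamini_hochberg([0.9, 0.001, 0.5])
        assert q[1] < q[2] < q[0]

    @pytest.mark.parametrize("bad", [[-0.1], [1.5], [float("nan")]])
    def test_domain_error(self, bad):
        with pytest.raises(ValueError):
            benjamini_hochberg(bad)


class TestSelectTopVariance:
    def test_count_is_ceiling_of_fraction(self):
        rng = np.random.default_rng(0)
        m = rng.random((100, 4))
        assert len(select_top_variance(m, 0.15)) == 15
        assert len(select_top_variance(m, 0.151)) == 16

    def test_constant_rows_lose_to_variable_rows(self):
        m = np.array([[0.5, 0.5, 0.5], [0.1, 0.5, 0.9]])
        assert select_top_variance(m, 0.5).tolist() == [1]

    def test_higher_variance_wins(self):
        m = np.array([[0.3, 0.5], [0.2, 0.6]])  # variances 0.02, 0.08
        assert select_top_variance(m, 0.5).tolist() == [1]

    def test_fraction_domain(self):
        with pytest.raises(ValueError):
            select_top_variance(np.ones((4, 2)), 0.0)
        with pytest.raises(ValueError):
            select_top_variance(np.ones((4, 2)), 1.2)


@pytest.fixture(scope="module")
def toy_annotation():
    chrom = "chr1"
    plus = GeneModel(
        "gp", "gp",
        body=GenomicInterval(chrom, 10_000, 16_000, "+"),
        exons=(
            GenomicInterval(chrom, 10_000, 10_500, "+"),
            GenomicInterval(chrom, 15_500, 16_000, "+"),
        ),
    )
    minus = GeneModel(
        "gm", "gm",
        body=GenomicInterval(chrom, 30_000, 34_000, "-"),
        exons=(GenomicInterval(chrom, 30_000, 30_500, "-"),),
    )
    cgi = [GenomicInterval(chrom, 50_000, 51_000)]
    return AnnotationSet(genes=[plus, minus], cgi=cgi)


class TestAnnotateSiteFeatures:
    def classify(self, ann, pos, chrom="chr1"):
        return annotate_site_features([(chrom, pos)], ann)[0]

    def test_upstream_of_plus_tss_is_promoter(self, toy_annotation):
        assert self.classify(toy_annotation, 9_000)[0] == "promoter"

    def test_upstream_of_minus_tss_is_promoter(self, toy_annotation):
        assert self.classify(toy_annotation, 35_000)[0] == "promoter"

    def test_exon_and_intron_and_intergenic(self, toy_annotation):
        assert self.classify(toy_annotation, 10_200)[0] == "exon"
        assert self.classify(toy_annotation, 12_000)[0] == "intron"
        assert self.classify(toy_annotation, 60_000)[0] == "intergenic"

    def test_promoter_beyond_2500_is_not_promoter(self, toy_annotation):
        assert self.classify(toy_annotation, 7_000)[0] == "intergenic"

    def test_cgi_context_bands(self, toy_annotation):
        assert self.classify(toy_annotation, 50_500)[1] == "cgi"
        assert self.classify(toy_annotation, 52_000)[1] == "shore"  # 1001 bp
        assert self.classify(toy_annotation, 53_999)[1] == "shelf"  # 3000 bp
        assert self.classify(toy_annotation, 56_000)[1] == "open_sea"  # 5001 bp

    def test_unknown_chromosome_falls_back(self, toy_annotation):
        assert self.classify(toy_annotation, 100, chrom="chrZ") == (
            "intergenic",
            "open_sea",
        )


class TestPermutationEnrichment:
    def test_at_the_mean_fold_one_p_half(self):
        e = _summarize_enrichment("promoter", 10, 10.0, 2.0)
        assert e.fold_change == pytest.approx(1.0)
        assert e.p == pytest.approx(0.5)

    def test_negative_reciprocal_fold(self):
        assert _summarize_enrichment("x", 20, 10.0, 2.0).fold_change == pytest.approx(2.0)
        assert _summarize_enrichment("x", 5, 10.0, 2.0).fold_change == pytest.approx(-2.0)

    def test_upper_tail_normal_p_at_z5(self):
        e = _summarize_enrichment("x", 20, 10.0, 2.0)
        assert e.p == pytest.approx(stats.norm.sf(5.0), rel=1e-9)
        assert e.p == pytest.approx(2.8665e-7, rel=1e-3)
        assert e.log_p == pytest.approx(math.log(e.p), rel=1e-9)

    def test_log_p_finite_far_in_the_tail(self):
        e = _summarize_enrichment("x", 5000, 10.0, 2.0)
        assert math.isfinite(e.log_p) and e.log_p < -745
        assert e.p > 0

    def test_degenerate_zero_sd(self):
        at_mean = _summarize_enrichment("x", 10, 10.0, 0.0)
        assert at_mean.p == 1.0 and not at_mean.degenerate
        off_mean = _summarize_enrichment("x", 12, 10.0, 0.0)
        assert off_mean.degenerate and math.isfinite(off_mean.log_p)

    def test_expected_mean_approaches_dmc_count_times_coverage(self, toy_annotation):
        # promoter of the + gene covers [7500, 10000); build a background with
        # a known fraction of sites inside it
        rng = np.random.default_rng(1)
        inside = [("chr1", int(p)) for p in rng.integers(7_500, 10_000, 250)]
        outside = [("chr1", int(p)) for p in rng.integers(60_000, 90_000, 750)]
        background = sorted(set(inside + outside))
        frac = sum(7_500 <= p < 10_000 for _, p in background) / len(background)
        dmcs = [background[i] for i in rng.choice(len(background), 100, replace=False)]
        enr = permutation_feature_enrichment(
            dmcs, background, toy_annotation, n_perm=600, seed=7
        )
        prom = next(e for e in enr if e.feature == "promoter")
        assert prom.expected_mean == pytest.approx(100 * frac, rel=0.1)

    def test_complementing_the_dmc_set_flips_fold_sign(self, toy_annotation):
        rng = np.random.default_rng(2)
        inside = [("chr1", int(p)) for p in rng.integers(7_500, 10_000, 300)]
        outside = [("chr1", int(p)) for p in rng.integers(60_000, 90_000, 300)]
        background = sorted(set(inside + outside))
        enriched = [p for p in background if p[1] < 10_000][:150]
        depleted = [p for p in background if p[1] >= 60_000][:150]
        e1 = permutation_feature_enrichment(enriched, background, toy_annotation, 300, seed=3)
        e2 = permutation_feature_enrichment(depleted, background, toy_annotation, 300, seed=3)
        p1 = next(e for e in e1 if e.feature == "promoter")
        p2 = next(e for e in e2 if e.feature == "promoter")
        assert p1.fold_change > 1 and p2.fold_change < -1

    def test_deterministic_given_seed(self, toy_annotation):
        rng = np.random.default_rng(3)
        background = sorted(
            {("chr1", int(p)) for p in rng.integers(0, 90_000, 500)}
        )
        dmcs = background[::5]
        runs = [
            permutation_feature_enrichment(dmcs, background, toy_annotation, 100, seed=9)
            for _ in range(2)
        ]
        assert [(e.p, e.fold_change) for e in runs[0]] == [
            (e.p, e.fold_change) for e in runs[1]
        ]

    def test_dmcs_must_be_subset_of_background(self, toy_annotation):
        with pytest.raises(ValueError):
            permutation_feature_enrichment(
                [("chr1", 42)], [("chr1", 7)], toy_annotation, 10, seed=0
            )

    def test_more_dmcs_than_background_rejected(self, toy_annotation):
        bg = [("chr1", 7)]
        with pytest.raises(ValueError):
            permutation_feature_enrichment(
                [("chr1", 7), ("chr1", 8)], bg, toy_annotation, 10, seed=0
            )
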