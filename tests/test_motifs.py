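"""PWM scanning, TFBS enrichment, and proximal-gene integration."""

import math

import numpy as np
import pandas as pd
import pytest

from mammomics.chromatin import Peak
from mammomics.genome_io import (
    PWM,
    AnnotationSet,
    GeneModel,
    GenomicInterval,
    open_genome,
    reverse_complement,
)
from mammomics.motifs import (
    distance_to_nearest_peak,
    dmc_windows,
    index_peaks,
    motif_enrichment,
    proximal_gene_integration,
    scan_pwm,
)


def write_fasta(path, seqs: dict[str, str]):
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    return open_genome(path)


def sharp_pwm(consensus: str, main=0.97, motif_id="m") -> PWM:
    mat = np.full((len(consensus), 4), (1 - main) / 3)
    for j, b in enumerate(consensus):
        mat[j, "ACGT".index(b)] = main
    return PWM(motif_id, mat)


class TestScanPwm:
    def test_consensus_score_closed_form(self, tmp_path):
        pwm = sharp_pwm("ACGT", main=0.97)
        genome = write_fasta(tmp_path / "g.fa", {"chr1": "TTTTTACGTTTTTT"})
        hits = scan_pwm([GenomicInterval("chr1", 0, 14)], genome, pwm)
        expected = 4 * math.log2(0.97 / 0.25)  # ~7.82 bits
        best = max(hits, key=lambda h: h.score)
        assert best.score == pytest.approx(expected, rel=1e-9)
        assert (best.site.start, best.site.end) == (5, 9)

    def test_uniform_pwm_scores_zero_everywhere(self, tmp_path):
        pwm = PWM("u", np.full((4, 4), 0.25), score_threshold=0.0)
        genome = write_fasta(tmp_path / "g.fa", {"chr1": "ACGTACGTAC"})
        hits = scan_pwm([GenomicInterval("chr1", 0, 10)], genome, pwm)
        assert hits and all(h.score == 0.0 for h in hits)

    def test_palindromic_motif_hits_both_strands_identically(self, tmp_path):
        consensus = "ACGT"  # reverse complement of itself
        assert reverse_complement(consensus) == consensus
        pwm = sharp_pwm(consensus)
        genome = write_fasta(tmp_path / "g.fa", {"chr1": "GGACGTGGGACGTGG"})
        hits = scan_pwm([GenomicInterval("chr1", 0, 15)], genome, pwm)
        fwd = {(h.site.start, h.site.end) for h in hits if h.strand == "+"}
        rev = {(h.site.start, h.site.end) for h in hits if h.strand == "-"}
        assert fwd == rev == {(2, 6), (9, 13)}

    def test_reverse_strand_hit_reported_on_forward_axis(self, tmp_path):
        pwm = sharp_pwm("AACCG")
        genome = write_fasta(
            tmp_path / "g.fa", {"chr1": "TTTT" + reverse_complement("AACCG") + "TTTT"}
        )
        hits = scan_pwm([GenomicInterval("chr1", 0, 13)], genome, pwm)
        (hit,) = [h for h in hits if h.strand == "-"]
        assert (hit.site.start, hit.site.end) == (4, 9)

    def test_ambiguous_region_skipped(self, tmp_path):
        pwm = sharp_pwm("ACGT")
        genome = write_fasta(tmp_path / "g.fa", {"chr1": "NNNNNNNNACGT"})
        hits = scan_pwm([GenomicInterval("chr1", 0, 12)], genome, pwm)
        assert hits == []  # 8/12 ambiguous > 50%

    def test_out_of_bounds_region_rejected(self, tmp_path):
        genome = write_fasta(tmp_path / "g.fa", {"chr1": "ACGTACGT"})
        with pytest.raises(ValueError):
            scan_pwm([GenomicInterval("chr1", 0, 100)], genome, sharp_pwm("ACGT"))


class TestDmcWindows:
    def test_centered_window(self):
        (w,) = dmc_windows([("chr1", 1000)])
        assert (w.start, w.end) == (850, 1150)

    def test_clipped_at_chromosome_start(self):
        (w,) = dmc_windows([("chr1", 50)])
        assert (w.start, w.end) == (0, 200)

    def test_one_window_per_dmc(self):
        assert len(dmc_windows([("chr1", p) for p in range(300, 900, 100)])) == 6

    def test_positive_flank_required(self):
        with pytest.raises(ValueError):
            dmc_windows([("chr1", 10)], flank=0)


def hypergeom_upper_tail_enumeration(k_t, n_t, k_b, n_b) -> float:
    """P(X >= k_t) drawing n_t from n_t+n_b with k_t+k_b successes (exact)."""
    M, K, n = n_t + n_b, k_t + k_b, n_t
    total = math.comb(M, n)
    return sum(
        math.comb(K, k) * math.comb(M - K, n - k)
        for k in range(k_t, min(K, n) + 1)
    ) / total


class TestMotifEnrichment:
    def _genome_with_rates(self, tmp_path, rng, consensus, n_t, rate_t, n_b, rate_b):
        """Target/background windows with the consensus planted at set rates."""
        bases = np.array(list("ACGT"))
        seq = list("".join(bases[rng.integers(0, 4, 60 * (n_t + n_b))]))
        target, background = [], []
        planted_t = planted_b = 0
        for i in range(n_t + n_b):
            start, width = 60 * i, 60
            iv = GenomicInterval("chr1", start, start + width)
            plant = rng.random() < (rate_t if i < n_t else rate_b)
            if plant:
                off = start + int(rng.integers(0, width - len(consensus)))
                seq[off : off + len(consensus)] = list(consensus)
                if i < n_t:
                    planted_t += 1
                else:
                    planted_b += 1
            (target if i < n_t else background).append(iv)
        genome = write_fasta(tmp_path / "g.fa", {"chr1": "".join(seq)})
        return genome, target, background, planted_t, planted_b

    def test_enrichment_score_examples(self, tmp_path):
        rng = np.random.default_rng(0)
        consensus = "TGTTTACTTA"
        genome, target, background, pt, pb = self._genome_with_rates(
            tmp_path, rng, consensus, 80, 0.5, 400, 0.25
        )
        (res,) = motif_enrichment(target, background, [sharp_pwm(consensus, 0.91)], genome)
        # percentages reflect exactly the planted windows (sharp threshold)
        assert res.pct_target == pytest.approx(100 * pt / 80)
        assert res.pct_background == pytest.approx(100 * pb / 400)
        assert res.enrichment == pytest.approx(
            math.log2((pt / 80) / (pb / 400)), rel=1e-12
        )
        k_t, k_b = pt, pb
        assert res.p == pytest.approx(
            hypergeom_upper_tail_enumeration(k_t, 80, k_b, 400), rel=1e-9
        )

    def test_equal_percentages_give_zero(self, tmp_path):
        rng = np.random.default_rng(1)
        consensus = "AGATAAGAGC"
        genome, target, background, *_ = self._genome_with_rates(
            tmp_path, rng, consensus, 50, 1.0, 50, 1.0
        )
        (res,) = motif_enrichment(target, background, [sharp_pwm(consensus, 0.91)], genome)
        assert res.enrichment == 0.0

    def test_antisymmetric_under_target_background_swap(self, tmp_path):
        rng = np.random.default_rng(2)
        consensus = "AACCGGAAGT"
        genome, target, background, *_ = self._genome_with_rates(
            tmp_path, rng, consensus, 60, 0.6, 60, 0.2
        )
        pwms = [sharp_pwm(consensus, 0.91)]
        (fwd,) = motif_enrichment(target, background, pwms, genome)
        (rev,) = motif_enrichment(background, target, pwms, genome)
        assert fwd.enrichment == pytest.approx(-rev.enrichment, rel=1e-12)

    def test_planted_contrast_recovers_log2_3(self, tmp_path):
        rng = np.random.default_rng(3)
        consensus = "TGTTTACTTA"
        genome, target, background, *_ = self._genome_with_rates(
            tmp_path, rng, consensus, 150, 0.6, 150, 0.2
        )
        (res,) = motif_enrichment(target, background, [sharp_pwm(consensus, 0.91)], genome)
        assert res.enrichment == pytest.approx(math.log2(3), abs=0.3)
        assert res.q < 0.01

    def test_zero_background_percentage_flagged(self, tmp_path):
        rng = np.random.default_rng(4)
        consensus = "TGTTTACTTA"
        genome, target, background, *_ = self._genome_with_rates(
            tmp_path, rng, consensus, 20, 1.0, 20, 0.0
        )
        (res,) = motif_enrichment(target, background, [sharp_pwm(consensus, 0.91)], genome)
        assert res.unbounded and math.isinf(res.enrichment)

    def test_motif_without_any_hits_dropped(self, tmp_path):
        genome = write_fasta(tmp_path / "g.fa", {"chr1": "AC" * 200})
        target = [GenomicInterval("chr1", 0, 50)]
        background = [GenomicInterval("chr1", 100, 150)]
        assert motif_enrichment(target, background, [sharp_pwm("TTTTTTTTGG", 0.97)], genome) == []

    @pytest.mark.parametrize("seed", range(3))
    def test_hypergeometric_p_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n_t, n_b = int(rng.integers(5, 100)), int(rng.integers(5, 100))  # <= 200
        k_t, k_b = int(rng.integers(0, n_t + 1)), int(rng.integers(0, n_b + 1))
        from scipy import stats

        p_impl = float(stats.hypergeom.sf(k_t - 1, n_t + n_b, k_t + k_b, n_t))
        assert p_impl == pytest.approx(
            hypergeom_upper_tail_enumeration(k_t, n_t, k_b, n_b), rel=1e-9
        )


class TestDistanceToPeak:
    def test_overlap_zero_gap_and_far(self):
        peaks = index_peaks([Peak(GenomicInterval("chr1", 100, 200), "basal")])
        assert distance_to_nearest_peak(GenomicInterval("chr1", 150, 160), peaks) == 0
        assert distance_to_nearest_peak(GenomicInterval("chr1", 400, 410), peaks) == 200
        assert distance_to_nearest_peak(GenomicInterval("chr2", 0, 10), peaks) == math.inf

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        peaks = [
            Peak(GenomicInterval("chr1", int(s), int(s) + int(rng.integers(1, 100))), "b")
            for s in rng.integers(0, 10_000, 500)
        ]
        index = index_peaks(peaks)
        for _ in range(50):
            s = int(rng.integers(0, 10_000))
            site = GenomicInterval("chr1", s, s + 10)
            brute = min(site.distance(p.interval) for p in peaks)
            assert distance_to_nearest_peak(site, index) == brute


class TestProximalGeneIntegration:
    def _setup(self):
        genes = [
            GeneModel("coding", "coding",
                      body=GenomicInterval("chr1", 10_000, 14_000, "+"),
                      exons=(GenomicInterval("chr1", 10_000, 14_000, "+"),)),
            GeneModel("coding2", "coding2",
                      body=GenomicInterval("chr1", 30_000, 34_000, "+"),
                      exons=(GenomicInterval("chr1", 30_000, 34_000, "+"),)),
            GeneModel("noncoding", "noncoding",
                      body=GenomicInterval("chr1", 50_000, 54_000, "+"),
                      exons=(GenomicInterval("chr1", 50_000, 54_000, "+"),),
                      is_protein_coding=False),
        ]
        ann = AnnotationSet(genes=genes, cgi=[])
        expression = pd.DataFrame(
            {"gene_id": ["coding", "coding2"], "rna_log2fc": [1.0, 3.0], "q": [0.01, 0.5]}
        )
        return ann, expression

    def _hit(self, motif, start):
        from mammomics.motifs import MotifHit

        return MotifHit(motif, GenomicInterval("chr1", start, start + 10), "+", 10.0)

    def test_distance_threshold_and_mean_fc(self):
        ann, expression = self._setup()
        peaks = [
            Peak(GenomicInterval("chr1", 11_000, 11_500), "basal"),
            Peak(GenomicInterval("chr1", 31_000, 31_500), "basal"),
        ]
        hits = [
            self._hit("m1", 10_790),  # 200 bp from first peak -> kept
            self._hit("m1", 31_800),  # 300 bp from second peak -> dropped
            self._hit("m1", 31_100),  # overlapping second peak -> kept
        ]
        (summary,), multi = proximal_gene_integration(hits, peaks, ann, expression)
        assert summary.motif_id == "m1"
        assert {g["gene_id"] for g in summary.genes} == {"coding", "coding2"}
        assert summary.mean_rna_log2fc == pytest.approx(2.0)  # (+1 + 3) / 2
        flags = {g["gene_id"]: g["significant"] for g in summary.genes}
        assert flags == {"coding": True, "coding2": False}

    def test_non_coding_and_missing_expression_excluded(self):
        ann, expression = self._setup()
        peaks = [Peak(GenomicInterval("chr1", 50_500, 51_000), "basal")]
        hits = [self._hit("m1", 50_600)]  # inside the non-coding gene only
        summaries, multi = proximal_gene_integration(hits, peaks, ann, expression)
        assert summaries == [] and multi == {}

    def test_distinct_motif_count_per_gene(self):
        ann, expression = self._setup()
        peaks = [Peak(GenomicInterval("chr1", 11_000, 11_500), "basal")]
        hits = [self._hit(m, 11_100) for m in ("m1", "m2", "m3")]
        _, multi = proximal_gene_integration(hits, peaks, ann, expression)
        assert multi == {"coding": 3}

    def test_empty_peaks_drop_everything(self):
        ann, expression = self._setup()
        summaries, multi = proximal_gene_integration(
            [self._hit("m1", 11_000)], [], ann, expression
        )
        assert summaries == [] and multi == {}
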