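"""PWM scanning and transcription-factor binding-site (TFBS) enrichment.

Scanning scores every window on both strands as the sum of per-position
log2(p_base / background_base); a hit is a window scoring at or above the
motif's threshold. The enrichment score for a motif between a target and a
background region set is log2 of the ratio of the percentages of regions
containing >= 1 hit, with a hypergeometric tail p-value. Hypomethylated
TFBSs are integrated with open chromatin by keeping hits within 250 bp of
an ATAC-seq peak and mapping them to protein-coding genes present in the
expression data.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .chromatin import Peak, assign_peaks_to_genes
from .genome_io import (
    BASES,
    PWM,
    AnnotationSet,
    GenomicInterval,
    fetch_sequence,
)
from .methylome import DMC, benjamini_hochberg

logger = logging.getLogger(__name__)

_CHAR_TO_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _CHAR_TO_CODE[ord(_b)] = _i


@dataclass(frozen=True)
class MotifHit:
    motif_id: str
    site: GenomicInterval
    strand: str
    score: float  # log2-odds (bits)


@dataclass
class MotifEnrichment:
    motif_id: str
    pct_target: float
    pct_background: float
    enrichment: float  # log2(pct_target / pct_background)
    p: float
    q: float = math.nan
    unbounded: bool = False  # background percentage was zero


@dataclass
class ProximalGeneSummary:
    """Expression behaviour of genes proximal to one motif's TFBSs."""

    motif_id: str
    genes: list[dict] = field(default_factory=list)
    mean_rna_log2fc: float = math.nan
    n_genes: int = 0


def _encode(seq: str) -> np.ndarray:
    return _CHAR_TO_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _window_scores(codes: np.ndarray, lod: np.ndarray) -> np.ndarray:
    """Score every length-L window; windows containing non-ACGT score -inf."""
    L = lod.shape[0]
    n_win = len(codes) - L + 1
    if n_win <= 0:
        return np.empty(0)
    scores = np.zeros(n_win)
    bad = np.zeros(n_win, dtype=bool)
    for j in range(L):
        col = codes[j : j + n_win]
        invalid = col >= 4
        bad |= invalid
        scores += np.where(invalid, 0.0, lod[j, np.minimum(col, 3)])
    scores[bad] = -np.inf
    return scores


def scan_pwm(
    regions: Sequence[GenomicInterval],
    genome,
    pwm: PWM,
    max_ambiguous_fraction: float = 0.5,
) -> list[MotifHit]:
    """Scan a PWM over both strands of each region.

    Hits are windows with log2-odds score >= ``pwm.score_threshold``;
    reverse-strand hits are reported on forward-axis coordinates. Regions
    with more than ``max_ambiguous_fraction`` non-ACGT bases are skipped
    with a warning; out-of-bounds regions raise.
    """
    lod = pwm.log_odds()
    lod_rc = pwm.reverse_complement().log_odds()
    L = len(pwm)
    hits: list[MotifHit] = []
    n_skipped = 0
    for region in regions:
        seq = fetch_sequence(genome, region)
        codes = _encode(seq)
        if len(codes) and (codes >= 4).mean() > max_ambiguous_fraction:
            n_skipped += 1
            continue
        fwd = _window_scores(codes, lod)
        rev = _window_scores(codes, lod_rc)
        for strand, scores in (("+", fwd), ("-", rev)):
            idx = np.nonzero(scores >= pwm.score_threshold)[0]
            for i in idx:
                hits.append(
                    MotifHit(
                        motif_id=pwm.motif_id,
                        site=GenomicInterval(
                            region.chrom,
                            region.start + int(i),
                            region.start + int(i) + L,
                            strand,
                        ),
                        strand=strand,
                        score=float(scores[i]),
                    )
                )
    if n_skipped:
        logger.warning("scan_pwm(%s): skipped %d ambiguous regions", pwm.motif_id, n_skipped)
    return hits


def dmc_windows(
    dmcs: Sequence[DMC] | Sequence[tuple[str, int]], flank: int = 150
) -> list[GenomicInterval]:
    """300-bp (2 x flank) windows centred on each DMC, clipped at 0."""
    if flank <= 0:
        raise ValueError("flank must be positive")
    out = []
    for d in dmcs:
        chrom, pos = (d.site.chrom, d.site.pos) if isinstance(d, DMC) else d
        out.append(GenomicInterval(chrom, max(0, pos - flank), pos + flank))
    return out


def motif_enrichment(
    target: Sequence[GenomicInterval],
    background: Sequence[GenomicInterval],
    motifs: Sequence[PWM],
    genome,
) -> list[MotifEnrichment]:
    """Per-motif target-vs-background enrichment with hypergeometric p.

    pct = 100 * (regions with >= 1 hit) / (regions scanned); the score is
    log2(pct_target / pct_background). Significance is the upper
    hypergeometric tail of the target hit count when drawing
    ``len(target)`` regions from the combined pool with all hit-bearing
    regions as successes; q-values are BH across motifs.
    """
    if not target or not background:
        raise ValueError("target and background region sets must be non-empty")
    results: list[MotifEnrichment] = []
    for pwm in motifs:
        k_t = _n_regions_with_hit(target, genome, pwm)
        k_b = _n_regions_with_hit(background, genome, pwm)
        n_t, n_b = len(target), len(background)
        pct_t = 100.0 * k_t / n_t
        pct_b = 100.0 * k_b / n_b
        if pct_t == 0 and pct_b == 0:
            logger.warning("motif %s has no hits in target or background; dropped", pwm.motif_id)
            continue
        if pct_b == 0:
            enr, unbounded = math.inf, True
        else:
            enr = math.log2(pct_t / pct_b) if pct_t > 0 else -math.inf
            unbounded = pct_t == 0
        p = float(stats.hypergeom.sf(k_t - 1, n_t + n_b, k_t + k_b, n_t))
        results.append(
            MotifEnrichment(
                motif_id=pwm.motif_id,
                pct_target=pct_t,
                pct_background=pct_b,
                enrichment=enr,
                p=p,
                unbounded=unbounded,
            )
        )
    if results:
        qs = benjamini_hochberg([r.p for r in results])
        for r, q in zip(results, qs):
            r.q = float(q)
    return results


def _n_regions_with_hit(
    regions: Sequence[GenomicInterval], genome, pwm: PWM
) -> int:
    lod = pwm.log_odds()
    lod_rc = pwm.reverse_complement().log_odds()
    n = 0
    for region in regions:
        codes = _encode(fetch_sequence(genome, region))
        if len(codes) and (codes >= 4).mean() > 0.5:
            continue
        fwd = _window_scores(codes, lod)
        rev = _window_scores(codes, lod_rc)
        if (fwd.size and fwd.max() >= pwm.score_threshold) or (
            rev.size and rev.max() >= pwm.score_threshold
        ):
            n += 1
    return n


# ---------------------------------------------------------------------------
# distance to peaks and proximal-gene integration
# ---------------------------------------------------------------------------


def distance_to_nearest_peak(
    site: GenomicInterval, peaks_by_chrom: Mapping[str, np.ndarray]
) -> float:
    """Gap (bp) to the nearest peak; 0 if overlapping; inf if none on chrom."""
    arr = peaks_by_chrom.get(site.chrom)
    if arr is None or len(arr) == 0:
        return math.inf
    starts, ends = arr[:, 0], arr[:, 1]
    overlap = (starts < site.end) & (site.start < ends)
    if overlap.any():
        return 0.0
    gaps = np.where(
        ends <= site.start, site.start - ends, np.where(starts >= site.end, starts - site.end, 0)
    )
    return float(gaps.min())


def index_peaks(peaks: Sequence[Peak]) -> dict[str, np.ndarray]:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for p in peaks:
        by_chrom.setdefault(p.interval.chrom, []).append(
            (p.interval.start, p.interval.end)
        )
    return {
        c: np.array(sorted(v), dtype=np.int64).reshape(-1, 2)
        for c, v in by_chrom.items()
    }


def proximal_gene_integration(
    hits: Sequence[MotifHit],
    peaks: Sequence[Peak],
    ann: AnnotationSet,
    expression: pd.DataFrame,
    proteome_log2fc: Mapping[str, float] | None = None,
    max_dist: int = 250,
    sig_q: float = 0.05,
    upstream: int = 2500,
) -> tuple[list[ProximalGeneSummary], dict[str, int]]:
    """Summarize expression of genes proximal to each motif's TFBS hits.

    Keeps hits within ``max_dist`` bp of any ATAC-seq peak (shared or
    restricted), maps them to protein-coding genes present in
    ``expression`` (columns ``gene_id``, ``rna_log2fc``, ``q``) via the
    gene-window rule, and reports per motif the gene list with
    significance flags (q < ``sig_q``) and the mean RNA log2 fold change.
    Also returns the per-gene count of distinct motifs with a proximal
    hypomethylated TFBS.
    """
    if not peaks:
        logger.warning("proximal_gene_integration: empty peak set, all hits dropped")
        return [], {}
    peak_index = index_peaks(peaks)
    kept = [
        h for h in hits if distance_to_nearest_peak(h.site, peak_index) <= max_dist
    ]
    expr = expression.set_index("gene_id")
    coding = {g.gene_id for g in ann.genes if g.is_protein_coding}

    # cell_type carries the hit index so identical coordinates from
    # different motifs stay distinguishable through the assignment
    hit_peaks = [Peak(interval=h.site, cell_type=str(i)) for i, h in enumerate(kept)]
    assignments = assign_peaks_to_genes(hit_peaks, ann, upstream=upstream)
    gene_motifs: dict[str, set[str]] = {}
    motif_genes: dict[str, set[str]] = {}
    for gid, assigned in assignments.items():
        if gid is None or gid not in coding or gid not in expr.index:
            continue
        for hp in assigned:
            h = kept[int(hp.cell_type)]
            gene_motifs.setdefault(gid, set()).add(h.motif_id)
            motif_genes.setdefault(h.motif_id, set()).add(gid)

    summaries = []
    for motif_id in sorted(motif_genes):
        rows = []
        for gid in sorted(motif_genes[motif_id]):
            rec = expr.loc[gid]
            rows.append(
                {
                    "gene_id": gid,
                    "rna_log2fc": float(rec["rna_log2fc"]),
                    "significant": bool(rec["q"] < sig_q),
                    "protein_log2fc": (
                        float(proteome_log2fc[gid])
                        if proteome_log2fc and gid in proteome_log2fc
                        else None
                    ),
                }
            )
        mean_fc = (
            float(np.mean([r["rna_log2fc"] for r in rows])) if rows else math.nan
        )
        summaries.append(
            ProximalGeneSummary(
                motif_id=motif_id,
                genes=rows,
                mean_rna_log2fc=mean_fc,
                n_genes=len(rows),
            )
        )
    multi_tfbs = {g: len(ms) for g, ms in gene_motifs.items()}
    return summaries, multi_tfbs
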