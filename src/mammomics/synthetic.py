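"""Self-contained synthetic study generator with recorded ground truth.

Emulates the data layers of a two-lineage (basal vs. luminal) mammary
study: a small genome, gene models with CpG islands, per-CpG
bisulfite counts for 2 replicates per cell type (beta-binomial), ATAC-seq
peak sets with planted lineage restriction, PWM motifs embedded into the
genome around hypomethylated DMCs, RNA fold changes (4 replicates'
worth of array-style statistics), a MaxQuant-like protein-group table with
LFQ missingness backed by iBAQ, and limiting-dilution transplant outcomes.

Dependencies between layers are planted on the log-odds scale (open
chromatin -> RNA, RNA -> protein) so the downstream association estimators
have a known truth to recover. Everything is deterministic given the seed,
and every planted parameter and membership list is recorded in
``ground_truth.json``.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import genome_io
from .genome_io import PWM, AnnotationSet, GeneModel, GenomicInterval
from .integration import LayerState, RelationshipState
from .lda import simulate_lda
from .methylome import annotate_site_features

DEFAULT_MOTIF_CONSENSI = {
    "FOXA1_like": "TGTTTACTTA",
    "GATA_like": "AGATAAGAGC",
    "ELF5_like": "AACCGGAAGT",
}


@dataclass
class SimulationConfig:
    """Planted parameters of the synthetic study.

    Defaults mirror the study design: two cell types; 2 bisulfite and
    proteome replicates and 4 expression replicates per type; DMCs planted
    at a 3x rate in promoters; motif consensus embedded at contrasting
    target/background rates; chromatin->RNA and RNA->protein dependence on
    the log-odds scale; stem-cell frequency near 1 in 2,000 with a 4-fold
    lower treated group.
    """

    seed: int
    n_chroms: int = 3
    chrom_length: int = 3_200_000
    n_genes: int = 360
    protein_coding_fraction: float = 0.9
    n_cpg_background: int = 20_000
    dmc_rate: float = 0.05
    promoter_enrichment_fold: float = 3.0
    delta_beta_shift: float = 0.3
    methylation_dispersion: float = 0.01
    mean_coverage: int = 40
    n_peaks: int = 1200
    peak_restriction_fraction: float = 0.4
    motif_plant_rates: dict = field(
        default_factory=lambda: {
            "FOXA1_like": (0.6, 0.2),
            "GATA_like": (0.5, 0.2),
            "ELF5_like": (0.4, 0.2),
        }
    )
    log_odds_chromatin_rna: float = 1.5
    log_odds_rna_protein: float = 2.0
    base_up_rate: float = 0.15
    chromatin_up_rate: float = 0.2
    rna_protein_rho_by_quantile: tuple = (0.2, 0.35, 0.45, 0.6)
    lfq_missing_rate: float = 0.15
    protein_floor_fraction: float = 0.05
    protein_detect_fraction: float = 0.85
    lda_true_frequency: float = 1 / 2000
    lda_treated_frequency: float = 1 / 8000
    lda_doses: tuple = ((500, 12), (2000, 12), (10000, 12))

    def __post_init__(self) -> None:
        for name in (
            "dmc_rate",
            "peak_restriction_fraction",
            "lfq_missing_rate",
            "protein_floor_fraction",
            "protein_detect_fraction",
            "base_up_rate",
            "chromatin_up_rate",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if round(self.dmc_rate * self.n_cpg_background) > self.n_cpg_background:
            raise ValueError("more planted DMCs than CpG sites")
        if self.n_genes * 25_000 > self.n_chroms * self.chrom_length:
            raise ValueError("genome too small for the requested gene count")
        for name, (t, b) in self.motif_plant_rates.items():
            if not (0 <= t <= 1 and 0 <= b <= 1):
                raise ValueError(f"motif_plant_rates[{name}] outside [0, 1]")
        if not 0 < self.lda_true_frequency < 1:
            raise ValueError("lda_true_frequency must be in (0, 1)")


# ---------------------------------------------------------------------------
# focused generators used directly by statistical property tests
# ---------------------------------------------------------------------------


def simulate_state_pairs(
    n_genes: int,
    log_odds: float,
    rng: np.random.Generator,
    base_up: float = 0.15,
    pred_up: float = 0.2,
) -> dict[str, RelationshipState]:
    """Gene states with a planted chromatin->RNA log-odds dependence.

    The RNA state is multinomial with P(up_d) proportional to
    ``base_odds * exp(log_odds)`` when the chromatin state equals d and
    ``base_odds`` otherwise (neutral carries weight 1), which makes
    ``log_odds`` exactly the quantity the pairwise association fit
    estimates. Methylation and protein are neutral throughout.
    """
    base_odds = base_up / (1 - 2 * base_up)
    # chromatin: 0 = up_basal, 1 = up_luminal, 2 = neutral
    chrom = rng.choice(3, size=n_genes, p=[pred_up, pred_up, 1 - 2 * pred_up])
    boost = math.exp(log_odds)
    w_b = base_odds * np.where(chrom == 0, boost, 1.0)
    w_l = base_odds * np.where(chrom == 1, boost, 1.0)
    total = w_b + w_l + 1.0
    u = rng.random(n_genes) * total
    rna = np.where(u < w_b, 0, np.where(u < w_b + w_l, 1, 2))
    codes = (LayerState.UP_BASAL, LayerState.UP_LUMINAL, LayerState.NEUTRAL)
    return {
        f"G{i:05d}": RelationshipState(
            chromatin=codes[chrom[i]],
            methylation=LayerState.NEUTRAL,
            rna=codes[rna[i]],
            protein=LayerState.NEUTRAL,
        )
        for i in range(n_genes)
    }


def simulate_rna_protein(
    n_genes: int,
    rho_by_quantile: tuple = (0.2, 0.35, 0.45, 0.6),
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """RNA/protein fold changes with per-peptide-count-quantile correlation.

    Within each quantile the pair is bivariate normal with the Pearson
    correlation chosen so the Spearman correlation equals the requested
    value (rho_pearson = 2 sin(pi rho_s / 6)).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    n_q = len(rho_by_quantile)
    per_q = n_genes // n_q
    count_ranges = [(2, 4), (5, 9), (10, 19), (20, 60)][:n_q]
    rows = []
    for q, rho_s in enumerate(rho_by_quantile):
        rho_p = 2 * math.sin(math.pi * rho_s / 6)
        cov = [[1, rho_p], [rho_p, 1]]
        xy = rng.multivariate_normal([0, 0], cov, size=per_q)
        lo, hi = count_ranges[q]
        counts = rng.integers(lo, hi + 1, size=per_q)
        for j in range(per_q):
            rows.append(
                {
                    "rna_log2fc": xy[j, 0],
                    "protein_log2fc": xy[j, 1],
                    "peptide_count": int(counts[j]),
                    "true_quantile": q + 1,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# full bundle
# ---------------------------------------------------------------------------


def _make_genes(cfg: SimulationConfig, rng: np.random.Generator) -> list[GeneModel]:
    genes = []
    gi = 0
    for c in range(cfg.n_chroms):
        chrom = f"chr{c + 1}"
        cursor = 6000
        while gi < cfg.n_genes:
            length = int(rng.integers(2000, 20001))
            if cursor + length + 6000 > cfg.chrom_length:
                break
            start, end = cursor, cursor + length
            strand = "+" if rng.random() < 0.5 else "-"
            n_exons = int(rng.integers(3, 9))
            cuts = np.sort(rng.choice(np.arange(start + 1, end), size=2 * n_exons - 2, replace=False))
            bounds = np.concatenate([[start], cuts, [end]])
            exons = tuple(
                GenomicInterval(chrom, int(bounds[2 * k]), int(bounds[2 * k + 1]), strand)
                for k in range(n_exons)
                if bounds[2 * k + 1] > bounds[2 * k]
            )
            genes.append(
                GeneModel(
                    gene_id=f"G{gi:05d}",
                    name=f"Gene{gi:05d}",
                    body=GenomicInterval(chrom, start, end, strand),
                    exons=exons,
                    is_protein_coding=bool(rng.random() < cfg.protein_coding_fraction),
                )
            )
            gi += 1
            cursor = end + int(rng.integers(3000, 10000))
        if gi >= cfg.n_genes:
            break
    if gi < cfg.n_genes:
        raise ValueError("genome too small to place all genes")
    return genes


def _make_cgis(
    cfg: SimulationConfig, genes: list[GeneModel], rng: np.random.Generator
) -> list[GenomicInterval]:
    cgis = []
    for g in genes:
        if rng.random() < 0.3:
            tss = g.tss
            if g.strand == "+":
                start, end = max(0, tss - 400), tss + 200
            else:
                start, end = max(0, tss - 200), tss + 400
            cgis.append(GenomicInterval(g.body.chrom, start, min(end, cfg.chrom_length)))
    for _ in range(50):
        c = f"chr{int(rng.integers(1, cfg.n_chroms + 1))}"
        s = int(rng.integers(0, cfg.chrom_length - 600))
        cgis.append(GenomicInterval(c, s, s + int(rng.integers(300, 700))))
    return sorted(cgis, key=lambda i: (i.chrom, i.start))


def _make_cpg_positions(
    cfg: SimulationConfig, cgis: list[GenomicInterval], rng: np.random.Generator
) -> list[tuple[str, int]]:
    n_cgi = int(0.4 * cfg.n_cpg_background)
    n_uniform = cfg.n_cpg_background - n_cgi
    positions = set()
    while len(positions) < n_uniform:
        need = n_uniform - len(positions)
        chroms = rng.integers(1, cfg.n_chroms + 1, size=need)
        pos = rng.integers(200, cfg.chrom_length - 200, size=need)
        for c, p in zip(chroms, pos):
            positions.add((f"chr{c}", int(p)))
    target = n_uniform + n_cgi
    while len(positions) < target:
        iv = cgis[int(rng.integers(0, len(cgis)))]
        positions.add((iv.chrom, int(rng.integers(iv.start, iv.end))))
    return sorted(positions)


def _beta_binomial(
    beta: np.ndarray, coverage: np.ndarray, rho: float, rng: np.random.Generator
) -> np.ndarray:
    b = np.clip(beta, 1e-4, 1 - 1e-4)
    a = b * (1 / rho - 1)
    bb = (1 - b) * (1 / rho - 1)
    p = rng.beta(a, bb)
    return rng.binomial(coverage.astype(np.int64), p)


def _draw_direction(
    up_weight_basal: float, up_weight_luminal: float, base_odds: float, rng
) -> LayerState:
    w_b = base_odds * up_weight_basal
    w_l = base_odds * up_weight_luminal
    total = w_b + w_l + 1.0
    r = rng.random() * total
    if r < w_b:
        return LayerState.UP_BASAL
    if r < w_b + w_l:
        return LayerState.UP_LUMINAL
    return LayerState.NEUTRAL


def simulate_study(cfg: SimulationConfig, outdir: str | Path) -> dict:
    """Write the full synthetic bundle to ``outdir``; return the ground truth.

    Files written: ``genome.fa``, ``genes.tsv``, ``cgi.bed``,
    ``methylation.tsv``, ``peaks_basal.bed``, ``peaks_luminal.bed``,
    ``motifs.pfm``, ``expression.tsv``, ``proteins.tsv``, ``lda.tsv``,
    ``markers.txt`` and ``ground_truth.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    genes = _make_genes(cfg, rng)
    cgis = _make_cgis(cfg, genes, rng)
    ann = AnnotationSet(genes=genes, cgi=cgis)
    cpgs = _make_cpg_positions(cfg, cgis, rng)
    n_cpg = len(cpgs)

    # ---- planted DMCs: promoter overlap at fold x the uniform expectation,
    # so the permutation enrichment has a known truth of exactly the fold
    labels = annotate_site_features(cpgs, ann)
    in_promoter = np.array([g == "promoter" for g, _ in labels])
    n_dmc = int(round(cfg.dmc_rate * n_cpg))
    f_prom = in_promoter.mean()
    k_prom = int(round(cfg.promoter_enrichment_fold * f_prom * n_dmc))
    prom_idx = np.nonzero(in_promoter)[0]
    other_idx = np.nonzero(~in_promoter)[0]
    if k_prom > min(len(prom_idx), n_dmc) or n_dmc - k_prom > len(other_idx):
        raise ValueError(
            "promoter_enrichment_fold infeasible for this promoter fraction"
        )
    dmc_idx = np.sort(
        np.concatenate(
            [
                rng.choice(prom_idx, size=k_prom, replace=False),
                rng.choice(other_idx, size=n_dmc - k_prom, replace=False),
            ]
        )
    )
    is_dmc = np.zeros(n_cpg, dtype=bool)
    is_dmc[dmc_idx] = True
    hypo_in_basal = rng.random(n_cpg) < 0.55  # direction per planted DMC

    # ---- methylation counts (2 replicates per cell type, beta-binomial)
    cgi_label = np.array([c == "cgi" for _, c in labels])
    base_beta = np.where(
        cgi_label, rng.beta(2, 8, size=n_cpg), rng.beta(8, 2, size=n_cpg)
    )
    beta_high = np.clip(base_beta, cfg.delta_beta_shift + 0.1, 0.95)
    beta_low = beta_high - cfg.delta_beta_shift
    beta_basal = np.where(is_dmc, np.where(hypo_in_basal, beta_low, beta_high), base_beta)
    beta_luminal = np.where(is_dmc, np.where(hypo_in_basal, beta_high, beta_low), base_beta)

    meth_samples = ["basal_1", "basal_2", "luminal_1", "luminal_2"]
    meth_counts = {}
    for s in meth_samples:
        beta = beta_basal if s.startswith("basal") else beta_luminal
        cov = rng.poisson(cfg.mean_coverage, size=n_cpg) + 5
        meth = _beta_binomial(beta, cov, cfg.methylation_dispersion, rng)
        meth_counts[s] = (meth, cov - meth)
    sites = [
        genome_io.CpGSite(
            chrom=c,
            pos=p,
            strand="+",
            meth=np.array([meth_counts[s][0][i] for s in meth_samples]),
            unmeth=np.array([meth_counts[s][1][i] for s in meth_samples]),
        )
        for i, (c, p) in enumerate(cpgs)
    ]
    genome_io.write_beta_table(outdir / "methylation.tsv", meth_samples, sites)

    # ---- latent layer directions with planted log-odds dependence
    base_odds = cfg.base_up_rate / (1 - 2 * cfg.base_up_rate)
    chrom_dir = {}
    rna_dir = {}
    prot_dir = {}
    for g in genes:
        r = rng.random()
        if r < cfg.chromatin_up_rate:
            cd = LayerState.UP_BASAL
        elif r < 2 * cfg.chromatin_up_rate:
            cd = LayerState.UP_LUMINAL
        else:
            cd = LayerState.NEUTRAL
        chrom_dir[g.gene_id] = cd
        rd = _draw_direction(
            math.exp(cfg.log_odds_chromatin_rna) if cd == LayerState.UP_BASAL else 1.0,
            math.exp(cfg.log_odds_chromatin_rna) if cd == LayerState.UP_LUMINAL else 1.0,
            base_odds,
            rng,
        )
        rna_dir[g.gene_id] = rd
        prot_dir[g.gene_id] = _draw_direction(
            math.exp(cfg.log_odds_rna_protein) if rd == LayerState.UP_BASAL else 1.0,
            math.exp(cfg.log_odds_rna_protein) if rd == LayerState.UP_LUMINAL else 1.0,
            base_odds,
            rng,
        )

    # ---- ATAC peaks honoring the chromatin directions
    peaks_basal: list[GenomicInterval] = []
    peaks_luminal: list[GenomicInterval] = []

    def _window_peak(g: GeneModel) -> GenomicInterval:
        w = g.window_with_upstream(2500)
        width = int(rng.integers(200, 601))
        s = int(rng.integers(w.start, max(w.start + 1, w.end - width)))
        return GenomicInterval(w.chrom, s, min(s + width, cfg.chrom_length))

    for g in genes:
        n_shared = int(rng.poisson(0.8))
        for _ in range(n_shared):
            iv = _window_peak(g)
            jitter = int(rng.integers(-40, 41))
            iv2_start = max(0, iv.start + jitter)
            peaks_basal.append(iv)
            peaks_luminal.append(GenomicInterval(iv.chrom, iv2_start, iv2_start + len(iv)))
        cd = chrom_dir[g.gene_id]
        if cd != LayerState.NEUTRAL:
            n_extra = 1 + int(rng.poisson(0.7))
            target = peaks_basal if cd == LayerState.UP_BASAL else peaks_luminal
            for _ in range(n_extra):
                target.append(_window_peak(g))

    def _random_peak() -> GenomicInterval:
        c = f"chr{int(rng.integers(1, cfg.n_chroms + 1))}"
        width = int(rng.integers(200, 601))
        s = int(rng.integers(0, cfg.chrom_length - width))
        return GenomicInterval(c, s, s + width)

    while len(peaks_basal) < cfg.n_peaks or len(peaks_luminal) < cfg.n_peaks:
        iv = _random_peak()
        if rng.random() < 1 - cfg.peak_restriction_fraction:
            if len(peaks_basal) < cfg.n_peaks:
                peaks_basal.append(iv)
            if len(peaks_luminal) < cfg.n_peaks:
                jitter = int(rng.integers(-40, 41))
                s = max(0, iv.start + jitter)
                peaks_luminal.append(GenomicInterval(iv.chrom, s, s + len(iv)))
        else:
            if rng.random() < 0.5 and len(peaks_basal) < cfg.n_peaks:
                peaks_basal.append(iv)
            elif len(peaks_luminal) < cfg.n_peaks:
                peaks_luminal.append(iv)
    genome_io.write_bed(outdir / "peaks_basal.bed", sorted(peaks_basal))
    genome_io.write_bed(outdir / "peaks_luminal.bed", sorted(peaks_luminal))

    # ---- expression table (array-style log2 fold changes and q-values)
    expr_rows = []
    for g in genes:
        rd = rna_dir[g.gene_id]
        if rd == LayerState.UP_BASAL:
            fc = 1.2 + rng.exponential(0.6)
        elif rd == LayerState.UP_LUMINAL:
            fc = -(1.2 + rng.exponential(0.6))
        else:
            fc = float(np.clip(rng.normal(0, 0.3), -0.9, 0.9))
        base = rng.normal(7, 1.5)
        q = rng.uniform(1e-6, 0.01) if abs(fc) > 1 else rng.uniform(0.2, 1.0)
        expr_rows.append(
            {
                "gene_id": g.gene_id,
                "rna_basal": 2 ** (base + fc / 2),
                "rna_luminal": 2 ** (base - fc / 2),
                "rna_log2fc": fc,
                "q": q,
            }
        )
    pd.DataFrame(expr_rows).to_csv(outdir / "expression.tsv", sep="\t", index=False)

    # ---- proteome table (LFQ + iBAQ, missingness, detection-only proteins)
    prot_samples = ["basal_1", "basal_2", "luminal_1", "luminal_2"]
    prot_rows = []
    detected = [g for g in genes if rng.random() < cfg.protein_detect_fraction]
    floor_only = set(
        g.gene_id
        for g in detected
        if rng.random() < cfg.protein_floor_fraction
    )
    for pi, g in enumerate(detected):
        pdir = prot_dir[g.gene_id]
        if pdir == LayerState.UP_BASAL:
            fc = 1.2 + rng.exponential(0.6)
        elif pdir == LayerState.UP_LUMINAL:
            fc = -(1.2 + rng.exponential(0.6))
        else:
            fc = float(np.clip(rng.normal(0, 0.3), -0.9, 0.9))
        pbase = rng.normal(20, 1.5)
        peptides = int(min(60, 2 + rng.negative_binomial(2, 0.15)))
        ibaq_divisor = rng.uniform(5, 50)
        row = {
            "group_id": f"P{pi:05d}",
            "gene_symbol": g.gene_id,
            "n_peptides": peptides,
        }
        only_in = None
        if g.gene_id in floor_only:
            only_in = "basal" if rng.random() < 0.5 else "luminal"
        for s in prot_samples:
            sign = 1 if s.startswith("basal") else -1
            lfq = 2 ** (pbase + sign * fc / 2 + rng.normal(0, 0.15))
            ibaq = lfq / ibaq_divisor
            if only_in and not s.startswith(only_in):
                lfq, ibaq = 0.0, 0.0
            elif rng.random() < cfg.lfq_missing_rate:
                lfq = 0.0
            row[f"lfq_{s}"] = lfq
            row[f"ibaq_{s}"] = ibaq
        prot_rows.append(row)
    pd.DataFrame(prot_rows).to_csv(outdir / "proteins.tsv", sep="\t", index=False)

    # ---- genome with motif consensus planted around DMC / background CpGs
    chrom_seqs = {
        f"chr{c + 1}": rng.integers(0, 4, size=cfg.chrom_length).astype(np.int8)
        for c in range(cfg.n_chroms)
    }
    hypo_basal_dmcs = [cpgs[i] for i in dmc_idx if hypo_in_basal[i]]
    # background windows for the TFBS contrast must not interleave with the
    # target windows (CpGs cluster in islands), or plants leak across sets;
    # keep only non-DMC CpGs at least 450 bp from any hypo-basal DMC
    target_by_chrom: dict[str, list[int]] = {}
    for c, p in hypo_basal_dmcs:
        target_by_chrom.setdefault(c, []).append(p)
    target_pos = {c: np.array(sorted(v)) for c, v in target_by_chrom.items()}

    def _far_from_targets(c: str, p: int, min_dist: int = 450) -> bool:
        arr = target_pos.get(c)
        if arr is None or len(arr) == 0:
            return True
        j = int(np.searchsorted(arr, p))
        for k in (j - 1, j):
            if 0 <= k < len(arr) and abs(int(arr[k]) - p) < min_dist:
                return False
        return True

    non_dmc_idx = np.array(
        [i for i in np.nonzero(~is_dmc)[0] if _far_from_targets(*cpgs[i])]
    )
    bg_draw = rng.choice(
        non_dmc_idx,
        size=min(len(hypo_basal_dmcs), len(non_dmc_idx)),
        replace=False,
    )
    background_cpgs = [cpgs[i] for i in np.sort(bg_draw)]

    motif_truth = {}
    pwms = []
    for name, consensus in DEFAULT_MOTIF_CONSENSI.items():
        if name not in cfg.motif_plant_rates:
            continue
        t_rate, b_rate = cfg.motif_plant_rates[name]
        mat = np.full((len(consensus), 4), 0.03)
        for j, b in enumerate(consensus):
            mat[j, genome_io.BASES.index(b)] = 0.91
        pwms.append(PWM(motif_id=name, matrix=mat))
        n_t = n_b = 0
        for group, rate, count_attr in (
            (hypo_basal_dmcs, t_rate, "t"),
            (background_cpgs, b_rate, "b"),
        ):
            for chrom, pos in group:
                if rng.random() >= rate:
                    continue
                offset = int(rng.integers(-120, 110))
                start = max(0, pos + offset)
                seq = chrom_seqs[chrom]
                if start + len(consensus) > len(seq):
                    continue
                for j, b in enumerate(consensus):
                    seq[start + j] = genome_io.BASES.index(b)
                if count_attr == "t":
                    n_t += 1
                else:
                    n_b += 1
        motif_truth[name] = {
            "consensus": consensus,
            "target_rate": t_rate,
            "background_rate": b_rate,
            "n_planted_target": n_t,
            "n_planted_background": n_b,
        }
    base_chars = np.array(list(genome_io.BASES))
    with open(outdir / "genome.fa", "w") as fh:
        for chrom, codes in chrom_seqs.items():
            fh.write(f">{chrom}\n")
            seq = "".join(base_chars[codes])
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    genome_io.write_pwm(outdir / "motifs.pfm", pwms)

    genome_io.write_gene_table(outdir / "genes.tsv", genes)
    genome_io.write_bed(outdir / "cgi.bed", cgis)

    # ---- markers: fully concordant genes, half per lineage
    def _pick_markers(direction: LayerState, n: int) -> list[str]:
        full = [
            g.gene_id
            for g in genes
            if chrom_dir[g.gene_id] == direction
            and rna_dir[g.gene_id] == direction
            and prot_dir[g.gene_id] == direction
        ]
        partial = [
            g.gene_id
            for g in genes
            if g.gene_id not in full
            and rna_dir[g.gene_id] == direction
            and prot_dir[g.gene_id] == direction
        ]
        return (full + partial)[:n]

    markers = _pick_markers(LayerState.UP_BASAL, 11) + _pick_markers(
        LayerState.UP_LUMINAL, 11
    )
    (outdir / "markers.txt").write_text("\n".join(markers) + "\n")

    # ---- limiting-dilution tables
    lda_vehicle = simulate_lda(cfg.lda_true_frequency, cfg.lda_doses, rng, "vehicle")
    lda_treated = simulate_lda(cfg.lda_treated_frequency, cfg.lda_doses, rng, "treated")
    with open(outdir / "lda.tsv", "w") as fh:
        fh.write("group\tdose\tn_injected\tn_positive\n")
        for exp in (lda_vehicle, lda_treated):
            for dse, n, k in exp.doses:
                fh.write(f"{exp.group_label}\t{dse}\t{n}\t{k}\n")

    truth = {
        "config": _config_dict(cfg),
        "n_cpg": n_cpg,
        "n_planted_dmcs": int(n_dmc),
        "dmc_sites": [
            {
                "chrom": cpgs[i][0],
                "pos": int(cpgs[i][1]),
                "direction": "hypo_in_basal" if hypo_in_basal[i] else "hypo_in_luminal",
            }
            for i in dmc_idx
        ],
        "n_promoter_cpgs": int(in_promoter.sum()),
        "n_promoter_dmcs": int(in_promoter[dmc_idx].sum()),
        "background_motif_cpgs": [
            {"chrom": c, "pos": int(p)} for c, p in background_cpgs
        ],
        "layer_directions": {
            g.gene_id: {
                "chromatin": chrom_dir[g.gene_id].value,
                "rna": rna_dir[g.gene_id].value,
                "protein": prot_dir[g.gene_id].value,
            }
            for g in genes
        },
        "motifs": motif_truth,
        "markers": markers,
        "lda": {
            "vehicle_frequency": cfg.lda_true_frequency,
            "treated_frequency": cfg.lda_treated_frequency,
            "doses": list(map(list, cfg.lda_doses)),
        },
    }
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
    return truth


def _config_dict(cfg: SimulationConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["rna_protein_rho_by_quantile"] = list(cfg.rna_protein_rho_by_quantile)
    d["lda_doses"] = list(map(list, cfg.lda_doses))
    return d
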