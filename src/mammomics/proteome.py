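"""Label-free proteomics harmonization and differential abundance.

Protein groups identified with fewer than two peptides are discarded. A
protein quantified by LFQ in every sample keeps its LFQ intensities;
otherwise its iBAQ intensities are rescaled to the LFQ scale with a
per-sample median ratio computed over LFQ-complete records. Intensities
still missing (or zero) after the fallback are floored to 1, which makes
detection in only one lineage show up as an absolute log2 fold change
above 15 on realistic intensity scales. Normalized abundance divides each
protein's values by its maximum over samples.
"""

from __future__ import annotations

import logging
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .methylome import benjamini_hochberg

logger = logging.getLogger(__name__)

ABUNDANCE_FLOOR = 1.0


def _columns(df: pd.DataFrame, prefix: str) -> list[str]:
    return [c for c in df.columns if c.startswith(prefix)]


def sample_names(df: pd.DataFrame) -> list[str]:
    return [c[len("lfq_") :] for c in _columns(df, "lfq_")]


def filter_min_peptides(df: pd.DataFrame, min_peptides: int = 2) -> pd.DataFrame:
    """Keep protein groups identified with >= ``min_peptides`` peptides."""
    kept = df[df["n_peptides"] >= min_peptides].reset_index(drop=True)
    logger.info("peptide filter: kept %d / %d protein groups", len(kept), len(df))
    return kept


def harmonize_abundance(df: pd.DataFrame) -> pd.DataFrame:
    """Fill per-sample ``abund_<s>`` columns from LFQ with iBAQ fallback.

    Input columns: ``group_id``, ``gene_symbol``, ``n_peptides``,
    ``lfq_<sample>`` and ``ibaq_<sample>`` (0 or NaN = missing). Records
    LFQ-complete in every sample pass LFQ through verbatim; the rest use
    iBAQ scaled per sample by median(LFQ)/median(iBAQ) over the complete
    records. Remaining missing values are floored to 1.
    """
    samples = sample_names(df)
    if not samples:
        raise ValueError("no lfq_<sample> columns found")
    lfq = df[[f"lfq_{s}" for s in samples]].to_numpy(dtype=float)
    ibaq = df[[f"ibaq_{s}" for s in samples]].to_numpy(dtype=float)
    lfq = np.where(np.nan_to_num(lfq) <= 0, np.nan, lfq)
    ibaq = np.where(np.nan_to_num(ibaq) <= 0, np.nan, ibaq)

    complete = ~np.isnan(lfq).any(axis=1)
    scale = np.ones(len(samples))
    if complete.any():
        anchor_lfq = lfq[complete]
        anchor_ibaq = ibaq[complete]
        for j in range(len(samples)):
            ok = ~np.isnan(anchor_ibaq[:, j])
            if ok.any():
                scale[j] = np.median(anchor_lfq[ok, j]) / np.median(anchor_ibaq[ok, j])
    else:
        logger.warning("no LFQ-complete records; iBAQ used unscaled")

    abund = np.where(complete[:, None], lfq, ibaq * scale)
    n_floored = int(np.isnan(abund).sum())
    if n_floored:
        logger.info("harmonize_abundance: floored %d missing values to 1", n_floored)
    abund = np.where(np.isnan(abund) | (abund < ABUNDANCE_FLOOR), ABUNDANCE_FLOOR, abund)

    out = df.copy()
    for j, s in enumerate(samples):
        out[f"abund_{s}"] = abund[:, j]
    return out


def normalize_max(df: pd.DataFrame) -> pd.DataFrame:
    """Add ``norm_<s>`` columns: abundance divided by the row maximum."""
    samples = sample_names(df)
    abund = df[[f"abund_{s}" for s in samples]].to_numpy(dtype=float)
    norm = abund / abund.max(axis=1, keepdims=True)
    out = df.copy()
    for j, s in enumerate(samples):
        out[f"norm_{s}"] = norm[:, j]
    return out


def differential_proteins(
    df: pd.DataFrame,
    groups: Mapping[str, str],
    fc_min: float = 2.0,
    p_max: float = 0.05,
) -> pd.DataFrame:
    """Differential abundance between the two cell types.

    ``log2fc`` is log2(mean basal abundance / mean luminal abundance) on
    the harmonized scale; ``p`` is a Welch two-sided t-test on log2
    abundance. Proteins whose abundance sits at the floor in exactly one
    group (detected only in the other) are flagged ``detected_only_in``
    and counted as differential regardless of the test. Returns the input
    plus ``log2fc``, ``p``, ``q``, ``detected_only_in``, ``is_differential``.
    """
    samples = sample_names(df)
    basal = [s for s in samples if groups[s] == "basal"]
    luminal = [s for s in samples if groups[s] == "luminal"]
    if not basal or not luminal:
        raise ValueError("both basal and luminal samples required")
    ab = df[[f"abund_{s}" for s in basal]].to_numpy(dtype=float)
    al = df[[f"abund_{s}" for s in luminal]].to_numpy(dtype=float)

    log2fc = np.log2(ab.mean(axis=1) / al.mean(axis=1))
    lb, ll = np.log2(ab), np.log2(al)
    pvals = np.ones(len(df))
    for i in range(len(df)):
        vb, vl = lb[i], ll[i]
        if vb.std(ddof=1 if len(vb) > 1 else 0) == 0 and vl.std(
            ddof=1 if len(vl) > 1 else 0
        ) == 0:
            pvals[i] = 1.0 if vb.mean() == vl.mean() else 0.0
            continue
        pvals[i] = stats.ttest_ind(vb, vl, equal_var=False).pvalue

    floor_b = (ab <= ABUNDANCE_FLOOR).all(axis=1)
    floor_l = (al <= ABUNDANCE_FLOOR).all(axis=1)
    detected_only = np.where(
        floor_b & ~floor_l, "luminal", np.where(floor_l & ~floor_b, "basal", "none")
    )

    out = df.copy()
    out["log2fc"] = log2fc
    out["p"] = pvals
    out["q"] = benjamini_hochberg(pvals)
    out["detected_only_in"] = detected_only
    out["is_differential"] = (
        (np.abs(log2fc) >= math.log2(fc_min)) & (pvals < p_max)
    ) | (detected_only != "none")
    return out


def zscore_rows(matrix: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise z-scores (x - mean) / SD with sample SD (n - 1).

    Constant rows are emitted as all-zero and flagged. Returns
    (zscores, constant_row_flags).
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("matrix must be 2-D with >= 2 columns")
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    constant = (sd == 0).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (x - mean) / sd
    z[constant] = 0.0
    return z, constant


def rna_protein_correlation(
    rna_log2fc: Sequence[float],
    protein_log2fc: Sequence[float],
    peptide_counts: Sequence[float],
    n_quantiles: int = 4,
) -> dict:
    """Spearman correlation of RNA vs. protein fold change, overall and by
    peptide-count quantile.

    Quantile boundaries are the empirical quartiles of the peptide counts;
    a count equal to a boundary goes to the lower quantile. Returns
    ``{"global_rho": .., "global_p": .., "quantiles": [{...}, ...]}`` with
    quantiles ordered from lowest (Q1) to highest (Q4) peptide counts.
    """
    rna = np.asarray(rna_log2fc, dtype=float)
    prot = np.asarray(protein_log2fc, dtype=float)
    counts = np.asarray(peptide_counts, dtype=float)
    if not (len(rna) == len(prot) == len(counts)):
        raise ValueError("input vectors must have equal length")
    rho, p = stats.spearmanr(rna, prot)
    if len(np.unique(counts)) < n_quantiles:
        logger.warning("fewer distinct peptide counts than quantiles; bins merged")
    edges = np.quantile(counts, np.linspace(0, 1, n_quantiles + 1)[1:-1])
    bins = np.searchsorted(edges, counts, side="left")
    quantiles = []
    for b in range(n_quantiles):
        mask = bins == b
        if mask.sum() >= 3:
            qr, qp = stats.spearmanr(rna[mask], prot[mask])
        else:
            qr, qp = math.nan, math.nan
        quantiles.append(
            {
                "quantile": f"Q{b + 1}",
                "n": int(mask.sum()),
                "rho": float(qr),
                "p": float(qp),
            }
        )
    return {"global_rho": float(rho), "global_p": float(p), "quantiles": quantiles}
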