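"""Lineage-restricted ATAC-seq peak classification and peak-to-gene counts.

A peak is *shared* when it overlaps (>= 1 bp, half-open) at least one peak
called in the other cell type, otherwise it is restricted to its own
lineage. Peaks are assigned to every gene whose body-plus-2.5-kb-upstream
window they overlap; no nearest-gene tie-break is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .genome_io import AnnotationSet, GenomicInterval

RESTRICTIONS = ("basal_only", "luminal_only", "shared")


@dataclass(frozen=True)
class Peak:
    """An open-chromatin interval with cell-type provenance."""

    interval: GenomicInterval
    cell_type: str  # "basal" | "luminal"
    restriction: str | None = None  # set by classify_restriction


@dataclass(frozen=True)
class GenePeakCounts:
    gene_id: str
    n_peaks_basal: int
    n_peaks_luminal: int


def _overlap_any(peaks: Sequence[Peak], others: Sequence[Peak]) -> np.ndarray:
    """Boolean per peak: overlaps >= 1 peak in ``others`` (sorted sweep)."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for p in others:
        by_chrom.setdefault(p.interval.chrom, []).append(
            (p.interval.start, p.interval.end)
        )
    arrays = {
        c: np.array(sorted(v), dtype=np.int64).reshape(-1, 2)
        for c, v in by_chrom.items()
    }
    out = np.zeros(len(peaks), dtype=bool)
    for i, p in enumerate(peaks):
        arr = arrays.get(p.interval.chrom)
        if arr is None:
            continue
        starts = arr[:, 0]
        j = int(np.searchsorted(starts, p.interval.end, side="left"))
        out[i] = bool((arr[:j, 1] > p.interval.start).any())
    return out


def classify_restriction(
    peaks_basal: Sequence[Peak], peaks_luminal: Sequence[Peak]
) -> tuple[list[Peak], list[Peak]]:
    """Label every peak shared / basal_only / luminal_only (symmetric)."""
    basal_shared = _overlap_any(peaks_basal, peaks_luminal)
    luminal_shared = _overlap_any(peaks_luminal, peaks_basal)
    basal = [
        replace(p, restriction="shared" if s else "basal_only")
        for p, s in zip(peaks_basal, basal_shared)
    ]
    luminal = [
        replace(p, restriction="shared" if s else "luminal_only")
        for p, s in zip(peaks_luminal, luminal_shared)
    ]
    return basal, luminal


def assign_peaks_to_genes(
    peaks: Sequence[Peak],
    ann: AnnotationSet,
    upstream: int = 2500,
) -> dict[str | None, list[Peak]]:
    """Map gene_id -> peaks overlapping the gene window (body + upstream).

    The window is the gene body extended ``upstream`` bp 5' of the TSS,
    strand-aware. A peak may be assigned to several genes; peaks assigned
    to none are retained under the key ``None``.
    """
    windows: dict[str, list[tuple[int, int, str]]] = {}
    for g in ann.genes:
        w = g.window_with_upstream(upstream)
        windows.setdefault(w.chrom, []).append((w.start, w.end, g.gene_id))
    sorted_windows = {
        c: sorted(v) for c, v in windows.items()
    }
    assignments: dict[str | None, list[Peak]] = {g.gene_id: [] for g in ann.genes}
    assignments[None] = []
    for p in peaks:
        hits = []
        for ws, we, gid in sorted_windows.get(p.interval.chrom, ()):
            if ws < p.interval.end and p.interval.start < we:
                hits.append(gid)
        if hits:
            for gid in hits:
                assignments[gid].append(p)
        else:
            assignments[None].append(p)
    return assignments


def count_peaks_per_gene(
    assignments: dict[str | None, list[Peak]],
    restriction_filter: str = "all",
) -> list[GenePeakCounts]:
    """Per-gene basal/luminal peak counts under the chosen filter.

    ``restriction_filter`` is ``"all"`` or ``"restricted_only"`` (drops
    shared peaks from both counts).
    """
    if restriction_filter not in ("all", "restricted_only"):
        raise ValueError(f"unknown restriction_filter {restriction_filter!r}")
    out = []
    for gid, peaks in assignments.items():
        if gid is None:
            continue
        if restriction_filter == "restricted_only":
            peaks = [p for p in peaks if p.restriction != "shared"]
        nb = sum(1 for p in peaks if p.cell_type == "basal")
        nl = sum(1 for p in peaks if p.cell_type == "luminal")
        out.append(GenePeakCounts(gene_id=gid, n_peaks_basal=nb, n_peaks_luminal=nl))
    return out
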