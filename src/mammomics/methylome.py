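"""Differential methylation calling and feature enrichment.

A differentially methylated cytosine (DMC) is a CpG whose replicate-pooled
beta values differ between the two cell types by at least ``delta_min``
(default 0.15) with a Benjamini-Hochberg adjusted Fisher-exact p-value below
``q_max`` (default 0.01). Enrichment of DMCs in genomic features is measured
against permutations drawn uniformly without replacement from the background
CpG set, with a normal-approximation tail p-value computed in log space so
extreme enrichments never underflow to an exact zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome_io import AnnotationSet, CpGSite, GenomicInterval

logger = logging.getLogger(__name__)

GENIC_FEATURES = ("promoter", "exon", "intron", "intergenic")
CGI_FEATURES = ("cgi", "shore", "shelf", "open_sea")
ALL_FEATURES = GENIC_FEATURES + CGI_FEATURES

# smallest positive double; used when a log-space p underflows exp()
_MIN_P = 5e-324
# ln p floor reported for degenerate (zero-SD) permutation nulls
_DEGENERATE_LOG_P = math.log(_MIN_P)

Direction = Literal["hypo_in_basal", "hypo_in_luminal"]


@dataclass
class DMC:
    """A differentially methylated cytosine between two cell types."""

    site: CpGSite
    delta_beta: float  # beta(group 1) - beta(group 2), pooled counts
    p: float
    q: float
    direction: str

    def interval(self) -> GenomicInterval:
        return self.site.interval()


@dataclass
class FeatureEnrichment:
    """Observed vs. permuted DMC overlap with one genomic feature class."""

    feature: str
    observed: int
    expected_mean: float
    expected_sd: float
    fold_change: float  # signed: >= +1 enrichment, <= -1 depletion
    p: float
    log_p: float  # natural log; finite even when p underflows
    degenerate: bool = False


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """BH step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# DMC calling
# ---------------------------------------------------------------------------


def call_dmcs(
    sites: Sequence[CpGSite],
    group_labels: Sequence[str],
    delta_min: float = 0.15,
    q_max: float = 0.01,
    group_order: tuple[str, str] | None = None,
) -> list[DMC]:
    """Call DMCs from per-sample counts via pooled-count Fisher exact tests.

    ``group_labels`` gives the cell type of each sample column. Counts are
    pooled within each group; each site is tested with a two-sided Fisher
    exact test on the 2x2 (group x methylated/unmethylated) table, adjusted
    by BH over all testable sites. ``delta_beta`` is pooled beta of the
    first group minus the second (default order: ``("basal", "luminal")``
    when present, else sorted); the group with the lower beta is the
    hypomethylated one. Sites lacking coverage in a group are skipped.
    """
    labels = list(group_labels)
    groups = sorted(set(labels))
    if len(groups) != 2:
        raise ValueError(f"exactly two groups required, got {groups}")
    if group_order is None:
        group_order = ("basal", "luminal") if set(groups) == {"basal", "luminal"} else (groups[0], groups[1])
    g1, g2 = group_order
    if {g1, g2} != set(groups):
        raise ValueError(f"group_order {group_order} does not match labels {groups}")
    idx1 = np.array([i for i, l in enumerate(labels) if l == g1])
    idx2 = np.array([i for i, l in enumerate(labels) if l == g2])

    testable: list[tuple[CpGSite, float, float]] = []
    n_skipped = 0
    for site in sites:
        m1, u1 = int(site.meth[idx1].sum()), int(site.unmeth[idx1].sum())
        m2, u2 = int(site.meth[idx2].sum()), int(site.unmeth[idx2].sum())
        if m1 + u1 == 0 or m2 + u2 == 0:
            n_skipped += 1
            continue
        beta1, beta2 = m1 / (m1 + u1), m2 / (m2 + u2)
        _, p = stats.fisher_exact([[m1, u1], [m2, u2]], alternative="two-sided")
        testable.append((site, beta1 - beta2, p))
    if n_skipped:
        logger.info("call_dmcs: skipped %d sites with zero coverage in a group", n_skipped)
    if not testable:
        return []
    qvals = benjamini_hochberg([t[2] for t in testable])
    out: list[DMC] = []
    for (site, delta, p), q in zip(testable, qvals):
        if abs(delta) >= delta_min and q < q_max:
            direction = f"hypo_in_{g1}" if delta < 0 else f"hypo_in_{g2}"
            out.append(DMC(site=site, delta_beta=delta, p=p, q=float(q), direction=direction))
    return out


def select_top_variance(
    beta_matrix: np.ndarray, fraction: float = 0.15
) -> np.ndarray:
    """Indices of the ceil(fraction * n) rows with largest sample variance.

    Ties are broken by original row order (earlier rows win).
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    beta = np.asarray(beta_matrix, dtype=float)
    if beta.ndim != 2 or beta.shape[1] < 2:
        raise ValueError("beta_matrix must be 2-D with >= 2 samples")
    if np.isnan(beta).any():
        raise ValueError("beta_matrix must not contain missing values")
    k = math.ceil(fraction * beta.shape[0])
    var = beta.var(axis=1, ddof=1)
    order = np.argsort(-var, kind="stable")
    return np.sort(order[:k])


# ---------------------------------------------------------------------------
# feature annotation
# ---------------------------------------------------------------------------


class _FeatureIndex:
    """Per-chromosome sorted interval arrays for fast site classification."""

    def __init__(
        self,
        ann: AnnotationSet,
        promoter_upstream: int = 2500,
        shore_bp: int = 2000,
        shelf_bp: int = 2000,
    ) -> None:
        self.shore_bp = shore_bp
        self.shelf_bp = shelf_bp
        self.promoters: dict[str, np.ndarray] = {}
        self.exons: dict[str, np.ndarray] = {}
        self.bodies: dict[str, np.ndarray] = {}
        self.islands: dict[str, np.ndarray] = {}
        prom: dict[str, list] = {}
        exo: dict[str, list] = {}
        bod: dict[str, list] = {}
        for g in ann.genes:
            p = g.promoter(promoter_upstream)
            prom.setdefault(p.chrom, []).append((p.start, p.end))
            bod.setdefault(g.body.chrom, []).append((g.body.start, g.body.end))
            for e in g.exons:
                exo.setdefault(e.chrom, []).append((e.start, e.end))
        isl: dict[str, list] = {}
        for i in ann.cgi:
            isl.setdefault(i.chrom, []).append((i.start, i.end))
        for target, source in (
            (self.promoters, prom),
            (self.exons, exo),
            (self.bodies, bod),
            (self.islands, isl),
        ):
            for chrom, pairs in source.items():
                target[chrom] = np.array(sorted(pairs), dtype=np.int64).reshape(-1, 2)
        self.known_chroms = (
            set(self.promoters) | set(self.bodies) | set(self.islands)
        )

    @staticmethod
    def _covers(arr: np.ndarray | None, pos: int) -> bool:
        if arr is None or len(arr) == 0:
            return False
        # intervals may overlap, so check every interval starting at or
        # before pos; arrays are small per chromosome in practice, but use
        # bisect on starts and scan left while ends could still cover
        starts = arr[:, 0]
        i = int(np.searchsorted(starts, pos, side="right"))
        return bool((arr[:i, 1] > pos).any())

    @staticmethod
    def _edge_distance(arr: np.ndarray | None, pos: int) -> float:
        """Distance from pos to the nearest island edge (0 if inside)."""
        if arr is None or len(arr) == 0:
            return math.inf
        starts, ends = arr[:, 0], arr[:, 1]
        inside = (starts <= pos) & (ends > pos)
        if inside.any():
            return 0.0
        left_gap = np.where(ends <= pos, pos - ends + 1, np.inf)
        right_gap = np.where(starts > pos, starts - pos, np.inf)
        return float(min(left_gap.min(), right_gap.min()))

    def classify(self, chrom: str, pos: int) -> tuple[str, str]:
        if chrom not in self.known_chroms:
            return "intergenic", "open_sea"
        if self._covers(self.promoters.get(chrom), pos):
            genic = "promoter"
        elif self._covers(self.exons.get(chrom), pos):
            genic = "exon"
        elif self._covers(self.bodies.get(chrom), pos):
            genic = "intron"
        else:
            genic = "intergenic"
        d = self._edge_distance(self.islands.get(chrom), pos)
        if d == 0:
            cgi = "cgi"
        elif d <= self.shore_bp:
            cgi = "shore"
        elif d <= self.shore_bp + self.shelf_bp:
            cgi = "shelf"
        else:
            cgi = "open_sea"
        return genic, cgi


def annotate_site_features(
    positions: Sequence[tuple[str, int]],
    ann: AnnotationSet,
    promoter_upstream: int = 2500,
    shore_bp: int = 2000,
    shelf_bp: int = 2000,
) -> list[tuple[str, str]]:
    """Classify positions into (genic_feature, cgi_context) labels.

    Genic precedence: promoter > exon > intron > intergenic, with the
    promoter a strand-aware window of ``promoter_upstream`` bp ending at the
    TSS. CGI context: island > shore (<= 2 kb from an island edge) > shelf
    (2-4 kb) > open sea. Positions on chromosomes absent from the annotation
    fall back to intergenic / open_sea (counted in a warning).
    """
    index = _FeatureIndex(ann, promoter_upstream, shore_bp, shelf_bp)
    labels = []
    n_unknown = 0
    for chrom, pos in positions:
        if chrom not in index.known_chroms:
            n_unknown += 1
        labels.append(index.classify(chrom, pos))
    if n_unknown:
        logger.warning(
            "annotate_site_features: %d positions on chromosomes absent from annotation",
            n_unknown,
        )
    return labels


# ---------------------------------------------------------------------------
# permutation enrichment
# ---------------------------------------------------------------------------


def permutation_feature_enrichment(
    dmc_positions: Sequence[tuple[str, int]],
    background_positions: Sequence[tuple[str, int]],
    ann: AnnotationSet,
    n_perm: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    promoter_upstream: int = 2500,
) -> list[FeatureEnrichment]:
    """Likelihood-of-methylation enrichment of DMCs in each feature class.

    Observed overlap counts are compared with ``n_perm`` permutations, each
    drawing ``len(dmc_positions)`` sites uniformly without replacement from
    the background. The p-value is the normal tail at the observed count
    given the permutation mean/SD (upper tail when observed > mean, lower
    otherwise), evaluated in natural-log space. The fold change is
    observed / mean(expected); ratios below 1 are reported as the negative
    reciprocal, so positive values mean enrichment and negative depletion.
    """
    n_dmc = len(dmc_positions)
    n_bg = len(background_positions)
    if n_dmc > n_bg:
        raise ValueError("more DMCs than background sites")
    if n_perm < 2:
        raise ValueError("n_perm must be >= 2")
    bg_set = set(background_positions)
    if not all(p in bg_set for p in dmc_positions):
        raise ValueError("DMC positions must be a subset of the background")
    if rng is None:
        rng = np.random.default_rng(seed)

    labels = annotate_site_features(
        background_positions, ann, promoter_upstream=promoter_upstream
    )
    feat_code = {f: i for i, f in enumerate(ALL_FEATURES)}
    # each site carries one genic and one cgi label; count both
    genic = np.array([feat_code[g] for g, _ in labels])
    cgi = np.array([feat_code[c] for _, c in labels])
    pos_index = {p: i for i, p in enumerate(background_positions)}
    dmc_idx = np.array([pos_index[p] for p in dmc_positions])

    n_feat = len(ALL_FEATURES)
    observed = np.bincount(genic[dmc_idx], minlength=n_feat) + np.bincount(
        cgi[dmc_idx], minlength=n_feat
    )
    perm_counts = np.empty((n_perm, n_feat), dtype=np.int64)
    for k in range(n_perm):
        draw = rng.choice(n_bg, size=n_dmc, replace=False)
        perm_counts[k] = np.bincount(genic[draw], minlength=n_feat) + np.bincount(
            cgi[draw], minlength=n_feat
        )
    means = perm_counts.mean(axis=0)
    sds = perm_counts.std(axis=0, ddof=1)

    out = []
    for f in ALL_FEATURES:
        i = feat_code[f]
        out.append(
            _summarize_enrichment(f, int(observed[i]), float(means[i]), float(sds[i]))
        )
    return out


def _summarize_enrichment(
    feature: str, observed: int, mean: float, sd: float
) -> FeatureEnrichment:
    degenerate = False
    if sd == 0:
        if observed == mean:
            log_p, p = 0.0, 1.0
        else:
            log_p, p = _DEGENERATE_LOG_P, _MIN_P
            degenerate = True
    else:
        z = (observed - mean) / sd
        log_p = float(stats.norm.logsf(z) if observed > mean else stats.norm.logcdf(z))
        p = max(math.exp(log_p), _MIN_P)
    if mean == 0:
        fold = math.inf if observed > 0 else 1.0
        degenerate = True
    else:
        ratio = observed / mean
        if ratio == 0:
            fold = -math.inf
            degenerate = True
        elif ratio < 1:
            fold = -1.0 / ratio
        else:
            fold = ratio
    return FeatureEnrichment(
        feature=feature,
        observed=observed,
        expected_mean=mean,
        expected_sd=sd,
        fold_change=fold,
        p=p,
        log_p=log_p,
        degenerate=degenerate,
    )
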