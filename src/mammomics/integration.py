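"""Per-gene relationship states across chromatin, methylation, RNA and protein.

Each gene in the universe (genes observed in all four data layers) gets a
ternary label per layer — up in basal, up in luminal, or neutral — forming
one of 81 possible relationship states with the all-neutral state as the
reference. Associations between layers are fitted as two-category
multinomial logits (each "up" direction vs. neutral) on a binary predictor;
with a single binary predictor the maximum-likelihood log-odds equals the
2x2 contingency closed form, with the Haldane-Anscombe +0.5 correction when
a cell is empty.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd
from scipy import stats


class LayerState(str, Enum):
    UP_BASAL = "up_basal"
    UP_LUMINAL = "up_luminal"
    NEUTRAL = "neutral"


class RelationshipState(NamedTuple):
    chromatin: LayerState
    methylation: LayerState
    rna: LayerState
    protein: LayerState


ALL_NEUTRAL = RelationshipState(
    LayerState.NEUTRAL, LayerState.NEUTRAL, LayerState.NEUTRAL, LayerState.NEUTRAL
)

LAYERS = ("chromatin", "methylation", "rna", "protein")


@dataclass
class AssociationResult:
    predictor_layer: str
    outcome_layer: str
    outcome_category: LayerState
    log_odds: float
    se: float
    p: float
    corrected: bool = False  # Haldane-Anscombe applied
    degenerate: bool = False  # constant predictor


def _ternary_from_counts(a: float, b: float) -> LayerState:
    """UP_BASAL iff a > b strictly, UP_LUMINAL iff b > a, else neutral."""
    if a > b:
        return LayerState.UP_BASAL
    if b > a:
        return LayerState.UP_LUMINAL
    return LayerState.NEUTRAL


def _ternary_from_ratio(a: float, b: float, fold_min: float) -> LayerState:
    """UP_X iff the linear-scale ratio exceeds fold_min strictly."""
    if b > 0 and a / b > fold_min:
        return LayerState.UP_BASAL
    if a > 0 and b / a > fold_min:
        return LayerState.UP_LUMINAL
    if a == 0 and b > 0:
        return LayerState.UP_LUMINAL
    if b == 0 and a > 0:
        return LayerState.UP_BASAL
    return LayerState.NEUTRAL


def assign_layer_states(
    gene_universe: Iterable[str],
    peak_counts: Mapping[str, tuple[int, int]],
    dmc_counts: Mapping[str, tuple[int, int]],
    rna: Mapping[str, tuple[float, float]],
    protein: Mapping[str, tuple[float, float]],
    fold_min: float = 2.0,
) -> tuple[dict[str, RelationshipState], int]:
    """Assign each gene its 4-layer relationship state.

    Per-gene inputs are (basal, luminal) pairs: ATAC peak counts, counts of
    DMCs hypomethylated in each cell type, and linear-scale RNA / protein
    abundances. Chromatin and methylation are "up" in the cell type with
    the strictly greater count (methylation "up" = more hypomethylation,
    i.e. the more active configuration); RNA and protein are "up" when the
    abundance ratio strictly exceeds ``fold_min``. Genes missing from any
    layer are excluded; returns (states, n_excluded).
    """
    states: dict[str, RelationshipState] = {}
    n_excluded = 0
    for gid in gene_universe:
        if not all(gid in m for m in (peak_counts, dmc_counts, rna, protein)):
            n_excluded += 1
            continue
        states[gid] = RelationshipState(
            chromatin=_ternary_from_counts(*peak_counts[gid]),
            methylation=_ternary_from_counts(*dmc_counts[gid]),
            rna=_ternary_from_ratio(*rna[gid], fold_min),
            protein=_ternary_from_ratio(*protein[gid], fold_min),
        )
    return states, n_excluded


def enumerate_states(states: Mapping[str, RelationshipState]) -> pd.DataFrame:
    """Frequency table of observed relationship states, sorted descending."""
    counts = Counter(states.values())
    rows = [
        {
            "chromatin": s.chromatin.value,
            "methylation": s.methylation.value,
            "rna": s.rna.value,
            "protein": s.protein.value,
            "n_genes": n,
            "is_reference": s == ALL_NEUTRAL,
        }
        for s, n in counts.items()
    ]
    df = pd.DataFrame(rows).sort_values(
        ["n_genes", "chromatin", "methylation", "rna", "protein"],
        ascending=[False, True, True, True, True],
    )
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# layer association (multinomial logit vs. all-neutral reference)
# ---------------------------------------------------------------------------


def log_odds_2x2(
    n11: float, n10: float, n01: float, n00: float
) -> tuple[float, float, bool]:
    """Closed-form log odds ratio ln[(n11/n10)/(n01/n00)] with Wald SE.

    Applies the Haldane-Anscombe +0.5 to every cell when any is zero;
    returns (log_odds, se, corrected).
    """
    cells = [n11, n10, n01, n00]
    corrected = any(c == 0 for c in cells)
    if corrected:
        cells = [c + 0.5 for c in cells]
    a, b, c, d = cells
    lo = math.log((a / b) / (c / d))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return lo, se, corrected


def fit_layer_association(
    states: Mapping[str, RelationshipState],
    predictor_layer: str,
    outcome_layer: str,
) -> list[AssociationResult]:
    """Association of one layer with another, per direction, vs. neutral.

    For each direction d in {up_basal, up_luminal}: the predictor is the
    indicator [predictor layer == d]; genes whose outcome layer is d or
    neutral enter a 2-category multinomial logit (equivalently a binary
    logit of d vs. neutral). With one binary predictor the MLE equals the
    contingency closed form; p-values are two-sided Wald.
    """
    for layer in (predictor_layer, outcome_layer):
        if layer not in LAYERS:
            raise ValueError(f"unknown layer {layer!r}")
    results = []
    for d in (LayerState.UP_BASAL, LayerState.UP_LUMINAL):
        n = {(1, 1): 0, (1, 0): 0, (0, 1): 0, (0, 0): 0}
        for s in states.values():
            out = getattr(s, outcome_layer)
            if out not in (d, LayerState.NEUTRAL):
                continue
            x = int(getattr(s, predictor_layer) == d)
            y = int(out == d)
            n[(x, y)] += 1
        if n[(1, 1)] + n[(0, 1)] == 0:
            continue  # outcome category empty: omitted
        if n[(1, 1)] + n[(1, 0)] == 0 or n[(0, 1)] + n[(0, 0)] == 0:
            results.append(
                AssociationResult(
                    predictor_layer,
                    outcome_layer,
                    d,
                    math.nan,
                    math.inf,
                    1.0,
                    degenerate=True,
                )
            )
            continue
        lo, se, corrected = log_odds_2x2(
            n[(1, 1)], n[(1, 0)], n[(0, 1)], n[(0, 0)]
        )
        z = lo / se
        p = float(2 * stats.norm.sf(abs(z)))
        results.append(
            AssociationResult(
                predictor_layer,
                outcome_layer,
                d,
                lo,
                se,
                max(p, 5e-324),
                corrected=corrected,
            )
        )
    return results


def fit_all_associations(
    states: Mapping[str, RelationshipState]
) -> list[AssociationResult]:
    """Pairwise associations for every ordered layer pair."""
    out = []
    for pred in LAYERS:
        for outc in LAYERS:
            if pred != outc:
                out.extend(fit_layer_association(states, pred, outc))
    return out


# ---------------------------------------------------------------------------
# concordance and marker reports
# ---------------------------------------------------------------------------


def percent_round(numerator: int, denominator: int) -> float | None:
    """Percentage rounded half away from zero to an integer; None if 0/0."""
    if denominator == 0:
        return None
    frac = 100.0 * numerator / denominator
    return math.floor(frac + 0.5) if frac >= 0 else -math.floor(-frac + 0.5)


def concordance_table(
    up_genes: Mapping[tuple[str, str], set[str]],
    associations: Mapping[str, Mapping[str, bool]],
    association_kinds: Mapping[str, tuple[str, str]] = {
        "restricted_peak": ("peak_basal", "peak_luminal"),
        "hypo_dmc": ("hypo_basal", "hypo_luminal"),
    },
) -> pd.DataFrame:
    """Lineage concordance of up-regulated genes with genomic associations.

    ``up_genes`` maps (layer, direction) -> genes up-regulated in that cell
    type under the tabular criteria; ``associations`` maps gene ->
    {flag: bool} with flags named per ``association_kinds`` (matching
    lineage first for "basal", second for "luminal"). For each pair, the
    denominator is the up-genes carrying any association of that kind and
    the numerator those whose association matches the lineage; percentages
    are rounded half away from zero.
    """
    rows = []
    for (layer, direction), genes in sorted(up_genes.items()):
        for kind, (flag_b, flag_l) in association_kinds.items():
            match_flag = flag_b if direction == "basal" else flag_l
            with_any = [
                g
                for g in genes
                if g in associations
                and (associations[g].get(flag_b) or associations[g].get(flag_l))
            ]
            matching = [g for g in with_any if associations[g].get(match_flag)]
            num, den = len(matching), len(with_any)
            rows.append(
                {
                    "layer": layer,
                    "direction": direction,
                    "association": kind,
                    "n_matching": num,
                    "n_with_association": den,
                    "percent": percent_round(num, den),
                }
            )
    return pd.DataFrame(rows)


def marker_signature_report(
    marker_genes: Sequence[str],
    states: Mapping[str, RelationshipState],
    z_rna: Mapping[str, Sequence[float]],
    z_protein: Mapping[str, Sequence[float]],
    hypomethylated: Mapping[str, bool],
    peak_counts: Mapping[str, tuple[int, int]],
) -> dict:
    """Marker-panel report: z-scores, methylation, peak balance, concordance.

    Per marker: RNA/protein z-score vectors, hypomethylation flag, the
    basal:luminal peak proportion, and whether the lineage with more peaks
    matches the lineage with higher RNA (chromatin-expression concordance).
    Summary fractions cover chromatin concordance, unmethylated markers
    (no hypomethylated DMC in either lineage), and RNA-protein agreement.
    """
    rows = []
    n_chrom_concordant = 0
    n_unmethylated = 0
    n_rna_protein_concordant = 0
    n_present = 0
    for gid in marker_genes:
        if gid not in states:
            rows.append({"gene_id": gid, "present": False})
            continue
        n_present += 1
        s = states[gid]
        nb, nl = peak_counts.get(gid, (0, 0))
        total = nb + nl
        prop_basal = nb / total if total else math.nan
        chrom_dir = _ternary_from_counts(nb, nl)
        concordant = (
            chrom_dir != LayerState.NEUTRAL
            and s.rna != LayerState.NEUTRAL
            and chrom_dir == s.rna
        )
        unmeth = not hypomethylated.get(gid, False)
        rna_prot = (
            s.rna == s.protein
            if (s.rna != LayerState.NEUTRAL or s.protein != LayerState.NEUTRAL)
            else True
        )
        n_chrom_concordant += concordant
        n_unmethylated += unmeth
        n_rna_protein_concordant += rna_prot
        rows.append(
            {
                "gene_id": gid,
                "present": True,
                "z_rna": list(map(float, z_rna.get(gid, []))),
                "z_protein": list(map(float, z_protein.get(gid, []))),
                "hypomethylated": not unmeth,
                "peak_proportion_basal": prop_basal,
                "chromatin_concordant": concordant,
                "rna_protein_concordant": rna_prot,
            }
        )
    return {
        "markers": rows,
        "n_markers": len(marker_genes),
        "n_present": n_present,
        "chromatin_concordant": (
            n_chrom_concordant,
            n_present,
            percent_round(n_chrom_concordant, n_present),
        ),
        "unmethylated": (
            n_unmethylated,
            n_present,
            percent_round(n_unmethylated, n_present),
        ),
        "rna_protein_concordant": (
            n_rna_protein_concordant,
            n_present,
            percent_round(n_rna_protein_concordant, n_present),
        ),
    }
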