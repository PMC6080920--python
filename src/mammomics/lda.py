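"""Single-hit limiting-dilution analysis of stem-cell frequency.

Under the single-hit Poisson model, a transplant of d cells from a
population with repopulating-unit frequency f produces an outgrowth with
probability 1 - exp(-f d). The frequency is estimated by maximizing the
binomial log-likelihood over ln f; 95% confidence intervals come from the
profile likelihood (chi-square(1) cutoff 3.841), and two experiments are
compared with a likelihood-ratio test against the pooled fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

CHI2_95 = 3.841458820694124  # chi-square(1) 95th percentile
_THETA_LO, _THETA_HI = math.log(1e-12), math.log(0.999999)


@dataclass(frozen=True)
class LDAExperiment:
    """Limiting-dilution doses: (cells injected, n injected, n positive)."""

    doses: tuple[tuple[int, int, int], ...]
    group_label: str = ""

    def __post_init__(self) -> None:
        if not self.doses:
            raise ValueError("at least one dose required")
        for d, n, k in self.doses:
            if d <= 0 or n <= 0:
                raise ValueError(f"dose and n must be positive, got ({d}, {n})")
            if not 0 <= k <= n:
                raise ValueError(f"n_positive {k} outside [0, {n}]")

    @property
    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        a = np.array(self.doses, dtype=float)
        return a[:, 0], a[:, 1], a[:, 2]


@dataclass
class LDAFit:
    frequency: float  # repopulating units per cell
    ci_low: float
    ci_high: float
    loglik: float
    all_positive: bool = False
    all_negative: bool = False
    experiment: LDAExperiment | None = field(default=None, repr=False)

    @property
    def one_in(self) -> float:
        """Frequency expressed as '1 in N' cells."""
        return 1.0 / self.frequency if self.frequency > 0 else math.inf


def _loglik(theta: float, d: np.ndarray, n: np.ndarray, k: np.ndarray) -> float:
    """Binomial log-likelihood at theta = ln f (additive constants dropped)."""
    lam = np.exp(theta) * d
    # P(positive) = 1 - exp(-lam); log1p(-exp(-lam)) is stable for small lam
    with np.errstate(divide="ignore"):
        log_p = np.log1p(-np.exp(-lam))
    log_q = -lam
    ll = k * log_p + (n - k) * log_q
    return float(ll.sum())


def fit_single_hit(exp: LDAExperiment) -> LDAFit:
    """MLE of the repopulating-unit frequency with profile-likelihood CI.

    Degenerate data (every transplant positive, or every one negative)
    yields a one-sided interval and a flag; the point estimate is then the
    corresponding profile bound.
    """
    d, n, k = exp.arrays
    total_pos, total_neg = k.sum(), (n - k).sum()
    all_positive = total_neg == 0
    all_negative = total_pos == 0

    if all_negative:
        # likelihood maximized as f -> 0; report upper 95% bound
        ll_max = 0.0
        upper = _profile_root(d, n, k, ll_max, side="upper", start=_THETA_LO)
        return LDAFit(0.0, 0.0, math.exp(upper), ll_max, all_negative=True, experiment=exp)
    if all_positive:
        ll_max = 0.0  # likelihood -> 0 = log(1) as f -> inf (capped at 1/cell)
        lower = _profile_root(d, n, k, ll_max, side="lower", start=_THETA_HI)
        return LDAFit(
            math.exp(_THETA_HI), math.exp(lower), 1.0, ll_max, all_positive=True, experiment=exp
        )

    res = optimize.minimize_scalar(
        lambda t: -_loglik(t, d, n, k),
        bounds=(_THETA_LO, _THETA_HI),
        method="bounded",
        options={"xatol": 1e-12},
    )
    theta_hat = float(res.x)
    ll_max = -float(res.fun)
    lower = _profile_root(d, n, k, ll_max, side="lower", start=theta_hat)
    upper = _profile_root(d, n, k, ll_max, side="upper", start=theta_hat)
    return LDAFit(
        frequency=math.exp(theta_hat),
        ci_low=math.exp(lower),
        ci_high=math.exp(upper),
        loglik=ll_max,
        experiment=exp,
    )


def _profile_root(
    d: np.ndarray,
    n: np.ndarray,
    k: np.ndarray,
    ll_max: float,
    side: str,
    start: float,
) -> float:
    """Theta where the log-likelihood drops CHI2_95/2 below its maximum."""
    target = ll_max - CHI2_95 / 2

    def g(t: float) -> float:
        return _loglik(t, d, n, k) - target

    if side == "lower":
        lo, hi = _THETA_LO, start
        if g(lo) > 0:
            return lo
        return float(optimize.brentq(g, lo, hi, xtol=1e-10))
    lo, hi = start, _THETA_HI
    if g(hi) > 0:
        return hi
    return float(optimize.brentq(g, lo, hi, xtol=1e-10))


def compare_groups(a: LDAExperiment, b: LDAExperiment) -> dict:
    """Likelihood-ratio test of equal frequencies between two experiments.

    Returns ``{"p": .., "lr_stat": .., "fit_a": .., "fit_b": .., "fit_pooled": ..}``.
    """
    fit_a = fit_single_hit(a)
    fit_b = fit_single_hit(b)
    pooled = LDAExperiment(doses=a.doses + b.doses, group_label="pooled")
    fit_p = fit_single_hit(pooled)
    lr = 2 * (fit_a.loglik + fit_b.loglik - fit_p.loglik)
    lr = max(lr, 0.0)
    p = float(stats.chi2.sf(lr, df=1))
    return {
        "p": p,
        "lr_stat": float(lr),
        "fit_a": fit_a,
        "fit_b": fit_b,
        "fit_pooled": fit_p,
    }


def read_lda_table(path) -> dict[str, LDAExperiment]:
    """Read a TSV with columns group, dose, n_injected, n_positive."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    required = {"group", "dose", "n_injected", "n_positive"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: missing columns {required - set(df.columns)}")
    out = {}
    for g, sub in df.groupby("group"):
        doses = tuple(
            (int(r.dose), int(r.n_injected), int(r.n_positive))
            for r in sub.itertuples(index=False)
        )
        out[str(g)] = LDAExperiment(doses=doses, group_label=str(g))
    return out


def simulate_lda(
    frequency: float,
    doses: Sequence[tuple[int, int]],
    rng: np.random.Generator,
    group_label: str = "sim",
) -> LDAExperiment:
    """Draw Bernoulli(1 - exp(-f d)) outcomes for each (dose, n) schedule."""
    rows = []
    for d, n in doses:
        p = 1 - math.exp(-frequency * d)
        rows.append((d, n, int(rng.binomial(n, p))))
    return LDAExperiment(doses=tuple(rows), group_label=group_label)
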